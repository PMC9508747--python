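"""Tau-PET positivity scoring.

The tau tracer shows off-target binding, so raw SUVRs mix a background
("off-target") distribution with an elevated on-target distribution in
regions that carry fibrillar tau.  Pooling a cohort's baseline SUVRs per
ROI therefore yields an (approximately) bimodal distribution.  We fit a
two-component univariate Gaussian mixture per ROI, take the posterior
probability that a subject's value belongs to the higher-mean
(on-target) component as the *tau-positivity probability*, and multiply
it by the original SUVR to obtain the positivity-weighted *tau-PET
score*.  Follow-up scans are scored with baseline-fitted parameters so
longitudinal change in scores is not confounded by refitting.

Also provided: amyloid-positivity classification from tracer-specific
global-SUVR cut-offs, and tau-negativity screening from the temporal
meta-ROI (cut-off < 1.29).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .datatypes import (
    AMYLOID_TRACERS,
    META_ROI_REGIONS,
    GmmFitSet,
    SuvrTable,
    TauScoreTable,
)
from .exceptions import (
    IncompleteMetaRoiError,
    InvalidFitError,
    MissingFitError,
    SampleSizeError,
    TracerMismatchError,
)

#: Tracer-specific global amyloid-SUVR positivity cut-offs (strict >).
AMYLOID_CUTOFFS = {
    "florbetapir": 1.11,
    "florbetaben": 1.08,
    "flutemetamol": 0.575,
}

#: Temporal meta-ROI tau-negativity cut-off (strict <) on the unweighted
#: mean of the six constituent regions.
TAU_META_ROI_CUTOFF = 1.29

MIN_SUBJECTS_FOR_GMM = 20

# EM settings for the per-ROI mixtures.
_GMM_KW = dict(
    n_components=2,
    covariance_type="full",
    tol=1e-6,
    max_iter=500,
    n_init=5,
    init_params="kmeans",
    reg_covar=1e-10,
)


def _fit_one_roi(x: np.ndarray, seed: int) -> dict:
    """Fit one ROI's 1-D mixture; relabel so mean_on >= mean_off."""
    n = x.size
    if np.ptp(x) == 0.0:
        # All values identical: EM is meaningless; report a degenerate
        # point mass split evenly between the two components.
        v = float(x[0])
        return dict(
            mean_off=v, sd_off=1e-6, weight_off=0.5,
            mean_on=v, sd_on=1e-6, weight_on=0.5,
            converged=False, degenerate=True, n_fit=n,
        )
    gm = GaussianMixture(random_state=seed, **_GMM_KW)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)  # off = lower mean, on = higher mean
    off, on = order[0], order[1]
    sep = abs(means[on] - means[off])
    degenerate = bool(
        sep < 0.5 * max(sds[on], sds[off]) or weights.min() < 0.01
    )
    return dict(
        mean_off=float(means[off]), sd_off=float(sds[off]),
        weight_off=float(weights[off]),
        mean_on=float(means[on]), sd_on=float(sds[on]),
        weight_on=float(weights[on]),
        converged=bool(gm.converged_), degenerate=degenerate, n_fit=n,
    )


def fit_tau_gmm(baseline: SuvrTable, seed: int = 0) -> GmmFitSet:
    """Fit per-ROI two-component Gaussian mixtures on pooled baseline SUVRs.

    The mixture is fit across participants (all groups pooled) for each
    ROI separately: EM with k-means initialization, tolerance 1e-6, at
    most 500 iterations, 5 restarts keeping the best likelihood.
    Components are relabeled so the on-target component has the larger
    mean.  A fit is flagged degenerate when the means are closer than
    half the larger sigma or either weight falls below 0.01.
    """
    n_subj = len(baseline.subjects)
    if n_subj < MIN_SUBJECTS_FOR_GMM:
        raise SampleSizeError(
            f"GMM fitting needs >= {MIN_SUBJECTS_FOR_GMM} subjects, got {n_subj}"
        )
    rows = {}
    for roi in baseline.values.columns:
        x = baseline.values[roi].to_numpy(dtype=float)
        rows[int(roi)] = _fit_one_roi(x, seed)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "roi_id"
    return GmmFitSet(table=table, seed=seed)


def tau_positivity_probability(fit: Mapping, suvr: np.ndarray | float):
    """Posterior probability that SUVR(s) belong to the on-target component.

    ``fit`` is one row of a :class:`GmmFitSet` table (mapping-like with
    the six parameter fields plus ``degenerate``).  Degenerate fits
    return 0.5 everywhere - an explicit "uninformative" fallback, never
    a silent exclusion.
    """
    if fit["sd_off"] <= 0 or fit["sd_on"] <= 0:
        raise InvalidFitError("component sigma must be positive")
    x = np.asarray(suvr, dtype=float)
    if bool(fit.get("degenerate", False)):
        return np.full_like(x, 0.5) if x.ndim else 0.5
    # log-space Bayes for numerical stability far in the tails
    log_on = np.log(fit["weight_on"]) + norm.logpdf(x, fit["mean_on"], fit["sd_on"])
    log_off = np.log(fit["weight_off"]) + norm.logpdf(x, fit["mean_off"], fit["sd_off"])
    m = np.maximum(log_on, log_off)
    p = np.exp(log_on - m) / (np.exp(log_on - m) + np.exp(log_off - m))
    return float(p) if p.ndim == 0 else p


def compute_tau_scores(suvr: SuvrTable, fits: GmmFitSet) -> TauScoreTable:
    """Positivity probabilities and weighted scores for a SUVR table.

    ``fits`` must have been fit on the baseline table of the same
    cohort; follow-up rows are scored with those baseline parameters.
    """
    missing = set(int(c) for c in suvr.values.columns) - set(
        int(i) for i in fits.roi_ids
    )
    if missing:
        raise MissingFitError(f"no mixture fit for ROI(s) {sorted(missing)}")
    prob = pd.DataFrame(
        index=suvr.values.index, columns=suvr.values.columns, dtype=float
    )
    for roi in suvr.values.columns:
        row = fits.table.loc[int(roi)]
        prob[roi] = tau_positivity_probability(row, suvr.values[roi].to_numpy())
    score = prob * suvr.values
    return TauScoreTable(probability=prob, score=score, timepoint=suvr.timepoint)


def classify_amyloid_status(global_suvr: float, tracer: str) -> str:
    """'positive' iff the global SUVR strictly exceeds the tracer cut-off."""
    if tracer not in AMYLOID_TRACERS:
        raise TracerMismatchError(
            f"{tracer!r} is not an amyloid tracer (expected one of "
            f"{sorted(AMYLOID_TRACERS)})"
        )
    return "positive" if global_suvr > AMYLOID_CUTOFFS[tracer] else "negative"


def is_tau_negative(roi_suvrs: Mapping[str, float]) -> bool:
    """Tau negativity from the temporal meta-ROI.

    The unweighted mean SUVR over amygdala, entorhinal, fusiform,
    parahippocampal, inferior temporal, and middle temporal must be
    strictly below 1.29.
    """
    missing = [r for r in META_ROI_REGIONS if r not in roi_suvrs]
    if missing:
        raise IncompleteMetaRoiError(f"meta-ROI regions missing: {missing}")
    mean = float(np.mean([float(roi_suvrs[r]) for r in META_ROI_REGIONS]))
    return mean < TAU_META_ROI_CUTOFF
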