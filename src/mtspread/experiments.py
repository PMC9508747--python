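"""Seeded recovery experiments on synthetic studies.

Each function plants known structure with the generators in
:mod:`mtspread.synthetic`, runs the corresponding analysis path, and
returns what was recovered.  They serve as the package's built-in
checks that the pipeline can read back the parameters the generator
wrote - mixture means, the spatial MWF-tau rank correlation, the
edge-wise interaction coefficient, test calibration under the null,
and bootstrap CI coverage.

All experiments are pure functions of their seed; per-repetition seeds
are derived with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import rankdata

from .datatypes import ABPOS_GROUPS, EdgeMatrix, SuvrTable
from .stats import edge_interaction_model, spatial_correlation, stratified_bootstrap_rho
from .synthetic import (
    SynthesisConfig,
    build_target_change_correlation,
    generate_connectome,
    synthesize_study,
)
from .tau_change import annual_change, change_covariance
from .tau_scoring import compute_tau_scores, fit_tau_gmm

#: Study conditions at the parcellation's native scale: 200 ROIs and a
#: 100-subject amyloid-positive cohort; fiber MWF from the parametric
#: edge generator (the streamline image path is exercised at desk scale).
SPATIAL_RECOVERY_CONFIG = SynthesisConfig(
    n_rois=200,
    grid_shape=(40, 40, 40),
    n_per_group={"CN_Abpos": 40, "MCI_Abpos": 30, "AD_dementia": 30},
    use_streamline_mwf=False,
)

#: Conditions for interaction recovery: 60 ROIs, 150 longitudinal
#: amyloid-positive subjects, planted (a, b, c) = (0.1, 0.5, -0.4).
INTERACTION_RECOVERY_CONFIG = SynthesisConfig(
    n_rois=60,
    grid_shape=(28, 28, 28),
    n_per_group={"CN_Abpos": 60, "MCI_Abpos": 45, "AD_dementia": 45},
    use_streamline_mwf=False,
)


def _seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# --------------------------------------------------------------------------
# mixture recovery
# --------------------------------------------------------------------------

def gmm_recovery(
    seed: int,
    n_subjects: int = 400,
    n_rois: int = 6,
    pi_on: float = 0.3,
    off=(1.15, 0.10),
    on=(1.80, 0.30),
) -> dict:
    """Fit mixtures on data drawn from known components.

    Returns the mean absolute error of the fitted component means
    (averaged over ROIs) and the accuracy of posterior >= 0.5
    classification against the drawn component labels.
    """
    rng = np.random.default_rng(seed)
    labels = rng.random((n_subjects, n_rois)) < pi_on
    vals = np.where(
        labels,
        rng.normal(on[0], on[1], (n_subjects, n_rois)),
        rng.normal(off[0], off[1], (n_subjects, n_rois)),
    )
    vals = np.clip(vals, 0.05, None)
    frame = pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(n_subjects)],
        columns=np.arange(1, n_rois + 1),
    )
    table = SuvrTable(frame, "baseline", "flortaucipir", "inferior_cerebellar_gm")
    fits = fit_tau_gmm(table, seed=seed)
    scores = compute_tau_scores(table, fits)
    pred = scores.probability.to_numpy() >= 0.5
    return {
        "mean_off_error": float(np.abs(fits.table["mean_off"] - off[0]).mean()),
        "mean_on_error": float(np.abs(fits.table["mean_on"] - on[0]).mean()),
        "max_mean_error": float(
            max(
                np.abs(fits.table["mean_off"] - off[0]).max(),
                np.abs(fits.table["mean_on"] - on[0]).max(),
            )
        ),
        "accuracy": float((pred == labels).mean()),
        "n": n_subjects,
    }


# --------------------------------------------------------------------------
# spatial recovery
# --------------------------------------------------------------------------

def _score_pipeline(study, seed: int):
    fits = fit_tau_gmm(study.baseline, seed=seed)
    baseline_scores = compute_tau_scores(study.baseline, fits)
    followup_scores = compute_tau_scores(study.followup, fits)
    return baseline_scores, followup_scores


def spatial_recovery(seed: int, n_seeds: int = 20) -> list[dict]:
    """Estimate the planted MWF-tau rank correlation over seeded studies.

    The generator plants a Spearman of -0.30 between cortical MWF and the
    amyloid-positive group's on-target probabilities; each repetition
    synthesizes a study, scores it, and re-estimates the spatial
    correlation from group-average tau scores.
    """
    out = []
    for s in _seeds(seed, n_seeds):
        study = synthesize_study(SPATIAL_RECOVERY_CONFIG, seed=s)
        baseline_scores, _ = _score_pipeline(study, s)
        mean_tau = baseline_scores.score.mean(axis=0).to_numpy()
        rho, p = spatial_correlation(study.cortical_mwf, mean_tau)
        out.append({"rho": rho, "p": p})
    return out


# --------------------------------------------------------------------------
# interaction recovery
# --------------------------------------------------------------------------

def _target_as_edge_matrix(study) -> EdgeMatrix:
    z = np.arctanh(np.clip(study.truth.target_change_correlation, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return EdgeMatrix(z, study.fc.roi_ids, "fisher_z_spearman_cov")


def interaction_recovery(
    seed: int, n_seeds: int = 20, use_scores: bool = True
) -> list[dict]:
    """Recover the planted FC x fiber-MWF interaction per seeded study.

    For each study the full longitudinal path runs (scoring, annualized
    change, Spearman covariance-in-change, edge model); the reference
    effect is the same model fit with the noiseless planted correlation
    matrix (Fisher-z) as outcome.
    """
    out = []
    for s in _seeds(seed, n_seeds):
        study = synthesize_study(INTERACTION_RECOVERY_CONFIG, seed=s)
        if use_scores:
            bl, fu = _score_pipeline(study, s)
        else:
            bl, fu = study.baseline, study.followup
        changes = annual_change(bl, fu, study.intervals)
        cov = change_covariance(changes)
        fit = edge_interaction_model(
            cov, study.fc, study.fiber_mwf, mask=study.structural_counts
        )
        ref = edge_interaction_model(
            _target_as_edge_matrix(study), study.fc, study.fiber_mwf,
            mask=study.structural_counts,
        )
        out.append({
            "beta_interaction": float(fit.coefficients["beta_interaction"]),
            "p_interaction": float(fit.p_values["beta_interaction"]),
            "beta_reference": float(ref.coefficients["beta_interaction"]),
            "n_edges": fit.n_edges,
        })
    return out


# --------------------------------------------------------------------------
# null calibration
# --------------------------------------------------------------------------

def null_interaction_calibration(
    seed: int,
    n_replicates: int = 200,
    n_rois: int = 40,
    n_subjects: int = 150,
    alpha: float = 0.05,
) -> dict:
    """Type-I rate of the interaction test under independent edge noise.

    The outcome is the null target (b = c = 0, so a constant Fisher-z
    of a) plus iid symmetric edge noise at the scale of a Fisher-z
    Spearman correlation estimated from ``n_subjects`` participants
    (sd = sqrt(1.06 / (n - 3))).  Classical OLS inference is exact for
    independent noise, so the empirical rate should sit near alpha.
    """
    noise_sd = float(np.sqrt(1.06 / (n_subjects - 3)))
    hits = 0
    iu, ju = np.triu_indices(n_rois, k=1)
    for s in _seeds(seed, n_replicates):
        rng = np.random.default_rng(s)
        mwf = rng.uniform(0.05, 0.25, n_rois)
        fc, counts, fiber = generate_connectome(
            n_rois, 0.5, mwf, seed=int(rng.integers(2**31))
        )
        target, _ = build_target_change_correlation(fc, fiber, 0.1, 0.0, 0.0)
        z = np.arctanh(np.clip(target, -1 + 1e-7, 1 - 1e-7))
        noise = np.zeros((n_rois, n_rois))
        noise[iu, ju] = rng.normal(0.0, noise_sd, iu.size)
        noise += noise.T
        y = z + noise
        np.fill_diagonal(y, 0.0)
        outcome = EdgeMatrix(y, fc.roi_ids, "fisher_z_spearman_cov")
        fit = edge_interaction_model(outcome, fc, fiber, mask=counts)
        hits += fit.p_values["beta_interaction"] < alpha
    return {"type_i_rate": hits / n_replicates, "n": n_replicates}


# --------------------------------------------------------------------------
# bootstrap coverage
# --------------------------------------------------------------------------

def _planted_mean_vector(
    mwf: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    base: float = 0.4,
    spread: float = 0.9,
) -> np.ndarray:
    """ROI mean-tau vector whose Spearman with mwf equals rho exactly."""
    n = mwf.size
    u = rankdata(mwf)
    u_std = (u - u.mean()) / u.std()
    eps = rng.standard_normal(n)
    eps_std = (eps - eps.mean()) / eps.std()
    sign = -1.0 if rho < 0 else 1.0

    def realized(w: float) -> float:
        return float(np.corrcoef(u, rankdata(sign * w * u_std + (1 - w) * eps_std))[0, 1])

    if sign * realized(0.0) > abs(rho):
        eps_std = -eps_std
    w = brentq(lambda x: sign * realized(x) - abs(rho), 0.0, 1.0, xtol=1e-6)
    latent = sign * w * u_std + (1 - w) * eps_std
    return base + spread * (rankdata(latent) - 0.5) / n


def bootstrap_coverage(
    seed: int,
    n_sims: int = 50,
    n_rois: int = 200,
    n_per_stratum: int = 100,
    B: int = 500,
    rho: float = -0.30,
    subject_sd: float = 0.4,
) -> dict:
    """Coverage of the stratified percentile CI for a planted rank rho.

    Each simulation plants ``rho`` exactly between MWF and the ROI mean
    tau-score vector, adds iid subject noise (sd 0.4, the order of
    between-subject tau-score spread), splits 2 x ``n_per_stratum``
    subjects into two strata, bootstraps each, and checks whether each
    stratum's 95% CI contains the planted value.
    """
    n_subjects = 2 * n_per_stratum
    covered = 0
    total = 0
    max_width = 0.0
    for s in _seeds(seed, n_sims):
        rng = np.random.default_rng(s)
        mwf = rng.uniform(0.05, 0.25, n_rois)
        means = _planted_mean_vector(mwf, rho, rng)
        vals = means[None, :] + rng.normal(0.0, subject_sd, (n_subjects, n_rois))
        frame = pd.DataFrame(
            vals,
            index=[f"s{i}" for i in range(n_subjects)],
            columns=np.arange(1, n_rois + 1),
        )
        strata = {
            f"s{i}": ("carrier" if i < n_per_stratum else "noncarrier")
            for i in range(n_subjects)
        }
        boot = stratified_bootstrap_rho(frame, strata, mwf, B=B, seed=s)
        for stratum in boot.strata.values():
            total += 1
            covered += stratum.ci_low <= rho <= stratum.ci_high
            max_width = max(max_width, stratum.ci_high - stratum.ci_low)
    return {
        "coverage": covered / total,
        "max_ci_width": max_width,
        "n": n_sims,
    }


# --------------------------------------------------------------------------
# control-group null
# --------------------------------------------------------------------------

def control_group_null(seed: int, n_seeds: int = 20) -> list[dict]:
    """Spatial and interaction p-values on the amyloid-negative subset.

    Controls draw only off-target SUVRs and near-diagonal change
    correlations, so both analyses should be non-significant in most
    seeded studies.
    """
    out = []
    for s in _seeds(seed, n_seeds):
        study = synthesize_study(seed=s)  # desk-scale defaults
        baseline_scores, followup_scores = _score_pipeline(study, s)
        cohort = study.cohort.set_index("subject_id")
        ctrl = cohort.index[~cohort["group"].isin(ABPOS_GROUPS)]
        mean_tau = baseline_scores.score.loc[ctrl].mean(axis=0).to_numpy()
        _, p_spatial = spatial_correlation(study.cortical_mwf, mean_tau)
        changes = annual_change(baseline_scores, followup_scores, study.intervals)
        from .datatypes import ChangeTable

        ctrl_changes = ChangeTable(
            annual_change=changes.annual_change.loc[ctrl],
            intervals=changes.intervals.loc[ctrl],
            kind=changes.kind,
        )
        cov = change_covariance(ctrl_changes)
        fit = edge_interaction_model(
            cov, study.fc, study.fiber_mwf, mask=study.structural_counts
        )
        out.append({
            "p_spatial": float(p_spatial),
            "p_interaction": float(fit.p_values["beta_interaction"]),
            "beta_interaction": float(fit.coefficients["beta_interaction"]),
        })
    return out
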