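"""Spatial MWF-tau correlations and the edge-wise interaction model.

Two questions are answered here:

1. *Spatial*: across ROIs, is cortical myelin water fraction (MWF)
   rank-correlated with group-average tau burden?  Plain Spearman,
   partial Spearman (e.g. controlling regional amyloid), and an
   APOE-stratified bootstrap (percentile 95% CIs over subject resamples)
   are provided.

2. *Edge-wise*: does fiber-tract MWF modulate the association between
   functional connectivity and the covariance in tau change?  An OLS of
   the vectorized covariance-in-change matrix on standardized FC,
   standardized fiber MWF, and their product (the interaction of
   interest), optionally with a standardized control matrix (e.g.
   covariance in amyloid change).

Inference on the edge model is classical OLS despite edge
non-independence, matching the reference analysis; an optional
edge-label permutation p-value is available for users who want a
dependence-agnostic check.
"""

from __future__ import annotations

from itertools import permutations
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata, spearmanr, t as t_dist

from .datatypes import BootstrapResult, EdgeMatrix, ModelResult, StratumRho
from .exceptions import (
    CollinearityError,
    SampleSizeError,
    UndefinedCorrelationError,
    ValidationError,
)

_EXACT_PERM_MAX_N = 8  # 8! = 40320 enumerable permutations
_SAMPLED_PERMS = 100_000


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D vector")
    if np.ptp(v) == 0:
        raise UndefinedCorrelationError(f"{name} is constant")
    return v


def spatial_correlation(
    mwf: np.ndarray, tau: np.ndarray, seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation across ROIs, with a two-sided p.

    For N > 10 the usual t approximation is used; for N <= 10 a
    permutation p is computed (exhaustive up to N = 8, else 10^5
    sampled permutations seeded by ``seed``).
    """
    mwf = _check_vector(mwf, "mwf")
    tau = _check_vector(tau, "tau")
    n = mwf.size
    if n != tau.size:
        raise ValidationError("vectors must have equal length")
    if n < 5:
        raise SampleSizeError("spatial correlation needs >= 5 ROIs")
    rho, p_t = spearmanr(mwf, tau)
    rho = float(rho)
    if n > 10:
        return rho, float(p_t)
    # small-N: permutation p on |rho|
    r_m = rankdata(mwf)
    r_t = rankdata(tau)
    obs = abs(np.corrcoef(r_m, r_t)[0, 1])
    if n <= _EXACT_PERM_MAX_N:
        perms = np.array(list(permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(_SAMPLED_PERMS)])
    permuted = r_t[perms]  # (P, n)
    rm_c = r_m - r_m.mean()
    pt_c = permuted - permuted.mean(axis=1, keepdims=True)
    num = pt_c @ rm_c
    den = np.sqrt((pt_c**2).sum(axis=1) * (rm_c**2).sum())
    stats = np.abs(num / den)
    if n <= _EXACT_PERM_MAX_N:
        p = float(np.mean(stats >= obs - 1e-12))
    else:
        p = float((np.sum(stats >= obs - 1e-12) + 1) / (len(stats) + 1))
    return rho, p


def partial_spatial_correlation(
    mwf: np.ndarray, tau: np.ndarray, control: np.ndarray
) -> tuple[float, float]:
    """Partial Spearman of mwf and tau given one control vector.

    Both vectors are rank-transformed, the control's ranks are
    regressed out (with intercept), and the residuals are
    Pearson-correlated; p is two-sided t at N - 3 degrees of freedom.
    A constant control reduces to the plain Spearman correlation.
    """
    mwf = _check_vector(mwf, "mwf")
    tau = _check_vector(tau, "tau")
    control = np.asarray(control, dtype=float)
    n = mwf.size
    if tau.size != n or control.size != n:
        raise ValidationError("vectors must have equal length")
    if n < 5:
        raise SampleSizeError("partial spatial correlation needs >= 5 ROIs")
    r_m, r_t = rankdata(mwf), rankdata(tau)
    if np.ptp(control) == 0:
        design = np.ones((n, 1))
    else:
        r_c = rankdata(control)
        design = np.column_stack([np.ones(n), r_c])
    bm, *_ = np.linalg.lstsq(design, r_m, rcond=None)
    bt, *_ = np.linalg.lstsq(design, r_t, rcond=None)
    em = r_m - design @ bm
    et = r_t - design @ bt
    # a vector fully explained by the control leaves only rounding noise:
    # its partial correlation is 0 by definition
    scale_m = np.sqrt(((r_m - r_m.mean()) ** 2).sum())
    scale_t = np.sqrt(((r_t - r_t.mean()) ** 2).sum())
    if (
        np.sqrt((em**2).sum()) < 1e-8 * max(scale_m, 1.0)
        or np.sqrt((et**2).sum()) < 1e-8 * max(scale_t, 1.0)
    ):
        return 0.0, 1.0
    denom = np.sqrt((em**2).sum() * (et**2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float((em * et).sum() / denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, 0.0
    tval = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * t_dist.sf(abs(tval), df))
    return rho, p


def _group_mean_tau(values: pd.DataFrame, rows: np.ndarray) -> np.ndarray:
    return values.to_numpy(dtype=float)[rows].mean(axis=0)


def stratified_bootstrap_rho(
    scores,
    strata: Mapping[str, str] | pd.Series,
    mwf: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the spatial Spearman rho within subject strata.

    For each stratum (e.g. APOE e4 carriers vs non-carriers), subjects
    are resampled with replacement B times; each resample yields a
    group-average tau vector whose Spearman correlation with ``mwf`` is
    recorded.  The 95% CI is the 2.5/97.5 percentile (linear
    interpolation).  ``cis_overlap`` reports whether all strata's CIs
    pairwise overlap - the decision rule used to declare "no significant
    difference" between strata.

    The resampling stream is seeded identically in every stratum, so
    two strata holding identical data produce identical CIs.
    """
    if isinstance(scores, pd.DataFrame):
        values = scores
    else:
        values = getattr(scores, "values", None)
    if not isinstance(values, pd.DataFrame):
        raise ValidationError("scores must expose a subjects x ROIs DataFrame")
    mwf = _check_vector(mwf, "mwf")
    if mwf.size != values.shape[1]:
        raise ValidationError("mwf length must match the number of ROIs")
    strata = pd.Series(dict(strata)) if not isinstance(strata, pd.Series) else strata
    labels = sorted(strata.unique())
    rank_mwf = rankdata(mwf)
    out: dict[str, StratumRho] = {}
    for label in labels:
        subj = strata.index[strata == label]
        subj = values.index.intersection(subj)
        if len(subj) < 10:
            raise SampleSizeError(
                f"stratum {label!r} has {len(subj)} subjects (< 10)"
            )
        rows = values.index.get_indexer(subj)
        arr = values.to_numpy(dtype=float)[rows]
        point = _spearman_against_ranks(rank_mwf, arr.mean(axis=0))
        rng = np.random.default_rng(seed)
        n_s = len(subj)
        rhos = np.empty(B)
        for b in range(B):
            pick = rng.integers(0, n_s, size=n_s)
            rhos[b] = _spearman_against_ranks(rank_mwf, arr[pick].mean(axis=0))
        lo, hi = np.percentile(rhos, [2.5, 97.5])
        out[str(label)] = StratumRho(rho_hat=point, ci_low=float(lo), ci_high=float(hi))
    overlap: bool | None = None
    if len(labels) > 1:
        overlap = True
        items = list(out.values())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a.ci_high < b.ci_low or b.ci_high < a.ci_low:
                    overlap = False
    return BootstrapResult(strata=out, n_iterations=B, seed=seed, cis_overlap=overlap)


def _spearman_against_ranks(rank_x: np.ndarray, y: np.ndarray) -> float:
    ry = rankdata(y)
    rx = rank_x
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return np.nan
    return float((rxc * ryc).sum() / denom)


def vectorize_edges(
    m: EdgeMatrix, mask: EdgeMatrix | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Upper-triangle (i < j) edge values, optionally mask-restricted.

    With a streamline-count mask only pairs with count > 0 are kept;
    missing values are always dropped.  Returns the values and the
    parallel (i, j) index arrays (0-based positions).
    """
    n = m.n
    iu, ju = np.triu_indices(n, k=1)
    keep = ~m.missing_mask[iu, ju]
    if mask is not None:
        if mask.n != n:
            raise ValidationError("mask shape mismatch")
        mv = mask.values[iu, ju]
        keep &= ~np.isnan(mv) & (mv > 0)
    if not keep.any():
        raise ValidationError("edge selection is empty")
    return m.values[iu[keep], ju[keep]], (iu[keep], ju[keep])


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise CollinearityError(f"{name} has zero variance on the edge set")
    return (v - v.mean()) / sd


def edge_interaction_model(
    cov: EdgeMatrix,
    fc: EdgeMatrix,
    fiber_mwf: EdgeMatrix,
    mask: EdgeMatrix | None = None,
    control_cov: EdgeMatrix | None = None,
    n_permutations: int = 0,
    seed: int = 0,
) -> ModelResult:
    """OLS of covariance-in-change on FC, fiber MWF, and their product.

    All matrices are vectorized on the common edge set (upper triangle,
    restricted to the structural mask when given, dropping edges missing
    in any input).  Outcome, FC, and MWF are z-standardized; the
    interaction term is the product of the standardized main effects
    (not re-standardized).  Reports standardized coefficients with
    classical SEs and two-sided t p-values.
    """
    n = cov.n
    if fc.n != n or fiber_mwf.n != n or (control_cov is not None and control_cov.n != n):
        raise ValidationError("matrices must be conformable")
    iu, ju = np.triu_indices(n, k=1)
    keep = (
        ~cov.missing_mask[iu, ju]
        & ~fc.missing_mask[iu, ju]
        & ~fiber_mwf.missing_mask[iu, ju]
    )
    if control_cov is not None:
        keep &= ~control_cov.missing_mask[iu, ju]
    if mask is not None:
        if mask.n != n:
            raise ValidationError("mask shape mismatch")
        mv = mask.values[iu, ju]
        keep &= ~np.isnan(mv) & (mv > 0)
    n_edges = int(keep.sum())
    if n_edges < 30:
        raise SampleSizeError(f"only {n_edges} usable edges (< 30)")
    y = _standardize(cov.values[iu[keep], ju[keep]], "outcome")
    x_fc = _standardize(fc.values[iu[keep], ju[keep]], "functional connectivity")
    x_mwf = _standardize(fiber_mwf.values[iu[keep], ju[keep]], "fiber MWF")
    cols = {"intercept": np.ones(n_edges), "beta_fc": x_fc, "beta_mwf": x_mwf,
            "beta_interaction": x_fc * x_mwf}
    if cols["beta_interaction"].std(ddof=1) == 0:
        raise CollinearityError("interaction column has zero variance")
    if control_cov is not None:
        cols["beta_control"] = _standardize(
            control_cov.values[iu[keep], ju[keep]], "control"
        )
    X = np.column_stack(list(cols.values()))
    if np.linalg.cond(X) > 1e8:
        raise CollinearityError("design condition number exceeds 1e8")
    fit = sm.OLS(y, X).fit()
    names = list(cols.keys())
    result = ModelResult(
        coefficients=pd.Series(fit.params, index=names),
        standard_errors=pd.Series(fit.bse, index=names),
        t_statistics=pd.Series(fit.tvalues, index=names),
        p_values=pd.Series(fit.pvalues, index=names),
        n_edges=n_edges,
        r_squared=float(fit.rsquared),
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        k = names.index("beta_interaction")
        obs = abs(fit.params[k])
        count = 0
        for _ in range(n_permutations):
            yp = y[rng.permutation(n_edges)]
            bp = np.linalg.lstsq(X, yp, rcond=None)[0][k]
            if abs(bp) >= obs - 1e-15:
                count += 1
        result.permutation_p = (count + 1) / (n_permutations + 1)
    return result
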