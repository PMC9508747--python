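"""Annualized tau change and covariance-in-change matrices.

The edge-level statistic of the spreading analysis: for each ROI pair,
the Spearman correlation across participants of annualized per-ROI
change ("covariance in tau change"), Fisher-z transformed, with
autocorrelations set to zero.  A covariate-adjusted variant uses partial
Spearman correlation (Pearson on rank residuals) controlling for, e.g.,
age, sex, education, APOE e4 status, diagnosis, and site.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .connectome import fisher_z
from .datatypes import ChangeTable, EdgeMatrix, SuvrTable, TauScoreTable, validate_covariates
from .exceptions import (
    CollinearityError,
    KindMismatchError,
    SampleSizeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MIN_SUBJECTS_FOR_COV = 10


def _values_and_kind(table) -> tuple[pd.DataFrame, str]:
    if isinstance(table, SuvrTable):
        return table.values, "suvr"
    if isinstance(table, TauScoreTable):
        return table.score, "score"
    raise ValidationError(f"unsupported table type {type(table).__name__}")


def annual_change(baseline, followup, intervals: pd.Series) -> ChangeTable:
    """(followup - baseline) / interval per subject and ROI.

    ``baseline`` and ``followup`` must be the same kind of table (both
    SUVR tables or both score tables).  Subjects missing either
    timepoint or an interval are dropped (logged); intervals must be
    positive years.
    """
    bl, kind_bl = _values_and_kind(baseline)
    fu, kind_fu = _values_and_kind(followup)
    if kind_bl != kind_fu:
        raise KindMismatchError(
            f"cannot mix {kind_bl} baseline with {kind_fu} followup"
        )
    if not bl.columns.equals(fu.columns):
        raise ValidationError("baseline/followup ROI sets differ")
    intervals = pd.Series(intervals, dtype=float)
    common = bl.index.intersection(fu.index).intersection(intervals.index)
    dropped = len(set(bl.index) | set(fu.index)) - len(common)
    if dropped:
        logger.info("annual_change: dropped %d subject(s) missing a timepoint", dropped)
    if len(common) == 0:
        raise ValidationError("no subject has both timepoints")
    ivals = intervals.loc[common]
    if not (ivals > 0).all():
        bad = ivals.index[ivals <= 0].tolist()
        raise ValidationError(f"non-positive follow-up interval for {bad}")
    delta = (fu.loc[common] - bl.loc[common]).div(ivals, axis=0)
    return ChangeTable(annual_change=delta, intervals=ivals, kind=kind_bl)


def _complete_change_matrix(changes: ChangeTable) -> tuple[np.ndarray, np.ndarray]:
    """Listwise-complete subjects x ROIs change array.

    Subjects missing any ROI are dropped for the whole matrix so every
    edge is estimated on the same n.
    """
    df = changes.annual_change
    complete = df.dropna(axis=0)
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("change_covariance: dropped %d incomplete subject(s)", dropped)
    if len(complete) < MIN_SUBJECTS_FOR_COV:
        raise SampleSizeError(
            f"need >= {MIN_SUBJECTS_FOR_COV} complete subjects, got {len(complete)}"
        )
    return complete.to_numpy(dtype=float), np.asarray(df.columns, dtype=int)


def _cov_from_columns(x: np.ndarray, roi_ids: np.ndarray) -> EdgeMatrix:
    """Pearson-correlate columns, clip, Fisher-z, zero the diagonal.

    Columns with zero variance get missing (NaN) edges plus a warning.
    """
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant change for ROI(s) {roi_ids[constant].tolist()}; "
            "their edges are set to missing",
            stacklevel=3,
        )
    xs = x.copy()
    xs[:, constant] = np.nan  # propagate NaN into their correlations
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        xc = xs - np.nanmean(xs, axis=0)
        denom = np.sqrt(np.nansum(xc**2, axis=0))
        denom[constant] = np.nan
        r = (xc.T @ xc) / np.outer(denom, denom)
    r = np.clip(r, -1.0, 1.0)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = np.where(np.isnan(z) & ~np.isnan(z.T), z.T, z)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return EdgeMatrix(z, roi_ids, "fisher_z_spearman_cov")


def change_covariance(changes: ChangeTable) -> EdgeMatrix:
    """Fisher-z Spearman correlation of annual change between ROI pairs.

    Ranks use average ranks for ties.  Correlations are clipped to
    |rho| <= 1 - 1e-7 before atanh; autocorrelations (the diagonal) are
    set to zero.
    """
    x, roi_ids = _complete_change_matrix(changes)
    ranks = rankdata(x, axis=0, method="average")
    return _cov_from_columns(ranks, roi_ids)


def build_control_design(
    covariates: pd.DataFrame,
    controls: Sequence[str],
    subjects: pd.Index,
    rank_numeric: bool = True,
) -> np.ndarray:
    """Control design matrix (with intercept) aligned to ``subjects``.

    Numeric controls are rank-transformed by default (the conventional
    all-ranks Spearman partial correlation); categorical controls are
    expanded to indicator columns with the first (reference) level
    dropped.  Raises on rank deficiency, naming the collinear columns.
    """
    covariates = validate_covariates(covariates)
    cov = covariates.set_index("subject_id").loc[subjects]
    missing = [c for c in controls if c not in cov.columns]
    if missing:
        raise ValidationError(f"controls not in covariate table: {missing}")
    blocks = [pd.Series(1.0, index=cov.index, name="intercept")]
    for name in controls:
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            vals = col.astype(float)
            if rank_numeric and vals.nunique() > 1:
                vals = pd.Series(
                    rankdata(vals.to_numpy()), index=vals.index, name=name
                )
            blocks.append(vals)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                blocks.append(dummies[c])
    design = pd.concat(blocks, axis=1)
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        kept: list[int] = []
        for k in range(x.shape[1]):
            trial = x[:, kept + [k]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(k)
            else:
                collinear.append(design.columns[k])
        raise CollinearityError(f"collinear control columns: {collinear}")
    return x


def partial_change_covariance(
    changes: ChangeTable,
    covariates: pd.DataFrame,
    controls: Sequence[str],
) -> EdgeMatrix:
    """Covariate-adjusted covariance in change (partial Spearman).

    Per pair: rank-transform both change vectors, regress each on the
    control design (with intercept), and Pearson-correlate the
    residuals; then clip, Fisher-z, and zero the diagonal as in
    :func:`change_covariance`.
    """
    df = changes.annual_change.dropna(axis=0)
    if len(df) < MIN_SUBJECTS_FOR_COV:
        raise SampleSizeError(
            f"need >= {MIN_SUBJECTS_FOR_COV} complete subjects, got {len(df)}"
        )
    design = build_control_design(covariates, controls, df.index)
    ranks = rankdata(df.to_numpy(dtype=float), axis=0, method="average")
    beta, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    resid = ranks - design @ beta
    roi_ids = np.asarray(df.columns, dtype=int)
    # An ROI fully explained by the controls leaves a residual of pure
    # floating-point noise; its partial correlations are 0 by definition,
    # so force them rather than correlating rounding errors.
    rank_sd = ranks.std(axis=0)
    explained = (rank_sd > 0) & (resid.std(axis=0) < 1e-10 * np.maximum(rank_sd, 1.0))
    m = _cov_from_columns(resid, roi_ids)
    if explained.any():
        v = m.values
        v[explained, :] = 0.0
        v[:, explained] = 0.0
        m = EdgeMatrix(v, roi_ids, "fisher_z_spearman_cov")
    return m
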