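"""Myelin and connectivity inputs.

Builds the ROI-level inputs the spreading analysis consumes:

* parcel-mean myelin water fraction (MWF) under an optional gray-matter
  probability mask,
* mean MWF sampled along tractography streamlines per ROI pair,
* Fisher-z Pearson functional-connectivity matrices from ROI time
  series, and group averages of such matrices.

Symmetry of all outputs is by construction (each unordered pair is
computed once and mirrored), never by averaging an asymmetric result.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .datatypes import EdgeMatrix, RoiAtlas
from .exceptions import (
    GeometryError,
    GridError,
    SemanticsError,
    UndefinedCorrelationError,
    ValidationError,
)

#: Correlations are clipped to this magnitude before atanh so perfect
#: correlations stay finite (z(1 - 1e-7) ~ 8.4).
FISHER_CLIP = 1.0 - 1e-7

#: Arc-length step (in voxels) at which streamlines are resampled.
STREAMLINE_STEP = 0.5

#: Default gray-matter probability threshold for masking parcels.
GM_THRESHOLD = 0.3


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with the package-wide clip policy applied first."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def parcel_means(
    value_volume: np.ndarray,
    atlas: RoiAtlas,
    gm_probability: np.ndarray | None = None,
    threshold: float = GM_THRESHOLD,
) -> np.ndarray:
    """Mean of ``value_volume`` over each parcel, GM-masked if requested.

    Voxels with ``gm_probability < threshold`` are excluded (mirroring
    subject-space parcellations binarized at a 0.3 gray-matter
    probability).  A parcel with no surviving voxels yields NaN and a
    warning rather than an error, so a single thin ROI does not abort a
    whole-atlas extraction.
    """
    value_volume = np.asarray(value_volume, dtype=float)
    if value_volume.shape != atlas.shape:
        raise GridError(
            f"value volume shape {value_volume.shape} != atlas {atlas.shape}"
        )
    labels = atlas.label_volume
    keep = labels > 0
    if gm_probability is not None:
        gm_probability = np.asarray(gm_probability, dtype=float)
        if gm_probability.shape != atlas.shape:
            raise GridError("gray-matter probability volume shape mismatch")
        keep &= gm_probability >= threshold
    lab = labels[keep]
    val = value_volume[keep]
    n = atlas.n_rois
    counts = np.bincount(lab, minlength=n + 1)[1:]
    sums = np.bincount(lab, weights=val, minlength=n + 1)[1:]
    out = np.full(n, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if (~nz).any():
        empty = atlas.roi_ids[~nz].tolist()
        warnings.warn(f"parcels with no surviving voxels: {empty}", stacklevel=2)
    return out


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at fixed arc-length steps (endpoint included)."""
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    total = float(seglen.sum())
    if total <= 0:
        raise GeometryError("zero-length streamline")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.arange(0.0, total, step)
    if total - s[-1] > 1e-9:
        s = np.concatenate([s, [total]])
    # piecewise-linear interpolation along arc length
    out = np.empty((s.size, 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, points[:, d])
    return out


def sample_streamline_mean(
    streamline: np.ndarray | Sequence[Sequence[float]],
    value_volume: np.ndarray,
    step: float = STREAMLINE_STEP,
) -> float:
    """Mean volume value along a streamline.

    The polyline is resampled at a fixed arc-length step (0.5 voxel by
    default) and each sample reads the nearest voxel; out-of-bounds
    samples are clamped to the nearest in-bounds voxel.
    """
    pts = np.asarray(streamline, dtype=float)
    value_volume = np.asarray(value_volume, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise GeometryError("a streamline needs >= 2 points in 3-D")
    samples = _resample_polyline(pts, step)
    idx = np.rint(samples).astype(int)
    for d, size in enumerate(value_volume.shape):
        np.clip(idx[:, d], 0, size - 1, out=idx[:, d])
    vals = value_volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(vals.mean())


def edge_fiber_mwf(
    streamlines: Mapping[tuple[int, int], Sequence[np.ndarray]],
    mwf_volume: np.ndarray,
    roi_ids: Sequence[int] | np.ndarray,
) -> EdgeMatrix:
    """Per-edge mean MWF along the streamlines connecting two parcels.

    Each edge value is the mean over that edge's streamlines of the
    per-streamline mean MWF.  Edges with no streamlines are missing.
    """
    roi_ids = np.asarray(roi_ids, dtype=int)
    n = roi_ids.size
    pos = {int(r): k for k, r in enumerate(roi_ids)}
    values = np.full((n, n), np.nan)
    any_edge = False
    for (i, j), streams in streamlines.items():
        if not streams:
            continue
        any_edge = True
        m = float(np.mean([sample_streamline_mean(s, mwf_volume) for s in streams]))
        a, b = pos[int(i)], pos[int(j)]
        values[a, b] = values[b, a] = m
    if not any_edge:
        raise ValidationError("no edge has any streamline")
    return EdgeMatrix(values, roi_ids, "fiber_mwf")


def fc_from_timeseries(
    timeseries: np.ndarray,
    roi_ids: Sequence[int] | np.ndarray | None = None,
) -> EdgeMatrix:
    """Fisher-z Pearson correlations between all ROI pairs.

    ``timeseries`` is T x N (timepoints by ROIs).  Correlations are
    clipped to 1 - 1e-7 in magnitude before atanh; the diagonal is 0.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValidationError("time series must be a T x N matrix")
    t, n = ts.shape
    if t < 10:
        raise ValidationError(f"need >= 10 timepoints, got {t}")
    sd = ts.std(axis=0)
    if (sd == 0).any():
        which = np.flatnonzero(sd == 0)
        ids = (
            np.asarray(roi_ids)[which].tolist()
            if roi_ids is not None
            else which.tolist()
        )
        raise UndefinedCorrelationError(f"constant time series for ROI(s) {ids}")
    r = np.corrcoef(ts.T)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # numerically exact symmetry; corrcoef is symmetric
    if roi_ids is None:
        roi_ids = np.arange(1, n + 1)
    return EdgeMatrix(z, np.asarray(roi_ids, dtype=int), "fisher_z_fc")


def group_average(matrices: Sequence[EdgeMatrix]) -> EdgeMatrix:
    """Missing-aware elementwise mean of same-semantics edge matrices."""
    if not matrices:
        raise ValidationError("group_average of an empty list")
    sem = matrices[0].semantics
    n = matrices[0].n
    ids = matrices[0].roi_ids
    for m in matrices[1:]:
        if m.semantics != sem:
            raise SemanticsError(
                f"cannot average {sem!r} with {m.semantics!r} matrices"
            )
        if m.n != n or not np.array_equal(m.roi_ids, ids):
            raise ValidationError("matrices must share shape and ROI ids")
    stack = np.stack([m.values for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        out = np.nanmean(stack, axis=0)
    if sem.startswith("fisher_z"):
        np.fill_diagonal(out, 0.0)
    return EdgeMatrix(out, ids.copy(), sem)
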