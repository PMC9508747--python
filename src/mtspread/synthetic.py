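"""Synthetic study generator with known ground truth.

Everything the pipeline consumes can be synthesized here from a seed:

* a toy cortical parcellation (Voronoi parcels on an ellipsoidal shell),
* a myelin water fraction (MWF) volume plus its per-ROI cortical means,
* a functional connectome (Fisher-z), a structural streamline-count
  matrix, and a fiber-tract MWF matrix coupled to endpoint cortical MWF,
* straight jittered streamlines between connected parcels (to exercise
  the image-space sampling code),
* a four-group cohort (CN Ab-/Tau-, CN Ab+, MCI Ab+, AD dementia) with
  covariates,
* baseline tau-PET SUVRs drawn per ROI from a two-component off-/on-
  target mixture, with on-target probability anti-coupled to cortical
  MWF (the planted spatial effect), and
* longitudinal change whose inter-regional correlation follows a planted
  connectivity x fiber-MWF interaction (the planted spreading effect).

All generators are pure functions of (config, seed): reruns are
bit-identical.  The recorded :class:`SyntheticTruth` lets recovery tests
compare pipeline estimates against the planted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm, rankdata, truncnorm

from .connectome import edge_fiber_mwf, fisher_z
from .datatypes import (
    ABPOS_GROUPS,
    GROUPS,
    META_ROI_REGIONS,
    EdgeMatrix,
    RoiAtlas,
    SuvrTable,
    SyntheticTruth,
    validate_covariates,
)
from .exceptions import (
    DegenerateGraphError,
    SizingError,
    ValidationError,
)

_NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")


# --------------------------------------------------------------------------
# atlas and volumes
# --------------------------------------------------------------------------

def generate_atlas(
    n_rois: int, grid_shape: tuple[int, int, int], seed: int
) -> RoiAtlas:
    """Toy cortical parcellation: Voronoi parcels on an ellipsoidal shell.

    Centers are placed by farthest-point sampling (deterministic given
    the seed), which keeps parcel sizes balanced.  The first six ROIs
    are named after the temporal meta-ROI regions so tau-negativity
    screening can run on synthetic data; the rest get generic names.
    """
    if n_rois < 2:
        raise ValidationError("need at least 2 ROIs")
    grid_shape = tuple(int(s) for s in grid_shape)
    if int(np.prod(grid_shape)) < 10 * n_rois:
        raise SizingError(
            f"grid {grid_shape} too small for {n_rois} ROIs (need >= 10 voxels each)"
        )
    rng = np.random.default_rng(seed)
    coords = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    half = (np.array(grid_shape) - 1) / 2.0
    rad = np.sqrt((((coords - half) / np.maximum(half, 1e-9)) ** 2).sum(axis=1))
    shell = (rad >= 0.35) & (rad <= 1.05)
    shell_coords = coords[shell]
    if shell_coords.shape[0] < 10 * n_rois:
        raise SizingError(
            f"cortex shell has {shell_coords.shape[0]} voxels; "
            f"cannot tile {n_rois} ROIs of >= 10 voxels"
        )
    # farthest-point sampling of parcel centers
    centers = np.empty((n_rois, 3))
    first = rng.integers(shell_coords.shape[0])
    centers[0] = shell_coords[first]
    d = np.linalg.norm(shell_coords - centers[0], axis=1)
    for k in range(1, n_rois):
        idx = int(np.argmax(d))
        centers[k] = shell_coords[idx]
        d = np.minimum(d, np.linalg.norm(shell_coords - centers[k], axis=1))
    # Voronoi assignment of shell voxels to centers
    d2 = ((shell_coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    label_flat = np.zeros(coords.shape[0], dtype=np.int32)
    label_flat[shell] = np.argmin(d2, axis=1) + 1
    label_volume = label_flat.reshape(grid_shape)
    names = [
        META_ROI_REGIONS[k] if k < len(META_ROI_REGIONS) and n_rois >= 6
        else f"roi_{k + 1:03d}"
        for k in range(n_rois)
    ]
    networks = {k + 1: _NETWORKS[k % len(_NETWORKS)] for k in range(n_rois)}
    return RoiAtlas(
        label_volume=label_volume,
        roi_ids=np.arange(1, n_rois + 1),
        roi_names=names,
        network_assignment=networks,
    )


def generate_mwf(
    atlas: RoiAtlas,
    mwf_range: tuple[float, float] = (0.05, 0.25),
    seed: int = 0,
    noise_sd: float = 0.01,
    noise_smoothing: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """MWF volume with per-ROI means drawn uniformly in ``mwf_range``.

    Smooth voxel noise (Gaussian-filtered white noise of sd ``noise_sd``)
    is added on top of the parcel means.  The returned ``cortical_mwf``
    is recomputed as the parcel means of the final volume, so the pair
    is self-consistent by construction.
    """
    low, high = mwf_range
    if not (0 <= low < high <= 1):
        raise ValidationError("mwf_range must satisfy 0 <= low < high <= 1")
    rng = np.random.default_rng(seed)
    roi_means = rng.uniform(low, high, size=atlas.n_rois)
    volume = np.zeros(atlas.shape, dtype=float)
    lookup = np.concatenate([[0.0], roi_means])
    volume = lookup[atlas.label_volume]
    if noise_sd > 0:
        noise = rng.standard_normal(atlas.shape)
        if noise_smoothing > 0:
            noise = ndimage.gaussian_filter(noise, noise_smoothing)
            noise /= max(noise.std(), 1e-12)
        volume = volume + noise_sd * noise
    volume = np.clip(volume, 0.0, 1.0)
    volume[atlas.label_volume == 0] = 0.0
    from .connectome import parcel_means  # local import avoids cycle at load

    cortical_mwf = parcel_means(volume, atlas)
    return volume, cortical_mwf


# --------------------------------------------------------------------------
# connectome
# --------------------------------------------------------------------------

def generate_connectome(
    n_rois: int,
    edge_density: float,
    cortical_mwf: np.ndarray,
    mwf_coupling: float = 0.7,
    seed: int = 0,
) -> tuple[EdgeMatrix, EdgeMatrix, EdgeMatrix]:
    """Functional, structural, and fiber-MWF matrices.

    * ``fc``: Fisher-z correlations from a latent-factor time-series
      model (gives a realistic, PSD-consistent correlation structure).
    * ``structural_counts``: ~``edge_density`` of unordered pairs carry
      a positive streamline count (1 + Poisson(9)).
    * ``fiber_mwf``: defined exactly where counts > 0; correlated with
      the mean endpoint cortical MWF at strength ``mwf_coupling``.
    """
    if not (0 < edge_density <= 1):
        raise ValidationError("edge_density must be in (0, 1]")
    if not (0 <= mwf_coupling <= 1):
        raise ValidationError("mwf_coupling must be in [0, 1]")
    cortical_mwf = np.asarray(cortical_mwf, dtype=float)
    if cortical_mwf.size != n_rois:
        raise ValidationError("cortical_mwf length must equal n_rois")
    rng = np.random.default_rng(seed)
    roi_ids = np.arange(1, n_rois + 1)
    iu, ju = np.triu_indices(n_rois, k=1)
    n_pairs = iu.size

    # functional connectivity from a factor-structured time series
    t_len, k = 150, min(6, n_rois - 1)
    loadings = rng.normal(0.0, 0.6, size=(n_rois, k))
    factors = rng.standard_normal((t_len, k))
    ts = factors @ loadings.T + rng.standard_normal((t_len, n_rois))
    r = np.corrcoef(ts.T)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    fc = EdgeMatrix(z, roi_ids, "fisher_z_fc")

    # structural counts
    present = rng.random(n_pairs) < edge_density
    if not present.any():
        raise DegenerateGraphError(
            f"edge density {edge_density} produced an empty structural graph"
        )
    counts_flat = np.where(present, 1 + rng.poisson(9.0, size=n_pairs), 0)
    counts = np.zeros((n_rois, n_rois))
    counts[iu, ju] = counts_flat
    counts += counts.T
    structural = EdgeMatrix(counts, roi_ids, "streamline_count")

    # fiber MWF: coupled to mean endpoint cortical MWF where connected
    endpoint_mean = (cortical_mwf[iu] + cortical_mwf[ju]) / 2.0
    em_sd = endpoint_mean[present].std()
    em_std = (
        (endpoint_mean - endpoint_mean[present].mean()) / em_sd
        if em_sd > 0
        else np.zeros_like(endpoint_mean)
    )
    latent = mwf_coupling * em_std + np.sqrt(
        max(0.0, 1.0 - mwf_coupling**2)
    ) * rng.standard_normal(n_pairs)
    fiber_flat = np.clip(0.20 + 0.05 * latent, 0.0, 1.0)
    fiber = np.full((n_rois, n_rois), np.nan)
    fiber[iu[present], ju[present]] = fiber_flat[present]
    fiber[ju[present], iu[present]] = fiber_flat[present]
    fiber_mwf = EdgeMatrix(fiber, roi_ids, "fiber_mwf")
    return fc, structural, fiber_mwf


def generate_streamlines(
    atlas: RoiAtlas,
    structural_counts: EdgeMatrix,
    n_points: int = 12,
    seed: int = 0,
    jitter_sd: float = 0.5,
) -> dict[tuple[int, int], list[np.ndarray]]:
    """Straight jittered polylines between connected parcels.

    For each unordered pair with count > 0, returns that many
    streamlines running from a random voxel of parcel i to a random
    voxel of parcel j, with jittered interior points clamped to the
    grid.  These are deliberately simple geometries - enough to exercise
    the arc-length resampling and nearest-voxel lookup.
    """
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    voxels = {int(r): atlas.parcel_voxels(int(r)).astype(float) for r in atlas.roi_ids}
    for r, v in voxels.items():
        if v.shape[0] == 0:
            raise ValidationError(f"parcel {r} is empty but has connections")
    shape = np.array(atlas.shape, dtype=float)
    out: dict[tuple[int, int], list[np.ndarray]] = {}
    n = structural_counts.n
    vals = structural_counts.values
    for a in range(n):
        for b in range(a + 1, n):
            c = vals[a, b]
            if np.isnan(c) or c <= 0:
                continue
            i, j = int(structural_counts.roi_ids[a]), int(structural_counts.roi_ids[b])
            streams = []
            for _ in range(int(c)):
                start = voxels[i][rng.integers(voxels[i].shape[0])]
                end = voxels[j][rng.integers(voxels[j].shape[0])]
                t = np.linspace(0.0, 1.0, n_points)
                pts = start[None, :] + t[:, None] * (end - start)[None, :]
                if n_points > 2:
                    pts[1:-1] += rng.normal(0.0, jitter_sd, size=(n_points - 2, 3))
                pts = np.clip(pts, 0.0, shape - 1.0)
                # consecutive points must be distinct for arc-length sampling
                same = np.all(np.isclose(np.diff(pts, axis=0), 0.0), axis=1)
                while same.any():
                    pts[1:][same] += rng.normal(0.0, 0.05, size=(int(same.sum()), 3))
                    pts = np.clip(pts, 0.0, shape - 1.0)
                    same = np.all(np.isclose(np.diff(pts, axis=0), 0.0), axis=1)
                streams.append(pts)
            out[(i, j)] = streams
    return out


# --------------------------------------------------------------------------
# cohort and PET tables
# --------------------------------------------------------------------------

#: Default APOE e4 carrier rates per group (carrier fractions in the
#: spirit of large AD-spectrum cohorts: rising with disease stage).
DEFAULT_APOE4_RATES = {
    "CN_Abneg_Tauneg": 0.27,
    "CN_Abpos": 0.53,
    "MCI_Abpos": 0.65,
    "AD_dementia": 0.64,
}

DEFAULT_AGE_MEANS = {
    "CN_Abneg_Tauneg": 71.0,
    "CN_Abpos": 74.6,
    "MCI_Abpos": 74.8,
    "AD_dementia": 76.2,
}

_DIAGNOSIS = {
    "CN_Abneg_Tauneg": "CN",
    "CN_Abpos": "CN",
    "MCI_Abpos": "MCI",
    "AD_dementia": "AD",
}


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n_per_group: Mapping[str, int],
    seed: int = 0,
    female_rate: float = 0.5,
    apoe4_rates: Mapping[str, float] | None = None,
    n_sites: int = 3,
) -> pd.DataFrame:
    """Covariate table with one row per subject.

    Age ~ Normal(group mean, 7) truncated to [55, 95]; education ~
    Normal(14, 3) truncated to [6, 22]; sex, APOE e4 carriership, and
    site are categorical with configurable rates.
    """
    bad = set(n_per_group) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group(s): {sorted(bad)}")
    total = sum(int(v) for v in n_per_group.values())
    if total < 2:
        raise ValidationError("cohort needs at least 2 subjects")
    apoe4_rates = dict(DEFAULT_APOE4_RATES, **(apoe4_rates or {}))
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for group in GROUPS:
        n = int(n_per_group.get(group, 0))
        if n == 0:
            continue
        age = _truncated_normal(rng, DEFAULT_AGE_MEANS[group], 7.0, 55.0, 95.0, n)
        edu = _truncated_normal(rng, 14.0, 3.0, 6.0, 22.0, n)
        sex = np.where(rng.random(n) < female_rate, "F", "M")
        apoe = np.where(
            rng.random(n) < apoe4_rates[group], "carrier", "noncarrier"
        )
        site = rng.integers(1, n_sites + 1, size=n)
        for k in range(n):
            counter += 1
            rows.append(
                dict(
                    subject_id=f"sub-{counter:04d}",
                    group=group,
                    age=float(age[k]),
                    sex=str(sex[k]),
                    education=float(edu[k]),
                    apoe4=str(apoe[k]),
                    diagnosis=_DIAGNOSIS[group],
                    site=f"site{int(site[k])}",
                )
            )
    return validate_covariates(pd.DataFrame(rows))


@dataclass(frozen=True)
class TauSuvrParams:
    """Mixture parameters for the baseline tau-PET SUVR generator."""

    off_mean: float = 1.15
    off_sd: float = 0.10
    on_mean: float = 1.80
    on_sd: float = 0.30
    #: Per-ROI on-target probability range for amyloid-positive subjects.
    p_range: tuple[float, float] = (0.10, 0.50)
    #: Target Spearman between cortical MWF and Ab+ group-mean burden.
    true_spatial_rho: float = -0.30

    def __post_init__(self):
        if self.on_mean <= self.off_mean:
            raise ValidationError("on-target mean must exceed off-target mean")
        if self.off_sd <= 0 or self.on_sd <= 0:
            raise ValidationError("mixture sigmas must be positive")


def _planted_probabilities(
    cortical_mwf: np.ndarray, params: TauSuvrParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-ROI on-target probabilities anti-coupled to MWF.

    The probability is a monotone-increasing function of a latent
    variable that blends (negated) MWF ranks with seeded noise; the
    blend weight is solved per realization (bisection) so the sample
    Spearman correlation between MWF and the probabilities equals
    ``true_spatial_rho`` to ~1e-4.  Planting the rank correlation
    exactly - rather than only in expectation - makes subject sampling
    the sole noise source between the planted value and pipeline
    estimates, which is what recovery and bootstrap-coverage checks
    assume.
    """
    from scipy.optimize import brentq

    n = cortical_mwf.size
    u = rankdata(cortical_mwf)
    u_std = (u - u.mean()) / u.std()
    eps = rng.standard_normal(n)
    eps_std = (eps - eps.mean()) / eps.std()
    rho_s = float(params.true_spatial_rho)
    sign = -1.0 if rho_s < 0 else 1.0

    def realized(w: float) -> float:
        latent = sign * w * u_std + (1.0 - w) * eps_std
        r = np.corrcoef(u, rankdata(latent))[0, 1]
        return float(r)

    target = abs(rho_s)
    if target < 1e-12:
        latent = eps_std
    else:
        if sign * realized(0.0) > target:
            eps_std = -eps_std  # noise already over-correlated; flip it
        f = lambda w: sign * realized(w) - target
        w_star = brentq(f, 0.0, 1.0, xtol=1e-6)
        latent = sign * w_star * u_std + (1.0 - w_star) * eps_std
    lo, hi = params.p_range
    return lo + (hi - lo) * (rankdata(latent) - 0.5) / n


def simulate_tau_suvr(
    cohort: pd.DataFrame,
    cortical_mwf: np.ndarray,
    params: TauSuvrParams | None = None,
    seed: int = 0,
) -> tuple[SuvrTable, SyntheticTruth]:
    """Baseline tau-PET SUVRs from the per-ROI two-component mixture.

    Amyloid-negative subjects draw only off-target values; amyloid-
    positive subjects draw the on-target component per ROI with the
    planted (MWF-anti-coupled) probability.  Component memberships are
    recorded as ground truth.
    """
    params = params or TauSuvrParams()
    cohort = validate_covariates(cohort)
    cortical_mwf = np.asarray(cortical_mwf, dtype=float)
    n_rois = cortical_mwf.size
    rng = np.random.default_rng(seed)
    p = _planted_probabilities(cortical_mwf, params, rng)
    subjects = cohort["subject_id"].to_numpy()
    abpos = cohort["group"].isin(ABPOS_GROUPS).to_numpy()
    n_subj = subjects.size
    labels = np.zeros((n_subj, n_rois), dtype=bool)
    labels[abpos] = rng.random((int(abpos.sum()), n_rois)) < p[None, :]
    off = rng.normal(params.off_mean, params.off_sd, size=(n_subj, n_rois))
    on = rng.normal(params.on_mean, params.on_sd, size=(n_subj, n_rois))
    values = np.where(labels, on, off)
    values = np.clip(values, 0.05, None)  # SUVRs are strictly positive
    roi_ids = np.arange(1, n_rois + 1)
    frame = pd.DataFrame(values, index=pd.Index(subjects, name="subject_id"),
                         columns=roi_ids)
    table = SuvrTable(
        values=frame,
        timepoint="baseline",
        tracer="flortaucipir",
        reference_region="inferior_cerebellar_gm",
    )
    truth = SyntheticTruth(
        positivity_labels=pd.DataFrame(labels, index=frame.index, columns=roi_ids),
        on_target_probability=p,
        true_spatial_rho=params.true_spatial_rho,
    )
    return table, truth


# --------------------------------------------------------------------------
# planted change correlation and longitudinal simulation
# --------------------------------------------------------------------------

def build_target_change_correlation(
    fc: EdgeMatrix,
    fiber_mwf: EdgeMatrix,
    a: float,
    b: float,
    c: float,
) -> tuple[np.ndarray, int]:
    """Planted N x N change-correlation matrix.

    Edge-wise raw values z_ij = a + b*FC_ij + c*FC_ij*MWF*_ij (MWF*
    standardized over defined edges; missing fiber MWF imputed with the
    matrix median for generation only) are mapped through inverse
    Fisher (tanh) to correlations, the diagonal set to one, and the
    matrix repaired to the nearest positive semi-definite correlation
    by eigenvalue clipping at 1e-6 plus diagonal renormalization.

    Returns the repaired matrix and the number of clipped (|r| pinned
    to 1 - 1e-7) off-diagonal entries pre-repair.
    """
    n = fc.n
    if fiber_mwf.n != n:
        raise ValidationError("fc and fiber_mwf must be conformable")
    iu, ju = np.triu_indices(n, k=1)
    f = fc.values[iu, ju]
    m = fiber_mwf.values[iu, ju].copy()
    defined = ~np.isnan(m)
    if defined.any():
        med = np.nanmedian(m)
        m[~defined] = med
        sd = m.std()
        m_std = (m - m.mean()) / sd if sd > 0 else np.zeros_like(m)
    else:
        m_std = np.zeros_like(m)
    z = a + b * f + c * f * m_std
    r = np.tanh(z)
    clip = 1.0 - 1e-7
    n_clipped = int(np.sum(np.abs(r) >= clip))
    r = np.clip(r, -clip, clip)
    corr = np.eye(n)
    corr[iu, ju] = r
    corr[ju, iu] = r
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 1e-6, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diagonal(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, n_clipped


#: Amyloid-negative controls draw change from a near-diagonal
#: correlation so control-group analyses are near-null by construction.
CONTROL_CORR_SHRINKAGE = 0.1


def simulate_longitudinal_change(
    cohort: pd.DataFrame,
    baseline: SuvrTable,
    target_corr: np.ndarray,
    change_mean: np.ndarray | float = 0.02,
    change_sd: np.ndarray | float = 0.05,
    interval_range: tuple[float, float] = (0.7, 4.0),
    seed: int = 0,
) -> tuple[SuvrTable, pd.Series]:
    """Follow-up SUVRs: baseline + annual change x interval.

    Amyloid-positive subjects draw their per-ROI annual-change vector
    from a multivariate normal with correlation ``target_corr`` (must be
    PSD - build it with :func:`build_target_change_correlation`),
    scaled by ``change_sd`` and shifted by ``change_mean``.  Controls
    draw from the shrunk correlation 0.1*target + 0.9*I.  Follow-up
    intervals are uniform in ``interval_range`` years.
    """
    cohort = validate_covariates(cohort)
    n_rois = baseline.values.shape[1]
    target_corr = np.asarray(target_corr, dtype=float)
    if target_corr.shape != (n_rois, n_rois):
        raise ValidationError("target_corr shape must match the ROI count")
    w = np.linalg.eigvalsh(target_corr)
    if w.min() < -1e-10:
        raise ValidationError(
            "target_corr is not PSD; build it with build_target_change_correlation"
        )
    change_mean = np.broadcast_to(np.asarray(change_mean, dtype=float), (n_rois,))
    change_sd = np.broadcast_to(np.asarray(change_sd, dtype=float), (n_rois,))
    if not (change_sd >= 0).all():
        raise ValidationError("change_sd must be non-negative")
    rng = np.random.default_rng(seed)
    subjects = baseline.values.index
    cov = cohort.set_index("subject_id").loc[subjects]
    abpos = cov["group"].isin(ABPOS_GROUPS).to_numpy()
    jitter = 1e-10
    chol_pos = np.linalg.cholesky(target_corr + jitter * np.eye(n_rois))
    ctrl_corr = (
        CONTROL_CORR_SHRINKAGE * target_corr
        + (1 - CONTROL_CORR_SHRINKAGE) * np.eye(n_rois)
    )
    chol_ctrl = np.linalg.cholesky(ctrl_corr + jitter * np.eye(n_rois))
    n_subj = len(subjects)
    z = rng.standard_normal((n_subj, n_rois))
    change = np.empty((n_subj, n_rois))
    change[abpos] = z[abpos] @ chol_pos.T
    change[~abpos] = z[~abpos] @ chol_ctrl.T
    change = change_mean[None, :] + change_sd[None, :] * change
    lo, hi = interval_range
    if not (0 < lo <= hi):
        raise ValidationError("interval_range must be positive and ordered")
    intervals = pd.Series(
        rng.uniform(lo, hi, size=n_subj), index=subjects, name="interval_years"
    )
    fu_values = baseline.values.to_numpy() + change * intervals.to_numpy()[:, None]
    fu_values = np.clip(fu_values, 0.05, None)
    followup = SuvrTable(
        values=pd.DataFrame(
            fu_values, index=subjects, columns=baseline.values.columns
        ),
        timepoint="followup",
        tracer=baseline.tracer,
        reference_region=baseline.reference_region,
    )
    return followup, intervals


def simulate_amyloid_suvr(
    cohort: pd.DataFrame,
    n_rois: int,
    seed: int = 0,
    tracer: str = "florbetapir",
) -> tuple[pd.Series, SuvrTable]:
    """Synthetic global + regional amyloid-PET SUVRs (plumbing).

    Global SUVRs place amyloid-positive groups above and controls below
    the tracer's positivity cut-off; regional values are the global
    value plus independent noise.  This exists so the status-screening
    and amyloid-controlled sensitivity stages of the pipeline can run
    end-to-end on synthetic data; it plants no amyloid-tau structure.
    """
    from .tau_scoring import AMYLOID_CUTOFFS

    cutoff = AMYLOID_CUTOFFS[tracer]
    cohort = validate_covariates(cohort)
    rng = np.random.default_rng(seed)
    abpos = cohort["group"].isin(ABPOS_GROUPS).to_numpy()
    n = len(cohort)
    glob = np.where(
        abpos,
        cutoff + 0.10 + 0.15 * np.abs(rng.standard_normal(n)),
        cutoff - 0.08 - 0.04 * np.abs(rng.standard_normal(n)),
    )
    glob = np.clip(glob, 0.05, None)
    regional = glob[:, None] + rng.normal(0.0, 0.05, size=(n, n_rois))
    regional = np.clip(regional, 0.05, None)
    idx = pd.Index(cohort["subject_id"].to_numpy(), name="subject_id")
    table = SuvrTable(
        values=pd.DataFrame(regional, index=idx, columns=np.arange(1, n_rois + 1)),
        timepoint="baseline",
        tracer=tracer,
        reference_region="whole_cerebellum",
    )
    return pd.Series(glob, index=idx, name="global_amyloid_suvr"), table


def simulate_amyloid_followup(
    amyloid_regional: SuvrTable,
    intervals: pd.Series,
    seed: int = 0,
    change_sd: float = 0.02,
) -> SuvrTable:
    """Follow-up amyloid SUVRs with independent per-ROI annual change.

    Plumbing for the amyloid-controlled sensitivity branch: the amyloid
    change carries no planted structure, so its covariance-in-change is
    a noise control matrix.
    """
    rng = np.random.default_rng(seed)
    values = amyloid_regional.values
    change = rng.normal(0.0, change_sd, size=values.shape)
    fu = values.to_numpy() + change * intervals.loc[values.index].to_numpy()[:, None]
    return SuvrTable(
        values=pd.DataFrame(
            np.clip(fu, 0.05, None), index=values.index, columns=values.columns
        ),
        timepoint="followup",
        tracer=amyloid_regional.tracer,
        reference_region=amyloid_regional.reference_region,
    )


# --------------------------------------------------------------------------
# whole-study orchestration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthesisConfig:
    """One seeded configuration generating a complete synthetic study.

    Defaults are the package's desk-scale study conditions: 40 ROIs and
    a 120-subject four-group cohort; 200 ROIs are supported by raising
    ``n_rois`` (and the grid).
    """

    n_rois: int = 40
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {
            "CN_Abneg_Tauneg": 40,
            "CN_Abpos": 30,
            "MCI_Abpos": 25,
            "AD_dementia": 25,
        }
    )
    mwf_range: tuple[float, float] = (0.05, 0.25)
    mwf_noise_sd: float = 0.01
    edge_density: float = 0.5
    mwf_coupling: float = 0.7
    suvr: TauSuvrParams = field(default_factory=TauSuvrParams)
    #: Planted generative coefficients (a, b, c) of the change-correlation
    #: model z = a + b*FC + c*FC*MWF*; c < 0 is the planted attenuation.
    coefficients: tuple[float, float, float] = (0.1, 0.5, -0.4)
    change_mean: float = 0.02
    change_sd: float = 0.05
    interval_range: tuple[float, float] = (0.7, 4.0)
    n_streamline_points: int = 12
    #: When True, the fiber-MWF matrix is sampled along generated
    #: streamlines through the MWF volume (exercises the image path);
    #: when False it comes from the parametric edge generator (fast,
    #: used at 200-ROI scale).
    use_streamline_mwf: bool = True
    with_amyloid: bool = True


@dataclass
class StudyData:
    """Everything the pipeline consumes, plus the recorded ground truth."""

    config: SynthesisConfig
    seed: int
    atlas: RoiAtlas
    mwf_volume: np.ndarray
    cortical_mwf: np.ndarray
    fc: EdgeMatrix
    structural_counts: EdgeMatrix
    fiber_mwf: EdgeMatrix
    streamlines: dict[tuple[int, int], list[np.ndarray]] | None
    cohort: pd.DataFrame
    baseline: SuvrTable
    followup: SuvrTable
    intervals: pd.Series
    truth: SyntheticTruth
    amyloid_global: pd.Series | None = None
    amyloid_regional: SuvrTable | None = None


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def synthesize_study(config: SynthesisConfig | None = None, seed: int = 0) -> StudyData:
    """Generate a full synthetic study from one master seed."""
    config = config or SynthesisConfig()
    seeds = _stage_seeds(seed, 8)
    atlas = generate_atlas(config.n_rois, config.grid_shape, seeds[0])
    mwf_volume, cortical_mwf = generate_mwf(
        atlas, config.mwf_range, seeds[1], noise_sd=config.mwf_noise_sd
    )
    fc, structural, fiber_param = generate_connectome(
        config.n_rois, config.edge_density, cortical_mwf,
        mwf_coupling=config.mwf_coupling, seed=seeds[2],
    )
    streamlines = None
    if config.use_streamline_mwf:
        streamlines = generate_streamlines(
            atlas, structural, n_points=config.n_streamline_points, seed=seeds[3]
        )
        fiber_mwf = edge_fiber_mwf(streamlines, mwf_volume, atlas.roi_ids)
    else:
        fiber_mwf = fiber_param
    cohort = generate_cohort(config.n_per_group, seed=seeds[4])
    baseline, truth = simulate_tau_suvr(
        cohort, cortical_mwf, params=config.suvr, seed=seeds[5]
    )
    a, b, c = config.coefficients
    target_corr, _ = build_target_change_correlation(fc, fiber_mwf, a, b, c)
    followup, intervals = simulate_longitudinal_change(
        cohort, baseline, target_corr,
        change_mean=config.change_mean, change_sd=config.change_sd,
        interval_range=config.interval_range, seed=seeds[6],
    )
    truth = replace(
        truth,
        target_change_correlation=target_corr,
        generative_coefficients=(a, b, c),
    )
    amyloid_global = amyloid_regional = None
    if config.with_amyloid:
        amyloid_global, amyloid_regional = simulate_amyloid_suvr(
            cohort, config.n_rois, seed=seeds[7]
        )
    return StudyData(
        config=config, seed=seed, atlas=atlas, mwf_volume=mwf_volume,
        cortical_mwf=cortical_mwf, fc=fc, structural_counts=structural,
        fiber_mwf=fiber_mwf, streamlines=streamlines, cohort=cohort,
        baseline=baseline, followup=followup, intervals=intervals, truth=truth,
        amyloid_global=amyloid_global, amyloid_regional=amyloid_regional,
    )
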