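"""Core data containers.

The package works on ROI-level tables and symmetric ROI x ROI matrices:

* :class:`SuvrTable` - subjects x ROIs tracer uptake ratios (SUVR) at one
  timepoint, tagged with tracer and reference region.
* :class:`TauScoreTable` - tau-positivity probabilities and the
  positivity-weighted tau-PET scores derived from them.
* :class:`ChangeTable` - annualized per-ROI change rates plus follow-up
  intervals.
* :class:`EdgeMatrix` - a symmetric ROI x ROI matrix with a value-semantics
  tag (Fisher-z functional connectivity, Fisher-z Spearman covariance in
  change, fiber-tract myelin water fraction, or streamline counts) and an
  explicit missingness mask.
* :class:`RoiAtlas` - a 3-D integer label volume with ROI ids/names.

Subject-level tables are thin wrappers around wide pandas DataFrames
(index = subject id, columns = ROI id); matrices wrap numpy arrays.
Validation happens at construction so downstream code can assume the
invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SemanticsError, ValidationError

TAU_TRACERS = frozenset({"flortaucipir"})
AMYLOID_TRACERS = frozenset({"florbetapir", "florbetaben", "flutemetamol"})

#: Reference region conventions: tau tracers are intensity-normalized to
#: inferior cerebellar gray matter, amyloid tracers to the whole cerebellum.
TAU_REFERENCE = "inferior_cerebellar_gm"
AMYLOID_REFERENCE = "whole_cerebellum"

GROUPS = ("CN_Abneg_Tauneg", "CN_Abpos", "MCI_Abpos", "AD_dementia")
ABPOS_GROUPS = frozenset({"CN_Abpos", "MCI_Abpos", "AD_dementia"})

EDGE_SEMANTICS = (
    "fisher_z_fc",
    "fisher_z_spearman_cov",
    "fiber_mwf",
    "streamline_count",
)

#: The six regions of the temporal meta-ROI used for tau-negativity
#: screening (unweighted mean, cut-off < 1.29).
META_ROI_REGIONS = (
    "amygdala",
    "entorhinal",
    "fusiform",
    "parahippocampal",
    "inferior_temporal",
    "middle_temporal",
)

SYMMETRY_TOL = 1e-10


@dataclass
class RoiAtlas:
    """A 3-D parcellation: 0 = background, labels 1..N = ROIs."""

    label_volume: np.ndarray
    roi_ids: np.ndarray
    roi_names: list[str]
    network_assignment: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValidationError("label_volume must be 3-D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValidationError("label_volume must be an integer grid")
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        n = self.roi_ids.size
        if n < 2:
            raise ValidationError("an atlas needs at least 2 ROIs")
        if not np.array_equal(self.roi_ids, np.arange(1, n + 1)):
            raise ValidationError("roi_ids must be contiguous 1..N")
        present = np.unique(self.label_volume)
        missing = set(self.roi_ids.tolist()) - set(present.tolist())
        if missing:
            raise ValidationError(f"labels absent from volume: {sorted(missing)}")
        if len(self.roi_names) != n:
            raise ValidationError("roi_names length must equal number of ROIs")

    @property
    def n_rois(self) -> int:
        return int(self.roi_ids.size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape  # type: ignore[return-value]

    def parcel_voxels(self, roi_id: int) -> np.ndarray:
        """Integer voxel coordinates (k, 3) belonging to one parcel."""
        return np.argwhere(self.label_volume == roi_id)


@dataclass
class EdgeMatrix:
    """Symmetric ROI x ROI matrix with a value-semantics tag.

    ``values`` holds NaN at missing entries; ``missing_mask`` mirrors the
    NaN pattern and is kept so callers can distinguish "structurally
    absent" from "not yet computed" when writing files.
    """

    values: np.ndarray
    roi_ids: np.ndarray
    semantics: str
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("EdgeMatrix values must be square")
        if v.shape[0] != self.roi_ids.size:
            raise ValidationError("roi_ids length must match matrix size")
        if self.semantics not in EDGE_SEMANTICS:
            raise SemanticsError(f"unknown semantics {self.semantics!r}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(v)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            v[self.missing_mask] = np.nan
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if not np.array_equal(self.missing_mask, self.missing_mask.T):
            raise ValidationError("missing_mask must be symmetric")
        if np.isfinite(asym) and asym > SYMMETRY_TOL:
            raise ValidationError(f"matrix asymmetric (max |A-A'| = {asym:g})")
        if self.semantics.startswith("fisher_z"):
            diag = np.diagonal(v)
            ok = np.isnan(diag) | (diag == 0.0)
            if not ok.all():
                raise ValidationError("fisher_z matrices must have zero diagonal")
        if self.semantics == "fiber_mwf":
            finite = v[~self.missing_mask]
            if finite.size and ((finite < 0) | (finite > 1)).any():
                raise ValidationError("fiber MWF values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.roi_ids.size)

    def copy_with(self, values: np.ndarray, semantics: str | None = None) -> "EdgeMatrix":
        return EdgeMatrix(values, self.roi_ids.copy(), semantics or self.semantics)


def _check_wide(values: pd.DataFrame, what: str) -> pd.DataFrame:
    if values.index.has_duplicates:
        raise ValidationError(f"{what}: duplicate subject ids")
    if values.columns.has_duplicates:
        raise ValidationError(f"{what}: duplicate ROI ids")
    return values


@dataclass
class SuvrTable:
    """Subjects x ROIs SUVR values at a single timepoint.

    ``values``: wide DataFrame, index = subject_id, columns = ROI id.
    """

    values: pd.DataFrame
    timepoint: str
    tracer: str
    reference_region: str

    def __post_init__(self) -> None:
        _check_wide(self.values, "SuvrTable")
        if self.timepoint not in ("baseline", "followup"):
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.tracer in TAU_TRACERS:
            expected = TAU_REFERENCE
        elif self.tracer in AMYLOID_TRACERS:
            expected = AMYLOID_REFERENCE
        else:
            raise ValidationError(f"unknown tracer {self.tracer!r}")
        if self.reference_region != expected:
            raise ValidationError(
                f"tracer {self.tracer} must use reference region {expected}, "
                f"got {self.reference_region}"
            )
        arr = self.values.to_numpy(dtype=float)
        if not (arr > 0).all():
            raise ValidationError("SUVR values must be positive")

    @property
    def kind(self) -> str:
        return "suvr"

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def roi_ids(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=int)


@dataclass
class TauScoreTable:
    """Tau-positivity probabilities and positivity-weighted scores.

    ``score = probability * SUVR`` elementwise; both frames share index
    and columns with the SUVR table they were computed from.
    """

    probability: pd.DataFrame
    score: pd.DataFrame
    timepoint: str

    def __post_init__(self) -> None:
        _check_wide(self.score, "TauScoreTable")
        if not self.probability.index.equals(self.score.index) or not (
            self.probability.columns.equals(self.score.columns)
        ):
            raise ValidationError("probability/score frames must align")
        p = self.probability.to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("probabilities must lie in [0, 1]")

    @property
    def kind(self) -> str:
        return "score"

    @property
    def values(self) -> pd.DataFrame:
        """The analysis values of this table (the weighted scores)."""
        return self.score

    @property
    def subjects(self) -> pd.Index:
        return self.score.index

    @property
    def roi_ids(self) -> np.ndarray:
        return np.asarray(self.score.columns, dtype=int)


@dataclass
class ChangeTable:
    """Annualized per-ROI change, plus the per-subject follow-up interval."""

    annual_change: pd.DataFrame
    intervals: pd.Series
    kind: str  # "suvr" or "score"

    def __post_init__(self) -> None:
        _check_wide(self.annual_change, "ChangeTable")
        if not self.annual_change.index.equals(self.intervals.index):
            raise ValidationError("intervals must be indexed by the same subjects")
        if not (self.intervals.to_numpy(dtype=float) > 0).all():
            raise ValidationError("follow-up intervals must be positive")
        if self.kind not in ("suvr", "score"):
            raise ValidationError(f"unknown change kind {self.kind!r}")

    @property
    def subjects(self) -> pd.Index:
        return self.annual_change.index

    @property
    def roi_ids(self) -> np.ndarray:
        return np.asarray(self.annual_change.columns, dtype=int)


COVARIATE_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "apoe4",
    "diagnosis",
    "site",
)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a covariate table (one row per subject) and return it.

    Raises :class:`ValidationError` naming the first offending row.
    """
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"covariate table missing columns: {missing_cols}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup!r}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        row = int(np.flatnonzero(bad_group.to_numpy())[0])
        raise ValidationError(
            f"row {row}: unknown group {df['group'].iloc[row]!r} "
            f"(allowed: {list(GROUPS)})"
        )
    if df["group"].isna().any():
        raise ValidationError("group may not be missing")
    bad_sex = ~df["sex"].isin(["M", "F"])
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise ValidationError(f"row {row}: sex must be M or F")
    bad_apoe = ~df["apoe4"].isin(["carrier", "noncarrier"])
    if bad_apoe.any():
        row = int(np.flatnonzero(bad_apoe.to_numpy())[0])
        raise ValidationError(f"row {row}: apoe4 must be carrier/noncarrier")
    return df


@dataclass
class GmmFitSet:
    """Per-ROI two-component univariate Gaussian mixture parameters.

    ``table`` is indexed by ROI id with columns mean_off, sd_off,
    weight_off, mean_on, sd_on, weight_on, converged, degenerate, n_fit.
    Labeling convention: the on-target component has the larger mean.
    """

    table: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        req = {
            "mean_off", "sd_off", "weight_off",
            "mean_on", "sd_on", "weight_on",
            "converged", "degenerate", "n_fit",
        }
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"GmmFitSet missing columns: {sorted(missing)}")
        t = self.table
        w = (t["weight_off"] + t["weight_on"]).to_numpy()
        if np.abs(w - 1.0).max() > 1e-9:
            raise ValidationError("component weights must sum to 1")
        if not ((t["sd_off"] > 0) & (t["sd_on"] > 0)).all():
            raise ValidationError("component sigmas must be positive")
        if not (t["mean_on"] >= t["mean_off"]).all():
            raise ValidationError("labeling convention: mean_on >= mean_off")

    @property
    def roi_ids(self) -> np.ndarray:
        return np.asarray(self.table.index, dtype=int)


@dataclass
class ModelResult:
    """Standardized OLS results for the edge-wise interaction model."""

    coefficients: pd.Series
    standard_errors: pd.Series
    t_statistics: pd.Series
    p_values: pd.Series
    n_edges: int
    r_squared: float
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        if self.n_edges < len(self.coefficients) + 1:
            raise ValidationError("fewer edges than coefficients + 1")
        p = self.p_values.to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("p-values must lie in [0, 1]")


@dataclass
class StratumRho:
    rho_hat: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValidationError("ci_low must be <= ci_high")


@dataclass
class BootstrapResult:
    """Per-stratum bootstrapped Spearman rho with percentile 95% CIs."""

    strata: dict[str, StratumRho]
    n_iterations: int
    seed: int
    #: True when the CIs of every pair of strata overlap (the study's
    #: decision rule for "no significant difference between groups").
    cis_overlap: bool | None = None


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic generators."""

    positivity_labels: pd.DataFrame | None = None
    on_target_probability: np.ndarray | None = None
    true_spatial_rho: float | None = None
    target_change_correlation: np.ndarray | None = None
    generative_coefficients: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        c = self.target_change_correlation
        if c is not None:
            c = np.asarray(c, dtype=float)
            if np.abs(c - c.T).max() > 1e-8:
                raise ValidationError("target correlation must be symmetric")
            if np.abs(np.diagonal(c) - 1.0).max() > 1e-8:
                raise ValidationError("target correlation must have unit diagonal")
            w = np.linalg.eigvalsh(c)
            if w.min() < -1e-10:
                raise ValidationError("target correlation must be PSD")
            self.target_change_correlation = c


def abpos_mask(covariates: pd.DataFrame) -> pd.Series:
    """Boolean mask (indexed by subject_id) of amyloid-positive subjects."""
    m = covariates["group"].isin(ABPOS_GROUPS)
    return pd.Series(m.to_numpy(), index=covariates["subject_id"].to_numpy())
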