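"""Reading and writing the package's on-disk formats.

Tables and matrices are TSV: matrices carry an ROI-id header row and
column with ``NA`` tokens for missing edges; subject tables are wide
(one row per subject, one column per ROI) with ``#key=value`` metadata
lines for tags like tracer and timepoint.  Volumes are NIfTI-1 via
nibabel; streamlines are long-format TSV point lists; ground truth and
manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    ChangeTable,
    EdgeMatrix,
    GmmFitSet,
    SuvrTable,
    SyntheticTruth,
    TauScoreTable,
    validate_covariates,
)
from .exceptions import ValidationError

READ_SYMMETRY_TOL = 1e-8


# --------------------------------------------------------------------------
# matrices
# --------------------------------------------------------------------------

def write_matrix(m: EdgeMatrix, path: str | Path) -> Path:
    """TSV with ROI-id header row and column; NaN encoded as ``NA``."""
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.roi_ids, columns=m.roi_ids)
    with open(path, "w") as fh:
        fh.write(f"#semantics={m.semantics}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index_label="roi_id")
    return path


def read_matrix(path: str | Path, semantics: str | None = None) -> EdgeMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#semantics="):
            file_sem = first.split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
        else:
            file_sem = None
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    sem = semantics or file_sem
    if sem is None:
        raise ValidationError(f"{path}: no semantics tag and none supplied")
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: matrix is not square ({df.shape})")
    rows = np.asarray(df.index, dtype=int)
    cols = np.asarray(df.columns, dtype=int)
    if not np.array_equal(rows, cols):
        raise ValidationError(f"{path}: header row and column disagree")
    values = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        asym = np.nanmax(np.abs(values - values.T)) if values.size else 0.0
    if np.isfinite(asym) and asym > READ_SYMMETRY_TOL:
        raise ValidationError(f"{path}: asymmetric beyond {READ_SYMMETRY_TOL:g}")
    values = (values + values.T) / 2.0
    return EdgeMatrix(values, rows, sem)


# --------------------------------------------------------------------------
# subject tables
# --------------------------------------------------------------------------

def _write_wide(df: pd.DataFrame, path: Path, meta: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index_label="subject_id")
    return path


def _read_wide(
    path: Path, coerce_int: bool = True
) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, v = line[1:].strip().split("=", 1)
            meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    if coerce_int:
        df.columns = [int(c) for c in df.columns]
    return df, meta


def write_suvr_table(table: SuvrTable, path: str | Path) -> Path:
    meta = dict(
        timepoint=table.timepoint,
        tracer=table.tracer,
        reference_region=table.reference_region,
    )
    return _write_wide(table.values, Path(path), meta)


def read_suvr_table(path: str | Path) -> SuvrTable:
    df, meta = _read_wide(Path(path))
    for key in ("timepoint", "tracer", "reference_region"):
        if key not in meta:
            raise ValidationError(f"{path}: missing #{key}= metadata line")
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~(arr > 0))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"{path}: non-positive SUVR at row {r + 1} "
            f"(subject {df.index[r]!r}, ROI {df.columns[c]})"
        )
    return SuvrTable(values=df, **meta)


def write_score_table(table: TauScoreTable, path_prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(path_prefix)
    p_prob = prefix.with_name(prefix.name + "_probability.tsv")
    p_score = prefix.with_name(prefix.name + "_score.tsv")
    _write_wide(table.probability, p_prob, {"timepoint": table.timepoint})
    _write_wide(table.score, p_score, {"timepoint": table.timepoint})
    return p_prob, p_score


def read_score_table(path_prefix: str | Path) -> TauScoreTable:
    prefix = Path(path_prefix)
    prob, meta = _read_wide(prefix.with_name(prefix.name + "_probability.tsv"))
    score, _ = _read_wide(prefix.with_name(prefix.name + "_score.tsv"))
    return TauScoreTable(probability=prob, score=score, timepoint=meta["timepoint"])


def write_covariates(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_covariates(df).to_csv(path, sep="\t", index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_covariates(df)


def write_change_table(table: ChangeTable, path: str | Path) -> Path:
    df = table.annual_change.copy()
    df.insert(0, "interval_years", table.intervals)
    return _write_wide(df, Path(path), {"kind": table.kind})


def read_change_table(path: str | Path) -> ChangeTable:
    df, meta = _read_wide(Path(path), coerce_int=False)
    intervals = df["interval_years"].astype(float)
    change = df.drop(columns=["interval_years"])
    change.columns = [int(c) for c in change.columns]
    return ChangeTable(
        annual_change=change, intervals=intervals, kind=meta.get("kind", "score")
    )


def write_gmm_fits(fits: GmmFitSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#seed={fits.seed}\n")
        fits.table.to_csv(fh, sep="\t", index_label="roi_id")
    return path


def read_gmm_fits(path: str | Path) -> GmmFitSet:
    with open(path) as fh:
        first = fh.readline().strip()
        seed = int(first.split("=", 1)[1]) if first.startswith("#seed=") else 0
        if not first.startswith("#"):
            fh.seek(0)
        table = pd.read_csv(fh, sep="\t", index_col="roi_id")
    table["converged"] = table["converged"].astype(bool)
    table["degenerate"] = table["degenerate"].astype(bool)
    return GmmFitSet(table=table, seed=seed)


# --------------------------------------------------------------------------
# volumes, streamlines, truth
# --------------------------------------------------------------------------

def save_volume(volume: np.ndarray, path: str | Path) -> Path:
    """NIfTI-1 with identity affine (synthetic voxel space)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), np.eye(4))
    nib.save(img, str(path))
    return path


def save_label_volume(volume: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.int32), np.eye(4))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_streamlines(
    streams: dict[tuple[int, int], list[np.ndarray]], path: str | Path
) -> Path:
    """Long-format TSV: roi_i, roi_j, streamline, point, x, y, z."""
    path = Path(path)
    rows = []
    for (i, j), lst in sorted(streams.items()):
        for s_idx, pts in enumerate(lst):
            for p_idx, (x, y, z) in enumerate(np.asarray(pts, dtype=float)):
                rows.append((i, j, s_idx, p_idx, x, y, z))
    pd.DataFrame(
        rows, columns=["roi_i", "roi_j", "streamline", "point", "x", "y", "z"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_streamlines(path: str | Path) -> dict[tuple[int, int], list[np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[int, int], list[np.ndarray]] = {}
    for (i, j), edge in df.groupby(["roi_i", "roi_j"], sort=True):
        streams = []
        for _, s in edge.groupby("streamline", sort=True):
            pts = s.sort_values("point")[["x", "y", "z"]].to_numpy(dtype=float)
            streams.append(pts)
        out[(int(i), int(j))] = streams
    return out


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    payload: dict = {"true_spatial_rho": truth.true_spatial_rho}
    if truth.generative_coefficients is not None:
        a, b, c = truth.generative_coefficients
        payload["generative_coefficients"] = {"a": a, "b": b, "c": c}
    if truth.on_target_probability is not None:
        payload["on_target_probability"] = [
            float(v) for v in truth.on_target_probability
        ]
    if truth.positivity_labels is not None:
        payload["positivity_labels"] = {
            str(s): [bool(v) for v in row]
            for s, row in truth.positivity_labels.iterrows()
        }
    if truth.target_change_correlation is not None:
        payload["target_change_correlation"] = [
            [float(v) for v in row] for row in truth.target_change_correlation
        ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
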