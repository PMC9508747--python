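"""End-to-end orchestration: synthesis, scoring, matrices, statistics.

``run_pipeline`` executes, in order: synthesis (or loading of user
inputs), amyloid/tau status screening, GMM fitting and tau scoring, the
spatial MWF-tau analyses (plain, bootstrap-stratified, partial,
SUVR-based sensitivity), annualized change and (partial) covariance in
change, and the edge-wise interaction regression with its sensitivity
variants.  Every intermediate artifact is written to the output
directory so each stage is independently re-runnable, and a manifest
records the config hash, per-file checksums, versions, and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import ABPOS_GROUPS, EdgeMatrix, META_ROI_REGIONS
from .exceptions import MtspreadError, SampleSizeError, ValidationError
from . import io as mio
from .stats import (
    edge_interaction_model,
    partial_spatial_correlation,
    spatial_correlation,
    stratified_bootstrap_rho,
)
from .synthetic import (
    SynthesisConfig,
    TauSuvrParams,
    StudyData,
    simulate_amyloid_followup,
    synthesize_study,
)
from .tau_change import annual_change, change_covariance, partial_change_covariance
from .tau_scoring import classify_amyloid_status, compute_tau_scores, fit_tau_gmm, is_tau_negative

logger = logging.getLogger(__name__)

DEFAULT_CONTROLS = ("age", "sex", "education", "apoe4", "diagnosis", "site")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    use_scores: bool = True
    bootstrap_iterations: int = 1000
    covariate_controls: tuple[str, ...] = DEFAULT_CONTROLS
    amyloid_sensitivity: bool = True

    def validate(self) -> "RunConfig":
        if self.seed < 0 or self.seed >= 2**31:
            raise ValidationError("seed must be in [0, 2^31)")
        if self.bootstrap_iterations < 1:
            raise ValidationError("bootstrap_iterations must be >= 1")
        for c in self.covariate_controls:
            if c not in DEFAULT_CONTROLS:
                raise ValidationError(f"unknown covariate control {c!r}")
        return self

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        synth = data.pop("synthesis", {})
        if isinstance(synth, Mapping):
            synth = dict(synth)
            suvr = synth.pop("suvr", {})
            for key in ("grid_shape", "mwf_range", "interval_range", "coefficients"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            if "p_range" in suvr:
                suvr["p_range"] = tuple(suvr["p_range"])
            synth = SynthesisConfig(**synth, suvr=TauSuvrParams(**suvr))
        if "covariate_controls" in data:
            data["covariate_controls"] = tuple(data["covariate_controls"])
        return cls(synthesis=synth, **data).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    checksums: dict[str, str]
    versions: dict[str, str]
    warnings: list[str]
    results: dict[str, Any]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=str))
        return path


def _edge_payload(result) -> dict[str, Any]:
    return {
        "coefficients": result.coefficients.to_dict(),
        "standard_errors": result.standard_errors.to_dict(),
        "p_values": result.p_values.to_dict(),
        "n_edges": result.n_edges,
        "r_squared": result.r_squared,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute a full synthetic-study analysis; see the module docstring.

    Any stage failure is re-raised with the stage name attached.
    """
    config = config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    caught: list[str] = []
    results: dict[str, Any] = {}

    def record(name: str, path: Path) -> None:
        written[name] = path

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage %s", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, MtspreadError):
                    raise MtspreadError(f"stage {name!r} failed: {exc}") from exc
                if isinstance(exc, MtspreadError):
                    raise MtspreadError(f"stage {name!r}: {exc}") from exc
                return False

        return _Stage()

    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")

        with stage("synthesis"):
            study = synthesize_study(config.synthesis, seed=config.seed)
            record("atlas", mio.save_label_volume(
                study.atlas.label_volume, out / "atlas_labels.nii"))
            record("mwf_volume", mio.save_volume(study.mwf_volume, out / "mwf.nii"))
            cortical = pd.DataFrame({
                "roi_id": study.atlas.roi_ids,
                "roi_name": study.atlas.roi_names,
                "cortical_mwf": study.cortical_mwf,
            })
            p = out / "cortical_mwf.tsv"
            cortical.to_csv(p, sep="\t", index=False)
            record("cortical_mwf", p)
            record("fc", mio.write_matrix(study.fc, out / "fc.tsv"))
            record("structural_counts", mio.write_matrix(
                study.structural_counts, out / "structural_counts.tsv"))
            record("fiber_mwf", mio.write_matrix(study.fiber_mwf, out / "fiber_mwf.tsv"))
            record("cohort", mio.write_covariates(study.cohort, out / "cohort.tsv"))
            record("suvr_baseline", mio.write_suvr_table(
                study.baseline, out / "tau_suvr_baseline.tsv"))
            record("suvr_followup", mio.write_suvr_table(
                study.followup, out / "tau_suvr_followup.tsv"))
            record("truth", mio.write_truth(study.truth, out / "truth.json"))
            if study.streamlines is not None:
                record("streamlines", mio.write_streamlines(
                    study.streamlines, out / "streamlines.tsv"))

        with stage("status_classification"):
            status = _classify_status(study)
            p = out / "status.tsv"
            status.to_csv(p, sep="\t", index=False)
            record("status", p)
            results["n_amyloid_positive"] = int((status["amyloid_status"] == "positive").sum())

        with stage("tau_scoring"):
            fits = fit_tau_gmm(study.baseline, seed=config.seed)
            record("gmm_fits", mio.write_gmm_fits(fits, out / "gmm_fits.tsv"))
            scores_bl = compute_tau_scores(study.baseline, fits)
            scores_fu = compute_tau_scores(study.followup, fits)
            record("scores_baseline", mio.write_score_table(
                scores_bl, out / "tau_baseline")[1])
            record("scores_followup", mio.write_score_table(
                scores_fu, out / "tau_followup")[1])
            n_degen = int(fits.table["degenerate"].sum())
            if n_degen:
                caught.append(f"degenerate GMM fits in {n_degen} ROI(s)")
            results["n_degenerate_gmm_rois"] = n_degen

        cohort_idx = study.cohort.set_index("subject_id")
        abpos_subjects = cohort_idx.index[cohort_idx["group"].isin(ABPOS_GROUPS)]
        ctrl_subjects = cohort_idx.index[~cohort_idx["group"].isin(ABPOS_GROUPS)]

        with stage("spatial_correlation"):
            tau_values = scores_bl.score if config.use_scores else study.baseline.values
            mean_abpos = tau_values.loc[abpos_subjects].mean(axis=0).to_numpy()
            rho, pval = spatial_correlation(study.cortical_mwf, mean_abpos)
            results["spatial"] = {"abpos": {"rho": rho, "p": pval}}
            mean_ctrl = tau_values.loc[ctrl_subjects].mean(axis=0).to_numpy()
            rho_c, p_c = spatial_correlation(study.cortical_mwf, mean_ctrl)
            results["spatial"]["control"] = {"rho": rho_c, "p": p_c}
            # sensitivity: SUVR-based (unweighted) spatial correlation
            mean_suvr = study.baseline.values.loc[abpos_subjects].mean(axis=0).to_numpy()
            rho_s, p_s = spatial_correlation(study.cortical_mwf, mean_suvr)
            results["spatial"]["abpos_suvr"] = {"rho": rho_s, "p": p_s}

        with stage("stratified_bootstrap"):
            strata = cohort_idx.loc[abpos_subjects, "apoe4"]
            try:
                boot = stratified_bootstrap_rho(
                    scores_bl.score.loc[abpos_subjects], strata,
                    study.cortical_mwf, B=config.bootstrap_iterations,
                    seed=config.seed,
                )
                results["bootstrap"] = {
                    label: {"rho": s.rho_hat, "ci": [s.ci_low, s.ci_high]}
                    for label, s in boot.strata.items()
                }
                results["bootstrap"]["cis_overlap"] = boot.cis_overlap
            except SampleSizeError as exc:
                caught.append(f"bootstrap skipped: {exc}")

        if config.amyloid_sensitivity and study.amyloid_regional is not None:
            with stage("amyloid_partial_spatial"):
                am_mean = (
                    study.amyloid_regional.values.loc[abpos_subjects]
                    .mean(axis=0).to_numpy()
                )
                tau_values = scores_bl.score if config.use_scores else study.baseline.values
                mean_abpos = tau_values.loc[abpos_subjects].mean(axis=0).to_numpy()
                rho_p, p_p = partial_spatial_correlation(
                    study.cortical_mwf, mean_abpos, am_mean
                )
                results["spatial"]["abpos_amyloid_controlled"] = {"rho": rho_p, "p": p_p}

        with stage("annual_change"):
            bl_t, fu_t = (scores_bl, scores_fu) if config.use_scores else (
                study.baseline, study.followup)
            changes = annual_change(bl_t, fu_t, study.intervals)
            record("annual_change", mio.write_change_table(
                changes, out / "annual_change.tsv"))

        with stage("change_covariance"):
            ch_abpos = _subset_changes(changes, abpos_subjects)
            cov_abpos = change_covariance(ch_abpos)
            record("cov_change_abpos", mio.write_matrix(
                cov_abpos, out / "cov_change_abpos.tsv"))
            ch_ctrl = _subset_changes(changes, ctrl_subjects)
            cov_ctrl = change_covariance(ch_ctrl)
            record("cov_change_control", mio.write_matrix(
                cov_ctrl, out / "cov_change_control.tsv"))
            pcov = partial_change_covariance(
                ch_abpos, study.cohort, list(config.covariate_controls)
            )
            record("cov_change_abpos_adjusted", mio.write_matrix(
                pcov, out / "cov_change_abpos_adjusted.tsv"))

        with stage("edge_interaction"):
            model = edge_interaction_model(
                cov_abpos, study.fc, study.fiber_mwf, mask=study.structural_counts
            )
            results["interaction"] = {"abpos": _edge_payload(model)}
            model_adj = edge_interaction_model(
                pcov, study.fc, study.fiber_mwf, mask=study.structural_counts
            )
            results["interaction"]["abpos_adjusted"] = _edge_payload(model_adj)
            model_ctrl = edge_interaction_model(
                cov_ctrl, study.fc, study.fiber_mwf, mask=study.structural_counts
            )
            results["interaction"]["control"] = _edge_payload(model_ctrl)

        if config.amyloid_sensitivity and study.amyloid_regional is not None:
            with stage("amyloid_controlled_interaction"):
                am_fu = simulate_amyloid_followup(
                    study.amyloid_regional, study.intervals, seed=config.seed
                )
                am_changes = annual_change(
                    study.amyloid_regional, am_fu, study.intervals
                )
                am_cov = change_covariance(_subset_changes(am_changes, abpos_subjects))
                record("cov_amyloid_change", mio.write_matrix(
                    am_cov, out / "cov_amyloid_change_abpos.tsv"))
                model_am = edge_interaction_model(
                    cov_abpos, study.fc, study.fiber_mwf,
                    mask=study.structural_counts, control_cov=am_cov,
                )
                results["interaction"]["abpos_amyloid_controlled"] = _edge_payload(model_am)

        caught.extend(str(w.message) for w in wlog)

    p = out / "results.json"
    p.write_text(json.dumps(results, indent=1, default=str))
    record("results", p)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        checksums={name: mio.sha256_file(path) for name, path in sorted(written.items())},
        versions=_versions(),
        warnings=caught,
        results=results,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _subset_changes(changes, subjects):
    from .datatypes import ChangeTable

    keep = changes.annual_change.index.intersection(subjects)
    return ChangeTable(
        annual_change=changes.annual_change.loc[keep],
        intervals=changes.intervals.loc[keep],
        kind=changes.kind,
    )


def _classify_status(study: StudyData) -> pd.DataFrame:
    """Amyloid status from global amyloid SUVR; tau status from the
    temporal meta-ROI when the atlas names its six regions."""
    rows = []
    name_to_id = {n: i for i, n in zip(study.atlas.roi_ids, study.atlas.roi_names)}
    has_meta = all(r in name_to_id for r in META_ROI_REGIONS)
    for subj in study.baseline.values.index:
        amy = "unknown"
        if study.amyloid_global is not None:
            amy = classify_amyloid_status(
                float(study.amyloid_global.loc[subj]),
                study.amyloid_regional.tracer,
            )
        tau_neg = None
        if has_meta:
            roi_suvrs = {
                r: float(study.baseline.values.loc[subj, name_to_id[r]])
                for r in META_ROI_REGIONS
            }
            tau_neg = is_tau_negative(roi_suvrs)
        rows.append(dict(
            subject_id=subj, amyloid_status=amy,
            tau_negative="" if tau_neg is None else str(bool(tau_neg)),
        ))
    return pd.DataFrame(rows)


def _versions() -> dict[str, str]:
    import nibabel
    import scipy
    import sklearn
    import statsmodels

    return {
        "mtspread": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "nibabel": nibabel.__version__,
    }
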