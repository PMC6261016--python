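"""End-to-end orchestration: data → filters → mixture → per-subgroup
scaling and calibration → characterization, with a reproducibility manifest.

Stages run in the analysis order of the method: cohort assembly (simulated
scenario or supplied matrix), cohort filters, mixture-Rasch class selection
and modal assignment, then — within each subgroup independently — prevalence
screening, Mokken item selection, Guttman-error person fit, and 1PL/2PL
calibration with ICC profiles, finishing with covariate characterization.
A failure inside one subgroup quarantines that subgroup and the rest of the
run continues.  One global seed deterministically derives per-stage seeds,
so a rerun with the same config reproduces every numeric artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import characterize as chz
from . import mokken as mk
from . import preprocess as pp
from . import subgroup as sg
from .cohort_io import DiagnosisMatrix, read_matrix, write_matrix
from .mixture import estimates_to_frame, select_classes
from .synthetic import PRESET_NAMES, generate_cohort, generate_covariates, preset_scenario

logger = logging.getLogger("mdirt")

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable and round-trippable."""

    # inputs: exactly one of scenario / matrix_path
    scenario: str | None = None
    matrix_path: str | None = None
    covariates_path: str | None = None
    n_patients: int | None = None  # scenario-size override
    out_dir: str = "mdirt_run"
    # preprocessing
    max_missing: float = 0.90
    min_prev: float = 0.05
    max_prev: float = 0.95
    sample_fraction: float = 1.0
    # mixture
    class_range: list[int] = field(default_factory=lambda: [1, 2, 3])
    class_override: int | None = None
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    quadrature: int = 21
    # mokken
    h_min: float = 0.3
    max_errors: int = 1
    mono_alpha: float = 0.05
    min_group_size: int = 50
    # subgroup IRT
    subgroup_model: str = "auto"  # auto | 1pl | 2pl
    # characterization
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> list[str]:
        """Return the complete list of violations (empty when valid)."""
        errors = []
        if (self.scenario is None) == (self.matrix_path is None):
            errors.append("exactly one of scenario / matrix_path must be set")
        if self.scenario is not None and self.scenario not in PRESET_NAMES:
            errors.append(f"unknown scenario {self.scenario!r}; valid: {PRESET_NAMES}")
        if not (0 < self.max_missing <= 1):
            errors.append("max_missing must be in (0, 1]")
        if not (0 <= self.min_prev < self.max_prev <= 1):
            errors.append("need 0 <= min_prev < max_prev <= 1")
        if not (0 < self.sample_fraction <= 1):
            errors.append("sample_fraction must be in (0, 1]")
        if not self.class_range or any(c < 1 for c in self.class_range):
            errors.append("class_range must be non-empty positive integers")
        if self.class_override is not None and self.class_override not in self.class_range:
            errors.append("class_override must lie inside class_range")
        if self.n_starts < 1:
            errors.append("n_starts must be >= 1")
        if self.quadrature < 5:
            errors.append("quadrature must be >= 5")
        if not (0 <= self.h_min <= 1):
            errors.append("h_min must be in [0, 1]")
        if self.max_errors < 0:
            errors.append("max_errors must be >= 0")
        for name in ("mono_alpha", "alpha"):
            if not (0 < getattr(self, name) < 1):
                errors.append(f"{name} must be in (0, 1)")
        if self.min_group_size < 1:
            errors.append("min_group_size must be >= 1")
        if self.subgroup_model not in ("auto", "1pl", "2pl"):
            errors.append("subgroup_model must be auto, 1pl or 2pl")
        return errors

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a config file; raises with *all* violations listed."""
    config = PipelineConfig.from_file(path)
    errors = config.validate()
    if errors:
        raise ValueError("invalid config:\n- " + "\n- ".join(errors))
    return config


@dataclass
class RunManifest:
    """Reproducibility record: config, seeds, per-stage reports, artifacts."""

    config: dict[str, Any]
    seeds: dict[str, int] = field(default_factory=dict)
    stages: list[dict[str, Any]] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)
    subgroups: dict[str, Any] = field(default_factory=dict)
    complete: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _save(df: pd.DataFrame, path: Path, manifest: RunManifest, key: str, **kwargs) -> None:
    df.to_csv(path, **kwargs)
    manifest.artifacts[key] = str(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; every intermediate artifact is written to
    ``config.out_dir`` and recorded in the returned manifest."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid config:\n- " + "\n- ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())

    # ---- stage: cohort assembly ------------------------------------------
    covariates = None
    if config.scenario is not None:
        sim_seed = stage_seed(config.seed, "simulate")
        manifest.seeds["simulate"] = sim_seed
        spec = preset_scenario(config.scenario, seed=sim_seed, n_patients=config.n_patients)
        matrix, truth = generate_cohort(spec)
        write_matrix(matrix, out / "matrix.csv")
        truth.to_frame().to_csv(out / "truth.csv", index=False)
        spec.to_file(out / "cohort_spec.yaml")
        manifest.artifacts.update(
            {"matrix": str(out / "matrix.csv"), "truth": str(out / "truth.csv")}
        )
        if spec.covariate_probs:
            covariates = generate_covariates(truth, spec)
            _save(covariates, out / "covariates.csv", manifest, "covariates", index=False)
    else:
        matrix = read_matrix(config.matrix_path)
        if config.covariates_path:
            covariates = pd.read_csv(config.covariates_path)

    # ---- stage: cohort filters -------------------------------------------
    matrix, rep1 = pp.filter_missing_patients(matrix, config.max_missing)
    matrix, rep2 = pp.filter_zero_condition_patients(matrix)
    matrix, rep3 = pp.filter_conditions_by_prevalence(matrix, config.min_prev, config.max_prev)
    reports = [rep1, rep2, rep3]
    if config.sample_fraction < 1.0:
        sample_seed = stage_seed(config.seed, "sample")
        manifest.seeds["sample"] = sample_seed
        matrix, rep4 = pp.sample_patients(matrix, config.sample_fraction, sample_seed)
        reports.append(rep4)
    manifest.stages.extend(r.to_dict() for r in reports)
    write_matrix(matrix, out / "matrix_filtered.csv")
    manifest.artifacts["matrix_filtered"] = str(out / "matrix_filtered.csv")

    # ---- stage: mixture fitting and class selection ----------------------
    fit_seed = stage_seed(config.seed, "mixture")
    manifest.seeds["mixture"] = fit_seed
    selection = select_classes(
        matrix,
        config.class_range,
        override=config.class_override,
        seed=fit_seed,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol=config.tol,
        quadrature=config.quadrature,
    )
    _save(selection.table, out / "fit_table.csv", manifest, "fit_table")
    model = selection.models[selection.chosen]
    model.to_json(out / "mixture_model.json")
    manifest.artifacts["mixture_model"] = str(out / "mixture_model.json")
    manifest.subgroups["chosen_classes"] = selection.chosen
    if selection.errors:
        manifest.subgroups["selection_errors"] = selection.errors
        manifest.complete = False

    from .mixture import assign_classes  # local import avoids cycle at module load

    estimates = assign_classes(model, matrix)
    assign_df = estimates_to_frame(estimates)
    _save(assign_df, out / "assignments.csv", manifest, "assignments", index=False)

    # ---- per-subgroup stages ---------------------------------------------
    modal = assign_df.set_index("patient_id")["modal_class"]
    subgroup_results: dict[str, Any] = {}
    for k in range(1, selection.chosen + 1):
        tag = f"subgroup_{k}"
        members = modal.index[modal == k].tolist()
        record: dict[str, Any] = {"n_assigned": len(members)}
        subgroup_results[tag] = record
        try:
            sub = matrix.select_patients(members)
            sub, prev_rep = pp.filter_conditions_by_prevalence(
                sub, config.min_prev, config.max_prev
            )
            record["prevalence_filter"] = prev_rep.to_dict()
            scale = mk.select_scale_items(
                sub,
                H_min=config.h_min,
                min_group_size=config.min_group_size,
                alpha=config.mono_alpha,
            )
            record["selected_items"] = scale.selected_items
            record["H_scale"] = scale.H_scale
            record["scale_audit"] = scale.audit
            sub = sub.select_conditions(scale.selected_items)
            sub, fits, fit_rep = mk.person_fit_filter(sub, max_errors=config.max_errors)
            record["person_fit"] = fit_rep.to_dict()
            record["retained_fraction"] = fit_rep.parameters["retained_fraction"]
            pd.DataFrame(
                [
                    {"patient_id": f.patient_id, "guttman_errors": f.guttman_errors, "included": f.included}
                    for f in fits
                ]
            ).to_csv(out / f"{tag}_person_fit.csv", index=False)

            models = {}
            if config.subgroup_model in ("auto", "1pl"):
                models["1PL"] = sg.fit_1pl(sub, quadrature=config.quadrature)
            if config.subgroup_model in ("auto", "2pl"):
                models["2PL"] = sg.fit_2pl(sub, quadrature=config.quadrature)
            if config.subgroup_model == "auto":
                comparison = sg.compare_1pl_2pl(models["1PL"], models["2PL"])
                record["model_choice"] = comparison.rationale
                chosen_model = models[comparison.chosen]
            else:
                chosen_model = models[config.subgroup_model.upper()]
            record["model_type"] = chosen_model.model_type
            chosen_model.to_frame().to_csv(out / f"{tag}_coefficients.csv", index=False)
            profile = sg.icc_profile(chosen_model)
            profile.to_frame().to_csv(out / f"{tag}_icc.csv", index=False)
            manifest.artifacts[f"{tag}_coefficients"] = str(out / f"{tag}_coefficients.csv")
            manifest.artifacts[f"{tag}_icc"] = str(out / f"{tag}_icc.csv")
        except Exception as exc:  # quarantine this subgroup, keep going
            logger.warning("subgroup %d quarantined: %s", k, exc)
            record["error"] = str(exc)
            manifest.complete = False
    manifest.subgroups["results"] = subgroup_results

    # ---- stage: characterization -----------------------------------------
    if covariates is not None:
        cov_aligned = covariates.set_index("patient_id").loc[modal.index]
        char = chz.characterize_covariates(
            modal.to_numpy(), cov_aligned.reset_index(), alpha=config.alpha
        )
        _save(char, out / "characterization.csv", manifest, "characterization", index=False)
        desc = chz.descriptive_table(modal.to_numpy(), cov_aligned.reset_index())
        _save(desc, out / "descriptive.csv", manifest, "descriptive", index=False)

    manifest.to_json(out / "manifest.json")
    manifest.artifacts["manifest"] = str(out / "manifest.json")
    return manifest
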