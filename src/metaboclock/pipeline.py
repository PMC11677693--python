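"""End-to-end orchestration: simulate (or load) -> harmonize -> train ->
apply -> accelerate -> associate -> enrich, behind one validated config.

Each stage writes its outputs under the configured directory and the run
ends with a manifest listing every file with a SHA-256 checksum plus the
config hash, seed and library versions, so deterministic stages can be
verified to reproduce across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging import age_acceleration, compare_characteristics
from .associations import (concordance_quadrants, pathway_ora,
                           set_overlap_test, univariate_assoc)
from .clinical import GroupDefinition, assign_groups
from .harmonize import HarmonizationConfig, harmonize, write_missingness_report
from .io import (MetaboliteMatrix, read_metabolite_matrix, read_sample_table,
                 serialize_model, write_metabolite_matrix, write_sample_table)
from .scores import ElasticNetConfig, evaluate_score, fit_score_cv, predict_score
from .simulate import SimulationConfig, generate_cohort_pair


class ConfigError(ValueError):
    """Raised when the pipeline config violates its schema."""


@dataclass
class PipelineConfig:
    """Validated settings for :func:`run_full`.

    Exactly one of ``simulation`` (a :class:`SimulationConfig`) or
    ``paths`` (mapping with matrix_a/samples_a/matrix_b/samples_b) must
    be provided.
    """

    out_dir: str | Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    paths: dict | None = None
    groups: GroupDefinition = field(default_factory=GroupDefinition)
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    acceleration_threshold: float = 7.0
    association_alpha: float = 0.05
    ora_levels: tuple = ("sub", "super")

    def __post_init__(self):
        if (self.simulation is None) == (self.paths is None):
            raise ConfigError("exactly one of 'simulation' or 'paths' is required")
        if self.acceleration_threshold is None or self.acceleration_threshold <= 0:
            raise ConfigError("field 'acceleration_threshold' must be positive")
        if not 0 < self.association_alpha < 1:
            raise ConfigError("field 'association_alpha' must lie in (0, 1)")

    _REQUIRED = ("out_dir", "seed", "acceleration_threshold")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        missing = [k for k in cls._REQUIRED if k not in raw]
        if missing:
            raise ConfigError(f"config missing required field(s): {missing}")
        kw = dict(raw)
        if "simulation" in kw and isinstance(kw["simulation"], dict):
            sim = dict(kw["simulation"])
            for tup in ("n_subjects", "age_slope_range", "obstr_slope_range",
                        "batch_factor_range", "age_range"):
                if tup in sim and isinstance(sim[tup], list):
                    sim[tup] = tuple(sim[tup])
            kw["simulation"] = SimulationConfig(**sim)
        if "groups" in kw and isinstance(kw["groups"], dict):
            kw["groups"] = GroupDefinition(**kw["groups"])
        if "harmonization" in kw and isinstance(kw["harmonization"], dict):
            kw["harmonization"] = HarmonizationConfig(**kw["harmonization"])
        if "elastic_net" in kw and isinstance(kw["elastic_net"], dict):
            en = dict(kw["elastic_net"])
            if "alpha_grid" in en:
                en["alpha_grid"] = tuple(en["alpha_grid"])
            kw["elastic_net"] = ElasticNetConfig(**en)
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)
    payload = asdict(cfg)
    payload.pop("out_dir", None)  # hash the analysis settings, not the destination
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    stage_outputs: dict[str, list[str]] = {}

    def emit(stage: str, path: Path):
        files.append(path)
        stage_outputs.setdefault(stage, []).append(path.name)

    # -- stage 1: inputs ------------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation
            (mat_a, meta_a), (mat_b, meta_b), truth = generate_cohort_pair(sim)
            truth.metabolites.to_csv(out / "truth_metabolites.tsv", sep="\t")
            truth.subjects.to_csv(out / "truth_subjects.tsv", sep="\t", index=False)
            emit("simulate", out / "truth_metabolites.tsv")
            emit("simulate", out / "truth_subjects.tsv")
        else:
            p = config.paths
            for key in ("matrix_a", "samples_a", "matrix_b", "samples_b"):
                if key not in p:
                    raise ConfigError(f"paths block missing field {key!r}")
            mat_a = read_metabolite_matrix(p["matrix_a"])
            mat_b = read_metabolite_matrix(p["matrix_b"])
            meta_a = read_sample_table(p["samples_a"])
            meta_b = read_sample_table(p["samples_b"])
            truth = None
        for name, mat, meta in (("a", mat_a, meta_a), ("b", mat_b, meta_b)):
            write_metabolite_matrix(mat, out / f"matrix_{name}.tsv")
            write_sample_table(meta, out / f"samples_{name}.tsv")
            emit("simulate", out / f"matrix_{name}.tsv")
            emit("simulate", out / f"samples_{name}.tsv")
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    # -- stage 2: groups ------------------------------------------------------
    try:
        groups_a = assign_groups(meta_a, config.groups)
        groups_b = assign_groups(meta_b, config.groups)
        pd.concat([groups_a, groups_b]).to_csv(out / "analysis_groups.tsv", sep="\t")
        emit("groups", out / "analysis_groups.tsv")
    except Exception as exc:
        raise StageError("groups", exc) from exc

    # -- stage 3: harmonize ---------------------------------------------------
    try:
        proc_a, proc_b, report = harmonize(mat_a, mat_b, config.harmonization)
        write_missingness_report(report, out / "missingness_report.tsv")
        write_metabolite_matrix(proc_a, out / "processed_a.tsv")
        write_metabolite_matrix(proc_b, out / "processed_b.tsv")
        for f in ("missingness_report.tsv", "processed_a.tsv", "processed_b.tsv"):
            emit("harmonize", out / f)
    except Exception as exc:
        raise StageError("harmonize", exc) from exc

    # -- stage 4: train scores ------------------------------------------------
    try:
        ctrl_a = groups_a.index[groups_a == "control_training"]
        ctrl_b = groups_b.index[groups_b == "control_training"]
        en = config.elastic_net
        age_model = fit_score_cv(
            proc_a.select_samples(ctrl_a), meta_a.loc[ctrl_a, "age_actual"],
            en, outcome="age")
        obstr_model = fit_score_cv(
            proc_a, meta_a.loc[proc_a.sample_ids, "fev1_fvc"], en,
            outcome="fev1_fvc")
        serialize_model(age_model, out / "age_model.json")
        serialize_model(obstr_model, out / "obstruction_model.json")
        test_eval = evaluate_score(
            predict_score(age_model, proc_b.select_samples(ctrl_b)),
            meta_b.loc[ctrl_b, "age_actual"])
        obstr_eval = evaluate_score(
            predict_score(obstr_model, proc_b),
            meta_b.loc[proc_b.sample_ids, "fev1_fvc"])
        (out / "score_evaluation.json").write_text(json.dumps({
            "age_test_pearson_r": test_eval.pearson_r,
            "age_test_rmse": test_eval.rmse,
            "age_test_n": test_eval.n,
            "age_n_selected": age_model.n_selected,
            "obstruction_test_pearson_r": obstr_eval.pearson_r,
            "obstruction_test_rmse": obstr_eval.rmse,
            "obstruction_n_selected": obstr_model.n_selected,
        }, indent=1))
        for f in ("age_model.json", "obstruction_model.json",
                  "score_evaluation.json"):
            emit("train", out / f)
    except Exception as exc:
        raise StageError("train", exc) from exc

    # -- stage 5: acceleration ------------------------------------------------
    try:
        groups_all = pd.concat([groups_a, groups_b])
        meta_all = pd.concat([meta_a, meta_b])
        proc_all = pd.concat([proc_a.data, proc_b.data])
        apply_ids = groups_all.index[groups_all.isin(["disease", "current_no_copd"])]
        pred_age = predict_score(age_model, proc_all.loc[apply_ids])
        records = age_acceleration(
            apply_ids, meta_all.loc[apply_ids, "age_actual"], pred_age,
            threshold=config.acceleration_threshold)
        records["analysis_group"] = groups_all.loc[apply_ids].to_numpy()
        records.to_csv(out / "age_acceleration.tsv", sep="\t")
        emit("accelerate", out / "age_acceleration.tsv")

        disease = records[records["analysis_group"] == "disease"]
        tail_counts = disease["accel_class"].value_counts()
        path = out / "accelerated_vs_decelerated.tsv"
        if tail_counts.get("accelerated", 0) >= 2 and \
                tail_counts.get("decelerated", 0) >= 2:
            comparison = compare_characteristics(
                meta_all.loc[disease.index], disease["accel_class"],
                {"age_actual": "continuous", "fev1": "continuous",
                 "fvc": "continuous", "fev1_fvc": "continuous",
                 "emphysema_laa": "continuous", "sex": "categorical",
                 "smoking_status": "categorical", "diabetes": "categorical",
                 "heart_attack": "categorical",
                 "coronary_artery_disease": "categorical",
                 "chronic_bronchitis": "categorical"})
        else:
            # tails too thin to compare (small runs); emit an empty table
            comparison = pd.DataFrame(
                columns=["characteristic", "type", "test", "statistic", "p"])
        comparison.to_csv(path, sep="\t", index=False)
        emit("accelerate", path)
    except Exception as exc:
        raise StageError("accelerate", exc) from exc

    # -- stage 6: associations ------------------------------------------------
    try:
        ctrl_all = groups_all.index[groups_all == "control_training"]
        assoc_age = univariate_assoc(
            proc_all.loc[ctrl_all], meta_all.loc[ctrl_all, "age_actual"], "age")
        assoc_ratio = univariate_assoc(
            proc_all, meta_all.loc[proc_all.index, "fev1_fvc"], "fev1_fvc")
        assoc_age.to_csv(out / "assoc_age_controls.tsv", sep="\t")
        assoc_ratio.to_csv(out / "assoc_fev1_fvc_all.tsv", sep="\t")
        quad = concordance_quadrants(assoc_age, assoc_ratio,
                                     alpha=config.association_alpha)
        quad.to_frame().to_csv(out / "concordance_quadrants.tsv", sep="\t")
        for f in ("assoc_age_controls.tsv", "assoc_fev1_fvc_all.tsv",
                  "concordance_quadrants.tsv"):
            emit("associate", out / f)
    except Exception as exc:
        raise StageError("associate", exc) from exc

    # -- stage 7: overlap and enrichment --------------------------------------
    try:
        universe = proc_a.metabolite_ids
        overlap = set_overlap_test(age_model.metabolite_ids,
                                   obstr_model.metabolite_ids, universe)
        (out / "score_overlap.json").write_text(
            json.dumps(overlap.__dict__, indent=1))
        emit("enrich", out / "score_overlap.json")
        if truth is not None:
            for label, sel in (("age", age_model.metabolite_ids),
                               ("obstruction", obstr_model.metabolite_ids)):
                for level in config.ora_levels:
                    ora = pathway_ora(sel, truth.annotation, level=level,
                                      universe=universe)
                    path = out / f"ora_{label}_{level}.tsv"
                    ora.to_csv(path, sep="\t", index=False)
                    emit("enrich", path)
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    manifest = {
        "version": __version__,
        "seed": int(config.seed),
        "config_hash": _config_hash(config),
        "library_versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
        },
        "stages": stage_outputs,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
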