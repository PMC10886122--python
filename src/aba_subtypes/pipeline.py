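"""End-to-end orchestration: simulate -> brain age -> stratify -> cluster -> characterize.

Each stage persists its artifacts (delimited tables / JSON documents)
under the run's output directory and the run ends with a manifest
recording the configuration, per-stage row counts and SHA-256 checksums
of every file — two runs with the same configuration and seed are
file-identical.  A single global seed deterministically derives
per-stage sub-seeds so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brain_age import (
    DEFAULT_ALPHA_GRID,
    evaluate_mae,
    fit_brainage_model,
    predict_brainage,
    split_cohort,
)
from .characterize import characterize_subtypes
from .cohort_io import Cohort, filter_complete_cases, write_cohort
from .hydra import cluster_stability, fit_hydra, residualize_covariates
from .stratification import ABA, RBA, stratification_summary, stratify
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("aba_subtypes")

STAGES = ("simulate", "brainage", "stratify", "cluster", "characterize")


@dataclass
class RunConfig:
    """Everything a full run needs; defaults follow the study design
    (40/60 split, six-point penalty grid, residual bias correction,
    K in 2..5 with five-fold stability CV, q < 0.01 over the IDPs)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    train_fraction: float = 0.40
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    correction_mode: str = "residual"
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_folds: int = 5
    n_init: int = 10
    stability_n_init: int | None = None  # fewer fused runs inside stability CV
    C: float = 1.0
    q_threshold: float = 0.01
    alpha_level: float = 0.05
    seed: int = 0
    output_dir: str = "aba_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if isinstance(gen, dict):
            for k in ("age_range", "covariate_effects", "subtype_fractions"):
                if gen.get(k) is not None:
                    gen[k] = tuple(gen[k])
            gen = GeneratorConfig(**gen)
        for k in ("alpha_grid", "k_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(generator=gen, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=float))
    return path


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute all stages and return the manifest (also persisted as JSON).

    A user-supplied ``cohort`` replaces the simulate stage's synthetic
    one; ground-truth comparisons are then skipped.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": {},
        "files": {},
    }
    files: list[Path] = []

    def finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        log.info("stage %s done (%.1fs): %s", name, time.time() - t0, info)

    try:
        # -- simulate ---------------------------------------------------
        t0 = time.time()
        truth = None
        if cohort is None:
            gen = dataclasses.replace(config.generator, seed=seeds[0])
            cohort, truth = generate_cohort(gen)
            files.append(write_cohort(cohort, out / "cohort.csv"))
            truth_df = pd.DataFrame(
                {
                    "subject_id": cohort.subject_ids,
                    "aba_flag": truth.aba_flag.loc[cohort.subject_ids].to_numpy().astype(int),
                    "subtype": truth.labels_for(cohort.subject_ids),
                }
            )
            truth_df.to_csv(out / "ground_truth.csv", index=False)
            files.append(out / "ground_truth.csv")
        files.append(config.to_yaml(out / "run_config.yaml"))
        cohort.schema.to_yaml(out / "schema.yaml")
        files.append(out / "schema.yaml")
        finish_stage("simulate", t0, n_subjects=cohort.n_subjects)

        # -- brain age --------------------------------------------------
        t0 = time.time()
        # complete-case rule: subjects must have every covariate, cognitive
        # score and IDP (identity on synthetic cohorts)
        required = (
            list(cohort.schema.covariate_columns)
            + list(cohort.schema.cognitive_columns)
            + list(cohort.schema.idp_columns)
        )
        cohort = filter_complete_cases(cohort, required)
        train, test = split_cohort(cohort, config.train_fraction, seed=seeds[1])
        results = {}
        maes = {}
        pred_frames = []
        for modality in cohort.schema.modality_blocks:
            model = fit_brainage_model(
                train,
                modality,
                alpha_grid=config.alpha_grid,
                seed=seeds[1],
                correction_mode=config.correction_mode,
            )
            model.to_json(out / f"brainage_model_{modality}.json")
            files.append(out / f"brainage_model_{modality}.json")
            res = predict_brainage(model, test)
            results[modality] = res
            maes[modality] = evaluate_mae(res.predicted_raw, res.chronological_age)
            pred_frames.append(res.to_frame().set_index("subject_id"))
        preds = pd.concat(pred_frames, axis=1)
        preds = preds.loc[:, ~preds.columns.duplicated()]
        preds.insert(0, "subject_id", preds.index)
        preds.to_csv(out / "brainage_predictions.csv", index=False)
        files.append(out / "brainage_predictions.csv")
        finish_stage(
            "brainage",
            t0,
            n_train=train.n_subjects,
            n_test=test.n_subjects,
            test_mae_raw={k: round(v, 4) for k, v in maes.items()},
        )

        # -- stratify ---------------------------------------------------
        t0 = time.time()
        strat = stratify(
            results["sMRI"].brainage_series(),
            results["dMRI"].brainage_series(),
            results["rsfMRI"].brainage_series(),
        )
        strat.to_frame().to_csv(out / "stratification.csv", index=False)
        files.append(out / "stratification.csv")
        summary = stratification_summary(strat)
        files.append(_write_json(summary, out / "stratification_summary.json"))
        finish_stage("stratify", t0, **summary)

        # -- cluster ----------------------------------------------------
        t0 = time.time()
        aba_ids = strat.ids_in_group(ABA)
        rba_ids = strat.ids_in_group(RBA)
        if len(aba_ids) < max(config.k_range) * 2 or len(rba_ids) < 2:
            raise RuntimeError(
                f"too few subjects to cluster (ABA={len(aba_ids)}, RBA={len(rba_ids)})"
            )
        keep_ids = np.concatenate([rba_ids, aba_ids])
        sub = test.data.set_index(test.schema.id_column).loc[keep_ids]
        feats = residualize_covariates(
            sub.loc[:, list(test.schema.idp_columns)].to_numpy(dtype=float),
            sub.loc[:, list(test.schema.covariate_columns)].to_numpy(dtype=float),
            reference_mask=np.isin(keep_ids, rba_ids),
            feature_names=test.schema.idp_columns,
        )
        is_target = np.isin(keep_ids, aba_ids)
        curve = cluster_stability(
            feats,
            is_target,
            k_range=config.k_range,
            n_folds=config.n_folds,
            n_init=config.stability_n_init or config.n_init,
            C=config.C,
            seed=seeds[2],
        )
        curve.to_frame().to_csv(out / "stability_curve.csv", index=False)
        files.append(out / "stability_curve.csv")
        model = fit_hydra(
            feats,
            is_target,
            curve.selected_k,
            C=config.C,
            n_init=config.n_init,
            seed=seeds[3],
        )
        model.to_json(out / "polytope_model.json")
        files.append(out / "polytope_model.json")
        labels = pd.DataFrame(
            {
                "subject_id": keep_ids[is_target],
                "subtype": model.assignments + 1,  # 1-based in files
            }
        )
        labels.to_csv(out / "subtype_labels.csv", index=False)
        files.append(out / "subtype_labels.csv")
        finish_stage(
            "cluster",
            t0,
            selected_k=curve.selected_k,
            mean_ari={str(k): round(v, 4) for k, v in curve.mean_ari.items()},
            subtype_sizes=np.bincount(model.assignments).tolist(),
        )

        # -- characterize -----------------------------------------------
        t0 = time.time()
        group = pd.Series(RBA, index=pd.Index(rba_ids, name="subject_id"))
        sub_labels = pd.Series(
            [f"SubGroup {s}" for s in labels["subtype"]],
            index=pd.Index(labels["subject_id"], name="subject_id"),
        )
        group = pd.concat([group, sub_labels])
        report = characterize_subtypes(
            test,
            group,
            q_threshold=config.q_threshold,
            alpha=config.alpha_level,
            random_state=seeds[4],
        )
        report.idp_table.to_csv(out / "report_idps.csv", index=False)
        report.cognitive_table.to_csv(out / "report_cognitive.csv", index=False)
        report.qualitative_table.to_csv(out / "report_qualitative.csv", index=False)
        files += [
            out / "report_idps.csv",
            out / "report_cognitive.csv",
            out / "report_qualitative.csv",
        ]
        files.append(_write_json(report.summary(), out / "report_summary.json"))
        finish_stage("characterize", t0, **report.summary())
    except Exception as exc:
        # persist what we have, then re-raise with stage context
        done = list(manifest["stages"])
        stage = STAGES[len(done)] if len(done) < len(STAGES) else "?"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest["files"] = {f.name: _sha256(f) for f in files}
    _write_json(manifest, out / "manifest.json")
    return manifest
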