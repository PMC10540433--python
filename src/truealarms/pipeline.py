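"""End-to-end orchestration: simulate, train, sweep, audit, trend.

The pipeline runs the full study procedure — generate a cohort, hold out
a test split, impute with training statistics, tune and select the
classifier, score the test split, sweep specificity levels on two grids,
audit follow-up risk, and fit the trend regressions — writing every
interface table (CSV/JSON) plus a manifest with per-file checksums.

Reproducibility: a single master seed deterministically derives one seed
per stage (keyed by stage name via BLAKE2), so any stage can be re-run in
isolation and two runs with equal master seeds are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .audit import audit_sweep, audit_table
from .cohort import (
    CohortTable,
    GeneratorConfig,
    generate_cohort,
    impute_simple,
    read_cohort,
    write_cohort,
)
from .model import (
    ModelSpec,
    SplitParams,
    score,
    split_cohort,
    tune_and_select,
)
from .thresholds import SpecificityGrid, sweep, sweep_table
from .trends import convergence_trends, rr_trend, severity_profiles

__all__ = ["RunConfig", "RunManifest", "stage_seed", "run_pipeline"]

logger = logging.getLogger("truealarms")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, keyed by stage name."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    split: SplitParams = field(default_factory=SplitParams)
    coarse_grid: SpecificityGrid = field(default_factory=SpecificityGrid.coarse)
    fine_grid: SpecificityGrid = field(default_factory=SpecificityGrid.fine)
    scales_for_convergence: list[str] | None = None  # default: all signal scales
    output_dir: Path = Path("results/run")
    master_seed: int = 0

    def with_seeds(self) -> "RunConfig":
        """Derive per-stage seeds from the master seed."""
        gen = dataclasses.replace(
            self.generator, seed=stage_seed(self.master_seed, "generate")
        )
        mdl = dataclasses.replace(
            self.model, seed=stage_seed(self.master_seed, "model")
        )
        spl = dataclasses.replace(
            self.split, seed=stage_seed(self.master_seed, "split")
        )
        return dataclasses.replace(self, generator=gen, model=mdl, split=spl)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs: dict = {}
        if "generator" in d:
            kwargs["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "model" in d:
            kwargs["model"] = ModelSpec(**d["model"])
        if "split" in d:
            kwargs["split"] = SplitParams(**d["split"])
        if "coarse_grid" in d:
            kwargs["coarse_grid"] = SpecificityGrid(tuple(d["coarse_grid"]))
        if "fine_grid" in d:
            kwargs["fine_grid"] = SpecificityGrid(tuple(d["fine_grid"]))
        for key in ("scales_for_convergence", "master_seed"):
            if key in d:
                kwargs[key] = d[key]
        if "output_dir" in d:
            kwargs["output_dir"] = Path(d["output_dir"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    derived_seeds: dict
    outputs: dict  # file name -> sha256
    version: str
    timings: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    return {
        "generator": config.generator.to_dict(),
        "model": {
            "learner_name": config.model.learner_name,
            "hyperparameters": config.model.hyperparameters,
            "n_candidates": config.model.n_candidates,
            "cv_folds": config.model.cv_folds,
            "selection_metric": config.model.selection_metric,
            "seed": config.model.seed,
        },
        "split": dataclasses.asdict(config.split),
        "coarse_grid": list(config.coarse_grid.levels),
        "fine_grid": list(config.fine_grid.levels),
        "scales_for_convergence": config.scales_for_convergence,
        "master_seed": config.master_seed,
    }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full study procedure and write all interface files.

    Stage order: generate -> split -> impute (train statistics) ->
    tune_and_select -> score(test) -> sweep (coarse and fine grids) ->
    audit -> rr_trend -> severity profiles -> convergence trends.
    Wave-2 columns are never visible to the model (guarded in the model
    module); they are first read by the audit stage.
    """
    config = config.with_seeds()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def record(path: Path) -> None:
        outputs[path.name] = _sha256(path)

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc_type is not None:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    with stage("generate"):
        cohort = generate_cohort(config.generator)
        write_cohort(cohort, out / "cohort.csv")
        record(out / "cohort.csv")
        record(out / "cohort.csv.json")

    with stage("split"):
        split = split_cohort(cohort, config.split)
        (out / "split.json").write_text(
            json.dumps(
                {
                    "train_ids": split.train_ids.tolist(),
                    "test_ids": split.test_ids.tolist(),
                    "train_fraction": split.train_fraction,
                    "stratified": split.stratified,
                    "seed": split.seed,
                }
            )
        )
        record(out / "split.json")

    with stage("impute"):
        imputed = impute_simple(cohort, train_ids=split.train_ids)
        train = imputed.subset(split.train_ids)
        test = imputed.subset(split.test_ids)

    with stage("train"):
        model, cv_metrics = tune_and_select(train, config.model)

    with stage("score"):
        test_scores = score(model, test)
        test_labels = test.data.set_index("subject_id")["y1"]
        from .model import auprc, auroc

        metrics = {
            "cv": cv_metrics.to_dict(),
            "test_auprc": auprc(test_scores, test_labels),
            "test_auroc": auroc(test_scores, test_labels),
        }
        (out / "model_metrics.json").write_text(json.dumps(metrics, indent=2))
        record(out / "model_metrics.json")
        test_scores.rename("score").to_csv(out / "scores.csv")
        record(out / "scores.csv")

    with stage("sweep"):
        coarse = sweep(test_scores, test_labels, config.coarse_grid)
        fine = sweep(test_scores, test_labels, config.fine_grid)
        sweep_table(coarse).to_csv(out / "sweep_coarse.csv", index=False)
        sweep_table(fine).to_csv(out / "sweep_fine.csv", index=False)
        record(out / "sweep_coarse.csv")
        record(out / "sweep_fine.csv")

    with stage("audit"):
        audit = audit_sweep(coarse, cohort)
        audit_table(audit).to_csv(out / "audit.csv", index=False)
        record(out / "audit.csv")

    with stage("trend"):
        trends_out: dict = {}
        try:
            fit, excluded = rr_trend(audit)
            trends_out["rr_trend"] = {**fit.to_dict(), "excluded_levels": excluded}
        except ValueError as exc:
            trends_out["rr_trend"] = {"error": str(exc)}
        scales = config.scales_for_convergence
        if scales is None:
            scales = [f for f in cohort.feature_names if f.startswith("scale_")]
        profiles = severity_profiles(cohort, fine, scales)
        profiles.to_csv(out / "profiles.csv", index=False)
        record(out / "profiles.csv")
        conv = {}
        if not profiles.empty:
            for scale, (fit_s, n_used) in convergence_trends(profiles).items():
                conv[scale] = (
                    {"error": "insufficient common levels"}
                    if fit_s is None
                    else {**fit_s.to_dict(), "n_levels": n_used}
                )
        trends_out["convergence"] = conv
        (out / "trends.json").write_text(json.dumps(trends_out, indent=2))
        record(out / "trends.json")

    manifest = RunManifest(
        config=_config_echo(config),
        derived_seeds={
            "generate": config.generator.seed,
            "model": config.model.seed,
            "split": config.split.seed,
        },
        outputs=outputs,
        version=__version__,
        timings=timings,
    )
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest
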