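"""End-to-end orchestration: simulate -> calibrate -> qc -> moisture ->
preprocess -> model, with every stage's inputs and outputs persisted as CSV
or JSON and a manifest recording stage order, seed, and file checksums."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import calibration, models, preprocess, qc, simulate
from .io import write_profile_csv, write_table
from .moisture import moisture_table

DEFAULT_STAGES = ("simulate", "calibrate", "qc", "moisture", "preprocess", "model")
EXPOSURE_TIMES_S = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "runs/demo"
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    detection_ratio: float = 1.0 / 3.0
    improvement_threshold_pct: float = 33.0
    zero_threshold: float = 0.8
    r_threshold: float = 0.8
    alpha: float = 0.05
    train_fraction: float = 0.8
    k_folds: int = 5
    mtry_grid: tuple[int, ...] = models.DEFAULT_MTRY_GRID
    ntree_grid: tuple[int, ...] = models.DEFAULT_NTREE_GRID
    n_calibration_pairs: int = 12
    n_repeat_exposures: int = 5
    exposure_jitter_cv: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")
        if not (0 <= self.zero_threshold <= 1) or not (0 <= self.r_threshold <= 1):
            raise ValueError("filter thresholds must be in [0, 1]")
        if self.detection_ratio <= 0 or self.improvement_threshold_pct <= 0:
            raise ValueError("QC thresholds must be positive")
        unknown = [s for s in self.stages if s not in DEFAULT_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stages", "mtry_grid", "ntree_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = asdict(self)
        for key in ("stages", "mtry_grid", "ntree_grid"):
            data[key] = list(data[key])
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stateful single run; stages consume the outputs of earlier stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.generator = dataclasses.replace(
            simulate.default_config(seed=config.seed), apply_bias_to_profile=True
        )
        self.profile: pd.DataFrame | None = None
        self.calibrated: pd.DataFrame | None = None
        self.scaled: pd.DataFrame | None = None
        self.written: list[Path] = []
        self.stage_log: list[str] = []

    def _record(self, path: Path) -> None:
        self.written.append(path)

    def _working_table(self) -> pd.DataFrame:
        table = self.calibrated if self.calibrated is not None else self.profile
        if table is None:
            raise RuntimeError("no profile table available; run the simulate stage first")
        return table

    def stage_simulate(self) -> None:
        self.profile = simulate.generate_profile_table(self.generator)
        self._record(write_profile_csv(self.profile, self.outdir / "profile.csv"))

    def stage_calibrate(self) -> None:
        gen = self.generator
        pairs = {
            el: (
                simulate.generate_paired_calibration_set(
                    gen, el, self.config.n_calibration_pairs
                )
                if el in gen.bias_slope
                else None
            )
            for el in gen.element_roster
        }
        factors = calibration.fit_correction_factors(pairs)
        self._record(factors.to_csv(self.outdir / "correction_factors.csv"))
        self.calibrated, _flags = calibration.apply_correction(self._working_table(), factors)
        self._record(
            write_profile_csv(self.calibrated, self.outdir / "calibrated_profile.csv")
        )

    def stage_qc(self) -> None:
        cfg = self.config
        det = qc.detection_filter(self._working_table(), ratio=cfg.detection_ratio)
        self._record(write_table(det.stats, self.outdir / "detection_report.csv"))
        series = simulate.generate_exposure_series(
            self.generator, EXPOSURE_TIMES_S, jitter_cv=cfg.exposure_jitter_cv
        )
        selections = [
            qc.select_exposure_time(s, cfg.improvement_threshold_pct) for s in series
        ]
        self._record(
            write_table(
                qc.exposure_report(selections, series), self.outdir / "exposure_report.csv"
            )
        )
        repeats = simulate.generate_repeat_exposures(self.generator, cfg.n_repeat_exposures)
        self._record(
            write_table(
                qc.repeatability_summary(repeats), self.outdir / "repeatability_report.csv"
            )
        )

    def stage_moisture(self) -> None:
        pairs_tbl = simulate.generate_moisture_pairs(self.generator)
        self._record(pairs_tbl.to_csv(self.outdir / "moisture_pairs.csv"))
        self._record(
            write_table(
                moisture_table(pairs_tbl, alpha=self.config.alpha),
                self.outdir / "moisture_report.csv",
            )
        )

    def stage_preprocess(self) -> None:
        cfg = self.config
        self.scaled, report = preprocess.preprocess(
            self._working_table(), cfg.zero_threshold, cfg.r_threshold
        )
        self._record(write_profile_csv(self.scaled, self.outdir / "preprocessed.csv"))
        self._record(report.to_csv(self.outdir / "preprocess_report.csv"))

    def stage_model(self) -> None:
        cfg = self.config
        if self.scaled is None:
            raise RuntimeError("model stage requires the preprocess stage")
        table = self.scaled
        train, test = models.stratified_split(
            table, models.SplitSpec(train_fraction=cfg.train_fraction, seed=cfg.seed)
        )
        model, report = models.tune_random_forest(
            train,
            mtry_grid=cfg.mtry_grid,
            ntree_grid=cfg.ntree_grid,
            k_folds=cfg.k_folds,
            seed=cfg.seed,
        )
        acc, confusion, mis = models.evaluate_classifier(model, test)
        report.test_accuracy_pct = acc
        report.confusion = confusion
        report.misclassified = mis
        self._record(report.to_json(self.outdir / "model_report.json"))
        self._record(
            write_table(confusion, self.outdir / "confusion_matrix.csv", index=True)
        )
        _lda, lda_acc = models.fit_lda(train)
        lda_path = self.outdir / "lda_report.json"
        lda_path.write_text(json.dumps({"resub_accuracy_pct": lda_acc}, indent=2))
        self._record(lda_path)
        pca_res = models.pca(table)
        self._record(write_table(pca_res.scores, self.outdir / "pca_scores.csv"))
        nmds_res = models.nmds(table, seed=cfg.seed)
        self._record(
            write_table(nmds_res.coordinates, self.outdir / "nmds_coordinates.csv")
        )
        cda_res = models.cda(table)
        self._record(write_table(cda_res.scores, self.outdir / "cda_scores.csv"))
        self._record(
            write_table(cda_res.structure, self.outdir / "cda_structure.csv", index=True)
        )
        summary = {
            "n_train": len(train),
            "n_test": len(test),
            "rf_best_mtry": report.best_mtry,
            "rf_best_ntree": report.best_ntree,
            "rf_cv_accuracy_pct": report.cv_accuracy_pct,
            "rf_test_accuracy_pct": acc,
            "lda_resub_accuracy_pct": lda_acc,
            "nmds_stress": nmds_res.stress,
            "seed": cfg.seed,
        }
        summary_path = self.outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        self._record(summary_path)

    def run(self) -> Path:
        self.outdir.mkdir(parents=True, exist_ok=True)
        handlers = {
            "simulate": self.stage_simulate,
            "calibrate": self.stage_calibrate,
            "qc": self.stage_qc,
            "moisture": self.stage_moisture,
            "preprocess": self.stage_preprocess,
            "model": self.stage_model,
        }
        for stage in DEFAULT_STAGES:
            if stage not in self.config.stages:
                continue
            try:
                handlers[stage]()
            except Exception as exc:  # noqa: BLE001 - halt with stage context
                raise StageError(stage, exc) from exc
            self.stage_log.append(stage)
        self.config.to_yaml(self.outdir / "resolved_config.yaml")
        manifest = {
            "stages": self.stage_log,
            "seed": self.config.seed,
            "files": {
                p.name: _sha256(p)
                for p in sorted(set(self.written), key=lambda p: p.name)
            },
        }
        (self.outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return self.outdir


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages and return the run directory."""
    return PipelineRun(config).run()
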