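"""File-based pipeline stages behind a single YAML configuration.

Stages (``simulate -> parametric -> extract -> train -> evaluate``) read
and write standard formats under ``output_dir`` and each leaves a manifest
with the config hash and the seeds needed to regenerate its artifacts.
Stage defaults follow the published protocol: 5–15 / 20–40 min windows,
TBR threshold 1.6, 2.03-mm isotropic resampling, bin widths 0.18 / 0.13 /
5.0 (or derived via the IQR/4 rule on the training cohort), a stratified
70/30 split, 10-fold CV with PCC dedup at 0.99, and 1000 bootstrap
resamples.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .frames import default_frame_schedule
from .modeling import evaluate, stratified_split
from .parametric import segment_tumour, tbr_from_study, ttp_image
from .radiomics import DiscretizationRule, extract_all, iqr4_bin_width
from .synthetic import CohortSpec, iter_phantom
from .workflow import (
    DEFAULT_BIN_WIDTHS,
    EARLY_WINDOW_MIN,
    LATE_WINDOW_MIN,
    SEGMENT_THRESHOLD,
    fit_pipeline_model,
    predict_pipeline,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

STAGES = ("simulate", "parametric", "extract", "train", "evaluate")
KINDS = ("TBR_5_15", "TBR_20_40", "TTP")


@dataclass
class PipelineConfig:
    output_dir: str = "dynfet_run"
    kinds: tuple = KINDS
    synthetic: dict = field(
        default_factory=lambda: {
            "n_patients": 40,
            "wildtype_fraction": 0.2,
            "seed": 0,
            "effect": 1.0,
            "noise_sd": 0.05,
        }
    )
    windows: dict = field(
        default_factory=lambda: {"early": list(EARLY_WINDOW_MIN), "late": list(LATE_WINDOW_MIN)}
    )
    segmentation_threshold: float = SEGMENT_THRESHOLD
    resample_mm: float = 2.03
    bin_widths: dict = field(default_factory=lambda: dict(DEFAULT_BIN_WIDTHS))
    split: dict = field(default_factory=lambda: {"train_fraction": 0.7, "seed": 0})
    selection: dict = field(default_factory=lambda: {"folds": 10, "pcc_threshold": 0.99})
    bootstrap: dict = field(default_factory=lambda: {"n": 1000, "seed": 0})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            default = getattr(cfg, k)
            if isinstance(default, dict) and isinstance(v, dict):
                default.update(v)
            else:
                setattr(cfg, k, tuple(v) if isinstance(default, tuple) else v)
        return cfg

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _out(config: PipelineConfig) -> Path:
    return Path(config.output_dir)


def _manifest(config: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    from . import __version__

    payload = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "version": __version__,
        **(extra or {}),
    }
    path = _out(config) / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=1, default=str))


def _require(config: PipelineConfig, path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def _patient_ids(labels: pd.Series) -> list[str]:
    return list(labels.index)


def _stage_simulate(config: PipelineConfig) -> None:
    out = _out(config)
    (out / "studies").mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(**config.synthetic)
    labels, truth = {}, {}
    for i, ph in enumerate(iter_phantom(spec)):
        pid = f"P{i:03d}"
        labels[pid] = ph.label
        truth[pid] = ph.truth
        dio.write_study(ph.study, out / "studies" / f"{pid}_study.nii.gz")
        dio.write_mask(
            ph.tumour, ph.study.voxel_spacing_mm, out / "studies" / f"{pid}_tumour_truth.nii.gz"
        )
        dio.write_mask(
            ph.background, ph.study.voxel_spacing_mm, out / "studies" / f"{pid}_background.nii.gz"
        )
    labels = pd.Series(labels).sort_index()
    dio.write_labels(labels, out / "labels.csv")
    pd.DataFrame.from_dict(truth, orient="index").to_csv(out / "ground_truth.csv")
    (out / "cohort_spec.yaml").write_text(yaml.safe_dump(asdict(spec)))
    logger.info(
        "simulate: %d patients (%d wildtype / %d mutant)",
        len(labels), int((labels == 0).sum()), int((labels == 1).sum()),
    )
    _manifest(config, "simulate", {"n_patients": len(labels)})


def _stage_parametric(config: PipelineConfig) -> None:
    out = _out(config)
    labels = dio.read_labels(_require(config, out / "labels.csv", "simulate"))
    (out / "parametric").mkdir(exist_ok=True)
    schedule = default_frame_schedule()
    n_neg = 0
    for pid in _patient_ids(labels):
        study = dio.read_study(out / "studies" / f"{pid}_study.nii.gz", schedule)
        background = dio.read_mask(out / "studies" / f"{pid}_background.nii.gz", "background")
        late = tbr_from_study(study, background, tuple(config.windows["late"]), "TBR_20_40")
        tumour = segment_tumour(late, config.segmentation_threshold)
        early = tbr_from_study(study, background, tuple(config.windows["early"]), "TBR_5_15")
        ttp = ttp_image(study, tumour)
        sched_hash = dio.schedule_hash(schedule)
        for img, name in ((late, "TBR_20_40"), (early, "TBR_5_15"), (ttp, "TTP")):
            img.meta["schedule_hash"] = sched_hash
            img.meta["threshold"] = config.segmentation_threshold
            dio.write_parametric(img, out / "parametric" / f"{pid}_{name}.nii.gz")
        dio.write_mask(tumour, study.voxel_spacing_mm, out / "parametric" / f"{pid}_tumour.nii.gz")
    logger.info("parametric: %d studies, %d FET-negative", len(labels), n_neg)
    _manifest(config, "parametric")


def _resolve_bin_width(config: PipelineConfig, kind: str, per_patient_values: list) -> float:
    width = config.bin_widths.get(kind, DEFAULT_BIN_WIDTHS[kind])
    if width == "derive-by-iqr4":
        return iqr4_bin_width(per_patient_values)
    return float(width)


def _stage_extract(config: PipelineConfig) -> None:
    out = _out(config)
    labels = dio.read_labels(_require(config, out / "labels.csv", "simulate"))
    _require(config, out / "parametric", "parametric")
    split = stratified_split(labels, config.split["train_fraction"], config.split["seed"])

    rows = []
    for kind in config.kinds:
        images, masks = {}, {}
        for pid in _patient_ids(labels):
            images[pid] = dio.read_parametric(out / "parametric" / f"{pid}_{kind}.nii.gz")
            masks[pid] = dio.read_mask(out / "parametric" / f"{pid}_tumour.nii.gz")
        train_values = [
            images[pid].grid[masks[pid].grid] for pid in split.train_ids
        ]
        width = _resolve_bin_width(config, kind, train_values)
        rule = DiscretizationRule(width)
        for pid in _patient_ids(labels):
            feats = extract_all(images[pid], masks[pid], rule, resample_mm=config.resample_mm)
            rows.extend(
                {
                    "patient_id": pid,
                    "image_kind": kind,
                    "feature_name": k,
                    "value": v,
                    "bin_width": width,
                }
                for k, v in feats.items()
                if not k.startswith("_")
            )
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)
    _manifest(config, "extract")


def _load_feature_tables(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    out = _out(config)
    df = pd.read_csv(_require(config, out / "features.csv", "extract"))
    tables = {}
    for kind, sub in df.groupby("image_kind"):
        tables[kind] = sub.pivot(
            index="patient_id", columns="feature_name", values="value"
        ).sort_index()
    return tables


def _stage_train(config: PipelineConfig) -> None:
    out = _out(config)
    labels = dio.read_labels(_require(config, out / "labels.csv", "simulate"))
    tables = _load_feature_tables(config)
    split = stratified_split(labels, config.split["train_fraction"], config.split["seed"])
    (out / "models").mkdir(exist_ok=True)
    for kind in config.kinds:
        table = tables[kind]
        tr = list(split.train_ids)
        fitted = fit_pipeline_model(
            table.loc[tr],
            labels.loc[tr],
            folds=config.selection["folds"],
            pcc_threshold=config.selection["pcc_threshold"],
            seed=config.split["seed"],
        )
        model_json = {
            "kind": kind,
            "selected_features": list(fitted.model.selected_features),
            "theta": fitted.model.theta.tolist(),
            "intercept": fitted.model.intercept,
            "class_weights": {str(k): v for k, v in fitted.model.class_weights.items()},
            "standardization": {
                "mean": fitted.standardization.mean.to_dict(),
                "sd": fitted.standardization.sd.to_dict(),
            },
            "retained_after_pcc": list(fitted.retained_features),
            "n_selected": fitted.n_selected,
            "seed": config.split["seed"],
            "config_hash": config.config_hash(),
        }
        (out / "models" / f"model_{kind}.json").write_text(json.dumps(model_json, indent=1))
        pd.DataFrame(
            {"n_features": np.arange(1, len(fitted.cv_auc_per_n) + 1), "mean_cv_auc": fitted.cv_auc_per_n}
        ).to_csv(out / "models" / f"cv_curve_{kind}.csv", index=False)
        logger.info("train[%s]: selected %d features", kind, fitted.n_selected)
    _manifest(config, "train")


def _stage_evaluate(config: PipelineConfig) -> None:
    out = _out(config)
    labels = dio.read_labels(_require(config, out / "labels.csv", "simulate"))
    _require(config, out / "models", "train")
    tables = _load_feature_tables(config)
    split = stratified_split(labels, config.split["train_fraction"], config.split["seed"])
    metrics = {}
    for kind in config.kinds:
        model_path = _require(config, out / "models" / f"model_{kind}.json", "train")
        spec = json.loads(model_path.read_text())
        from .modeling import LogisticModel, StandardizationParams
        from .workflow import FittedPipeline

        fitted = FittedPipeline(
            standardization=StandardizationParams(
                pd.Series(spec["standardization"]["mean"]),
                pd.Series(spec["standardization"]["sd"]),
            ),
            retained_features=tuple(spec["retained_after_pcc"]),
            model=LogisticModel(
                tuple(spec["selected_features"]),
                np.asarray(spec["theta"]),
                spec["intercept"],
                spec["class_weights"],
            ),
            n_selected=spec["n_selected"],
            cv_auc_per_n=np.array([]),
            elimination_order=(),
        )
        metrics[kind] = {}
        for name, ids in (("train", list(split.train_ids)), ("test", list(split.test_ids))):
            probs = predict_pipeline(fitted, tables[kind].loc[ids])
            report = evaluate(
                probs,
                labels.loc[ids].to_numpy(),
                n_bootstrap=config.bootstrap["n"],
                seed=config.bootstrap["seed"],
            )
            metrics[kind][name] = {
                "metrics": report.metrics,
                "ci95": {k: list(v) for k, v in report.ci95.items()},
                "n": len(ids),
            }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, default=float))
    _manifest(config, "evaluate")


def run_stage(config: PipelineConfig, stage: str) -> None:
    """Run one pipeline stage (or ``all``); artifacts land under ``output_dir``."""
    _out(config).mkdir(parents=True, exist_ok=True)
    if stage == "all":
        for s in STAGES:
            run_stage(config, s)
        return
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    {
        "simulate": _stage_simulate,
        "parametric": _stage_parametric,
        "extract": _stage_extract,
        "train": _stage_train,
        "evaluate": _stage_evaluate,
    }[stage](config)
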