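"""Config-driven end-to-end runs: simulate → (preprocess) → split → train →
predict → reference-seg → evaluate → quantify → group statistics.

A run is fully determined by ``(config, seed)``: every stage draws its
randomness from the global seed, each stage writes its artifacts under
the output directory, and completed stages are skipped on resume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .cnn import UNetSegmenter, predict_volume, split_dataset
from .cnn import volume_to_slices
from .core import CohortManifest, VolumeImage
from .experiments import DESK_CLASS_WEIGHTS
from .metrics import aggregate_group, evaluate_examination
from .phantom import DESK_DIMS, DESK_SPACING, desk_group_configs, \
    generate_cohort, split_into_stations
from .preprocess import median_filter_volume, merge_stations, register_stations
from .reference import reference_segment
from .stats import cohort_report, fat_volumes

log = logging.getLogger("adiposeg")

__all__ = ["RunConfig", "default_config", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


REQUIRED_KEYS = ("seed", "out_dir", "cohort", "train")


def default_config(out_dir: str = "runs/demo", seed: int = 0) -> dict:
    """The desk-scale run configuration (all stages, small geometry)."""
    return {
        "seed": seed,
        "out_dir": out_dir,
        "cohort": {"n_per_group": 16,
                   "dims": list(DESK_DIMS), "spacing": list(DESK_SPACING)},
        "preprocess": {"enabled": False, "n_stations": 2, "overlap_slices": 2,
                       "max_shift_voxels": 1, "median_kernel": [3, 3, 3]},
        "train": {"epochs": 10, "batch_size": 16, "learning_rate": 1.0e-3,
                  "encoder_channels": [8, 16, 32], "bottleneck_channels": 64,
                  "dropout_rate": 0.5,
                  "class_weights": list(DESK_CLASS_WEIGHTS)},
        "evaluate": {"empty_policy": "exclude"},
        "verbosity": "info",
    }


@dataclasses.dataclass
class RunConfig:
    raw: dict

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        missing = [k for k in REQUIRED_KEYS if k not in mapping]
        if missing:
            raise ConfigError(f"config missing required key(s): {missing}")
        return cls(raw=dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)


def _stage(name, out_dir, resume, products, fn):
    """Run one stage unless all its products already exist."""
    paths = [out_dir / p for p in products]
    if resume and paths and all(p.exists() for p in paths):
        log.info("stage %-14s cached", name)
        return False
    t0 = time.time()
    try:
        fn()
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %-14s done in %.1fs", name, time.time() - t0)
    return True


def run_pipeline(cfg: RunConfig | dict, resume: bool = True) -> dict:
    """Execute every configured stage; returns a dict of artifact paths."""
    if isinstance(cfg, dict):
        cfg = RunConfig.from_mapping(cfg)
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging,
                                      str(cfg.get("verbosity", "info")).upper(),
                                      logging.INFO))
    (out / "config_snapshot.yaml").write_text(yaml.safe_dump(cfg.raw))

    dims = tuple(cfg["cohort"].get("dims", DESK_DIMS))
    spacing = tuple(cfg["cohort"].get("spacing", DESK_SPACING))
    n_per_group = int(cfg["cohort"].get("n_per_group", 16))
    cohort_dir = out / "cohort"

    def do_simulate():
        configs = desk_group_configs(base_seed=seed, n_subjects=n_per_group)
        generate_cohort(configs, cohort_dir, dims=dims, spacing=spacing)

    _stage("simulate", out, resume, ["cohort/manifest.json"], do_simulate)
    manifest = aio.read_manifest(cohort_dir / "manifest.json")

    pp = cfg.get("preprocess", {"enabled": False})
    if pp.get("enabled", False):
        def do_preprocess():
            rng = np.random.default_rng(seed + 101)
            b = float(pp.get("max_shift_voxels", 1))
            for s in manifest.subjects:
                v = aio.read_volume(s.volume_path)
                gt = aio.read_labelmap(s.mask_path)
                shifts = [tuple(rng.uniform(-b, b, 2)) + (0.0,)
                          for _ in range(int(pp.get("n_stations", 2)) - 1)]
                series = split_into_stations(
                    v, gt, int(pp.get("n_stations", 2)),
                    int(pp.get("overlap_slices", 2)), true_shifts=shifts)
                reg = register_stations(series, seed=seed + 202)
                merged = merge_stations(series, reg)
                merged = median_filter_volume(
                    merged, tuple(pp.get("median_kernel", (3, 3, 3))))
                aio.write_volume(merged, Path(s.volume_path))
        _stage("preprocess", out, resume, ["preprocess.done"],
               lambda: (do_preprocess(),
                        (out / "preprocess.done").write_text("ok")))

    def do_split():
        split = split_dataset(manifest, seed=seed + 1)
        aio.write_manifest(split, out / "manifest_split.json")
    _stage("split", out, resume, ["manifest_split.json"], do_split)
    manifest = aio.read_manifest(out / "manifest_split.json")

    tr = cfg["train"]
    model_dir = out / "model"

    def do_train():
        Xtr, ytr, Xv, yv = [], [], [], []
        for s in manifest.subjects:
            if s.split not in ("train", "val"):
                continue
            X, y = volume_to_slices(aio.read_volume(s.volume_path),
                                    aio.read_labelmap(s.mask_path))
            (Xtr if s.split == "train" else Xv).append(X)
            (ytr if s.split == "train" else yv).append(y)
        cw = tr.get("class_weights")
        model = UNetSegmenter(
            input_size=dims[:2],
            encoder_channels=tuple(tr.get("encoder_channels", (8, 16, 32))),
            bottleneck_channels=int(tr.get("bottleneck_channels", 64)),
            dropout_rate=float(tr.get("dropout_rate", 0.5)),
            epochs=int(tr.get("epochs", 10)),
            batch_size=int(tr.get("batch_size", 16)),
            learning_rate=float(tr.get("learning_rate", 1e-3)),
            class_weights=None if cw is None else tuple(cw),
            random_state=seed)
        val = ((np.concatenate(Xv), np.concatenate(yv)) if Xv else None)
        model.fit(np.concatenate(Xtr), np.concatenate(ytr),
                  validation_data=val)
        model.save(model_dir)
    _stage("train", out, resume, ["model/weights.npz"], do_train)
    model = UNetSegmenter.load(model_dir)

    pred_dir = out / "predicted"
    ref_dir = out / "reference"

    def do_predict():
        pred_dir.mkdir(exist_ok=True)
        ref_dir.mkdir(exist_ok=True)
        for s in manifest.by_split("test"):
            v = aio.read_volume(s.volume_path)
            aio.write_labelmap(predict_volume(model, v),
                               pred_dir / f"{s.subject_id}.nii.gz")
            aio.write_labelmap(reference_segment(v),
                               ref_dir / f"{s.subject_id}.nii.gz")
    _stage("predict", out, resume, ["predicted", "reference"], do_predict)

    def do_evaluate():
        exams, groups = [], []
        policy = cfg.get("evaluate", {}).get("empty_policy", "exclude")
        for s in manifest.by_split("test"):
            gt = aio.read_labelmap(s.mask_path)
            pred = aio.read_labelmap(pred_dir / f"{s.subject_id}.nii.gz")
            exams.append(evaluate_examination(gt, pred, empty_policy=policy))
            groups.append(s.group)
        aio.write_metrics_table(aggregate_group(exams, groups),
                                out / "metrics.csv")
    _stage("evaluate", out, resume, ["metrics.csv"], do_evaluate)

    report_dir = out / "report"

    def do_group_stats():
        report_dir.mkdir(exist_ok=True)
        predicted, reference = {}, {}
        for s in manifest.by_split("test"):
            predicted[s.subject_id] = aio.read_labelmap(
                pred_dir / f"{s.subject_id}.nii.gz")
            reference[s.subject_id] = aio.read_labelmap(
                ref_dir / f"{s.subject_id}.nii.gz")
        rep = cohort_report(manifest, predicted, reference)
        rep.volumes.to_csv(report_dir / "volumes.csv", index=False)
        pearson_rows = [{"group": g, "compartment": c, "r": r}
                        for (g, c), r in rep.pearson_r.items()]
        import pandas as pd
        pd.DataFrame(pearson_rows).to_csv(report_dir / "pearson.csv",
                                          index=False)
        (report_dir / "group_stats.json").write_text(
            json.dumps(dataclasses.asdict(rep.ratio_stats), indent=2))
    _stage("group-stats", out, resume, ["report/group_stats.json"],
           do_group_stats)

    return {"out_dir": str(out), "manifest": str(out / "manifest_split.json"),
            "model": str(model_dir), "metrics": str(out / "metrics.csv"),
            "report": str(report_dir)}
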