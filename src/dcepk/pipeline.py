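"""End-to-end orchestration: simulate -> conventional fits -> train (full and
ablation) -> sampled prediction -> evaluation report.

Everything derives from one master seed; with an output directory set, every
stage writes its artifacts (NIfTI maps, manifest, metrics, checkpoints,
report.json) stamped with the run-config hash.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from hashlib import sha256
from pathlib import Path

import numpy as np

from dcepk import io as dio
from dcepk.evaluation import ReliabilityReport, evaluate_cohort
from dcepk.nets import ModelConfig, TwoStageNet, normalize_series, save_checkpoint
from dcepk.phantom import CohortEffects, PhantomSpec, generate_cohort
from dcepk.physics import AcquisitionParams, PKMaps, TimeGrid, population_aif
from dcepk.tofts_fit import FitOptions, extract_aif, fit_volume
from dcepk.training import TrainConfig, train

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One reproducible experiment; defaults are the desk-scale conditions."""

    n_subjects: int = 50
    seed: int = 0
    # cohort
    class_mix: float = 0.5
    idh_mix: float = 0.5
    split: tuple = (0.6, 0.2, 0.2)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    effects: CohortEffects = field(default_factory=CohortEffects)
    # acquisition
    n_frames: int = 60
    dt_min: float = 1.0 / 12.0
    n_baseline: int = 5
    # conventional pathway
    rater_seeds: tuple = (101, 202)
    train_target: str = "conventional"  # or "oracle" (simulator truth)
    # networks
    model: ModelConfig = field(default_factory=ModelConfig)
    epochs_full: int = 300  # stage 2 only (stage-1 features cached), cheap
    epochs_tcn: int = 60
    batch_size: int = 2
    lr: float = 3e-3
    beta: float = 256.0  # strong prior/posterior coupling: prediction samples
    # should agree closely (the reliability claim), with uncertainty still > 0
    n_samples: int = 4
    train_ablation: bool = True

    def hash(self) -> str:
        return sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


def _subject_slice(subject, n_baseline: int) -> np.ndarray:
    return normalize_series(subject.dce.data[:, :, 0, :], n_baseline)


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Run every stage; returns a dict with the cohort, models and report.

    With ``out_dir`` set, artifacts are written beneath it (stage failures
    raise with the stage name attached).
    """
    t_start = time.time()
    cfg = config
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    run_log: list[dict] = []

    def stage(name):
        log.info("stage: %s (t=%.1fs)", name, time.time() - t_start)
        run_log.append({"stage": name, "t": round(time.time() - t_start, 2)})

    grid = TimeGrid.uniform(cfg.n_frames, cfg.dt_min, cfg.n_baseline)
    acq = AcquisitionParams()
    aif_true = population_aif(grid)

    stage("simulate")
    subjects, manifest = generate_cohort(
        cfg.n_subjects, cfg.class_mix, cfg.idh_mix, cfg.effects, cfg.split,
        seed=cfg.seed, base_spec=cfg.phantom, acq=acq, grid=grid,
    )
    by_split = {s: [] for s in ("train", "valid", "test")}
    split_of = dict(zip(manifest.subject_id, manifest.split))
    for s in subjects:
        by_split[split_of[s.subject_id]].append(s)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)

    stage("fit-train-targets")
    fit_opts = FitOptions(n_starts=1)
    targets = {}
    for s in by_split["train"] + by_split["valid"]:
        if cfg.train_target == "oracle":
            targets[s.subject_id] = s.gt_maps
        else:
            sel = extract_aif(s.dce, s.masks["vessel"])
            maps, _ = fit_volume(s.dce, sel.aif, s.masks["brain"], fit_opts)
            targets[s.subject_id] = maps

    def pairs(split):
        return [
            (_subject_slice(s, cfg.n_baseline), targets[s.subject_id])
            for s in by_split[split]
        ]

    # serial two-stage training: the temporal stage (also the Table-1-style
    # ablation comparator) is trained first and warm-starts the full model
    model_tcn, hist_tcn = None, []
    if cfg.train_ablation:
        stage("train-tcn-only")
        tc_tcn = TrainConfig(
            mode="tcn_only", epochs=cfg.epochs_tcn, batch_size=cfg.batch_size,
            lr=cfg.lr, seed=cfg.seed, model=cfg.model,
        )
        model_tcn, hist_tcn = train(pairs("train"), tc_tcn, valid_data=pairs("valid"))

    stage("train-full")
    tc_full = TrainConfig(
        mode="full", epochs=cfg.epochs_full, batch_size=cfg.batch_size,
        lr=cfg.lr, beta=cfg.beta, seed=cfg.seed, model=cfg.model,
        freeze_stage1=cfg.train_ablation,  # serial scheme: stage 2 refines
    )
    warm = TwoStageNet(cfg.model)
    if model_tcn is not None:
        warm.load_temporal_stage(model_tcn)
    model_full, hist_full = train(
        pairs("train"), tc_full, valid_data=pairs("valid"), model=warm
    )

    stage("conventional-test-fits")
    conventional = {}
    for s in by_split["test"]:
        raters = []
        for r, rseed in enumerate(cfg.rater_seeds):
            sel = extract_aif(
                s.dce, s.masks["vessel"],
                rater_seed=int(rseed) * 100003 + int(s.subject_id.split("-")[1]),
                rater_id=f"rater-{r + 1}",
            )
            maps, _ = fit_volume(s.dce, sel.aif, s.masks["brain"], fit_opts)
            raters.append(maps)
        conventional[s.subject_id] = raters

    stage("predict")
    predictions, tcn_maps = {}, {}
    for i, s in enumerate(by_split["test"]):
        x = _subject_slice(s, cfg.n_baseline)
        predictions[s.subject_id] = model_full.predict(
            x, n_samples=cfg.n_samples, seed=cfg.seed * 1009 + i * 17
        )
        if model_tcn is not None:
            ps = model_tcn.predict(x, n_samples=2, seed=0, mode="tcn_only")
            tcn_maps[s.subject_id] = ps.mean_maps

    stage("evaluate")
    report = evaluate_cohort(
        by_split["test"], conventional, predictions,
        tcn_only_maps=tcn_maps or None,
    )

    if out is not None:
        stage("write-artifacts")
        meta = {"config": json.loads(json.dumps(asdict(cfg), default=str)),
                "config_hash": cfg.hash(), "stages": run_log}
        (out / "run.json").write_text(json.dumps(meta, indent=2))
        report.to_json(out / "report.json")
        from dcepk.evaluation import plot_report

        plot_report(
            report,
            {pw: {p: np.asarray(v) for p, v in per.items()}
             for pw, per in report.subject_scores.items()},
            {t: np.asarray(v) for t, v in report.labels.items()},
            out / "plots",
        )
        with open(out / "metrics.jsonl", "w") as fh:
            for rec in hist_full:
                fh.write(json.dumps({"mode": "full", **rec}) + "\n")
            for rec in hist_tcn:
                fh.write(json.dumps({"mode": "tcn_only", **rec}) + "\n")
        save_checkpoint(model_full, out / "model_full.npz")
        if model_tcn is not None:
            save_checkpoint(model_tcn, out / "model_tcn_only.npz")
        for s in by_split["test"]:
            sdir = out / "test" / s.subject_id
            dio.write_maps(s.gt_maps, sdir, prefix="gt_")
            dio.write_maps(predictions[s.subject_id].mean_maps, sdir, prefix="pred_mean_")
            dio.write_maps(predictions[s.subject_id].uncertainty_maps, sdir, prefix="pred_sd_")
            for r, maps in enumerate(conventional[s.subject_id]):
                dio.write_maps(maps, sdir, prefix=f"conv_rater{r + 1}_")

    return {
        "subjects": subjects,
        "manifest": manifest,
        "by_split": by_split,
        "targets": targets,
        "model_full": model_full,
        "model_tcn": model_tcn,
        "history_full": hist_full,
        "history_tcn": hist_tcn,
        "conventional": conventional,
        "predictions": predictions,
        "tcn_maps": tcn_maps,
        "report": report,
        "config_hash": cfg.hash(),
    }
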