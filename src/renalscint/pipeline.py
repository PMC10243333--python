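"""End-to-end experiment orchestration.

``run_experiment`` drives the whole study from one configuration object:
simulate a phantom cohort, motion-correct each series, build the
short-time/full-time pair dataset with a case-level train/validation/test
split, train the three denoising architectures, evaluate image quality on
the test split (per-method NMSE/PSNR/SSIM table, pooled joint histograms),
and quantify renal uptake with Bland-Altman agreement against the
full-time reference.  Every stage writes its artifacts under the output
directory and drops a ``<stage>.done`` sentinel; completed stages are
skipped on re-run unless ``force`` is set.  All randomness flows from one
global seed, expanded deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import build_pairs, split_cases
from .io import DynamicSeries, load_series, save_series
from .metrics import evaluate_split, joint_histogram
from .models import ArchitectureSpec, build_model, load_model, save_model
from .phantom import PhantomSpec, make_phantom_cases
from .registration import register_series
from .training import TrainConfig, predict, train
from .uptake import ROISet, agreement_analysis, bland_altman_plot, uptake_from_image

log = logging.getLogger(__name__)

STAGES = ("simulate", "register", "build-dataset", "train", "evaluate", "uptake")


@dataclass
class ExperimentConfig:
    """Configuration of one end-to-end run; all blocks have working defaults."""

    out_dir: str = "experiment"
    seed: int = 0
    # phantom block
    n_cases: int = 20
    image_shape: tuple[int, int] = (64, 64)
    kidney_mean_counts_per_frame: float = 21.0
    background_mean_counts_per_frame: float = 2.0
    n_frames: int = 10
    uptake_range: tuple[float, float] = (0.14, 0.28)
    motion_max_px: float = 0.0
    motion_max_deg: float = 0.0
    # registration block
    register: bool = True
    registration_iterations: int = 100
    registration_learning_rate: float = 0.01
    # dataset block
    k: int = 2
    split_fractions: tuple[float, float, float] = (109 / 155, 23 / 155, 23 / 155)
    pairs_per_case: int | None = None  # None = all C(F, k) pairs
    # training block
    architectures: tuple[str, ...] = ("DnCNN", "Win5RB", "ResUnet")
    arch_overrides: dict = field(default_factory=dict)  # name -> ArchitectureSpec kwargs
    train_config: dict = field(default_factory=dict)  # TrainConfig kwargs
    # metrics / uptake blocks
    ssim_windowed: bool = False
    joint_hist_bins: int = 64
    attenuation_k: float = 1.0  # phantom has no attenuating medium

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("image_shape", "uptake_range", "split_fractions", "architectures"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def phantom_base(self) -> PhantomSpec:
        return PhantomSpec(
            image_shape=self.image_shape,
            n_frames=self.n_frames,
            kidney_mean_counts_per_frame=self.kidney_mean_counts_per_frame,
            background_mean_counts_per_frame=self.background_mean_counts_per_frame,
        )

    def arch_spec(self, name: str) -> ArchitectureSpec:
        kwargs = dict(self.arch_overrides.get(name, {}))
        if "resunet_level_filters" in kwargs:
            kwargs["resunet_level_filters"] = tuple(kwargs["resunet_level_filters"])
        return ArchitectureSpec(name=name, **kwargs)


def _stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def _done(out: Path, stage: str) -> Path:
    return out / f"{stage}.done"


def _save_ground_truth(gt, path: Path) -> None:
    np.savez_compressed(
        path,
        kidney_masks=np.stack(gt.kidney_masks),
        background_mask=gt.background_mask,
        noiseless_map=gt.noiseless_map,
        true_uptake_fraction=np.asarray(gt.true_uptake_fraction),
        total_dose_counts=gt.total_dose_counts,
    )


def run_experiment(config: ExperimentConfig, force: bool = False) -> Path:
    """Run all stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    for stage, fn in (
        ("simulate", _stage_simulate),
        ("register", _stage_register),
        ("build-dataset", _stage_dataset),
        ("train", _stage_train),
        ("evaluate", _stage_evaluate),
        ("uptake", _stage_uptake),
    ):
        sentinel = _done(out, stage)
        if sentinel.exists() and not force:
            log.info("stage %s already complete, skipping", stage)
            continue
        log.info("running stage %s", stage)
        t0 = time.time()
        try:
            fn(config, out)
        except Exception:
            log.error("stage %s failed; partial outputs kept under %s", stage, out)
            raise
        timings[stage] = round(time.time() - t0, 3)
        sentinel.write_text("ok")
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "config": dataclasses.asdict(config),
        "timings_s": timings,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


# -- stages ---------------------------------------------------------------

def _stage_simulate(config: ExperimentConfig, out: Path) -> None:
    cases_dir = out / "cases"
    cases_dir.mkdir(exist_ok=True)
    cases = make_phantom_cases(
        config.n_cases,
        seed=_stage_seed(config.seed, "simulate"),
        base=config.phantom_base(),
        uptake_range=config.uptake_range,
        motion_max_px=config.motion_max_px,
        motion_max_deg=config.motion_max_deg,
    )
    for _, series, gt in cases:
        cid = series.meta["case_id"]
        save_series(series, cases_dir / cid)
        _save_ground_truth(gt, cases_dir / f"{cid}_gt.npz")


def _case_ids(out: Path) -> list[str]:
    return sorted(p.stem for p in (out / "cases").glob("case*.npz") if not p.stem.endswith("_gt"))


def _stage_register(config: ExperimentConfig, out: Path) -> None:
    reg_dir = out / "registered"
    reg_dir.mkdir(exist_ok=True)
    transforms = {}
    for cid in _case_ids(out):
        series = load_series(out / "cases" / cid)
        if config.register:
            registered, tfs = register_series(
                series, config.registration_iterations, config.registration_learning_rate
            )
            transforms[cid] = [t.to_dict() for t in tfs]
        else:
            registered = series
            transforms[cid] = None
        save_series(registered, reg_dir / cid)
    (reg_dir / "transforms.json").write_text(json.dumps(transforms, indent=1))


def _stage_dataset(config: ExperimentConfig, out: Path) -> None:
    ids = _case_ids(out)
    tr, va, te = split_cases(ids, config.split_fractions, _stage_seed(config.seed, "build-dataset"))
    rng = np.random.default_rng(_stage_seed(config.seed, "build-dataset") + 1)
    manifest = {"splits": {"train": tr, "validation": va, "test": te}, "k": config.k, "pairs": {}}
    for cid in ids:
        series = load_series(out / "registered" / cid)
        pairs = build_pairs(series, cid, config.k)
        if config.pairs_per_case is not None and config.pairs_per_case < len(pairs):
            keep = sorted(rng.choice(len(pairs), config.pairs_per_case, replace=False))
            pairs = [pairs[i] for i in keep]
        manifest["pairs"][cid] = [list(p.frame_indices) for p in pairs]
    (out / "dataset_manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_pairs(out: Path, config: ExperimentConfig, split: str):
    manifest = json.loads((out / "dataset_manifest.json").read_text())
    pairs = []
    for cid in manifest["splits"][split]:
        series = load_series(out / "registered" / cid)
        full = series.frame_sum()
        for idx in manifest["pairs"][cid]:
            from .dataset import TrainingPair

            pairs.append(TrainingPair(cid, tuple(idx), series.frame_sum(idx), full))
    return pairs


def _stage_train(config: ExperimentConfig, out: Path) -> None:
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    train_pairs = _load_pairs(out, config, "train")
    val_pairs = _load_pairs(out, config, "validation")
    seed = _stage_seed(config.seed, "train")
    for name in config.architectures:
        spec = config.arch_spec(name)
        cfg = TrainConfig(seed=seed, **config.train_config)
        model = build_model(spec, seed=seed)
        model, history = train(model, train_pairs, val_pairs, cfg)
        save_model(model, spec, models_dir / name.lower())
        pd.DataFrame(
            {
                "epoch": range(len(history.train_loss)),
                "train_loss": history.train_loss,
                "val_loss": history.val_loss,
            }
        ).to_csv(models_dir / f"{name.lower()}_history.csv", index=False)
        log.info("%s: best epoch %d, best val loss %.6f", name, history.best_epoch, history.best_val_loss)


def _stage_evaluate(config: ExperimentConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = out / "report"
    report.mkdir(exist_ok=True)
    test_pairs = _load_pairs(out, config, "test")
    shorts = [p.short_time for p in test_pairs]
    refs = [p.full_time for p in test_pairs]
    predictions = {}
    for name in config.architectures:
        model, _ = load_model(out / "models" / name.lower())
        predictions[name] = [predict(model, s) for s in shorts]
        np.savez_compressed(report / f"predictions_{name.lower()}.npz", images=np.stack(predictions[name]))
    table = evaluate_split(predictions, shorts, refs, windowed=config.ssim_windowed)
    table.to_csv(report / "metrics.csv", index=False)
    correlations = {}
    for name, images in {"short-time": shorts, **predictions}.items():
        hist, xe, ye, r, r2 = joint_histogram(images, refs, bins=config.joint_hist_bins)
        np.savetxt(report / f"joint_hist_{name.replace(' ', '_')}.csv", hist, delimiter=",")
        correlations[name] = {"r": r, "r_squared": r2}
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(np.log1p(hist.T), origin="lower", extent=(xe[0], xe[-1], ye[0], ye[-1]), aspect="auto")
        ax.set_xlabel(name)
        ax.set_ylabel("full-time reference")
        ax.set_title(f"$r^2$ = {r2:.4f}")
        fig.tight_layout()
        fig.savefig(report / f"joint_hist_{name.replace(' ', '_')}.png", dpi=120)
        plt.close(fig)
    (report / "joint_hist_correlations.json").write_text(json.dumps(correlations, indent=1))


def _stage_uptake(config: ExperimentConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = out / "report"
    report.mkdir(exist_ok=True)
    manifest = json.loads((out / "dataset_manifest.json").read_text())
    rows = []
    per_method: dict[str, list[float]] = {}
    test_ids = manifest["splits"]["test"]
    model_cache = {name: load_model(out / "models" / name.lower())[0] for name in config.architectures}
    for cid in test_ids:
        series = load_series(out / "registered" / cid)
        with np.load(out / "cases" / f"{cid}_gt.npz") as gtf:
            rois = ROISet(
                kidney_masks=list(gtf["kidney_masks"].astype(bool)),
                background_mask=gtf["background_mask"].astype(bool),
                pixel_size_mm2=series.pixel_size_mm**2,
            )
            dose = float(gtf["total_dose_counts"])
        full = series.frame_sum()
        short = series.frame_sum(manifest["pairs"][cid][0])
        images = {"full-time": full, "short-time": short}
        for name, model in model_cache.items():
            images[name] = predict(model, short)
        for method, img in images.items():
            result = uptake_from_image(img, rois, dose, k=config.attenuation_k)
            for kk, ku in enumerate(result.kidneys):
                rows.append(
                    {
                        "case_id": cid,
                        "method": method,
                        "kidney": kk,
                        "U": ku.kidney_counts,
                        "B": ku.background_counts,
                        "k": ku.attenuation_k,
                        "D": dose,
                        "uptake_percent": ku.uptake_percent,
                        "negative_net_counts": ku.negative_net_counts,
                    }
                )
                per_method.setdefault(method, []).append(ku.uptake_percent)
    df = pd.DataFrame(rows)
    df.to_csv(report / "uptake.csv", index=False)
    agreement = {}
    ref = per_method["full-time"]
    for method, vals in per_method.items():
        if method == "full-time":
            continue
        if len(vals) < 3:
            log.warning("agreement for %s skipped: needs >= 3 paired values", method)
            agreement[method] = None
            continue
        agreement[method] = agreement_analysis(ref, vals)
        fig, ax = plt.subplots(figsize=(4, 3.2))
        bland_altman_plot(ref, vals, ax=ax, label_a="full-time", label_b=method)
        fig.tight_layout()
        fig.savefig(report / f"bland_altman_{method.replace(' ', '_')}.png", dpi=120)
        plt.close(fig)
    (report / "uptake_agreement.json").write_text(json.dumps(agreement, indent=1))
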