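"""Joint training of the detector and corrector.

"Trained simultaneously" is implemented as alternating steps on a shared
batch: one Adam step on the detector's Dice+BCE loss, then one Adam step
on the corrector's composite loss.  The corrector's data-consistency mask
is the detector's current binarised prediction, detached — no gradient
flows from the correction loss into the detector, and when
``dc_mask="predicted"`` the correction loss never reads the ground-truth
mask.

Two scale presets exist: ``full`` (batch 32, lr 2e-4, 25 epochs — the
full-data configuration) and ``desk`` (8 phantoms at 64x64, batch 4,
200 joint steps, lr 2e-3, seed 7 — a CPU-scale overfit harness used by the
test suite).  Everything is seeded; training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .correction import CorrectionConfig, Corrector, FeatureExtractor, total_loss
from .detection import (DetectionConfig, Detector, bce_loss, dice_loss,
                        kspace_channels, peripheral_exclusion_mask)
from .nn.engine import Tensor
from .kspace import ImageSlice, to_kspace
from .motion import corrupt
from .nn.layers import Adam
from .phantom import PhantomDataset, PhantomSpec, generate_dataset

__all__ = [
    "TrainConfig", "TrainResult", "desk_setup", "train", "run_ablation",
    "SCENARIOS",
]

# ablation scenarios: which loss weights are zeroed
SCENARIOS = {
    "l1": {"lambda_l": 0.0, "lambda_d": 0.0},
    "l1_dc": {"lambda_l": 0.0},
    "full": {},
}


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    lr: float = 2e-4
    epochs: int = 25
    steps: int | None = None        # overrides epochs when set
    adam_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    scale: str = "full"


def desk_setup(n_phantoms: int = 8, size: int = 64, steps: int = 200,
               seed: int = 7):
    """The CPU-scale overfit configuration used throughout the tests."""
    train_cfg = TrainConfig(batch_size=4, lr=2e-3, steps=steps, seed=seed,
                            scale="desk")
    det_cfg = DetectionConfig(depth=2, base_width=8, init_seed=seed)
    corr_cfg = CorrectionConfig(depth=2, base_width=8, window=4, n_heads=2,
                                blocks_per_stage=2, init_seed=seed + 1)
    dataset = generate_dataset(n_phantoms, PhantomSpec(size=size),
                               split=(0.75, 0.25), seed=seed)
    return dataset, train_cfg, det_cfg, corr_cfg


@dataclass
class TrainResult:
    detector: Detector
    corrector: Corrector
    feature_extractor: FeatureExtractor
    seg_curve: list[float]
    corr_curve: list[float]
    breakdown_curve: list[dict[str, float]]
    severity: str
    aborted: bool = False

    def save(self, directory: str | Path) -> None:
        from dataclasses import asdict

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "detector.npz", **self.detector.net.state_dict())
        np.savez(directory / "corrector.npz", **self.corrector.net.state_dict())
        with open(directory / "config.json", "w") as fh:
            json.dump({"detection": asdict(self.detector.config),
                       "correction": asdict(self.corrector.config)}, fh,
                      indent=2)
        with open(directory / "curves.json", "w") as fh:
            json.dump({"seg": self.seg_curve, "corr": self.corr_curve}, fh)


def corrupted_kspace(dataset: PhantomDataset, severity: str, idx: int):
    """Re-splice the corrupted spectrum of one sample from its provenance."""
    k_gt = to_kspace(ImageSlice(dataset.clean[idx]))
    k_mot, _ = corrupt(k_gt, dataset.events[severity][idx],
                       dataset.center_exclusion_frac)
    return k_mot


def _prepare(dataset: PhantomDataset, severity: str, idx: np.ndarray,
             det_cfg: DetectionConfig):
    """Stack detector channels, corrupted/clean image batches and masks."""
    chans, corr, clean, mgt = [], [], [], []
    for i in idx:
        k_mot = corrupted_kspace(dataset, severity, int(i))
        chans.append(kspace_channels(k_mot, det_cfg.log_magnitude_only))
        corr.append(dataset.corrupted[severity][i][None])
        clean.append(dataset.clean[i][None])
        mgt.append(dataset.masks[severity][i])
    return (np.stack(chans), np.stack(corr), np.stack(clean), np.stack(mgt))


def train(dataset: PhantomDataset, severity: str = "moderate",
          train_cfg: TrainConfig = TrainConfig(),
          det_cfg: DetectionConfig = DetectionConfig(),
          corr_cfg: CorrectionConfig = CorrectionConfig(),
          scenario: str = "full",
          checkpoint_dir: str | Path | None = None) -> TrainResult:
    """Alternating joint training on the dataset's training split.

    ``scenario`` selects the ablation variant by zeroing loss weights
    ("l1", "l1_dc", "full").  On a non-finite loss the run aborts and the
    last finite-state networks are returned (and saved, if a checkpoint
    directory is given).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick from {sorted(SCENARIOS)}")
    if len(dataset.train_idx) == 0:
        raise ValueError("empty training split")
    corr_cfg = replace(corr_cfg, **SCENARIOS[scenario])

    detector = Detector(det_cfg)
    corrector = Corrector(corr_cfg)
    fe = FeatureExtractor(seed=corr_cfg.feature_seed)
    opt_d = Adam(detector.net.parameters(), lr=train_cfg.lr,
                 betas=train_cfg.adam_betas)
    opt_c = Adam(corrector.net.parameters(), lr=train_cfg.lr,
                 betas=train_cfg.adam_betas)

    chans, corr_imgs, clean_imgs, mgts = _prepare(
        dataset, severity, dataset.train_idx, det_cfg)
    n = chans.shape[0]
    rng = np.random.default_rng(train_cfg.seed)

    n_steps = train_cfg.steps
    if n_steps is None:
        per_epoch = max(1, n // train_cfg.batch_size)
        n_steps = train_cfg.epochs * per_epoch

    seg_curve: list[float] = []
    corr_curve: list[float] = []
    breakdown_curve: list[dict[str, float]] = []
    last_good: tuple[dict, dict] | None = None
    aborted = False

    for step in range(n_steps):
        batch = rng.choice(n, size=min(train_cfg.batch_size, n), replace=False)
        cb, xb, yb, mb = (chans[batch], corr_imgs[batch],
                          clean_imgs[batch], mgts[batch])

        # --- detector step (Dice + BCE on averaged, excluded mask)
        pred = detector.forward_soft(cb)
        soft = pred.data[:, 0, :, 0].copy()      # detached snapshot
        keep = peripheral_exclusion_mask(cb.shape[-2], det_cfg.peripheral_frac)
        target = Tensor((mb * keep[None, :])[:, None, :, None])
        loss_d = dice_loss(pred, target) + bce_loss(pred, target)
        detector.net.zero_grad()
        loss_d.backward()
        opt_d.step()
        seg_curve.append(float(loss_d.data))

        # --- corrector step on the same batch
        if corr_cfg.dc_mask == "predicted":
            masks = (soft > det_cfg.threshold).astype(np.float64)
        else:
            masks = mb
        xhat = corrector.forward(xb)
        loss_c, breakdown = total_loss(xhat, yb, masks, corr_cfg, fe)
        corrector.net.zero_grad()
        loss_c.backward()
        opt_c.step()
        corr_curve.append(float(loss_c.data))
        breakdown_curve.append(breakdown)

        if not (np.isfinite(seg_curve[-1]) and np.isfinite(corr_curve[-1])):
            aborted = True
            if last_good is not None:
                detector.net.load_state_dict(last_good[0])
                corrector.net.load_state_dict(last_good[1])
            break
        last_good = (detector.net.state_dict(), corrector.net.state_dict())

    result = TrainResult(detector=detector, corrector=corrector,
                         feature_extractor=fe, seg_curve=seg_curve,
                         corr_curve=corr_curve,
                         breakdown_curve=breakdown_curve,
                         severity=severity, aborted=aborted)
    if checkpoint_dir is not None:
        result.save(checkpoint_dir)
    return result


def run_ablation(dataset: PhantomDataset, severity: str = "heavy",
                 scenarios: tuple[str, ...] = ("l1", "l1_dc", "full"),
                 seeds: tuple[int, ...] = (7, 8, 9),
                 steps: int = 150,
                 det_cfg: DetectionConfig | None = None,
                 corr_cfg: CorrectionConfig | None = None) -> dict:
    """Train each loss scenario on identical data/seeds; report test metrics.

    Returns ``{scenario: {"psnr_db", "ssim", "nmse_pct", "per_seed", ...}}``
    with group means and 95% bootstrap CIs over per-image test metrics
    pooled across seeds.  All scenarios consume the same dataset object,
    so corrupted inputs are identical by construction (hash included).
    """
    from .evaluation import bootstrap_ci, nmse, psnr, ssim

    input_hash = hash(dataset.corrupted[severity].tobytes())
    out: dict = {"severity": severity, "input_hash": input_hash, "scenarios": {}}
    for scenario in scenarios:
        vals = {"psnr_db": [], "ssim": [], "nmse_pct": []}
        for seed in seeds:
            cfg = TrainConfig(batch_size=4, lr=2e-3, steps=steps, seed=seed,
                              scale="desk")
            res = train(dataset, severity, cfg,
                        det_cfg or DetectionConfig(depth=2, base_width=8,
                                                   init_seed=seed),
                        corr_cfg or CorrectionConfig(depth=2, base_width=8,
                                                     init_seed=seed + 1),
                        scenario=scenario)
            for i in dataset.test_idx:
                fixed = res.corrector.correct(
                    ImageSlice(dataset.corrupted[severity][i])).pixels
                ref = dataset.clean[i]
                vals["psnr_db"].append(psnr(fixed, ref))
                vals["ssim"].append(ssim(fixed, ref))
                vals["nmse_pct"].append(nmse(fixed, ref))
        table = {}
        for metric, v in vals.items():
            arr = np.asarray(v)
            lo, hi = bootstrap_ci(arr, n_iter=2000, method="percentile",
                                  seed=0)
            table[metric] = {"mean": float(arr.mean()),
                             "ci_low": lo, "ci_high": hi}
        out["scenarios"][scenario] = table
    return out
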