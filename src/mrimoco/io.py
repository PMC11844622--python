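"""Readers/writers: NPZ paired archives, NIfTI volumes, configs, manifests.

The paired archive is a single NPZ holding clean slices, per-severity
corrupted slices and line masks, the motion-event provenance (one
``(n_slabs, 5)`` array per sample: theta, tx, ty, slab_start, slab_width)
and the train/test split — enough to regenerate every corrupted entry
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .kspace import ImageSlice
from .motion import MotionEvent
from .phantom import PhantomDataset, PhantomSpec

__all__ = [
    "save_dataset", "load_dataset", "load_nifti_slices", "save_nifti",
    "load_config", "write_manifest",
]


def _events_to_array(events: list[MotionEvent]) -> np.ndarray:
    return np.array([[e.theta_deg, e.tx_mm, e.ty_mm, e.slab_start, e.slab_width]
                     for e in events], dtype=np.float64).reshape(-1, 5)


def _events_from_array(arr: np.ndarray) -> list[MotionEvent]:
    return [MotionEvent(theta_deg=float(r[0]), tx_mm=float(r[1]),
                        ty_mm=float(r[2]), slab_start=int(r[3]),
                        slab_width=int(r[4])) for r in arr]


def save_dataset(ds: PhantomDataset, path: str | Path) -> None:
    payload: dict[str, np.ndarray] = {
        "clean": ds.clean,
        "train_idx": ds.train_idx,
        "test_idx": ds.test_idx,
        "seed": np.array(ds.seed),
        "center_exclusion_frac": np.array(ds.center_exclusion_frac),
        "severities": np.array(ds.severities),
        "spec": np.array([ds.spec.size, *ds.spec.n_ellipses_range,
                          ds.spec.rim_intensity, ds.spec.rim_thickness,
                          ds.spec.seed]),
    }
    for sev in ds.severities:
        payload[f"corrupted_{sev}"] = ds.corrupted[sev]
        payload[f"masks_{sev}"] = ds.masks[sev]
        payload[f"events_{sev}"] = np.stack(
            [_events_to_array(e) for e in ds.events[sev]])
    np.savez_compressed(path, **payload)


def load_dataset(path: str | Path) -> PhantomDataset:
    with np.load(path, allow_pickle=False) as z:
        severities = [str(s) for s in z["severities"]]
        spec_arr = z["spec"]
        spec = PhantomSpec(size=int(spec_arr[0]),
                           n_ellipses_range=(int(spec_arr[1]), int(spec_arr[2])),
                           rim_intensity=float(spec_arr[3]),
                           rim_thickness=float(spec_arr[4]),
                           seed=int(spec_arr[5]))
        return PhantomDataset(
            clean=z["clean"],
            corrupted={s: z[f"corrupted_{s}"] for s in severities},
            masks={s: z[f"masks_{s}"] for s in severities},
            events={s: [_events_from_array(a) for a in z[f"events_{s}"]]
                    for s in severities},
            train_idx=z["train_idx"],
            test_idx=z["test_idx"],
            seed=int(z["seed"]),
            spec=spec,
            center_exclusion_frac=float(z["center_exclusion_frac"]),
        )


def load_nifti_slices(path: str | Path, axis: int = 2, normalize: str = "minmax",
                      min_foreground_frac: float = 0.02,
                      pixel_spacing: float | None = None,
                      ) -> tuple[list[ImageSlice], int]:
    """Load a NIfTI volume as normalised 2-D slices.

    ``normalize``: "minmax" (per-slice min-max to [0, 1]) or "percentile"
    (0.5/99.5 percentile clip, robust to in-vivo intensity spikes).
    Near-empty slices (foreground fraction below ``min_foreground_frac``)
    are dropped; the dropped count is returned alongside the slices.
    """
    img = nib.load(str(path))
    vol = np.asarray(img.get_fdata(), dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {vol.shape}")
    if pixel_spacing is None:
        zooms = img.header.get_zooms()
        in_plane = [z for i, z in enumerate(zooms[:3]) if i != axis]
        pixel_spacing = float(np.mean(in_plane)) if in_plane else 1.0
    slices: list[ImageSlice] = []
    dropped = 0
    for i in range(vol.shape[axis]):
        sl = np.take(vol, i, axis=axis)
        if normalize == "percentile":
            lo, hi = np.percentile(sl, [0.5, 99.5])
            sl = np.clip(sl, lo, hi)
        lo, hi = sl.min(), sl.max()
        if hi > lo:
            sl = (sl - lo) / (hi - lo)
        else:
            sl = np.zeros_like(sl)
        if (sl > 0.1).mean() < min_foreground_frac:
            dropped += 1
            continue
        slices.append(ImageSlice(sl, pixel_spacing=pixel_spacing))
    return slices, dropped


def save_nifti(volume: np.ndarray, path: str | Path,
               pixel_spacing: float = 1.0) -> None:
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))


_KNOWN_BLOCKS = {
    "detection": {"depth", "base_width", "threshold", "peripheral_frac",
                  "log_magnitude_only", "init_seed"},
    "correction": {"lambda_r", "lambda_l", "lambda_d", "depth", "base_width",
                   "window", "n_heads", "blocks_per_stage", "dc_mask",
                   "feature_seed", "init_seed"},
    "training": {"batch_size", "lr", "epochs", "steps", "adam_betas", "seed",
                 "scale"},
    "simulate": {"severity", "center_exclusion_frac", "seed"},
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config; unknown blocks or keys fail fast."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping of blocks")
    for block, keys in cfg.items():
        if block not in _KNOWN_BLOCKS:
            raise ValueError(f"unknown config block {block!r}; "
                             f"known: {sorted(_KNOWN_BLOCKS)}")
        unknown = set(keys or {}) - _KNOWN_BLOCKS[block]
        if unknown:
            raise ValueError(f"unknown keys in block {block!r}: {sorted(unknown)}")
    return cfg


def write_manifest(path: str | Path, config: dict, seed: int) -> None:
    """Run manifest: config hash, seed and library versions."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
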