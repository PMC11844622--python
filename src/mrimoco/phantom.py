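"""Synthetic brain-like phantoms and paired clean/corrupted datasets.

The phantom emulates the two features of a T1-weighted axial brain slice
that matter for this package: a bright elliptical rim (subcutaneous fat,
the dominant source of ghosting when k-space lines are inconsistent) and
a piecewise-smooth interior of overlapping tissue-like ellipses.  Ellipse
geometry is randomised per seed so the detection task does not degenerate
to a single template.

``generate_dataset`` mirrors the paired-data protocol used for training:
for each clean phantom it stores one corrupted slice per severity preset
together with the ground-truth line mask and full motion-event provenance,
plus disjoint train/test index sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kspace import ImageSlice
from .motion import PRESETS, CENTER_EXCLUSION_FRAC, MotionEvent, build_mask, simulate

__all__ = ["PhantomSpec", "PhantomDataset", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 128
    n_ellipses_range: tuple[int, int] = (4, 8)
    rim_intensity: float = 0.95
    rim_thickness: float = 3.0
    seed: int = 0


@dataclass
class PhantomDataset:
    """Paired clean/corrupted phantoms with provenance."""

    clean: np.ndarray                        # (n, H, W)
    corrupted: dict[str, np.ndarray]         # severity -> (n, H, W)
    masks: dict[str, np.ndarray]             # severity -> (n, H) binary
    events: dict[str, list[list[MotionEvent]]]
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    spec: PhantomSpec
    center_exclusion_frac: float = field(default=CENTER_EXCLUSION_FRAC)

    @property
    def n(self) -> int:
        return self.clean.shape[0]

    @property
    def severities(self) -> list[str]:
        return list(self.corrupted)


def _ellipse(size: int, cy: float, cx: float, a: float, b: float,
             angle: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse; axes in pixels, angle in radians."""
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    yr = y * np.cos(angle) - x * np.sin(angle)
    xr = y * np.sin(angle) + x * np.cos(angle)
    return (yr / a) ** 2 + (xr / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> ImageSlice:
    """Deterministic brain-like phantom in [0, 1] for a given seed."""
    if spec.size < 32:
        raise ValueError(f"phantom size {spec.size} too small; need >= 32")
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    c = (n - 1) / 2.0

    # outer head ellipse, mildly randomised
    a_out = n * rng.uniform(0.40, 0.45)
    b_out = n * rng.uniform(0.33, 0.38)
    tilt = rng.uniform(-0.15, 0.15)
    cy = c + rng.uniform(-1.5, 1.5)
    cx = c + rng.uniform(-1.5, 1.5)
    outer = _ellipse(n, cy, cx, a_out, b_out, tilt)
    inner = _ellipse(n, cy, cx, a_out - spec.rim_thickness,
                     b_out - spec.rim_thickness, tilt)
    rim = outer & ~inner

    img = np.zeros((n, n))
    base = rng.uniform(0.30, 0.40)
    img[inner] = base

    n_ell = int(rng.integers(spec.n_ellipses_range[0],
                             spec.n_ellipses_range[1] + 1))
    for _ in range(n_ell):
        ea = n * rng.uniform(0.05, 0.18)
        eb = n * rng.uniform(0.05, 0.18)
        ecy = cy + rng.uniform(-0.2, 0.2) * n
        ecx = cx + rng.uniform(-0.2, 0.2) * n
        eang = rng.uniform(0, np.pi)
        delta = rng.uniform(-0.18, 0.28)
        mask = _ellipse(n, ecy, ecx, ea, eb, eang) & inner
        img[mask] += delta

    # light smoothing inside the head keeps tissue piecewise-smooth
    smoothed = ndimage.gaussian_filter(img, sigma=1.0)
    img = np.where(inner, smoothed, img)
    img[rim] = spec.rim_intensity
    img = np.clip(img, 0.0, 1.0)

    interior_mean = img[inner].mean() if inner.any() else 0.0
    if rim.any() and interior_mean > 0 and img[rim].mean() <= 1.2 * interior_mean:
        # construction guarantee: the rim must dominate the interior
        img[rim] = min(1.0, 1.5 * interior_mean + 0.2)
    return ImageSlice(img)


def generate_dataset(n: int, spec: PhantomSpec | None = None,
                     split: tuple[float, float] = (0.8, 0.2),
                     severities: tuple[str, ...] = ("minor", "moderate", "heavy"),
                     seed: int = 0,
                     center_exclusion_frac: float = CENTER_EXCLUSION_FRAC,
                     ) -> PhantomDataset:
    """Generate ``n`` phantoms with per-severity corruptions and a split.

    Train/test indices are disjoint; every corrupted slice stores the
    motion events and ground-truth mask that produced it, so the archive
    can be regenerated bit-exactly from its own provenance.
    """
    if n < 2:
        raise ValueError("need at least 2 phantoms to form a split")
    train_frac, test_frac = split
    if train_frac <= 0 or test_frac <= 0 or abs(train_frac + test_frac - 1.0) > 1e-9:
        raise ValueError(f"degenerate split {split}; fractions must be positive and sum to 1")
    n_train = int(round(n * train_frac))
    n_train = min(max(n_train, 1), n - 1)  # both partitions non-empty
    spec = spec or PhantomSpec()

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])

    clean = np.empty((n, spec.size, spec.size))
    for i in range(n):
        sub = PhantomSpec(size=spec.size,
                          n_ellipses_range=spec.n_ellipses_range,
                          rim_intensity=spec.rim_intensity,
                          rim_thickness=spec.rim_thickness,
                          seed=int(rng.integers(0, 2**31 - 1)))
        clean[i] = generate_phantom(sub).pixels

    corrupted: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    events: dict[str, list[list[MotionEvent]]] = {}
    for sev in severities:
        preset = PRESETS[sev]
        arr = np.empty_like(clean)
        msk = np.empty((n, spec.size))
        evs: list[list[MotionEvent]] = []
        for i in range(n):
            sim_seed = int(rng.integers(0, 2**31 - 1))
            corr, mask, ev = simulate(ImageSlice(clean[i]), preset, sim_seed,
                                      center_exclusion_frac)
            arr[i] = corr.pixels
            msk[i] = mask.values
            evs.append(ev)
        corrupted[sev] = arr
        masks[sev] = msk
        events[sev] = evs

    # provenance self-check: stored mask always reconstructible from events
    for sev in severities:
        for i in range(n):
            rebuilt = build_mask(events[sev][i], spec.size, center_exclusion_frac)
            assert np.array_equal(rebuilt.values, masks[sev][i])

    return PhantomDataset(clean=clean, corrupted=corrupted, masks=masks,
                          events=events, train_idx=train_idx, test_idx=test_idx,
                          seed=seed, spec=spec,
                          center_exclusion_frac=center_exclusion_frac)
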