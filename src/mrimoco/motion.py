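"""Rigid-motion corruption of Cartesian k-space.

The simulation assumes abrupt inter-shot motion: each motion event holds
one rigid transform ``Theta_i = (theta_deg, tx_mm, ty_mm)`` and owns one
contiguous slab of phase-encoding lines.  Corruption replaces those lines
of the clean spectrum with the same lines of the rigidly transformed
spectrum; all other lines are left bit-identical — the physical basis for
enforcing k-space data consistency during correction.

Severity presets follow the three-level protocol of corrupting 5 / 10 / 15
slabs of 3-7 lines each, with rotations bounded by +/-7 degrees and
translations by +/-5 mm.  A protected band at the centre of k-space (low
spatial frequencies, which carry image contrast) is never corrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kspace import ImageSlice, KSpaceSlice, from_kspace, kspace_rigid, to_kspace

CENTER_EXCLUSION_FRAC = 0.08  # fraction of PE lines protected at the centre

__all__ = [
    "MotionEvent", "SeverityPreset", "LineMask", "PRESETS",
    "sample_events", "build_mask", "center_band", "corrupt", "simulate",
    "CENTER_EXCLUSION_FRAC",
]


@dataclass(frozen=True)
class MotionEvent:
    """One rigid transform bound to one slab of phase-encoding lines."""

    theta_deg: float
    tx_mm: float
    ty_mm: float
    slab_start: int
    slab_width: int

    @property
    def lines(self) -> range:
        return range(self.slab_start, self.slab_start + self.slab_width)


@dataclass(frozen=True)
class SeverityPreset:
    name: str
    n_slabs: int
    slab_width_range: tuple[int, int] = (3, 7)
    rot_bound_deg: float = 7.0
    trans_bound_mm: float = 5.0


PRESETS: dict[str, SeverityPreset] = {
    "minor": SeverityPreset("minor", 5),
    "moderate": SeverityPreset("moderate", 10),
    "heavy": SeverityPreset("heavy", 15),
}


@dataclass
class LineMask:
    """Per-PE-line mask; values in [0, 1], one entry per k-space row."""

    values: np.ndarray
    binary: bool = field(default=True)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.binary and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary LineMask may contain only 0 and 1")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("LineMask values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size

    def to_2d(self, width: int) -> np.ndarray:
        """Broadcast along the frequency-encoding axis (columns)."""
        return np.repeat(self.values[:, None], width, axis=1)


def center_band(height: int, frac: float = CENTER_EXCLUSION_FRAC) -> tuple[int, int]:
    """Half-open row range [lo, hi) of the protected k-space centre."""
    band = max(1, int(round(frac * height)))
    lo = (height - band) // 2
    return lo, lo + band


def sample_events(preset: SeverityPreset, height: int,
                  rng: np.random.Generator | int,
                  center_exclusion_frac: float = CENTER_EXCLUSION_FRAC,
                  ) -> list[MotionEvent]:
    """Sample ``preset.n_slabs`` non-overlapping motion events.

    Slab widths are uniform integers on the preset's width range; rotation
    and translation parameters are uniform on their symmetric bounds.
    Slabs are rejection-sampled until pairwise disjoint and clear of the
    protected centre band, so each corrupted line has a unique owning
    event.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = preset.n_slabs
    if n == 0:
        return []
    wlo, whi = preset.slab_width_range
    lo, hi = center_band(height, center_exclusion_frac)
    # free segments below and above the protected centre band
    seg_len = np.array([lo, height - hi])
    if n * wlo > seg_len.sum():
        raise ValueError(
            f"cannot place {n} disjoint slabs of width >= {wlo} outside the "
            f"centre band on {height} PE lines; need a grid of at least "
            f"~{n * wlo + (hi - lo)} lines")
    for _ in range(10_000):
        widths = rng.integers(wlo, whi + 1, size=n)
        if widths.sum() > seg_len.sum():
            continue  # conditioned on feasibility; no-op on adequate grids
        # randomly assign slabs to the two segments within capacity
        order = rng.permutation(n)
        used = np.zeros(2)
        seg_of = np.empty(n, dtype=int)
        ok = True
        for i in order:
            probs = np.maximum(seg_len - used, 0.0)
            fits = (used + widths[i]) <= seg_len
            probs = probs * fits
            if probs.sum() == 0:
                ok = False
                break
            s = int(rng.choice(2, p=probs / probs.sum()))
            seg_of[i] = s
            used[s] += widths[i]
        if not ok:
            continue
        # uniform composition of free lines into gaps (stars and bars)
        starts = np.empty(n, dtype=int)
        for s, offset in ((0, 0), (1, hi)):
            members = np.where(seg_of == s)[0]
            if members.size == 0:
                continue
            members = members[rng.permutation(members.size)]
            k = members.size
            free = int(seg_len[s] - widths[members].sum())
            cuts = np.sort(rng.choice(free + k, size=k, replace=False))
            gaps = np.diff(np.concatenate([[0], cuts + 1])) - 1
            pos = offset
            for j, m in enumerate(members):
                pos += int(gaps[j])
                starts[m] = pos
                pos += int(widths[m])
        return [MotionEvent(
            theta_deg=float(rng.uniform(-preset.rot_bound_deg,
                                        preset.rot_bound_deg)),
            tx_mm=float(rng.uniform(-preset.trans_bound_mm,
                                    preset.trans_bound_mm)),
            ty_mm=float(rng.uniform(-preset.trans_bound_mm,
                                    preset.trans_bound_mm)),
            slab_start=int(starts[i]),
            slab_width=int(widths[i]),
        ) for i in range(n)]
    raise ValueError(
        f"failed to place {n} disjoint slabs outside the centre band on "
        f"{height} PE lines after many attempts; use a taller grid")


def build_mask(events: list[MotionEvent], height: int,
               center_exclusion_frac: float = CENTER_EXCLUSION_FRAC) -> LineMask:
    """Binary per-line mask: 1 on every slab line, 0 on the centre band."""
    values = np.zeros(height)
    for ev in events:
        if ev.slab_start < 0 or ev.slab_start + ev.slab_width > height:
            raise ValueError(f"slab {ev} falls outside [0, {height})")
        values[ev.slab_start:ev.slab_start + ev.slab_width] = 1.0
    lo, hi = center_band(height, center_exclusion_frac)
    values[lo:hi] = 0.0  # the centre is never corrupted
    return LineMask(values, binary=True)


def corrupt(k_gt: KSpaceSlice, events: list[MotionEvent],
            center_exclusion_frac: float = CENTER_EXCLUSION_FRAC,
            ) -> tuple[KSpaceSlice, LineMask]:
    """Splice motion-transformed lines into a clean spectrum.

    Every line owned by event ``i`` is replaced bit-exactly by the same
    line of ``kspace_rigid(k_gt, Theta_i)``; unmasked lines keep the
    original coefficients bit-exactly.
    """
    height = k_gt.shape[0]
    mask = build_mask(events, height, center_exclusion_frac)
    k_out = k_gt.coeffs.copy()
    for ev in events:
        rows = [r for r in ev.lines if mask.values[r] == 1.0]
        if not rows:
            continue
        k_t = kspace_rigid(k_gt, ev.theta_deg, ev.tx_mm, ev.ty_mm)
        k_out[rows, :] = k_t.coeffs[rows, :]
    return KSpaceSlice(k_out, pixel_spacing=k_gt.pixel_spacing), mask


def simulate(img: ImageSlice, preset: SeverityPreset | str,
             seed: np.random.Generator | int,
             center_exclusion_frac: float = CENTER_EXCLUSION_FRAC,
             ) -> tuple[ImageSlice, LineMask, list[MotionEvent]]:
    """Corrupt a clean slice end-to-end; reproducible from the seed.

    Returns the magnitude image reconstructed from the spliced spectrum,
    the ground-truth line mask, and the motion events used.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    events = sample_events(preset, img.shape[0], seed, center_exclusion_frac)
    k_gt = to_kspace(img)
    k_mot, mask = corrupt(k_gt, events, center_exclusion_frac)
    corrupted = from_kspace(k_mot)
    return corrupted, mask, events
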