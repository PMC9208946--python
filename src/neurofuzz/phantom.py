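"""Seeded generators for ground-truthed synthetic data.

Every downstream stage — denoising, fuzzy segmentation, ALFF — is exercised
on data built here: multi-tissue intensity phantoms with exact label maps,
impulse/Gaussian corruption, and 4D BOLD series with low-frequency
oscillations confined to labelled regions plus a matching motion trace.

The default phantom is concentric: a CSF-like core, a GM-like ring and a
WM-like exterior, with one intensity mean per class on an arbitrary [0, 255]
scale.  Class geometry is parametric, so class sizes are known and every
pixel's generating class is recorded in the returned label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alff import MOTION_COLUMNS, BoldSeries

__all__ = [
    "PhantomSpec",
    "OscillationSpec",
    "generate_tissue_phantom",
    "corrupt",
    "generate_bold_series",
]

INTENSITY_MIN = 0.0
INTENSITY_MAX = 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a tissue phantom.

    ``tissue_means`` holds one intensity per class ordered from the core
    outwards (default CSF < GM < WM); ``tissue_sd`` is the within-class
    spread.  ``geometry`` currently supports only ``"concentric"`` —
    equal-width radial bands around the grid centre.
    """

    shape: tuple[int, ...] = (64, 64)
    tissue_means: tuple[float, ...] = (20.0, 120.0, 220.0)
    tissue_sd: float = 5.0
    geometry: str = "concentric"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ValueError("phantom shape must be 2D or 3D")
        if min(self.shape) < 8:
            raise ValueError(f"each axis must be >= 8, got {self.shape}")
        if len(self.tissue_means) < 2:
            raise ValueError("need at least 2 tissue classes")
        if len(set(self.tissue_means)) != len(self.tissue_means):
            raise ValueError("tissue means must be distinct")
        if self.tissue_sd < 0:
            raise ValueError("tissue_sd must be non-negative")
        if self.geometry != "concentric":
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass(frozen=True)
class OscillationSpec:
    """A sinusoid injected into one labelled region of a BOLD series."""

    roi_label: int
    frequency: float  # Hz
    amplitude: float  # signal units
    phase: float = 0.0  # radians
    baseline: float = 100.0  # signal units
    noise_sd: float = 0.0  # signal units

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _concentric_labels(shape: tuple[int, ...], n_classes: int) -> np.ndarray:
    # Equal-width radial bands on the inscribed radius; everything beyond
    # the outermost edge belongs to the last class (the "exterior" tissue).
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, centre)))
    r_max = min(shape) / 2.0
    labels = np.clip((r / r_max * n_classes).astype(int), 0, n_classes - 1)
    return labels


def generate_tissue_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build an intensity image and its exact ground-truth label map.

    Returns ``(image, labels)`` on the same grid; pixel ``p`` was drawn from
    ``Normal(tissue_means[labels[p]], tissue_sd)``.  Identical specs (same
    seed included) produce identical outputs.

    Raises
    ------
    ValueError
        If the geometry leaves any class without pixels.
    """
    n_classes = len(spec.tissue_means)
    labels = _concentric_labels(spec.shape, n_classes)
    counts = np.bincount(labels.ravel(), minlength=n_classes)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"degenerate geometry: classes {empty} have zero pixels")
    means = np.asarray(spec.tissue_means, dtype=float)
    image = means[labels]
    if spec.tissue_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.tissue_sd, size=spec.shape)
    return image, labels


def corrupt(
    image: np.ndarray,
    model: str,
    level: float,
    seed: int,
    low: float = INTENSITY_MIN,
    high: float = INTENSITY_MAX,
) -> np.ndarray:
    """Corrupt an image with impulse (salt-and-pepper) or Gaussian noise.

    ``model="impulse"`` sets an exact fraction ``level`` of pixels — chosen
    without replacement — to ``low`` or ``high`` with equal probability;
    untouched pixels are bit-identical to the input.  ``model="gaussian"``
    adds zero-mean noise with standard deviation ``level``.
    """
    img = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    if model == "impulse":
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"impulse level must be in [0, 1], got {level}")
        out = img.copy()
        n_hit = int(round(level * img.size))
        if n_hit:
            idx = rng.choice(img.size, size=n_hit, replace=False)
            vals = rng.choice([low, high], size=n_hit)
            out.ravel()[idx] = vals
        return out
    if model == "gaussian":
        if level < 0:
            raise ValueError(f"gaussian level (sd) must be >= 0, got {level}")
        if level == 0:
            return img.copy()
        return img + rng.normal(0.0, level, size=img.shape)
    raise ValueError(f"unknown noise model {model!r}; use 'impulse' or 'gaussian'")


def generate_bold_series(
    labels: np.ndarray,
    oscillations: list[OscillationSpec],
    tr: float,
    n_volumes: int,
    seed: int,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    motion: str = "clean",
    motion_spike_volume: int | None = None,
    motion_spike_mm: float = 5.0,
) -> tuple[BoldSeries, pd.DataFrame]:
    """Simulate a 4D BOLD series over a label map, plus a motion trace.

    Voxels whose label matches an :class:`OscillationSpec` follow
    ``baseline + A·sin(2πft + φ) + Normal(0, noise_sd)`` with that spec's
    parameters; all other voxels are ``baseline + Normal(0, noise_sd)`` with
    the global arguments.  Time stamps are ``t = k·tr``.

    ``motion="clean"`` yields an all-zero trace; ``motion="spike"`` puts a
    single super-threshold translation at ``motion_spike_volume`` (middle
    volume by default).

    Raises
    ------
    ValueError
        If any oscillation frequency exceeds the Nyquist limit 1/(2·tr).
    """
    labels = np.asarray(labels)
    if n_volumes < 32:
        raise ValueError(f"n_volumes must be >= 32, got {n_volumes}")
    if not tr > 0:
        raise ValueError("tr must be positive")
    nyquist = 1.0 / (2.0 * tr)
    for osc in oscillations:
        if osc.frequency > nyquist:
            raise ValueError(
                f"oscillation frequency {osc.frequency} Hz exceeds the "
                f"Nyquist limit {nyquist:.4g} Hz for tr={tr}"
            )

    rng = np.random.default_rng(seed)
    t = np.arange(n_volumes) * tr
    data = np.full(labels.shape + (n_volumes,), float(baseline))
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    for osc in oscillations:
        roi = labels == osc.roi_label
        if not roi.any():
            raise ValueError(f"roi_label {osc.roi_label} has no voxels")
        wave = osc.baseline + osc.amplitude * np.sin(
            2.0 * np.pi * osc.frequency * t + osc.phase
        )
        series = np.broadcast_to(wave, (int(roi.sum()), n_volumes)).copy()
        if osc.noise_sd > 0:
            series += rng.normal(0.0, osc.noise_sd, size=series.shape)
        data[roi] = series

    trace = np.zeros((n_volumes, 6))
    if motion == "spike":
        vol = n_volumes // 2 if motion_spike_volume is None else motion_spike_volume
        if not 0 <= vol < n_volumes:
            raise ValueError(f"spike volume {vol} outside [0, {n_volumes})")
        trace[vol, 0] = motion_spike_mm
    elif motion != "clean":
        raise ValueError(f"unknown motion scenario {motion!r}")
    motion_df = pd.DataFrame(trace, columns=list(MOTION_COLUMNS))

    return BoldSeries(data, tr=tr), motion_df
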