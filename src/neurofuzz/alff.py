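"""Amplitude of low-frequency fluctuation (ALFF) analysis of BOLD series.

The resting-state stage operates on a 4D voxel time series: quality control
on the motion trace, trimming of unstable initial volumes, linear detrending,
a band-limited spectral amplitude per voxel (ALFF), and two whole-brain
normalisations — mALFF (divide by the in-mask mean) and zALFF (z-score
against the in-mask mean and standard deviation).

Conventions
-----------
* ALFF is the mean, over frequency bins inside the band, of the one-sided
  amplitude spectrum (the square root of periodogram power).  A summed-power
  variant is available via ``aggregate="sum"``.
* The band defaults to 0.01–0.08 Hz, the classical low-frequency window.
* zALFF uses the population (``ddof=0``) standard deviation by default.
* Motion limits are strict: a volume is offending only if a translation
  exceeds 3 mm or a rotation exceeds 3 degrees; exactly 3 passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BoldSeries",
    "ALFFMap",
    "ZALFFMap",
    "QCResult",
    "MOTION_COLUMNS",
    "qc_motion",
    "trim_initial",
    "compute_alff",
    "compute_malff",
    "compute_zalff",
    "regress_nuisance",
]

#: Canonical motion-trace column order: translations in mm, rotations in deg.
MOTION_COLUMNS = ("tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")


@dataclass
class BoldSeries:
    """A voxel time series with its repetition time.

    Parameters
    ----------
    data
        Array with the time axis last, e.g. ``(X, Y, Z, T)`` or ``(X, Y, T)``.
    tr
        Repetition time in seconds (sampling interval of the series).
    mask
        Boolean brain mask over the spatial grid; defaults to all-true.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2:
            raise ValueError("BoldSeries needs at least one spatial axis plus time")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:-1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:-1]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial grid "
                    f"{self.data.shape[:-1]}"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def nyquist(self) -> float:
        """Highest resolvable frequency, 1/(2·TR), in Hz."""
        return 1.0 / (2.0 * self.tr)


@dataclass
class ALFFMap:
    """Per-voxel band-limited amplitude with its band and mask."""

    values: np.ndarray
    band: tuple[float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("ALFF values and mask shapes differ")


@dataclass
class ZALFFMap:
    """Standardised ALFF: z-scores plus the mean/SD used to build them."""

    values: np.ndarray
    mask: np.ndarray
    source_mean: float
    source_sd: float
    band: tuple[float, float] | None = None


@dataclass
class QCResult:
    """Verdict of the motion check with the offending volume indices."""

    passed: bool
    offending_volumes: list[int] = field(default_factory=list)
    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0


def _as_motion_array(trace) -> np.ndarray:
    if isinstance(trace, pd.DataFrame):
        arr = trace[list(MOTION_COLUMNS)].to_numpy(dtype=float) \
            if set(MOTION_COLUMNS) <= set(trace.columns) \
            else trace.to_numpy(dtype=float)
    else:
        arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("motion trace contains non-finite values")
    return arr


def qc_motion(
    trace,
    max_trans_mm: float = 3.0,
    max_rot_deg: float = 3.0,
    n_volumes: int | None = None,
) -> QCResult:
    """Check a 6-column motion trace against translation/rotation limits.

    A subject fails if any volume translates *more than* ``max_trans_mm``
    along any axis or rotates *more than* ``max_rot_deg`` about any axis
    (strict inequality; a volume at exactly the limit passes).  Magnitudes
    are taken per-axis in absolute value.

    Parameters
    ----------
    trace
        ``(T, 6)`` array or DataFrame — three translations (mm) then three
        rotations (degrees).
    n_volumes
        If given, the trace length is validated against the series length.
    """
    arr = _as_motion_array(trace)
    if n_volumes is not None and arr.shape[0] != n_volumes:
        raise ValueError(
            f"motion trace has {arr.shape[0]} rows but series has "
            f"{n_volumes} volumes"
        )
    trans = np.abs(arr[:, :3])
    rot = np.abs(arr[:, 3:])
    bad = (trans > max_trans_mm).any(axis=1) | (rot > max_rot_deg).any(axis=1)
    return QCResult(
        passed=not bad.any(),
        offending_volumes=list(np.flatnonzero(bad)),
        max_translation_mm=float(trans.max()) if trans.size else 0.0,
        max_rotation_deg=float(rot.max()) if rot.size else 0.0,
    )


def trim_initial(series: BoldSeries, n: int = 15) -> BoldSeries:
    """Drop the first ``n`` volumes (unstable initial signal); TR unchanged."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if series.n_volumes <= n:
        raise ValueError(
            f"cannot trim {n} volumes from a series of {series.n_volumes}"
        )
    return BoldSeries(series.data[..., n:], tr=series.tr, mask=series.mask.copy())


def compute_alff(
    series: BoldSeries,
    band: tuple[float, float] = (0.01, 0.08),
    detrend: bool = True,
    aggregate: str = "mean",
) -> ALFFMap:
    """Band-limited spectral amplitude per voxel.

    Each voxel series is linearly detrended, transformed with a real FFT, and
    converted to a one-sided amplitude spectrum ``2·|X(f)|/T`` (the square
    root of periodogram power up to scale).  ALFF is the mean of the
    amplitudes over bins with ``f_lo <= f <= f_hi`` (``aggregate="sum"``
    sums instead).

    Raises
    ------
    ValueError
        If the band is not strictly inside (0, Nyquist).
    """
    f_lo, f_hi = band
    if not 0.0 < f_lo < f_hi:
        raise ValueError(f"band must satisfy 0 < f_lo < f_hi, got {band}")
    if f_hi > series.nyquist:
        raise ValueError(
            f"band upper edge {f_hi} Hz exceeds Nyquist limit "
            f"{series.nyquist:.4g} Hz for tr={series.tr}"
        )
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")

    data = series.data
    n_t = data.shape[-1]
    if detrend:
        data = signal.detrend(data, axis=-1, type="linear")
    freqs = np.fft.rfftfreq(n_t, d=series.tr)
    amp = (2.0 / n_t) * np.abs(np.fft.rfft(data, axis=-1))
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not in_band.any():
        raise ValueError(
            f"no frequency bins fall in {band} with T={n_t}, tr={series.tr}"
        )
    agg = amp[..., in_band]
    values = agg.mean(axis=-1) if aggregate == "mean" else agg.sum(axis=-1)
    values = np.where(series.mask, values, 0.0)
    return ALFFMap(values=values, band=(f_lo, f_hi), mask=series.mask.copy())


def compute_malff(alff: ALFFMap) -> ALFFMap:
    """Normalise by the in-mask mean ALFF, so the in-mask mean becomes 1."""
    inside = alff.values[alff.mask]
    mean = float(inside.mean())
    if mean <= 0:
        raise ValueError(f"in-mask mean ALFF must be positive, got {mean}")
    values = np.where(alff.mask, alff.values / mean, 0.0)
    return ALFFMap(values=values, band=alff.band, mask=alff.mask.copy())


def compute_zalff(alff: ALFFMap, ddof: int = 0) -> ZALFFMap:
    """Z-score the ALFF map against its in-mask mean and SD.

    By construction the in-mask mean of the output is 0 and its SD
    (population by default) is 1.  A constant map has zero SD and is
    rejected.
    """
    inside = alff.values[alff.mask]
    mean = float(inside.mean())
    sd = float(inside.std(ddof=ddof))
    if sd == 0.0:
        raise ValueError("ALFF map is constant inside the mask; SD is zero")
    values = np.where(alff.mask, (alff.values - mean) / sd, 0.0)
    return ZALFFMap(
        values=values,
        mask=alff.mask.copy(),
        source_mean=mean,
        source_sd=sd,
        band=alff.band,
    )


def regress_nuisance(series: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Residualise each voxel series against nuisance regressor columns.

    Ordinary least squares with an intercept added automatically; the
    residuals keep the voxel mean.  ``regressors`` is ``(T, k)``.
    """
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    if reg.shape[0] != series.n_volumes:
        raise ValueError(
            f"regressors have {reg.shape[0]} rows, series has "
            f"{series.n_volumes} volumes"
        )
    design = np.column_stack([np.ones(reg.shape[0]), reg])
    flat = series.data.reshape(-1, series.n_volumes).T  # (T, V)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design[:, 1:] @ beta[1:]  # keep the intercept in the data
    out = resid.T.reshape(series.data.shape)
    return BoldSeries(out, tr=series.tr, mask=series.mask.copy())
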