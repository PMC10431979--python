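"""Spatial pre-filtering and signal-to-concentration conversion.

DSC-MRI signal drops transiently as the paramagnetic bolus transits the
voxel; under the standard single-compartment T2* model the tracer
concentration is

    C_m(t) = -(k / TE) * ln(S(t) / S_0)

with S_0 the pre-bolus baseline and k a proportionality constant that
cancels between tissue and AIF in the flow/volume ratios, so k = 1 by
default.  Raw frames are first smoothed in-plane with a small normalized
Gaussian kernel (5-pixel support, sigma 0.5 px by default) to suppress
thermal noise; no temporal or through-slice mixing occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from ._errors import MetadataError, ParameterError
from .io import DSCSeries

__all__ = [
    "ConcentrationSeries",
    "gaussian_lowpass",
    "estimate_baseline",
    "signal_to_concentration",
    "DEFAULT_GAUSSIAN_DIAMETER",
    "DEFAULT_GAUSSIAN_SIGMA",
]

DEFAULT_GAUSSIAN_DIAMETER = 5
DEFAULT_GAUSSIAN_SIGMA = 0.5


@dataclass
class ConcentrationSeries:
    """Per-voxel tracer concentration time courses.

    conc has the same (slice, time, row, col) layout as the source signal,
    units 1/s (k fixed).  Voxel-frames where the logarithm is undefined
    (S <= 0 or S_0 <= 0) are NaN.
    """

    conc: np.ndarray
    baseline_s0: np.ndarray  # (slice, row, col)
    baseline_window: tuple[int, int]  # [start, stop) frame range used for S_0
    k_const: float = 1.0
    tr_s: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.conc.shape[1]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.tr_s


def gaussian_kernel_1d(diameter_px: int, sigma_px: float) -> np.ndarray:
    """Discretely normalized 1-D Gaussian of odd support ``diameter_px``."""
    if diameter_px < 1 or diameter_px % 2 == 0:
        raise ParameterError(f"Gaussian diameter must be odd and >= 1; got {diameter_px}")
    if sigma_px <= 0:
        raise ParameterError(f"Gaussian sigma must be > 0; got {sigma_px}")
    half = diameter_px // 2
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(x**2) / (2.0 * sigma_px**2))
    return w / w.sum()


def gaussian_lowpass(
    series: DSCSeries,
    diameter_px: int = DEFAULT_GAUSSIAN_DIAMETER,
    sigma_px: float = DEFAULT_GAUSSIAN_SIGMA,
) -> DSCSeries:
    """Smooth every frame in-plane with a separable normalized Gaussian.

    The kernel sums to exactly 1 (DC preserved); boundary handling is
    reflect padding, avoiding edge darkening on small acquisition matrices.
    """
    kern = gaussian_kernel_1d(diameter_px, sigma_px)
    smoothed = convolve1d(series.signal.astype(float), kern, axis=2, mode="reflect")
    smoothed = convolve1d(smoothed, kern, axis=3, mode="reflect")
    return DSCSeries(signal=smoothed, te_s=series.te_s, tr_s=series.tr_s)


def estimate_baseline(series: DSCSeries, window: tuple[int, int]) -> np.ndarray:
    """Per-voxel baseline S_0: temporal mean over the [start, stop) window."""
    start, stop = window
    if not (0 <= start < stop <= series.n_frames):
        raise ParameterError(
            f"baseline window [{start}, {stop}) empty or outside 0..{series.n_frames}"
        )
    return series.signal[:, start:stop].mean(axis=1)


def signal_to_concentration(
    series: DSCSeries,
    s0: np.ndarray,
    k_const: float = 1.0,
    clamp_nonpositive: bool = False,
    baseline_window: tuple[int, int] = (0, 1),
) -> ConcentrationSeries:
    """Convert signal to tracer concentration, C_m = -(k/TE)·ln(S/S_0).

    Voxel-frames with S <= 0 or S_0 <= 0 are set to NaN rather than
    aborting: isolated dead voxels must not kill a whole-map run.  Negative
    concentrations (signal overshooting baseline) are kept unless
    ``clamp_nonpositive`` floors them at 0.
    """
    if series.te_s <= 0:
        raise MetadataError(f"te_s must be > 0; got {series.te_s}")
    sig = series.signal.astype(float)
    s0b = np.asarray(s0, dtype=float)[:, None, :, :]
    valid = (sig > 0) & (s0b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = -(k_const / series.te_s) * np.log(np.where(valid, sig / s0b, 1.0))
    conc[~valid] = np.nan
    if clamp_nonpositive:
        conc = np.where(np.isnan(conc), np.nan, np.maximum(conc, 0.0))
    return ConcentrationSeries(
        conc=conc,
        baseline_s0=np.asarray(s0, dtype=float),
        baseline_window=tuple(baseline_window),
        k_const=k_const,
        tr_s=series.tr_s,
    )
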