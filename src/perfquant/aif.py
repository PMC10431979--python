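"""Arterial input function extraction and gamma-variate modelling.

The reference-vessel concentration curve (AIF or VOF) is the mean tracer
curve over a hand-drawn vessel mask.  Before deconvolution it may be
replaced by a fitted gamma-variate,

    C_AIF(t) = C0 · (t - t0)^r · exp(-(t - t0)/b)   for t > t0, else 0,

which suppresses noise and the recirculation bump.  t0 is the bolus arrival
time, r the shape exponent and b the decay time constant; the curve peaks at
t0 + r·b and integrates to C0 · b^(r+1) · Γ(r+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._errors import DataError, EmptyMaskError, FitError, ParameterError
from .io import MaskRaster
from .preprocessing import ConcentrationSeries

__all__ = [
    "ReferenceCurve",
    "GammaVariateModel",
    "extract_reference_curve",
    "gamma_variate_eval",
    "fit_gamma_variate",
    "detect_bolus_window",
]


@dataclass
class ReferenceCurve:
    """Mean concentration over the vessel mask, one value per frame."""

    times_s: np.ndarray
    conc: np.ndarray
    role: str = "aif"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times_s.shape != self.conc.shape:
            raise ParameterError("times and concentrations must have equal length")


@dataclass
class GammaVariateModel:
    """Fitted first-pass bolus model (see module docstring for the form)."""

    c0: float
    t0_s: float
    r: float
    b_s: float
    fit_window: tuple[int, int] = (0, 0)  # (arrival_frame, first_pass_end_frame)
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.r <= 0 or self.b_s <= 0:
            raise ParameterError(f"gamma-variate needs r > 0 and b > 0; got r={self.r}, b={self.b_s}")

    @property
    def peak_time_s(self) -> float:
        """Analytic maximum location, t0 + r·b."""
        return self.t0_s + self.r * self.b_s

    def __call__(self, times_s: np.ndarray) -> np.ndarray:
        return gamma_variate_eval(self, times_s)


def gamma_variate_eval(model: GammaVariateModel, times_s: np.ndarray) -> np.ndarray:
    """Evaluate the gamma-variate; exactly 0 for t <= t0."""
    t = np.asarray(times_s, dtype=float)
    dt = t - model.t0_s
    out = np.zeros_like(t, dtype=float)
    pos = dt > 0
    out[pos] = model.c0 * dt[pos] ** model.r * np.exp(-dt[pos] / model.b_s)
    return out


def extract_reference_curve(
    conc: ConcentrationSeries,
    mask: MaskRaster,
    slice_index: int = 0,
) -> ReferenceCurve:
    """Framewise arithmetic mean of concentration over the mask pixels.

    Non-finite voxel-frames are excluded from the mean; a frame where every
    mask voxel is non-finite is a gap and raises :class:`DataError`.
    """
    plane = mask.for_slice(slice_index)
    if not plane.any():
        raise EmptyMaskError(f"{mask.role} mask empty on slice {slice_index}")
    curves = conc.conc[slice_index][:, plane]  # (n_frames, n_pixels)
    finite = np.isfinite(curves)
    if (~finite.any(axis=1)).any():
        bad = np.where(~finite.any(axis=1))[0]
        raise DataError(f"all {mask.role} voxels non-finite at frame(s) {bad.tolist()}")
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(finite, curves, 0.0), axis=1) / finite.sum(axis=1)
    return ReferenceCurve(times_s=conc.frame_times_s, conc=mean, role=mask.role)


def detect_bolus_window(curve: ReferenceCurve, min_frames_above: int = 3) -> tuple[float, float]:
    """Automatic (arrival_s, first_pass_end_s) initializer.

    Arrival: the first frame where the curve exceeds 10% of its peak and
    stays above for ``min_frames_above`` consecutive frames.  First-pass
    end: the first local minimum after the peak, or the last frame if the
    curve decays monotonically (no recirculation).
    """
    c = curve.conc
    peak_idx = int(np.nanargmax(c))
    peak = c[peak_idx]
    if not np.isfinite(peak) or peak <= 0:
        raise DataError("reference curve has no positive peak; cannot locate bolus")
    above = c >= 0.1 * peak
    arrival_idx = None
    for i in range(peak_idx + 1):
        if above[i : i + min_frames_above].all() and i + min_frames_above <= len(c):
            arrival_idx = i
            break
    if arrival_idx is None:
        arrival_idx = peak_idx
    end_idx = len(c) - 1
    for j in range(peak_idx + 1, len(c) - 1):
        if c[j] <= c[j - 1] and c[j] < c[j + 1]:
            end_idx = j
            break
    return float(curve.times_s[arrival_idx]), float(curve.times_s[end_idx])


def fit_gamma_variate(
    curve: ReferenceCurve,
    arrival_s: float,
    first_pass_end_s: float,
    tr_s: float | None = None,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> GammaVariateModel:
    """Least-squares fit of the gamma-variate over [arrival_s, first_pass_end_s].

    t0 is initialized at ``arrival_s`` and bounded within ±2·TR of it; r and
    b are kept positive.  If the first optimization fails, up to
    ``n_restarts`` restarts with jittered (r, b) initial values are tried —
    gamma-variate fits are notoriously init-sensitive.

    Raises
    ------
    ParameterError
        If the window is empty or outside the grid.
    DataError
        If the restricted curve has no positive peak, or the window excludes
        the bolus peak entirely.
    FitError
        If no restart converges.
    """
    if not arrival_s < first_pass_end_s:
        raise ParameterError(f"need arrival_s < first_pass_end_s; got {arrival_s} >= {first_pass_end_s}")
    t, c = curve.times_s, curve.conc
    if arrival_s < t[0] or first_pass_end_s > t[-1]:
        raise ParameterError("fit window must lie inside the acquired time grid")
    if tr_s is None:
        tr_s = float(np.median(np.diff(t)))
    sel = (t >= arrival_s) & (t <= first_pass_end_s) & np.isfinite(c)
    if sel.sum() < 5:
        raise ParameterError(f"fit window contains only {int(sel.sum())} usable frames; need >= 5")
    tw, cw = t[sel], c[sel]

    peak_global = float(np.nanmax(c))
    peak_window = float(cw.max())
    if peak_global <= 0 or peak_window <= 0:
        raise DataError("curve has no positive peak in the fit window")
    if peak_window < 0.5 * peak_global:
        raise DataError(
            f"fit window excludes the bolus peak (window max {peak_window:.3g} "
            f"< 50% of curve max {peak_global:.3g}); adjust arrival/first-pass times"
        )

    t_peak = float(tw[np.argmax(cw)])
    r0 = 3.0
    b0 = max((t_peak - arrival_s) / r0, tr_s / 2.0)

    def model_fn(tt, c0, t0, r, b):
        return gamma_variate_eval(GammaVariateModel(c0=c0, t0_s=t0, r=r, b_s=b), tt)

    lower = [0.0, arrival_s - 2.0 * tr_s, 1e-3, 1e-3]
    upper = [np.inf, arrival_s + 2.0 * tr_s, 20.0, np.inf]

    rng = rng if rng is not None else np.random.default_rng(0)
    inits = [(r0, b0)]
    inits += [
        (r0 * float(rng.uniform(0.5, 2.0)), b0 * float(rng.uniform(0.5, 2.0)))
        for _ in range(n_restarts)
    ]
    last_exc: Exception | None = None
    for r_init, b_init in inits:
        c0_init = peak_window / max(
            (r_init * b_init) ** r_init * np.exp(-r_init), 1e-30
        )  # match model peak height to data peak
        try:
            popt, _ = curve_fit(
                model_fn,
                tw,
                cw,
                p0=[c0_init, arrival_s, r_init, b_init],
                bounds=(lower, upper),
                maxfev=20000,
            )
            resid = cw - model_fn(tw, *popt)
            arrival_frame = int(np.searchsorted(t, arrival_s))
            end_frame = int(np.searchsorted(t, first_pass_end_s))
            return GammaVariateModel(
                c0=float(popt[0]),
                t0_s=float(popt[1]),
                r=float(popt[2]),
                b_s=float(popt[3]),
                fit_window=(arrival_frame, end_frame),
                rss=float(resid @ resid),
            )
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
    raise FitError(
        f"gamma-variate fit did not converge after {len(inits)} initializations: {last_exc}"
    )
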