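"""Absolute parametric maps from residue functions and raw signals.

Deconvolution yields the flow-scaled residue function k(t) per voxel.
Absolute quantification follows:

    CBF [ml/100g/min] = 60 · k_H · max_t k(t)
    CBV [ml/100g]     = k_H · ∫ k(t) dt             (deconvolution route)
    CBV [ml/100g]     = k_H · ∫C_m dt / ∫C_AIF dt   (ratio route, no deconvolution)
    MTT [s]           = 60 · CBV / CBF              (central volume theorem)

with the composite calibration constant

    k_H = 100 · (K_T/K_A) · (1 − H_A)/(1 − H_T) / ρ_Voi

grouping the tissue-to-artery concentration scale factor ratio
(K_T/K_A = 0.136), the large-vessel (H_A = 0.45) and capillary
(H_T = 0.25) hematocrits, and the apparent brain density
(ρ_Voi = 1.04 g/ml): k_H = 9.5897 at these defaults.  The explicit ×60
converts the per-second flow of the internal time grid to the per-minute
convention the maps are printed in.

The model-free signal-recovery indices need no deconvolution:

    SR  [%] = 100 · (S_post − S_pre) / S_pre
    PSR [%] = 100 · (S_post − S_min) / (S_pre − S_min)

A signal returning exactly to baseline gives SR = 0 and PSR = 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import GeometryError, SingularSystemError
from .deconvolution import ResidueFunction
from .io import MapStack
from .preprocessing import ConcentrationSeries

__all__ = [
    "HemodynamicConstants",
    "SRPSRInputs",
    "compute_k_h",
    "compute_cbf",
    "compute_cbv_deconv",
    "compute_cbv_ratio",
    "compute_mtt",
    "compute_sr_psr",
]


@dataclass(frozen=True)
class HemodynamicConstants:
    """Calibration constants converting residue amplitudes to absolute units."""

    kt_over_ka: float = 0.136  # tissue-to-artery concentration scale factor ratio
    h_a: float = 0.45          # hematocrit in large arterial vessels
    h_t: float = 0.25          # hematocrit in the capillary bed
    rho_voi: float = 1.04      # apparent brain density, g/ml

    def __post_init__(self) -> None:
        if not (0 < self.h_a < 1 and 0 < self.h_t < 1):
            raise ValueError("hematocrits must lie in (0, 1)")
        if self.rho_voi <= 0:
            raise ValueError("brain density must be positive")

    @property
    def k_h(self) -> float:
        """Composite constant; always derived, never set independently."""
        return compute_k_h(self)


def compute_k_h(constants: HemodynamicConstants) -> float:
    """k_H = 100 · (K_T/K_A) · (1−H_A)/(1−H_T) / ρ_Voi (= 9.5897 at defaults)."""
    return (
        100.0
        * constants.kt_over_ka
        * (1.0 - constants.h_a)
        / (1.0 - constants.h_t)
        / constants.rho_voi
    )


def _residue_array(residue) -> np.ndarray:
    """(n_frames, ...) array from a ResidueFunction or a per-slice list thereof."""
    if isinstance(residue, ResidueFunction):
        return residue.k_t
    return np.stack([r.k_t for r in residue], axis=1)  # (n_frames, n_slices, rows, cols)


def compute_cbf(residue, constants: HemodynamicConstants = HemodynamicConstants()) -> MapStack:
    """CBF = 60·k_H·max_t k(t) per voxel; negative maxima floored at 0."""
    k = _residue_array(residue)
    with np.errstate(invalid="ignore"):
        peak = np.max(k, axis=0)
        cbf = 60.0 * compute_k_h(constants) * peak
        cbf = np.where(np.isnan(cbf), np.nan, np.maximum(cbf, 0.0))
    return MapStack(name="CBF", values=_as_stack(cbf))


def compute_cbv_deconv(
    residue,
    constants: HemodynamicConstants = HemodynamicConstants(),
    dt_s: float | None = None,
) -> MapStack:
    """CBV = k_H·∫k(t)dt over the acquired grid; floored at 0.

    The integral is the rectangle sum Δt·Σk — the quadrature conjugate to
    the rectangle-rule convolution operator the deconvolution inverts, so
    the identity ∫k = ∫C_m/∫C_AIF carries over to the discrete solution.
    (A trapezoid here would halve the first sample, where the regularized
    residue typically peaks, biasing CBV low.)
    """
    k = _residue_array(residue)
    if dt_s is None:
        dt_s = residue.dt_s if isinstance(residue, ResidueFunction) else residue[0].dt_s
    integral = np.sum(k, axis=0) * dt_s
    cbv = compute_k_h(constants) * integral
    with np.errstate(invalid="ignore"):
        cbv = np.where(np.isnan(cbv), np.nan, np.maximum(cbv, 0.0))
    return MapStack(name="CBV", values=_as_stack(cbv))


def compute_cbv_ratio(
    conc: ConcentrationSeries,
    aif_curve: np.ndarray,
    constants: HemodynamicConstants = HemodynamicConstants(),
) -> MapStack:
    """Non-deconvolution CBV: k_H times the ratio of tissue to AIF integrals."""
    aif = np.asarray(aif_curve, dtype=float)
    denom = np.trapezoid(aif, dx=conc.tr_s)
    if denom <= 0:
        raise SingularSystemError(f"AIF integral must be positive; got {denom}")
    num = np.trapezoid(conc.conc, dx=conc.tr_s, axis=1)  # (slice, row, col)
    cbv = compute_k_h(constants) * num / denom
    with np.errstate(invalid="ignore"):
        cbv = np.where(np.isnan(cbv), np.nan, np.maximum(cbv, 0.0))
    return MapStack(name="CBV", values=cbv)


def compute_mtt(cbv: MapStack, cbf: MapStack) -> MapStack:
    """MTT = 60·CBV/CBF seconds per voxel; CBF = 0 voxels flagged non-finite."""
    if cbv.values.shape != cbf.values.shape:
        raise GeometryError(
            f"CBV shape {cbv.values.shape} != CBF shape {cbf.values.shape}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = 60.0 * cbv.values / cbf.values
        mtt = np.where(cbf.values > 0, mtt, np.nan)
    return MapStack(name="MTT", values=mtt)


@dataclass
class SRPSRInputs:
    """Signal landmarks for the model-free recovery maps.

    s_pre : baseline signal (mean over the pre-bolus window), per voxel.
    s_post : post-bolus signal (window mean near arrival + 60 s), per voxel.
    s_min : signal at the designated minimum-intensity frame, per voxel.
    """

    s_pre: np.ndarray
    s_post: np.ndarray
    s_min: np.ndarray

    def __post_init__(self) -> None:
        self.s_pre = np.asarray(self.s_pre, dtype=float)
        self.s_post = np.asarray(self.s_post, dtype=float)
        self.s_min = np.asarray(self.s_min, dtype=float)
        if not (self.s_pre.shape == self.s_post.shape == self.s_min.shape):
            raise GeometryError("s_pre, s_post, s_min must share shape")


def compute_sr_psr(inputs: SRPSRInputs) -> tuple[MapStack, MapStack]:
    """SR and PSR in percent; PSR is non-finite where S_pre = S_min (flat curve)."""
    pre, post, smin = inputs.s_pre, inputs.s_post, inputs.s_min
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = 100.0 * (post - pre) / pre
        sr = np.where(pre > 0, sr, np.nan)
        denom = pre - smin
        psr = np.where(denom != 0, 100.0 * (post - smin) / denom, np.nan)
    return (
        MapStack(name="SR", values=_as_stack(sr)),
        MapStack(name="PSR", values=_as_stack(psr)),
    )


def _as_stack(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim == 3:
        return values
    if values.ndim == 2:
        return values[None]
    return values.reshape((1, 1, -1))  # scalar / per-voxel vector results
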