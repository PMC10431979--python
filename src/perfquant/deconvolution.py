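"""Regularized deconvolution of tissue curves by the AIF.

The tracer-kinetic model C_m(t) = k(t) * C_AIF(t) is discretized on the
uniform TR grid with the rectangle rule, giving a lower-triangular Toeplitz
system A k = c with A[i, j] = Δt · C_AIF(t_{i-j}) for i >= j.  The system is
severely ill-conditioned, so the pseudo-inverse is filtered through the SVD:

* TSVD  — reciprocal singular values are zeroed where σ_i < f · σ_max
  (truncation fraction f, default 0.2);
* Tikhonov — filter factors σ_i / (σ_i² + λ²) with λ = f · σ_max
  (default fraction 0.2).

20% of σ_max is the conventional operating point for bolus-tracking data;
both fractions are configurable.  The solution k(t) is the flow-scaled
residue function: its maximum is proportional to CBF and its time integral
to CBV.  Negative excursions (regularization ringing) are retained here;
flooring is map-stage policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svd, toeplitz

from ._errors import GeometryError, ParameterError, SingularSystemError

__all__ = [
    "ConvolutionSystem",
    "ResidueFunction",
    "build_convolution_matrix",
    "deconvolve_tsvd",
    "deconvolve_tikhonov",
    "deconvolve_volume",
    "DEFAULT_THRESHOLD_FRAC",
    "DEFAULT_LAMBDA_FRAC",
]

DEFAULT_THRESHOLD_FRAC = 0.2
DEFAULT_LAMBDA_FRAC = 0.2


@dataclass
class ConvolutionSystem:
    """Discrete convolution operator built from the AIF, with its SVD."""

    matrix: np.ndarray  # (n, n) lower-triangular Toeplitz
    dt_s: float
    # SVD factors, computed once and shared across all voxels of a run
    u: np.ndarray = field(repr=False, default=None)
    singular_values: np.ndarray = field(repr=False, default=None)
    vt: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ResidueFunction:
    """Flow-scaled residue function(s) k(t) recovered by deconvolution.

    ``k_t`` is (n_frames,) for a single voxel or (n_frames, n_voxels) for a
    stack.
    """

    k_t: np.ndarray
    method: str  # "tsvd" or "tikhonov"
    reg_param: float
    dt_s: float = 1.0


def build_convolution_matrix(aif_curve: np.ndarray, dt_s: float) -> ConvolutionSystem:
    """Build the lower-triangular Toeplitz operator A[i,j] = Δt·C_AIF(t_{i−j})."""
    aif = np.asarray(aif_curve, dtype=float)
    if aif.ndim != 1 or aif.size < 2:
        raise ParameterError(f"AIF curve must be 1-D with length >= 2; got shape {aif.shape}")
    if dt_s <= 0:
        raise ParameterError(f"dt_s must be > 0; got {dt_s}")
    if not np.any(aif):
        raise SingularSystemError("AIF curve is identically zero; system is singular")
    first_col = dt_s * aif
    first_row = np.zeros_like(first_col)
    first_row[0] = first_col[0]
    a = toeplitz(first_col, first_row)
    u, s, vt = svd(a)
    return ConvolutionSystem(matrix=a, dt_s=dt_s, u=u, singular_values=s, vt=vt)


def _check_curves(system: ConvolutionSystem, cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm, dtype=float)
    if cm.shape[0] != system.n:
        raise GeometryError(
            f"curve length {cm.shape[0]} does not match system size {system.n}"
        )
    return cm


def _filtered_solve(system: ConvolutionSystem, cm: np.ndarray, inv_s: np.ndarray) -> np.ndarray:
    # x = V diag(inv_s) U^T c, vectorized over voxel columns
    return system.vt.T @ (inv_s[:, None] * (system.u.T @ cm)) if cm.ndim == 2 else (
        system.vt.T @ (inv_s * (system.u.T @ cm))
    )


def deconvolve_tsvd(
    system: ConvolutionSystem,
    cm: np.ndarray,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> ResidueFunction:
    """Truncated-SVD solution: drop singular directions with σ < f·σ_max."""
    if not 0 < threshold_frac < 1:
        raise ParameterError(f"threshold_frac must lie in (0,1); got {threshold_frac}")
    cm = _check_curves(system, cm)
    s = system.singular_values
    keep = s >= threshold_frac * s[0]
    inv_s = np.where(keep & (s > 0), 1.0 / np.where(s > 0, s, 1.0), 0.0)
    k = _filtered_solve(system, cm, inv_s)
    return ResidueFunction(k_t=k, method="tsvd", reg_param=threshold_frac, dt_s=system.dt_s)


def deconvolve_tikhonov(
    system: ConvolutionSystem,
    cm: np.ndarray,
    lambda_frac: float = DEFAULT_LAMBDA_FRAC,
) -> ResidueFunction:
    """Tikhonov-filtered solution: filter factors σ/(σ² + λ²), λ = f·σ_max."""
    if lambda_frac <= 0:
        raise ParameterError(f"lambda_frac must be > 0; got {lambda_frac}")
    cm = _check_curves(system, cm)
    s = system.singular_values
    lam = lambda_frac * s[0]
    inv_s = s / (s**2 + lam**2)
    k = _filtered_solve(system, cm, inv_s)
    return ResidueFunction(k_t=k, method="tikhonov", reg_param=lambda_frac, dt_s=system.dt_s)


_SOLVERS = {"tsvd": deconvolve_tsvd, "tikhonov": deconvolve_tikhonov}


def deconvolve_volume(
    system: ConvolutionSystem,
    conc,
    brain_mask,
    method: str = "tsvd",
    reg_param: float | None = None,
) -> list[ResidueFunction]:
    """Deconvolve every in-mask voxel of a :class:`ConcentrationSeries`.

    Returns one :class:`ResidueFunction` per slice whose ``k_t`` is
    (n_frames, rows, cols), NaN outside the mask and at voxels with any
    non-finite concentration frame.  Results are identical to voxelwise
    solver calls (the SVD is shared; the solve is a matrix product).
    """
    if method not in _SOLVERS:
        raise ParameterError(f"method must be one of {sorted(_SOLVERS)}; got {method!r}")
    if reg_param is None:
        reg_param = DEFAULT_THRESHOLD_FRAC if method == "tsvd" else DEFAULT_LAMBDA_FRAC
    solver = _SOLVERS[method]

    def _plane(mask, s_idx):
        # accept a MaskRaster or a plain (possibly all-zero) boolean array
        if hasattr(mask, "for_slice"):
            return mask.for_slice(s_idx)
        m = np.asarray(mask) != 0
        return m if m.ndim == 2 else m[s_idx]

    out = []
    n_slices = conc.conc.shape[0]
    for s_idx in range(n_slices):
        plane = _plane(brain_mask, s_idx)
        rows, cols = plane.shape
        k_full = np.full((system.n, rows, cols), np.nan)
        if plane.any():
            curves = conc.conc[s_idx][:, plane]  # (n_frames, n_vox)
            usable = np.isfinite(curves).all(axis=0)
            if usable.any():
                sol = solver(system, curves[:, usable], reg_param).k_t
                buf = np.full(curves.shape, np.nan)
                buf[:, usable] = sol
                k_full[:, plane] = buf
        out.append(ResidueFunction(k_t=k_full, method=method, reg_param=reg_param, dt_s=system.dt_s))
    return out
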