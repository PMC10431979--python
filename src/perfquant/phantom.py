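"""Digital DSC-MRI phantom: known perfusion truth -> synthetic acquisition.

The phantom inverts the whole measurement chain so the pipeline can be
validated closed-loop without animal data.  Per tissue region with true
flow CBF and volume CBV (hence MTT = 60·CBV/CBF by the central volume
theorem), the flow-scaled residue function is mono-exponential,

    k_true(t) = F · exp(-t / MTT),    F = CBF / (60 · k_H),

the tissue concentration is the discrete convolution of k_true with a
gamma-variate AIF evaluated on a grid ``oversample`` times finer than TR
and then sampled at TR — emulating continuous tracer kinetics rather than
committing the inverse crime of generating data with the same coarse
operator the deconvolution inverts — and the signal follows the T2*
forward model S(t) = S0 · exp(-TE · C(t)), the exact inverse of the
pipeline's concentration conversion, plus optional additive Gaussian
noise.  AIF-mask
voxels carry the AIF curve itself through the same signal model, so AIF
extraction and the gamma refit are exercised, not bypassed.

Acquisition defaults emulate a preclinical bolus-tracking protocol:
TR = 1 s, 180 repetitions, TE = 6.2 ms, bolus injected 20 s after the
acquisition starts.

The brain and AIF masks are eroded a couple of pixels inside the painted
regions (``mask_margin_px``): the 5x5 Gaussian pre-filter mixes boundary
voxels with background, and ROIs are drawn away from edges in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import binary_erosion

from ._errors import ParameterError
from .aif import GammaVariateModel, gamma_variate_eval
from .io import (
    DSCSeries,
    MapStack,
    MaskRaster,
    write_dsc_dicom,
    write_map_tiff,
    write_mask_png,
)
from .maps import HemodynamicConstants, compute_k_h

__all__ = ["PhantomRegion", "PhantomSpec", "PhantomTruth", "synthesize_phantom", "write_phantom_fixture"]


@dataclass(frozen=True)
class PhantomRegion:
    """One homogeneous tissue compartment.

    shape: "circle" with params (center_row, center_col, radius) or "rect"
    with params (row0, col0, row1, col1), half-open.
    """

    shape: str
    params: tuple
    cbf_true: float  # ml/100g/min
    cbv_true: float  # ml/100g
    residue_model: str = "exponential"

    @property
    def mtt_true_s(self) -> float:
        return 60.0 * self.cbv_true / self.cbf_true

    def pixels(self, rows: int, cols: int) -> np.ndarray:
        rr, cc = np.mgrid[0:rows, 0:cols]
        if self.shape == "circle":
            r0, c0, rad = self.params
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        if self.shape == "rect":
            a, b, c, d = self.params
            return (rr >= a) & (rr < c) & (cc >= b) & (cc < d)
        raise ParameterError(f"unknown region shape {self.shape!r}")


def _default_regions() -> list[PhantomRegion]:
    # one healthy grey-matter-like compartment: CBF 60 ml/100g/min, CBV 4 ml/100g
    return [PhantomRegion(shape="circle", params=(22, 22, 12), cbf_true=60.0, cbv_true=4.0)]


def _default_aif() -> GammaVariateModel:
    # amplitude chosen for realistic first-pass depths at TE = 6.2 ms:
    # ~60% signal drop in the vessel, ~25% in tissue
    return GammaVariateModel(c0=30.0, t0_s=20.0, r=3.0, b_s=1.5)


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition."""

    rows: int = 40
    cols: int = 40
    n_slices: int = 1
    regions: list[PhantomRegion] = field(default_factory=_default_regions)
    aif_params: GammaVariateModel = field(default_factory=_default_aif)
    aif_block: tuple[int, int, int, int] = (2, 2, 9, 9)  # (row0, col0, row1, col1)
    te_s: float = 0.0062
    tr_s: float = 1.0
    n_frames: int = 180
    bolus_delay_s: float = 20.0
    s0_level: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0
    oversample: int = 20  # fine-grid factor for the forward convolution
    mask_margin_px: int = 2
    constants: HemodynamicConstants = field(default_factory=HemodynamicConstants)

    def validate(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.oversample < 1:
            raise ParameterError("oversample must be >= 1")
        for reg in self.regions:
            if reg.cbf_true <= 0 or reg.cbv_true <= 0:
                raise ParameterError(f"region perfusion values must be positive: {reg}")
            if reg.residue_model != "exponential":
                raise ParameterError(f"unsupported residue model {reg.residue_model!r}")
            if not reg.pixels(self.rows, self.cols).any():
                raise ParameterError(f"region {reg} lies outside the {self.rows}x{self.cols} grid")


@dataclass
class PhantomTruth:
    """Ground truth shipped alongside the synthetic series."""

    cbf_map: MapStack
    cbv_map: MapStack
    mtt_map: MapStack
    aif_curve_true: np.ndarray
    brain_mask: MaskRaster
    aif_mask: MaskRaster
    s_min_frame: int
    spec: PhantomSpec


def _erode(mask: np.ndarray, margin: int) -> np.ndarray:
    return binary_erosion(mask, iterations=margin) if margin > 0 else mask


def synthesize_phantom(spec: PhantomSpec) -> tuple[DSCSeries, PhantomTruth]:
    """Generate the synthetic series and its ground truth.

    Identical specs (including seed) give bit-identical output.
    """
    spec.validate()
    t = np.arange(spec.n_frames, dtype=float) * spec.tr_s
    aif_model = replace(spec.aif_params, t0_s=spec.bolus_delay_s)
    aif_true = gamma_variate_eval(aif_model, t)
    # forward convolution on a fine grid, then sampled at TR
    over = spec.oversample
    dt_fine = spec.tr_s / over
    t_fine = np.arange(spec.n_frames * over, dtype=float) * dt_fine
    aif_fine = gamma_variate_eval(aif_model, t_fine)
    k_h = compute_k_h(spec.constants)

    conc = np.zeros((spec.n_slices, spec.n_frames, spec.rows, spec.cols))
    cbf_truth = np.full((spec.rows, spec.cols), np.nan)
    cbv_truth = np.full((spec.rows, spec.cols), np.nan)
    brain_pixels = np.zeros((spec.rows, spec.cols), dtype=bool)

    for reg in spec.regions:
        pix = reg.pixels(spec.rows, spec.cols)
        f_amp = reg.cbf_true / (60.0 * k_h)
        k_fine = f_amp * np.exp(-t_fine / reg.mtt_true_s)
        cm = (dt_fine * np.convolve(aif_fine, k_fine)[: t_fine.size])[::over]
        conc[:, :, pix] = cm[None, :, None]
        cbf_truth[pix] = reg.cbf_true
        cbv_truth[pix] = reg.cbv_true
        brain_pixels |= pix

    a, b, c, d = spec.aif_block
    aif_pixels = np.zeros((spec.rows, spec.cols), dtype=bool)
    aif_pixels[a:c, b:d] = True
    if (aif_pixels & brain_pixels).any():
        raise ParameterError("AIF block overlaps a tissue region")
    conc[:, :, aif_pixels] = aif_true[None, :, None]

    signal = spec.s0_level * np.exp(-spec.te_s * conc)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)
    signal = signal.astype(np.float32)
    series = DSCSeries(signal=signal, te_s=spec.te_s, tr_s=spec.tr_s)

    with np.errstate(invalid="ignore"):
        mtt_truth = 60.0 * cbv_truth / cbf_truth
    brain_mask = MaskRaster(pixels=_erode(brain_pixels, spec.mask_margin_px), role="brain")
    aif_mask = MaskRaster(pixels=_erode(aif_pixels, spec.mask_margin_px), role="aif")

    mean_brain_signal = signal[:, :, brain_mask.pixels.astype(bool)].mean(axis=(0, 2))
    truth = PhantomTruth(
        cbf_map=MapStack(name="CBF", values=cbf_truth[None].repeat(spec.n_slices, axis=0)),
        cbv_map=MapStack(name="CBV", values=cbv_truth[None].repeat(spec.n_slices, axis=0)),
        mtt_map=MapStack(name="MTT", values=mtt_truth[None].repeat(spec.n_slices, axis=0)),
        aif_curve_true=aif_true,
        brain_mask=brain_mask,
        aif_mask=aif_mask,
        s_min_frame=int(np.argmin(mean_brain_signal)),
        spec=spec,
    )
    return series, truth


def write_phantom_fixture(
    series: DSCSeries,
    truth: PhantomTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Lay out a fixture directory the CLI can run end-to-end.

    Contents: ``dicom/`` series, ``brain_mask.png``, ``aif_mask.png``,
    ``truth/`` TIFF ground-truth maps and ``run_config.yaml`` with the
    matching pipeline inputs (minimum-intensity frame, bolus timing hints).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dicom_dir = directory / "dicom"
    write_dsc_dicom(series.signal, series.te_s, series.tr_s, dicom_dir)
    brain_path = write_mask_png(truth.brain_mask.pixels, directory / "brain_mask.png")
    aif_path = write_mask_png(truth.aif_mask.pixels, directory / "aif_mask.png")
    truth_dir = directory / "truth"
    for m in (truth.cbf_map, truth.cbv_map, truth.mtt_map):
        write_map_tiff(m, truth_dir)
    config = {
        "dicom_dir": str(dicom_dir),
        "brain_mask": str(brain_path),
        "aif_mask": str(aif_path),
        "s_min_frame": truth.s_min_frame,
        "arrival_s": float(truth.spec.bolus_delay_s),
        "first_pass_end_s": float(truth.spec.bolus_delay_s + 25.0),
        "seed": int(truth.spec.seed),
    }
    config_path = directory / "run_config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return {
        "dicom_dir": dicom_dir,
        "brain_mask": brain_path,
        "aif_mask": aif_path,
        "truth_dir": truth_dir,
        "config": config_path,
    }
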