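"""Non-interactive orchestration of the full quantification workflow.

Order of operations: read inputs -> in-plane Gaussian filter -> baseline ->
SR/PSR maps -> concentration -> AIF extraction -> gamma-variate refit
(optional, on by default) -> convolution system -> per-voxel deconvolution
-> CBF/CBV/MTT maps -> TIFF export + machine-readable report.

Everything interactive in the original workflow (picking the bolus arrival
and first-pass end on screen) is replaced by config scalars plus an
automatic initializer, so identical config + seed reproduce identical
outputs bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from ._errors import ConfigError, StageError
from .aif import (
    GammaVariateModel,
    detect_bolus_window,
    extract_reference_curve,
    fit_gamma_variate,
    gamma_variate_eval,
)
from .deconvolution import (
    DEFAULT_LAMBDA_FRAC,
    DEFAULT_THRESHOLD_FRAC,
    build_convolution_matrix,
    deconvolve_volume,
)
from .io import (
    DSCSeries,
    MapStack,
    MaskRaster,
    read_dsc_dicom,
    read_mask,
    write_map_tiff,
)
from .maps import (
    HemodynamicConstants,
    SRPSRInputs,
    compute_cbf,
    compute_cbv_deconv,
    compute_mtt,
    compute_sr_psr,
)
from .preprocessing import (
    DEFAULT_GAUSSIAN_DIAMETER,
    DEFAULT_GAUSSIAN_SIGMA,
    estimate_baseline,
    gaussian_lowpass,
    signal_to_concentration,
)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "quantify"]

logger = logging.getLogger("perfquant")

_METHODS = ("tsvd", "tikhonov")


@dataclass
class RunConfig:
    """All knobs of one quantification run; every field has a usable default
    except the four input paths and the minimum-intensity frame index."""

    dicom_dir: str | None = None
    brain_mask: str | None = None
    aif_mask: str | None = None
    out_dir: str = "perfquant_out"
    s_min_frame: int | None = None

    override_te_s: float | None = None
    override_tr_s: float | None = None

    # preprocessing
    gaussian_diameter: int = DEFAULT_GAUSSIAN_DIAMETER
    gaussian_sigma: float = DEFAULT_GAUSSIAN_SIGMA
    baseline_window: tuple[int, int] | None = None  # default [0, bolus_frame - 5)
    bolus_frame: int = 20
    clamp_nonpositive: bool = False
    k_const: float = 1.0

    # AIF
    aif_slice: int = 0
    aif_fit_enabled: bool = True
    arrival_s: float | None = None
    first_pass_end_s: float | None = None
    auto_window: bool = True

    # deconvolution
    method: str = "tsvd"
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    lambda_frac: float = DEFAULT_LAMBDA_FRAC

    # calibration constants
    kt_over_ka: float = 0.136
    h_a: float = 0.45
    h_t: float = 0.25
    rho_voi: float = 1.04

    # SR / PSR
    s_post_delay_s: float = 60.0
    s_post_window_frames: int = 5
    per_voxel_smin: bool = False

    log_level: str = "INFO"
    seed: int = 0
    save_figures: bool = True
    # stop after the AIF fit and export only the raw-vs-fitted curve figure;
    # the batch replacement for interactively re-picking the fit window
    aif_report_only: bool = False

    @property
    def constants(self) -> HemodynamicConstants:
        return HemodynamicConstants(
            kt_over_ka=self.kt_over_ka, h_a=self.h_a, h_t=self.h_t, rho_voi=self.rho_voi
        )

    @property
    def reg_param(self) -> float:
        return self.threshold_frac if self.method == "tsvd" else self.lambda_frac


def validate_config(config: dict | RunConfig, n_frames: int | None = None) -> RunConfig:
    """Fill defaults and check consistency; all violations reported together."""
    problems: list[str] = []
    if isinstance(config, dict):
        known = {f.name for f in fields(RunConfig)}
        unknown = set(config) - known
        if unknown:
            problems.append(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**{k: v for k, v in config.items() if k in known})
    else:
        cfg = config

    for key in ("dicom_dir", "brain_mask", "aif_mask"):
        val = getattr(cfg, key)
        if val is None:
            problems.append(f"{key} is required")
        elif not Path(val).exists():
            problems.append(f"{key} path does not exist: {val}")
    if cfg.s_min_frame is None:
        problems.append("s_min_frame (minimum-intensity frame index) is required")
    elif cfg.s_min_frame < 0:
        problems.append(f"s_min_frame must be >= 0; got {cfg.s_min_frame}")
    elif n_frames is not None and cfg.s_min_frame >= n_frames:
        problems.append(f"s_min_frame {cfg.s_min_frame} outside time axis of {n_frames} frames")

    if cfg.method not in _METHODS:
        problems.append(f"method must be one of {list(_METHODS)}; got {cfg.method!r}")
    if not 0 < cfg.threshold_frac < 1:
        problems.append(f"threshold_frac must lie in (0,1); got {cfg.threshold_frac}")
    if cfg.lambda_frac <= 0:
        problems.append(f"lambda_frac must be > 0; got {cfg.lambda_frac}")
    if cfg.gaussian_diameter % 2 == 0 or cfg.gaussian_diameter < 1:
        problems.append(f"gaussian_diameter must be odd and >= 1; got {cfg.gaussian_diameter}")
    if cfg.gaussian_sigma <= 0:
        problems.append(f"gaussian_sigma must be > 0; got {cfg.gaussian_sigma}")
    if not (0 < cfg.h_a < 1 and 0 < cfg.h_t < 1):
        problems.append("hematocrits h_a, h_t must lie in (0,1)")
    if cfg.rho_voi <= 0:
        problems.append("rho_voi must be > 0")
    if (cfg.arrival_s is None) != (cfg.first_pass_end_s is None):
        problems.append("arrival_s and first_pass_end_s must be given together")
    if (
        cfg.arrival_s is not None
        and cfg.first_pass_end_s is not None
        and cfg.arrival_s >= cfg.first_pass_end_s
    ):
        problems.append("arrival_s must be < first_pass_end_s")
    if cfg.baseline_window is not None:
        cfg.baseline_window = tuple(int(v) for v in cfg.baseline_window)
        if not cfg.baseline_window[0] < cfg.baseline_window[1]:
            problems.append(f"baseline_window {cfg.baseline_window} is empty")

    if problems:
        raise ConfigError("invalid run configuration:\n  - " + "\n  - ".join(problems))
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def quantify(
    series: DSCSeries,
    brain_mask: MaskRaster,
    aif_mask: MaskRaster,
    cfg: RunConfig,
) -> dict:
    """Run the computational pipeline in memory on already-loaded inputs.

    Returns a dict with the five MapStacks, the AIF curve and fitted model,
    and the machine-readable report.  Pure function of its inputs: file IO
    lives in :func:`run_pipeline`.
    """
    # --- filter + baseline ------------------------------------------------
    filtered = gaussian_lowpass(series, cfg.gaussian_diameter, cfg.gaussian_sigma)
    window = cfg.baseline_window or (0, max(cfg.bolus_frame - 5, 1))
    s0 = estimate_baseline(filtered, window)
    logger.info("baseline window frames [%d, %d)", *window)

    # --- concentration + AIF ----------------------------------------------
    conc = signal_to_concentration(
        filtered, s0, k_const=cfg.k_const,
        clamp_nonpositive=cfg.clamp_nonpositive, baseline_window=window,
    )
    aif_curve = extract_reference_curve(conc, aif_mask, cfg.aif_slice)
    if cfg.arrival_s is not None:
        arrival_s, first_pass_end_s = cfg.arrival_s, cfg.first_pass_end_s
    else:
        arrival_s, first_pass_end_s = detect_bolus_window(aif_curve)
    logger.info("bolus window: arrival %.1f s, first-pass end %.1f s", arrival_s, first_pass_end_s)

    gamma_model: GammaVariateModel | None = None
    if cfg.aif_fit_enabled:
        gamma_model = fit_gamma_variate(
            aif_curve, arrival_s, first_pass_end_s, tr_s=series.tr_s,
            rng=np.random.default_rng(cfg.seed),
        )
        aif_for_deconv = gamma_variate_eval(gamma_model, aif_curve.times_s)
        logger.info(
            "gamma fit: c0=%.4g t0=%.3f r=%.3f b=%.3f rss=%.4g",
            gamma_model.c0, gamma_model.t0_s, gamma_model.r, gamma_model.b_s, gamma_model.rss,
        )
    else:
        aif_for_deconv = aif_curve.conc

    if cfg.aif_report_only:
        report = _build_report({}, brain_mask, gamma_model, arrival_s, first_pass_end_s, cfg)
        return {
            "maps": {},
            "aif_curve": aif_curve,
            "aif_for_deconv": aif_for_deconv,
            "gamma_model": gamma_model,
            "report": report,
        }

    # --- SR / PSR (model-free, from the filtered signal) --------------------
    arrival_frame = int(round(arrival_s / series.tr_s))
    post_center = int(round((arrival_s + cfg.s_post_delay_s) / series.tr_s))
    half = cfg.s_post_window_frames // 2
    lo = max(min(post_center - half, series.n_frames - 1), 0)
    hi = min(post_center + half + 1, series.n_frames)
    s_post = filtered.signal[:, lo:hi].mean(axis=1)
    if cfg.per_voxel_smin:
        s_min = filtered.signal[:, arrival_frame:].min(axis=1)
    else:
        s_min = filtered.signal[:, int(cfg.s_min_frame)]
    sr_map, psr_map = compute_sr_psr(SRPSRInputs(s_pre=s0, s_post=s_post, s_min=s_min))

    # --- deconvolution + kinetic maps --------------------------------------
    system = build_convolution_matrix(aif_for_deconv, series.tr_s)
    residues = deconvolve_volume(system, conc, brain_mask, cfg.method, cfg.reg_param)
    cbf_map = compute_cbf(residues, cfg.constants)
    cbv_map = compute_cbv_deconv(residues, cfg.constants)
    mtt_map = compute_mtt(cbv_map, cbf_map)

    maps = {"CBF": cbf_map, "CBV": cbv_map, "MTT": mtt_map, "SR": sr_map, "PSR": psr_map}
    for m in maps.values():
        _apply_brain_mask(m, brain_mask)

    report = _build_report(maps, brain_mask, gamma_model, arrival_s, first_pass_end_s, cfg)
    return {
        "maps": maps,
        "aif_curve": aif_curve,
        "aif_for_deconv": aif_for_deconv,
        "gamma_model": gamma_model,
        "residues": residues,
        "conc": conc,
        "report": report,
    }


def _apply_brain_mask(map_stack: MapStack, brain_mask: MaskRaster) -> None:
    for s_idx in range(map_stack.values.shape[0]):
        plane = brain_mask.for_slice(s_idx)
        vals = map_stack.values[s_idx]
        vals[~plane] = np.nan


def _in_mask_stats(map_stack: MapStack, brain_mask: MaskRaster) -> dict:
    vals = []
    for s_idx in range(map_stack.values.shape[0]):
        plane = brain_mask.for_slice(s_idx)
        vals.append(map_stack.values[s_idx][plane])
    v = np.concatenate(vals)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"mean": None, "sd": None, "n_voxels": 0, "units": map_stack.units}
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "n_voxels": int(v.size),
        "units": map_stack.units,
    }


def _build_report(maps, brain_mask, gamma_model, arrival_s, first_pass_end_s, cfg) -> dict:
    import perfquant

    report = {
        "maps": {name: _in_mask_stats(m, brain_mask) for name, m in maps.items()},
        "aif": {
            "arrival_s": float(arrival_s),
            "first_pass_end_s": float(first_pass_end_s),
            "fit_enabled": cfg.aif_fit_enabled,
        },
        "deconvolution": {"method": cfg.method, "reg_param": cfg.reg_param},
        "seed": cfg.seed,
        "versions": {"perfquant": perfquant.__version__, "numpy": np.__version__},
    }
    if gamma_model is not None:
        report["aif"]["gamma_fit"] = {
            "c0": gamma_model.c0,
            "t0_s": gamma_model.t0_s,
            "r": gamma_model.r,
            "b_s": gamma_model.b_s,
            "rss": gamma_model.rss,
        }
    return report


def run_pipeline(config: dict | RunConfig) -> dict:
    """File-based end-to-end run: read inputs, quantify, write maps + report.

    All computation happens before any output is written, so a failed run
    leaves no partial map set behind.  Returns the report dict.
    """
    cfg = validate_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    series = _stage("read_dicom")(read_dsc_dicom)(
        cfg.dicom_dir, override_te_s=cfg.override_te_s, override_tr_s=cfg.override_tr_s
    )
    cfg = validate_config(cfg, n_frames=series.n_frames)
    shape = series.shape_2d
    brain = _stage("read_masks")(read_mask)(cfg.brain_mask, expected_shape=shape, role="brain")
    aif = _stage("read_masks")(read_mask)(cfg.aif_mask, expected_shape=shape, role="aif")

    result = _stage("quantify")(quantify)(series, brain, aif, cfg)

    out_dir = Path(cfg.out_dir)
    written: list[Path] = []
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        for m in result["maps"].values():
            written += write_map_tiff(m, out_dir)
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(result["report"], indent=2))
        written.append(report_path)
        if cfg.save_figures:
            written.append(_export_aif_figure(result, out_dir))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError("write_outputs", exc) from exc
    logger.info("wrote %d output files to %s", len(written), out_dir)
    return result["report"]


def _export_aif_figure(result: dict, out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = result["aif_curve"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.times_s, curve.conc, ".", label="measured AIF", ms=4)
    if result["gamma_model"] is not None:
        ax.plot(curve.times_s, result["aif_for_deconv"], "-", label="gamma-variate fit")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("concentration [1/s]")
    ax.legend()
    fig.tight_layout()
    path = out_dir / "aif_fit.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
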