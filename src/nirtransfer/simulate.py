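"""Synthetic paired-spectrometer generator with known ground truth.

Two instruments observe the *same* chemistry: each latent chemical factor
has a pure-component spectrum defined as a sum of Gaussian bands on the
continuous wavelength domain, so both instruments sample one underlying
function on their own grids — the essential assumption of the transfer
problem.  The default configuration mirrors a bench FT-NIR (1557 points,
1000-2500 nm, sharp) paired with a handheld unit (125 points, 908-1676 nm,
~10 nm smoothing) showing a systematic +0.1 AU offset, with 162 samples —
the scale of a small process-monitoring campaign.

Because the low-resolution instrument's smoothing is itself Gaussian, its
pure components stay analytic (a Gaussian band blurred by a Gaussian is a
Gaussian with the widths added in quadrature), so no discretized
convolution artefacts enter the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .spectra import SpectrumSet
from .splitting import SplitAssignment, make_split

__all__ = ["SimulationConfig", "TransferTask", "generate_pair", "generate_transfer_task"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated paired-instrument campaign.

    Defaults describe the bench/handheld pairing: 162 samples, 3 latent
    chemical factors, source axis 1000-2500 nm at 1557 points, target axis
    908-1676 nm at 125 points, +0.1 AU systematic target offset, 10 nm
    target resolution blur, 0.002 AU additive noise per instrument, analyte
    (factor 1) concentration uniform in 20-60 mg/mL.

    ``reference_noise_sd`` is the error of the reference assay itself (the
    wet-chemistry/analyzer value every model is trained and scored against);
    1.0 mg/mL = 2.5% at mid-range, typical of an automated protein assay.
    It floors the achievable RMSEP of every scenario alike.
    """

    n_samples: int = 162
    n_factors: int = 3
    src_axis_spec: tuple[float, float, int] = (1000.0, 2500.0, 1557)
    tgt_axis_spec: tuple[float, float, int] = (908.0, 1676.0, 125)
    offset: float = 0.1
    noise_sd: float = 0.002
    reference_noise_sd: float = 1.0
    resolution_blur: float = 10.0
    concentration_range: tuple[float, float] = (20.0, 60.0)
    baseline_slope: float = 0.0
    reference_unit: str = "mg/mL"
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi, npts in (self.src_axis_spec, self.tgt_axis_spec):
            if not (lo < hi and npts >= 2):
                raise ParameterError(f"invalid axis spec ({lo}, {hi}, {npts})")
        if self.n_samples < 1 or self.n_factors < 1:
            raise ParameterError("need n_samples >= 1 and n_factors >= 1")
        if min(self.noise_sd, self.reference_noise_sd, self.resolution_blur) < 0:
            raise ParameterError(
                "noise_sd, reference_noise_sd and resolution_blur must be >= 0"
            )
        if not self.concentration_range[0] < self.concentration_range[1]:
            raise ParameterError("empty concentration range")


@dataclass(frozen=True)
class TransferTask:
    """Everything an end-to-end run needs: paired sets, truth, split."""

    source: SpectrumSet
    target: SpectrumSet
    true_concentrations: np.ndarray
    split: SplitAssignment

    def subsets(self, which: str) -> tuple[SpectrumSet, SpectrumSet]:
        idx = {
            "calibration": self.split.calibration_idx,
            "transfer": self.split.transfer_idx,
            "validation": self.split.validation_idx,
        }[which]
        return self.source.subset(idx), self.target.subset(idx)


def _axis(spec: tuple[float, float, int]) -> np.ndarray:
    lo, hi, npts = spec
    return np.linspace(lo, hi, int(npts))


def _draw_bands(rng: np.random.Generator, n_factors: int, lo: float, hi: float):
    """Per factor: Gaussian band centres, widths (nm) and signed heights.

    4 bands per factor, widths 30-120 nm — broad overlapping NIR-like
    overtone/combination bands.
    """
    n_bands = 4
    centers = rng.uniform(lo, hi, size=(n_factors, n_bands))
    widths = rng.uniform(30.0, 120.0, size=(n_factors, n_bands))
    heights = rng.uniform(0.3, 1.0, size=(n_factors, n_bands))
    return centers, widths, heights


def _components_on_axis(
    axis: np.ndarray,
    centers: np.ndarray,
    widths: np.ndarray,
    heights: np.ndarray,
    blur: float,
    scale: float,
) -> np.ndarray:
    """Evaluate the pure-component spectra (n_factors x p) on ``axis``.

    ``blur`` > 0 convolves each band analytically with a Gaussian of that
    width: sigma' = sqrt(sigma^2 + blur^2), height scaled by sigma/sigma' so
    band area is conserved.
    """
    sig = np.sqrt(widths**2 + blur**2)
    amp = heights * widths / sig
    # (factors, bands, axis)
    z = (axis[None, None, :] - centers[:, :, None]) / sig[:, :, None]
    return scale * np.sum(amp[:, :, None] * np.exp(-0.5 * z**2), axis=1)


def pure_components(
    config: SimulationConfig, axis: np.ndarray, blur: float = 0.0
) -> np.ndarray:
    """Ground-truth pure-component spectra of ``config`` on an axis.

    Exposed so tests can compute analytic noise floors and rank structure.
    """
    rng = np.random.default_rng(config.seed)
    lo = min(config.src_axis_spec[0], config.tgt_axis_spec[0])
    hi = max(config.src_axis_spec[1], config.tgt_axis_spec[1])
    centers, widths, heights = _draw_bands(rng, config.n_factors, lo, hi)
    return _components_on_axis(axis, centers, widths, heights, blur, scale=0.02)


def generate_pair(
    config: SimulationConfig,
) -> tuple[SpectrumSet, SpectrumSet, np.ndarray]:
    """Draw one campaign: (source set, target set, true analyte values).

    Both SpectrumSets carry factor 1's concentration as their reference
    values; factors 2..n act as unquantified interferents.  Fully
    determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    src_axis = _axis(config.src_axis_spec)
    tgt_axis = _axis(config.tgt_axis_spec)
    lo = min(src_axis[0], tgt_axis[0])
    hi = max(src_axis[-1], tgt_axis[-1])
    centers, widths, heights = _draw_bands(rng, config.n_factors, lo, hi)
    S_src = _components_on_axis(src_axis, centers, widths, heights, 0.0, 0.02)
    S_tgt = _components_on_axis(
        tgt_axis, centers, widths, heights, config.resolution_blur, 0.02
    )
    c_lo, c_hi = config.concentration_range
    C = rng.uniform(c_lo, c_hi, size=(config.n_samples, config.n_factors))
    clean_src = C @ S_src
    clean_tgt = C @ S_tgt + config.offset
    if config.baseline_slope:
        clean_tgt = clean_tgt + config.baseline_slope * (tgt_axis - tgt_axis[0])
    noisy_src = clean_src + rng.normal(0.0, config.noise_sd, clean_src.shape)
    noisy_tgt = clean_tgt + rng.normal(0.0, config.noise_sd, clean_tgt.shape)
    ids = tuple(f"s{i + 1}" for i in range(config.n_samples))
    refs = C[:, 0] + rng.normal(0.0, config.reference_noise_sd, config.n_samples)
    source = SpectrumSet(
        wavelengths=src_axis,
        absorbance=noisy_src,
        sample_ids=ids,
        references=refs,
        reference_unit=config.reference_unit,
        instrument_label="simulated source (high resolution)",
    )
    target = SpectrumSet(
        wavelengths=tgt_axis,
        absorbance=noisy_tgt,
        sample_ids=ids,
        references=refs,
        reference_unit=config.reference_unit,
        instrument_label="simulated target (low resolution)",
    )
    return source, target, C[:, 0].copy()


def generate_transfer_task(
    config: SimulationConfig,
    n_cal: int = 90,
    n_transfer: int = 30,
    n_val: int = 42,
    split_seed: int | None = None,
    transfer_from: str = "prediction_pool",
) -> TransferTask:
    """Compose :func:`generate_pair` with the Kennard-Stone split.

    The split runs on the source instrument's spectra (the instrument whose
    calibration model exists).  ``split_seed`` defaults to ``config.seed``.
    """
    source, target, truth = generate_pair(config)
    split = make_split(
        source,
        n_cal=n_cal,
        n_transfer=n_transfer,
        n_val=n_val,
        seed=config.seed if split_seed is None else split_seed,
        transfer_from=transfer_from,
    )
    return TransferTask(
        source=source, target=target, true_concentrations=truth, split=split
    )
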