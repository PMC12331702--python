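"""Synthetic data: optical-constant fixtures, Latin-hypercube parameter
sampling, pretraining corpora and controlled domain-shift scenario pairs.

The fixture optical constants are not the published plate-model coefficient
tables (those are loaded from CSV when available) but a physiologically
shaped stand-in: Gaussian absorption bands at the canonical pigment and
water features, scaled so that trait concentrations in their typical ranges
produce realistic optical depths.  They make every test and simulation in
this package self-contained and download-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prospect import (
    DEFAULT_GRID,
    LeafParams,
    OpticalConstants,
    PARAM_NAMES,
    TRAIT_NAMES,
    leaf_rt,
    params_to_traits,
)
from .spectra import SpectraTable

__all__ = [
    "ParamRanges",
    "DomainShiftConfig",
    "synthetic_optical_constants",
    "latin_hypercube",
    "generate_corpus",
    "make_domain_pair",
]


def _gauss(wl: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)


def synthetic_optical_constants(
    grid=DEFAULT_GRID, seed: int = 0
) -> OpticalConstants:
    """Deterministic stand-in optical constants on ``grid``.

    Band placement follows leaf spectroscopy: chlorophyll absorbs in the
    blue and at ~670 nm, carotenoids ~490 nm, anthocyanins ~550 nm, water at
    ~1450 and ~1940 nm (plus weaker 1200 nm), dry matter broadly beyond
    1700 nm, brown pigments decay from 400 nm.  Amplitudes are chosen so the
    typical concentration ranges give optical depths of order 0.1-5.  The
    seed perturbs amplitudes slightly (+-5%) so distinct fixtures exist.
    """
    wl = np.asarray(grid, dtype=float)
    if wl.size == 0:
        raise ValueError("wavelength grid must be non-empty")
    rng = np.random.default_rng(seed)
    j = 1.0 + 0.05 * (rng.random(8) * 2 - 1)  # per-constituent amplitude jitter

    k_ab = j[0] * (_gauss(wl, 670, 45, 0.060) + _gauss(wl, 430, 40, 0.045))
    k_cx = j[1] * (_gauss(wl, 490, 35, 0.045) + _gauss(wl, 450, 30, 0.030))
    k_an = j[2] * _gauss(wl, 550, 40, 0.040)
    k_bp = j[3] * 0.9 * np.exp(-(wl - wl.min()) / 180.0)
    k_w = j[4] * (
        _gauss(wl, 1940, 90, 70.0)
        + _gauss(wl, 1450, 60, 32.0)
        + _gauss(wl, 1200, 50, 4.0)
        + _gauss(wl, 2400, 200, 25.0)
    )
    # dry matter: broad smooth rise past 1700 nm with mild features
    k_m = j[5] * (
        45.0 / (1.0 + np.exp(-(wl - 1900.0) / 150.0))
        + _gauss(wl, 2100, 80, 12.0)
        + _gauss(wl, 2300, 60, 15.0)
    )
    # refractive index: smooth decline 1.45 -> 1.33 across the range
    span = (wl - wl.min()) / max(wl.max() - wl.min(), 1.0)
    n = 1.45 - 0.12 * span
    return OpticalConstants(
        wavelengths_nm=wl, refractive_index=n,
        k_ab=k_ab, k_cx=k_cx, k_an=k_an, k_bp=k_bp, k_w=k_w, k_m=k_m,
    )


# default parameter box: the typical ranges of the seven plate-model inputs
_DEFAULT_BOUNDS = {
    "N": (1.0, 1.9),
    "Cab": (0.1, 100.0),
    "Ccx": (1.0, 25.0),
    "Can": (1.2, 1.8),
    "Cbp": (0.01, 1.0),
    "Cw": (0.01, 0.05),
    "Cm": (0.004, 0.009),
}


@dataclass(frozen=True)
class ParamRanges:
    """Per-parameter (low, high) sampling bounds for the seven leaf inputs."""

    N: tuple = _DEFAULT_BOUNDS["N"]
    Cab: tuple = _DEFAULT_BOUNDS["Cab"]
    Ccx: tuple = _DEFAULT_BOUNDS["Ccx"]
    Can: tuple = _DEFAULT_BOUNDS["Can"]
    Cbp: tuple = _DEFAULT_BOUNDS["Cbp"]
    Cw: tuple = _DEFAULT_BOUNDS["Cw"]
    Cm: tuple = _DEFAULT_BOUNDS["Cm"]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            low, high = getattr(self, name)
            if not low < high:
                raise ValueError(f"{name}: need low < high, got ({low}, {high})")

    def bounds(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])

    def shifted(self, **deltas) -> "ParamRanges":
        """Return ranges with (low, high) of the named parameters shifted by
        a constant, e.g. ``ranges.shifted(Cab=20)``."""
        kwargs = {}
        for name, d in deltas.items():
            low, high = getattr(self, name)
            kwargs[name] = (low + d, high + d)
        return ParamRanges(**{**{n: getattr(self, n) for n in PARAM_NAMES}, **kwargs})


def latin_hypercube(ranges: ParamRanges, n: int, seed: int) -> np.ndarray:
    """n x 7 Latin-hypercube sample of the parameter box.

    Each of the 7 dimensions is divided into n equal-width bins; exactly one
    sample lands in each bin, uniformly within it, with an independent random
    bin permutation per dimension.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bounds = ranges.bounds()
    out = np.empty((n, len(PARAM_NAMES)))
    for d in range(len(PARAM_NAMES)):
        perm = rng.permutation(n)
        u = rng.random(n)
        unit = (perm + u) / n
        low, high = bounds[d]
        out[:, d] = low + unit * (high - low)
    return out


def _params_frame(matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(matrix, columns=list(PARAM_NAMES))


def _simulate(matrix: np.ndarray, constants: OpticalConstants) -> np.ndarray:
    spectra = np.empty((matrix.shape[0], len(constants)))
    for i, row in enumerate(matrix):
        params = LeafParams(**dict(zip(PARAM_NAMES, row)))
        spectra[i] = leaf_rt(params, constants).reflectance
    return spectra


def _traits_from_params(matrix: np.ndarray) -> np.ndarray:
    traits = np.empty((matrix.shape[0], len(TRAIT_NAMES)))
    for i, row in enumerate(matrix):
        t = params_to_traits(LeafParams(**dict(zip(PARAM_NAMES, row))))
        traits[i] = [t[name] for name in TRAIT_NAMES]
    return traits


def generate_corpus(
    ranges: ParamRanges = ParamRanges(),
    n: int = 20000,
    constants: OpticalConstants | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    domain: str = "synthetic",
) -> SpectraTable:
    """Simulate a spectra-trait pretraining corpus.

    LHS parameters -> forward model reflectance (optionally plus i.i.d.
    Gaussian noise, clipped to [0, 1]) with traits derived from the
    parameters; the parameter matrix is retained as a side table.
    """
    if constants is None:
        constants = synthetic_optical_constants()
    rng = np.random.default_rng(seed)
    matrix = latin_hypercube(ranges, n, seed=int(rng.integers(2**31)))
    spectra = _simulate(matrix, constants)
    if noise_sd > 0:
        spectra = np.clip(spectra + rng.normal(0.0, noise_sd, spectra.shape), 0, 1)
    return SpectraTable(
        wavelengths_nm=constants.wavelengths_nm,
        reflectance=spectra,
        traits=_traits_from_params(matrix),
        ids=np.array([f"{domain}_{i}" for i in range(n)]),
        domain=np.full(n, domain, dtype=object),
        params=_params_frame(matrix),
    )


@dataclass
class DomainShiftConfig:
    """A controlled source/target shift scenario.

    The target domain draws leaf parameters from ``target_ranges`` (shifted
    or narrowed relative to the defaults), then applies a band-wise
    multiplicative gain, an additive offset, Gaussian smoothing and additive
    Gaussian noise — emulating instrument and ecosystem differences between
    spectral datasets.
    """

    source_ranges: ParamRanges = field(default_factory=ParamRanges)
    target_ranges: ParamRanges = field(default_factory=ParamRanges)
    gain_low: float = 1.0
    gain_high: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    smooth_fwhm_nm: float = 0.0
    n_source: int = 500
    n_target: int = 500
    fewshot_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_low <= 0 or self.gain_high <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_source < 1 or self.n_target < 1:
            raise ValueError("sample counts must be >= 1")
        if not 0 <= self.fewshot_fraction <= 1:
            raise ValueError("fewshot fraction must be in [0, 1]")


def _smooth(spectra: np.ndarray, wl: np.ndarray, fwhm_nm: float) -> np.ndarray:
    if fwhm_nm <= 0:
        return spectra
    step = float(np.median(np.diff(wl)))
    sigma = fwhm_nm / 2.355 / step
    half = max(int(np.ceil(3 * sigma)), 1)
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(spectra, ((0, 0), (half, half)), mode="edge")
    out = np.empty_like(spectra)
    for i in range(spectra.shape[0]):
        out[i] = np.convolve(padded[i], kernel, mode="valid")
    return out


def make_domain_pair(
    cfg: DomainShiftConfig, constants: OpticalConstants | None = None
) -> tuple[SpectraTable, SpectraTable]:
    """Generate (source, target) tables under the configured shift.

    The source is a clean draw from ``source_ranges``.  The target is drawn
    from ``target_ranges`` and then distorted: per-band gain (linear ramp
    from ``gain_low`` to ``gain_high`` across the grid), constant offset,
    smoothing, noise, and clipping to [0, 1].  A seeded random
    ``fewshot_fraction`` of target rows keeps labels flagged for few-shot
    adaptation (the rest keep labels too — protocols decide what to reveal —
    but only flagged rows are treated as labeled target data).
    """
    if constants is None:
        constants = synthetic_optical_constants()
    rng = np.random.default_rng(cfg.seed)
    s_seed, t_seed, noise_seed, few_seed = rng.integers(2**31, size=4)

    source = generate_corpus(
        cfg.source_ranges, cfg.n_source, constants, seed=int(s_seed),
        domain="source",
    )
    target = generate_corpus(
        cfg.target_ranges, cfg.n_target, constants, seed=int(t_seed),
        domain="target",
    )

    wl = constants.wavelengths_nm
    ramp = np.linspace(cfg.gain_low, cfg.gain_high, wl.size)
    spectra = target.reflectance * ramp + cfg.offset
    spectra = _smooth(spectra, wl, cfg.smooth_fwhm_nm)
    if cfg.noise_sd > 0:
        nrng = np.random.default_rng(int(noise_seed))
        spectra = spectra + nrng.normal(0.0, cfg.noise_sd, spectra.shape)
    spectra = np.clip(spectra, 0.0, 1.0)

    n_few = int(round(cfg.fewshot_fraction * cfg.n_target))
    fewshot = np.zeros(cfg.n_target, dtype=bool)
    if n_few > 0:
        idx = np.random.default_rng(int(few_seed)).choice(
            cfg.n_target, size=n_few, replace=False
        )
        fewshot[idx] = True

    target = SpectraTable(
        wavelengths_nm=wl,
        reflectance=spectra,
        traits=target.traits,
        ids=target.ids,
        domain=target.domain,
        fewshot_mask=fewshot,
        params=target.params,
    )
    return source, target
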