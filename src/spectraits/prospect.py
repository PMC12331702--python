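"""Leaf radiative transfer: the PROSPECT-D generalized plate model.

The leaf is modelled as ``N`` identical compact plates separated by air
spaces.  Each plate absorbs according to a linear mixture of constituent
specific absorption coefficients (chlorophylls, carotenoids, anthocyanins,
brown pigments, water, dry matter) and reflects/refracts at its interfaces
according to Fresnel theory averaged over an incidence cone.  Reflectance
and transmittance of the full stack follow from the classic Stokes
composition of identical layers, extended to non-integer ``N`` through
real-valued exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.special import exp1

__all__ = [
    "OpticalConstants",
    "LeafParams",
    "LeafSpectrum",
    "DEFAULT_GRID",
    "load_optical_constants",
    "tav",
    "elementary_transmission",
    "absorption_spectrum",
    "leaf_rt",
    "params_to_traits",
]

#: 400-2399 nm at 1 nm: 2000 bands, the grid the deep models consume.
DEFAULT_GRID = np.arange(400, 2400)

_K_COLUMNS = ("k_ab", "k_cx", "k_an", "k_bp", "k_w", "k_m")
_CSV_COLUMNS = ("wavelength_nm", "n") + _K_COLUMNS


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelength grid with refractive index and specific absorption spectra.

    Coefficients are per-constituent: ``k_ab`` chlorophyll a+b, ``k_cx``
    carotenoids, ``k_an`` anthocyanins, ``k_bp`` brown pigments, ``k_w``
    water, ``k_m`` dry matter.  Units are the reciprocal of the matching
    concentration unit so that concentration x coefficient is unitless
    optical depth.
    """

    wavelengths_nm: np.ndarray
    refractive_index: np.ndarray
    k_ab: np.ndarray
    k_cx: np.ndarray
    k_an: np.ndarray
    k_bp: np.ndarray
    k_w: np.ndarray
    k_m: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        n = np.asarray(self.refractive_index, dtype=float)
        object.__setattr__(self, "refractive_index", n)
        self._check_vector("refractive_index", n, lower=1.0)
        for name in _K_COLUMNS:
            k = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, k)
            self._check_vector(name, k, lower=0.0)

    def _check_vector(self, name: str, v: np.ndarray, lower: float) -> None:
        if v.shape != self.wavelengths_nm.shape:
            raise ValueError(
                f"{name} has shape {v.shape}, expected {self.wavelengths_nm.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} contains non-finite values")
        if np.any(v < lower):
            idx = int(np.argmax(v < lower))
            raise ValueError(f"{name} below {lower} at row {idx}")

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def to_frame(self) -> pd.DataFrame:
        data = {"wavelength_nm": self.wavelengths_nm, "n": self.refractive_index}
        data.update({name: getattr(self, name) for name in _K_COLUMNS})
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LeafParams:
    """The seven plate-model inputs for one leaf.

    N      structure index (effective plate count, unitless, >= 1)
    Cab    chlorophyll a+b content, ug/cm^2
    Ccx    total carotenoid content, ug/cm^2
    Can    total anthocyanin content, ug/cm^2
    Cbp    brown pigment content, unitless
    Cw     leaf water depth, cm
    Cm     dry matter content, g/cm^2
    """

    N: float = 1.5
    Cab: float = 40.0
    Ccx: float = 10.0
    Can: float = 1.5
    Cbp: float = 0.1
    Cw: float = 0.012
    Cm: float = 0.005

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"structure index N must be >= 1, got {self.N}")
        for name in ("Cab", "Ccx", "Can", "Cbp", "Cw", "Cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.N, self.Cab, self.Ccx, self.Can, self.Cbp, self.Cw, self.Cm]
        )


PARAM_NAMES = ("N", "Cab", "Ccx", "Can", "Cbp", "Cw", "Cm")


@dataclass(frozen=True)
class LeafSpectrum:
    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        t = np.asarray(self.transmittance, dtype=float)
        object.__setattr__(self, "reflectance", r)
        object.__setattr__(self, "transmittance", t)
        if np.any(r < 0) or np.any(t < 0):
            raise ValueError("reflectance/transmittance must be non-negative")
        if np.any(r + t > 1 + 1e-9):
            raise ValueError("reflectance + transmittance exceeds 1")

    @property
    def absorptance(self) -> np.ndarray:
        return 1.0 - self.reflectance - self.transmittance


def load_optical_constants(path) -> OpticalConstants:
    """Read an optical-constants table (CSV) and validate it.

    Expected columns: wavelength_nm, n, k_ab, k_cx, k_an, k_bp, k_w, k_m.
    Rows are sorted by wavelength; duplicate wavelengths are an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"optical constants file missing column(s): {missing}")
    df = df.sort_values("wavelength_nm", kind="stable").reset_index(drop=True)
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        dup = wl[1:][np.diff(wl) <= 0][0]
        raise ValueError(f"wavelength grid not strictly increasing near {dup} nm")
    return OpticalConstants(
        wavelengths_nm=wl,
        refractive_index=df["n"].to_numpy(dtype=float),
        **{name: df[name].to_numpy(dtype=float) for name in _K_COLUMNS},
    )


# ---------------------------------------------------------------------------
# interface optics


def _fresnel_transmission(theta: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unpolarized Fresnel transmissivity, broadcast over incidence angles
    (axis 0) and refractive indices (axis 1), from a medium of index 1 into
    index n.  Zero beyond the critical angle."""
    theta = theta[:, None]
    n = np.atleast_1d(n)[None, :]
    sin_t = np.sin(theta) / n
    ok = sin_t <= 1.0
    sin_t = np.where(ok, sin_t, 0.0)
    ct_i = np.cos(theta)
    ct_t = np.sqrt(1.0 - sin_t**2)
    rs = ((ct_i - n * ct_t) / (ct_i + n * ct_t)) ** 2
    rp = ((n * ct_i - ct_t) / (n * ct_i + ct_t)) ** 2
    return np.where(ok, 1.0 - 0.5 * (rs + rp), 0.0)


_GL_NODES, _GL_WEIGHTS = leggauss(64)


def tav(alpha_deg: float, n) -> np.ndarray | float:
    """Average transmissivity of a dielectric interface for isotropic light
    confined to an incidence cone of half-angle ``alpha_deg``.

    tav(a, n) = int_0^a t_F(th, n) sin th cos th dth / int_0^a sin th cos th dth

    evaluated by 64-node Gauss-Legendre quadrature; vectorized over ``n``.
    """
    if not 0 < alpha_deg <= 90:
        raise ValueError(f"alpha must be in (0, 90] degrees, got {alpha_deg}")
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(n_arr < 1):
        raise ValueError("refractive index must be >= 1")
    alpha = np.deg2rad(alpha_deg)
    theta = 0.5 * alpha * (_GL_NODES + 1.0)
    w = 0.5 * alpha * _GL_WEIGHTS
    meas = w * np.sin(theta) * np.cos(theta)
    vals = meas @ _fresnel_transmission(theta, n_arr) / meas.sum()
    return vals if np.ndim(n) else float(vals[0])


def elementary_transmission(k) -> np.ndarray | float:
    """Isotropic transmission of one elementary absorbing plate.

    tau(k) = (1 - k) e^{-k} + k^2 E1(k), with tau(0) = 1 by continuity.
    Strictly decreasing in the optical depth k >= 0.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k_arr < 0):
        raise ValueError("optical depth k must be non-negative")
    tau = np.ones_like(k_arr)
    pos = k_arr > 0
    kp = k_arr[pos]
    tau[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    tau = np.clip(tau, 0.0, 1.0)
    return tau if np.ndim(k) else float(tau[0])


def absorption_spectrum(params: LeafParams, constants: OpticalConstants) -> np.ndarray:
    """Per-plate optical depth: concentration-weighted sum of specific
    absorption coefficients divided by the structure index N."""
    k = (
        params.Cab * constants.k_ab
        + params.Ccx * constants.k_cx
        + params.Can * constants.k_an
        + params.Cbp * constants.k_bp
        + params.Cw * constants.k_w
        + params.Cm * constants.k_m
    ) / params.N
    return k


# ---------------------------------------------------------------------------
# plate stack

# floor on tau: below this the leaf is numerically opaque and the Stokes
# exponentials would overflow double precision
_TAU_FLOOR = 1e-128

# interface transmissivities depend only on (constants, alpha): cache them
# per OpticalConstants instance so corpus simulation pays the quadrature once
_INTERFACE_CACHE: dict = {}


def _interface_terms(constants: OpticalConstants, alpha_deg: float):
    key = (id(constants), float(alpha_deg))
    hit = _INTERFACE_CACHE.get(key)
    if hit is not None and hit[0] is constants:
        return hit[1]
    n = constants.refractive_index
    talf = np.atleast_1d(tav(alpha_deg, n))
    t12 = np.atleast_1d(tav(90.0, n))
    t21 = t12 / n**2
    terms = (talf, 1.0 - talf, t12, 1.0 - t12, t21, 1.0 - t21)
    if len(_INTERFACE_CACHE) > 32:
        _INTERFACE_CACHE.clear()
    _INTERFACE_CACHE[key] = (constants, terms)
    return terms


def leaf_rt(
    params: LeafParams,
    constants: OpticalConstants,
    alpha_deg: float = 40.0,
) -> LeafSpectrum:
    """Reflectance and transmittance of an N-plate leaf.

    The first plate sees direct light within a cone of half-angle
    ``alpha_deg`` (40 degrees by convention); all internal interfaces see
    isotropic light (90-degree cone).  The remaining N-1 plates are composed
    through the Stokes system with real-valued exponents so non-integer N is
    supported.
    """
    k = absorption_spectrum(params, constants)
    tau = np.maximum(np.atleast_1d(elementary_transmission(k)), _TAU_FLOOR)
    talf, ralf, t12, r12, t21, r21 = _interface_terms(constants, alpha_deg)

    # single plate, directional incidence on top
    x = 1.0 - r21**2 * tau**2
    Ta = talf * tau * t21 / x
    Ra = ralf + r21 * tau * Ta
    # single plate, isotropic incidence (as seen by the plates below)
    t = t12 * tau * t21 / x
    r = r12 + r21 * tau * t

    R, T = _stack_with_substack(Ra, Ta, r, t, params.N)
    R = np.clip(R, 0.0, 1.0)
    T = np.clip(T, 0.0, 1.0)
    # wash out eps-level conservation violations from the clipped algebra
    excess = R + T - 1.0
    over = excess > 0
    if np.any(over):
        R[over] -= 0.5 * excess[over]
        T[over] -= 0.5 * excess[over]
    return LeafSpectrum(constants.wavelengths_nm, R, T)


def _stack_with_substack(Ra, Ta, r, t, N: float):
    """Combine the top plate (Ra, Ta) with a Stokes substack of N-1 plates
    of isotropic single-plate properties (r, t)."""
    if N == 1:
        return Ra.copy(), Ta.copy()

    Rsub = np.empty_like(r)
    Tsub = np.empty_like(t)

    conserving = r + t >= 1.0  # k ~ 0: the discriminant vanishes; analytic limit
    if np.any(conserving):
        tc = t[conserving]
        Tsub[conserving] = tc / (tc + (1.0 - tc) * (N - 1.0))
        Rsub[conserving] = 1.0 - Tsub[conserving]

    g = ~conserving
    if np.any(g):
        rg, tg = r[g], t[g]
        D = np.sqrt(
            (1.0 + rg + tg) * (1.0 + rg - tg) * (1.0 - rg + tg) * (1.0 - rg - tg)
        )
        rq = rg**2
        tq = tg**2
        a = (1.0 + rq - tq + D) / (2.0 * rg)
        b = (1.0 - rq + tq + D) / (2.0 * tg)
        bNm1 = b ** (N - 1.0)
        bN2 = bNm1**2
        a2 = a**2
        denom = a2 * bN2 - 1.0
        Rsub[g] = a * (bN2 - 1.0) / denom
        Tsub[g] = bNm1 * (a2 - 1.0) / denom

    denom = 1.0 - Rsub * r
    T = Ta * Tsub / denom
    R = Ra + Ta * Rsub * t / denom
    return R, T


#: density of liquid water used to convert water depth (cm) to EWT (g/cm^2)
WATER_DENSITY_G_CM3 = 1.0

TRAIT_NAMES = ("CHL", "EWT", "LMA")
TRAIT_UNITS = {"CHL": "ug/cm^2", "EWT": "g/cm^2", "LMA": "g/cm^2"}


def params_to_traits(params: LeafParams) -> dict[str, float]:
    """Map plate-model inputs to the three functional traits.

    CHL = Cab (ug/cm^2); EWT = Cw * rho_water (g/cm^2, rho_water = 1 g/cm^3
    so the numeral is unchanged); LMA = Cm (g/cm^2).
    """
    return {
        "CHL": params.Cab,
        "EWT": params.Cw * WATER_DENSITY_G_CM3,
        "LMA": params.Cm,
    }
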