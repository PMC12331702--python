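"""Spectra-trait tables: the wide-CSV exchange format, grid resampling and
leakage-safe per-band standardization.

A :class:`SpectraTable` holds one row per leaf: a reflectance spectrum on a
common wavelength grid, optional trait labels (CHL, EWT, LMA) and a
domain/dataset label.  The CSV dialect mirrors public spectral-library
exports: an ``id`` column, an optional ``dataset`` column, numeric band
columns named by wavelength, and optional trait columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prospect import TRAIT_NAMES

__all__ = [
    "SpectraTable",
    "BandStats",
    "read_spectra_table",
    "write_spectra_table",
    "resample_to_grid",
    "fit_band_stats",
    "standardize",
    "unstandardize",
]


@dataclass
class SpectraTable:
    """n leaves x b bands of reflectance plus traits and domain labels.

    ``traits`` rows may be NaN throughout for unlabeled samples; a row is
    either fully labeled or fully missing.  ``labeled_mask`` marks the rows
    with trait labels; ``fewshot_mask`` optionally marks the labeled target
    subset available during adaptation.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    traits: np.ndarray
    ids: np.ndarray = None
    domain: np.ndarray = None
    fewshot_mask: np.ndarray = None
    params: pd.DataFrame | None = None  # generator side table, when simulated

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        n, b = self.reflectance.shape
        if self.wavelengths_nm.shape != (b,):
            raise ValueError("band count does not match wavelength grid")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains NaN/inf")
        if self.traits is None:
            self.traits = np.full((n, len(TRAIT_NAMES)), np.nan)
        self.traits = np.atleast_2d(np.asarray(self.traits, dtype=float))
        if self.traits.shape != (n, len(TRAIT_NAMES)):
            raise ValueError(f"traits must be n x {len(TRAIT_NAMES)}")
        row_nan = np.isnan(self.traits)
        partial = np.any(row_nan, axis=1) & ~np.all(row_nan, axis=1)
        if np.any(partial):
            raise ValueError("trait rows must be fully labeled or fully missing")
        if self.ids is None:
            self.ids = np.array([f"s{i}" for i in range(n)])
        self.ids = np.asarray(self.ids)
        if self.domain is None:
            self.domain = np.full(n, "unlabeled_domain", dtype=object)
        self.domain = np.asarray(self.domain, dtype=object)
        if self.fewshot_mask is None:
            self.fewshot_mask = np.zeros(n, dtype=bool)
        self.fewshot_mask = np.asarray(self.fewshot_mask, dtype=bool)
        for name, arr in (("ids", self.ids), ("domain", self.domain),
                          ("fewshot_mask", self.fewshot_mask)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per row")

    def __len__(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def labeled_mask(self) -> np.ndarray:
        return ~np.isnan(self.traits).any(axis=1)

    def subset(self, index) -> "SpectraTable":
        index = np.asarray(index)
        return SpectraTable(
            wavelengths_nm=self.wavelengths_nm,
            reflectance=self.reflectance[index],
            traits=self.traits[index],
            ids=self.ids[index],
            domain=self.domain[index],
            fewshot_mask=self.fewshot_mask[index],
            params=None if self.params is None
            else self.params.iloc[np.atleast_1d(index)].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids, "dataset": self.domain}
        for j, name in enumerate(TRAIT_NAMES):
            cols[name] = self.traits[:, j]
        for j, wl in enumerate(self.wavelengths_nm):
            label = f"{wl:g}"
            cols[label] = self.reflectance[:, j]
        return pd.DataFrame(cols)


def concat_tables(tables) -> SpectraTable:
    """Stack tables sharing a wavelength grid into one."""
    first = tables[0]
    for t in tables[1:]:
        if not np.array_equal(t.wavelengths_nm, first.wavelengths_nm):
            raise ValueError("tables are on different wavelength grids")
    return SpectraTable(
        wavelengths_nm=first.wavelengths_nm,
        reflectance=np.vstack([t.reflectance for t in tables]),
        traits=np.vstack([t.traits for t in tables]),
        ids=np.concatenate([t.ids for t in tables]),
        domain=np.concatenate([t.domain for t in tables]),
        fewshot_mask=np.concatenate([t.fewshot_mask for t in tables]),
    )


def write_spectra_table(table: SpectraTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_spectra_table(path) -> SpectraTable:
    """Read a wide spectra-trait CSV.

    Band columns are identified by numerically parseable headers; anything
    else outside {id, dataset, CHL, EWT, LMA} is a schema error.  Reflectance
    slightly outside [0, 1] (within 0.01, e.g. sensor noise) is clipped;
    larger excursions raise.
    """
    df = pd.read_csv(path)
    reserved = {"id", "dataset", *TRAIT_NAMES}
    band_cols: list[str] = []
    band_wl: list[float] = []
    for col in df.columns:
        if col in reserved:
            continue
        try:
            band_wl.append(float(col))
        except ValueError:
            raise ValueError(f"unparseable band header: {col!r}") from None
        band_cols.append(col)
    if not band_cols:
        raise ValueError("no band columns found")
    order = np.argsort(band_wl)
    wl = np.asarray(band_wl, dtype=float)[order]
    refl = df[band_cols].to_numpy(dtype=float)[:, order]
    if np.any(refl < -0.01) or np.any(refl > 1.01):
        bad = np.argwhere((refl < -0.01) | (refl > 1.01))[0]
        raise ValueError(
            f"reflectance outside [-0.01, 1.01] at row {bad[0]}, band {wl[bad[1]]:g}"
        )
    refl = np.clip(refl, 0.0, 1.0)
    n = len(df)
    traits = np.full((n, len(TRAIT_NAMES)), np.nan)
    for j, name in enumerate(TRAIT_NAMES):
        if name in df.columns:
            traits[:, j] = df[name].to_numpy(dtype=float)
    ids = df["id"].to_numpy() if "id" in df.columns else None
    domain = df["dataset"].to_numpy() if "dataset" in df.columns else None
    return SpectraTable(wl, refl, traits, ids=ids, domain=domain)


def resample_to_grid(table: SpectraTable, grid) -> SpectraTable:
    """Linearly interpolate every spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    wl = table.wavelengths_nm
    if grid[0] < wl[0] or grid[-1] > wl[-1]:
        raise ValueError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] extends beyond the table's span "
            f"[{wl[0]:g}, {wl[-1]:g}]"
        )
    if np.array_equal(grid, wl):
        return table
    refl = np.empty((len(table), grid.size))
    for i in range(len(table)):
        refl[i] = np.interp(grid, wl, table.reflectance[i])
    return SpectraTable(
        grid, refl, table.traits, ids=table.ids, domain=table.domain,
        fewshot_mask=table.fewshot_mask, params=table.params,
    )


@dataclass(frozen=True)
class BandStats:
    """Per-band mean/sd from a training split; the only statistics that may
    touch held-out rows."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean/sd length mismatch")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")


def fit_band_stats(train: SpectraTable) -> BandStats:
    if len(train) == 0:
        raise ValueError("cannot fit band statistics on an empty table")
    return BandStats(
        mean=train.reflectance.mean(axis=0),
        sd=train.reflectance.std(axis=0, ddof=0),
    )


def _scale(stats: BandStats, n_bands: int) -> np.ndarray:
    if stats.mean.shape != (n_bands,):
        raise ValueError(
            f"band stats of length {stats.mean.size} applied to {n_bands} bands"
        )
    # zero-variance bands are centred but not divided
    return np.where(stats.sd > 0, stats.sd, 1.0)


def standardize(table: SpectraTable, stats: BandStats) -> SpectraTable:
    scale = _scale(stats, table.n_bands)
    return replace_reflectance(table, (table.reflectance - stats.mean) / scale)


def unstandardize(table: SpectraTable, stats: BandStats) -> SpectraTable:
    scale = _scale(stats, table.n_bands)
    return replace_reflectance(table, table.reflectance * scale + stats.mean)


def replace_reflectance(table: SpectraTable, values: np.ndarray) -> SpectraTable:
    out = SpectraTable.__new__(SpectraTable)
    out.wavelengths_nm = table.wavelengths_nm
    out.reflectance = np.asarray(values, dtype=float)
    out.traits = table.traits
    out.ids = table.ids
    out.domain = table.domain
    out.fewshot_mask = table.fewshot_mask
    out.params = table.params
    if out.reflectance.shape != table.reflectance.shape:
        raise ValueError("replacement reflectance shape mismatch")
    return out
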