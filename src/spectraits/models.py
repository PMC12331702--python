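"""Model building blocks: spectrum-to-image encoding, the residual encoder
with its trait regression head, target scaling, and the PLSR baseline.

The deep pipeline reshapes a 1-D reflectance spectrum into a square
3-channel image (linear interpolation to side^2 samples, row-major fill,
channel replication) so a 2-D residual encoder can consume it.  The
transformation is approximately invertible: no spectral information is
destroyed beyond interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .nn import Linear, Module, ReLU, ResNetEncoder, Sequential

__all__ = [
    "EncoderConfig",
    "spectrum_to_image",
    "image_to_spectrum",
    "spectra_to_images",
    "build_encoder",
    "TraitNet",
    "TraitScaler",
    "plsr_fit",
    "plsr_predict",
    "PLSTraitRegressor",
]


# ---------------------------------------------------------------------------
# spectrum <-> image


def spectrum_to_image(spectrum: np.ndarray, side: int,
                      mode: str = "interp") -> np.ndarray:
    """Reshape a b-band spectrum into a (3, side, side) tensor.

    ``interp`` (default): linearly interpolate the spectrum to side^2
    samples and fill row-major — smooth, no dead inputs.  ``pad``: place the
    b values row-major and zero-pad the remainder (ablation alternative).
    The result is replicated across three identical channels.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1 or spectrum.size < 2:
        raise ValueError("spectrum must be a 1-D vector with at least 2 bands")
    if side < 2:
        raise ValueError("side must be >= 2")
    m = side * side
    if mode == "interp":
        x_new = np.linspace(0.0, 1.0, m)
        x_old = np.linspace(0.0, 1.0, spectrum.size)
        flat = np.interp(x_new, x_old, spectrum)
    elif mode == "pad":
        flat = np.zeros(m)
        flat[: min(m, spectrum.size)] = spectrum[:m]
    else:
        raise ValueError(f"unknown reshape mode: {mode!r}")
    plane = flat.reshape(side, side)
    return np.repeat(plane[None, :, :], 3, axis=0)


def image_to_spectrum(image: np.ndarray, b: int) -> np.ndarray:
    """Invert :func:`spectrum_to_image` (interp mode) back to b bands."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("image must be (3, side, side)")
    flat = image[0].ravel()
    x_old = np.linspace(0.0, 1.0, flat.size)
    x_new = np.linspace(0.0, 1.0, b)
    return np.interp(x_new, x_old, flat)


def spectra_to_images(X: np.ndarray, side: int, mode: str = "interp") -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], 3, side, side))
    for i in range(X.shape[0]):
        out[i] = spectrum_to_image(X[i], side, mode=mode)
    return out


# ---------------------------------------------------------------------------
# encoder + head

_PRESETS = {
    # side, stem channels, stage output channels, blocks per stage
    "paper": dict(side=224, stem=64, channels=(64, 256, 512, 1024),
                  blocks=(1, 2, 2, 2)),
    "small": dict(side=32, stem=16, channels=(16, 32, 64, 128),
                  blocks=(1, 1, 1, 1)),
}


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture preset for the residual encoder."""

    preset: str = "small"
    seed: int = 0
    reshape_mode: str = "interp"

    def __post_init__(self) -> None:
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; use 'paper' or 'small'")

    @property
    def side(self) -> int:
        return _PRESETS[self.preset]["side"]

    @property
    def channels(self) -> tuple:
        return _PRESETS[self.preset]["channels"]

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]


def build_encoder(cfg: EncoderConfig) -> ResNetEncoder:
    """Deterministically initialized residual encoder for ``cfg``."""
    p = _PRESETS[cfg.preset]
    rng = np.random.default_rng(cfg.seed)
    return ResNetEncoder(p["channels"], p["blocks"], p["stem"], rng)


def build_trait_head(feature_dim: int, rng: np.random.Generator,
                     n_traits: int = 3) -> Sequential:
    hidden = max(feature_dim // 2, 16)
    return Sequential(
        Linear(feature_dim, hidden, rng), ReLU(), Linear(hidden, n_traits, rng)
    )


class TraitNet(Module):
    """Residual encoder plus MLP regression head for the three traits.

    Predictions are in the head's internal (min-max scaled) target space;
    training code owns the :class:`TraitScaler` that maps them back to
    trait units.
    """

    def __init__(self, cfg: EncoderConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = build_encoder(
            EncoderConfig(cfg.preset, seed=int(rng.integers(2**31)),
                          reshape_mode=cfg.reshape_mode)
        )
        head_rng = np.random.default_rng(int(rng.integers(2**31)))
        self.head = build_trait_head(self.encoder.feature_dim, head_rng)

    def forward(self, images: np.ndarray) -> np.ndarray:
        return self.head(self.encoder(images))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.head.backward(grad))


class TraitScaler:
    """Min-max scaling of trait targets to [0, 1], fit on training rows only.

    Traits span four orders of magnitude across their units (CHL ~ tens of
    ug/cm^2, LMA ~ 5e-3 g/cm^2); without scaling a summed MSE is dominated
    by CHL.
    """

    def fit(self, Y: np.ndarray) -> "TraitScaler":
        Y = np.atleast_2d(Y)
        self.lo_ = Y.min(axis=0)
        span = Y.max(axis=0) - self.lo_
        self.span_ = np.where(span > 0, span, 1.0)
        return self

    def transform(self, Y: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(Y) - self.lo_) / self.span_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(Z) * self.span_ + self.lo_


# ---------------------------------------------------------------------------
# PLSR baseline


def plsr_fit(X: np.ndarray, Y: np.ndarray, ncomp: int) -> PLSRegression:
    """PLS2 regression of traits on spectra (centered X and Y)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= ncomp <= max_comp:
        raise ValueError(f"ncomp must be in [1, {max_comp}], got {ncomp}")
    model = PLSRegression(n_components=ncomp, scale=False)
    model.fit(X, Y)
    return model


def plsr_predict(model: PLSRegression, X: np.ndarray) -> np.ndarray:
    return np.atleast_2d(model.predict(np.asarray(X, dtype=float)))


class PLSTraitRegressor(BaseEstimator, RegressorMixin):
    """Partial least squares baseline with CV-selected component count.

    Parameters
    ----------
    n_components : int or "cv"
        Latent dimensionality; "cv" picks the best of 1..max_components by
        internal 5-fold cross-validated MSE.
    max_components : int
        Upper bound of the CV search.
    """

    def __init__(self, n_components="cv", max_components: int = 20,
                 cv_folds: int = 5, seed: int = 0):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("X and Y must be finite")
        hard_max = min(X.shape[0] - 1, X.shape[1])
        if self.n_components == "cv":
            best, best_err = 1, np.inf
            limit = min(self.max_components,
                        X.shape[0] - X.shape[0] // self.cv_folds - 1, X.shape[1])
            kf = KFold(self.cv_folds, shuffle=True, random_state=self.seed)
            for ncomp in range(1, max(limit, 1) + 1):
                err = 0.0
                for tr, te in kf.split(X):
                    m = plsr_fit(X[tr], Y[tr], ncomp)
                    err += float(np.mean((plsr_predict(m, X[te]) - Y[te]) ** 2))
                if err < best_err - 1e-12:
                    best, best_err = ncomp, err
            ncomp = best
        else:
            ncomp = int(self.n_components)
            if not 1 <= ncomp <= hard_max:
                raise ValueError(f"n_components must be in [1, {hard_max}]")
        self.n_components_ = ncomp
        self.model_ = plsr_fit(X, Y, ncomp)
        return self

    def predict(self, X):
        return plsr_predict(self.model_, X)
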