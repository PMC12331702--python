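"""scikit-learn style estimators over the deep training pipeline.

These wrap the table-level :func:`spectraits.adapt.pretrain` /
:func:`spectraits.adapt.adapt` procedures behind the familiar
``fit(X, y)`` / ``predict(X)`` surface so they compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .adapt import FittedTraitModel, TrainConfig, adapt, pretrain
from .models import EncoderConfig
from .prospect import DEFAULT_GRID
from .spectra import SpectraTable

__all__ = ["ResNetTraitRegressor", "DomainAdaptiveTraitRegressor"]


def _table_from_xy(X, y=None, wavelengths=None, domain="data",
                   fewshot_mask=None) -> SpectraTable:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    wl = np.asarray(wavelengths if wavelengths is not None
                    else np.arange(X.shape[1]), dtype=float)
    return SpectraTable(
        wavelengths_nm=wl, reflectance=np.clip(X, 0.0, 1.0), traits=y,
        domain=np.full(X.shape[0], domain, dtype=object),
        fewshot_mask=fewshot_mask,
    )


class ResNetTraitRegressor(BaseEstimator, RegressorMixin):
    """Residual spectral regressor: reflectance (n x b) -> traits (n x 3).

    Spectra are reshaped to 3-channel square images and passed through a
    bottleneck residual encoder with an MLP head; targets are min-max
    scaled internally and predictions returned in trait units.

    Parameters
    ----------
    preset : "small" | "paper"
        Encoder scale; "small" (32x32 input, 16-128 channels) is the
        desk-scale default, "paper" the full-scale 224x224 architecture.
    epochs, batch_size, lr, lr_final :
        Adam schedule; the learning rate decays linearly to ``lr_final``.
    val_fraction : float
        Held-out fraction for the validation-loss history / early stopping.
    patience : int or None
        Early-stopping patience on validation loss (None disables).
    """

    def __init__(self, preset: str = "small", epochs: int = 60,
                 batch_size: int = 64, lr: float = 1e-3,
                 lr_final: float = 1e-5, val_fraction: float = 0.15,
                 patience: int | None = None, seed: int = 0):
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_final = lr_final
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    def _cfg(self) -> TrainConfig:
        return TrainConfig(
            stage1_epochs=self.epochs, stage1_batch=self.batch_size,
            stage1_lr=self.lr, stage1_lr_final=self.lr_final,
            val_fraction=self.val_fraction, seed=self.seed,
        )

    def fit(self, X, y, init_model: FittedTraitModel | None = None):
        table = _table_from_xy(X, y)
        self.model_, self.history_ = pretrain(
            table, self._cfg(),
            encoder_cfg=EncoderConfig(preset=self.preset, seed=self.seed),
            model=init_model, patience=self.patience,
        )
        return self

    def predict(self, X):
        return self.model_.predict(np.atleast_2d(np.asarray(X, dtype=float)))


class DomainAdaptiveTraitRegressor(BaseEstimator, RegressorMixin):
    """Two-stage physics-pretrained, domain-adversarial trait regressor.

    Stage 1 pretrains the encoder on a simulated spectra-trait corpus
    (pass it to :meth:`fit` as ``corpus`` or call :meth:`pretrain_on`);
    stage 2 adapts on labeled source spectra plus a target domain of which
    only a few-shot subset is labeled, aligning features adversarially.

    ``lambda1``/``lambda2`` weight the regression and alignment losses;
    ``da_mode`` selects the gradient-reversed domain discriminator
    ("discriminator") or the direct cosine penalty ("cosine").
    """

    def __init__(self, preset: str = "small", lambda1: float = 1.0,
                 lambda2: float = 0.3, lambda_grl: float = 0.3,
                 da_mode: str = "discriminator",
                 stage1_epochs: int = 60, stage1_batch: int = 64,
                 stage1_lr: float = 1e-3, stage2_epochs: int = 40,
                 stage2_batch: int = 32, stage2_lr: float = 1e-4,
                 seed: int = 0):
        self.preset = preset
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda_grl = lambda_grl
        self.da_mode = da_mode
        self.stage1_epochs = stage1_epochs
        self.stage1_batch = stage1_batch
        self.stage1_lr = stage1_lr
        self.stage2_epochs = stage2_epochs
        self.stage2_batch = stage2_batch
        self.stage2_lr = stage2_lr
        self.seed = seed

    def _cfg(self) -> TrainConfig:
        return TrainConfig(
            stage1_epochs=self.stage1_epochs, stage1_batch=self.stage1_batch,
            stage1_lr=self.stage1_lr, stage2_epochs=self.stage2_epochs,
            stage2_batch=self.stage2_batch, stage2_lr=self.stage2_lr,
            lambda1=self.lambda1, lambda2=self.lambda2,
            lambda_grl=self.lambda_grl, da_mode=self.da_mode, seed=self.seed,
        )

    def _encoder_cfg(self) -> EncoderConfig:
        return EncoderConfig(preset=self.preset, seed=self.seed)

    def pretrain_on(self, corpus: SpectraTable):
        self.pretrained_, self.pretrain_history_ = pretrain(
            corpus, self._cfg(), encoder_cfg=self._encoder_cfg()
        )
        return self

    def fit(self, X, y, *, target_X, target_y=None, target_fewshot=None,
            corpus: SpectraTable | None = None):
        """Fit on labeled source (X, y) and a partially labeled target.

        ``target_fewshot`` is a boolean mask of target rows whose labels
        (``target_y``) may be used; unmasked rows participate only in the
        unsupervised alignment term.
        """
        if corpus is not None:
            self.pretrain_on(corpus)
        source = _table_from_xy(X, y, domain="source")
        target = _table_from_xy(target_X, target_y, domain="target",
                                fewshot_mask=target_fewshot)
        # adapt() trains in place; keep the pretrained weights reusable
        init = copy.deepcopy(getattr(self, "pretrained_", None))
        self.model_, self.history_ = adapt(
            init, source, target, self._cfg(),
            encoder_cfg=self._encoder_cfg(),
        )
        return self

    def predict(self, X):
        return self.model_.predict(np.atleast_2d(np.asarray(X, dtype=float)))
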