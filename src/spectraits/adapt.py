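"""Losses and the two-stage training procedure.

Stage 1 (``pretrain``) fits the encoder + trait head on a simulated
spectra-trait corpus by summed per-trait MSE.  Stage 2 (``adapt``) fine
tunes on real/shifted data: the MSE term uses labeled source rows plus the
few-shot labeled target subset, while a domain-alignment term acts on all
rows of both domains through a cosine-similarity contrastive attention
module followed by either a gradient-reversed domain discriminator
(default, DANN-style adversarial confusion) or a direct cosine alignment
penalty.  The composite objective is

    L = lambda1 * L_MSE + lambda2 * L_DA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import EncoderConfig, TraitNet, TraitScaler, spectra_to_images
from .nn import Adam, GradientReversal, Linear, Module, ReLU, Sequential
from .spectra import SpectraTable

__all__ = [
    "TrainConfig",
    "FittedTraitModel",
    "mse_loss",
    "contrastive_attention",
    "gradient_reversal",
    "DomainDiscriminator",
    "domain_adaptation_loss",
    "composite_loss",
    "pretrain",
    "adapt",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters for both training stages.

    Stage-1 defaults: 200 epochs, batch 64, Adam with learning rate decaying
    linearly from 1e-3 to 1e-5.  Stage-2: 100 epochs, batch 32, 1e-4.
    ``lambda1``/``lambda2`` weight the MSE and domain-adaptation terms;
    ``lambda_grl`` scales the reversed gradient.
    """

    stage1_epochs: int = 200
    stage1_batch: int = 64
    stage1_lr: float = 1e-3
    stage1_lr_final: float = 1e-5
    stage2_epochs: int = 100
    stage2_batch: int = 32
    stage2_lr: float = 1e-4
    lambda1: float = 1.0
    lambda2: float = 0.3
    lambda_grl: float = 0.3
    da_mode: str = "discriminator"
    fewshot_fraction: float = 0.10
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0 or self.lambda_grl < 0:
            raise ValueError("loss weights must be non-negative")
        if self.stage1_epochs < 0 or self.stage2_epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.stage1_batch < 1 or self.stage2_batch < 1:
            raise ValueError("batch size must be >= 1")
        if self.da_mode not in ("discriminator", "cosine"):
            raise ValueError(f"unknown da_mode {self.da_mode!r}")


# ---------------------------------------------------------------------------
# losses


def mse_loss(y: np.ndarray, yhat: np.ndarray):
    """Summed per-trait mean squared error.

    Returns ``(total, per_trait)`` where ``per_trait[m]`` is the mean over
    samples of the squared error of trait m and ``total`` is the sum over
    traits.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    per_trait = np.mean((y - yhat) ** 2, axis=0)
    return float(per_trait.sum()), per_trait


def _mse_grad(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    return 2.0 * (yhat - y) / y.shape[0]


def contrastive_attention(Fs: np.ndarray, Ft: np.ndarray):
    """Cross-domain cosine-similarity attention.

    Each source row is weighted by its best cosine similarity to any target
    row, clipped at zero (and symmetrically for target rows): shared
    patterns are emphasized, domain-specific rows suppressed.  Zero-norm
    rows get weight 0.  Returns (weighted Fs, weighted Ft, ws, wt).
    """
    Fs = np.atleast_2d(np.asarray(Fs, dtype=float))
    Ft = np.atleast_2d(np.asarray(Ft, dtype=float))
    if Fs.shape[1] != Ft.shape[1]:
        raise ValueError("feature dimensions differ between domains")
    ns = np.linalg.norm(Fs, axis=1)
    nt = np.linalg.norm(Ft, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Fs_n = np.where(ns[:, None] > 0, Fs / np.maximum(ns, 1e-300)[:, None], 0.0)
        Ft_n = np.where(nt[:, None] > 0, Ft / np.maximum(nt, 1e-300)[:, None], 0.0)
    S = Fs_n @ Ft_n.T
    ws = np.clip(S.max(axis=1), 0.0, 1.0)
    wt = np.clip(S.max(axis=0), 0.0, 1.0)
    ws = np.where(ns > 0, ws, 0.0)
    wt = np.where(nt > 0, wt, 0.0)
    return ws[:, None] * Fs, wt[:, None] * Ft, ws, wt


def gradient_reversal(x: np.ndarray, lambda_grl: float = 0.3) -> GradientReversal:
    """Build a gradient-reversal layer and run its forward pass.

    Returns the layer (holding nothing but lambda) — call ``.forward`` /
    ``.backward`` to use it inside a computation.  Provided for symmetry
    with the other loss operations; most code uses
    :class:`spectraits.nn.GradientReversal` directly.
    """
    layer = GradientReversal(lambda_grl)
    layer.forward(np.asarray(x))
    return layer


class DomainDiscriminator(Module):
    """Two-layer domain classifier emitting one logit per row."""

    def __init__(self, feature_dim: int, hidden: int = 32, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.net = Sequential(
            Linear(feature_dim, hidden, rng), ReLU(), Linear(hidden, 1, rng)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps)))


def _cosine_da(wFs: np.ndarray, wFt: np.ndarray, with_grad: bool):
    """L_DA = 1 - cos(mean weighted source, mean weighted target)."""
    mu_s = wFs.mean(axis=0)
    mu_t = wFt.mean(axis=0)
    ns, nt = np.linalg.norm(mu_s), np.linalg.norm(mu_t)
    if ns == 0 or nt == 0:
        loss = 1.0
        if not with_grad:
            return loss
        return loss, np.zeros_like(wFs), np.zeros_like(wFt)
    c = float(mu_s @ mu_t / (ns * nt))
    loss = 1.0 - c
    if not with_grad:
        return loss
    dmu_s = -(mu_t / (ns * nt) - c * mu_s / ns**2)
    dmu_t = -(mu_s / (ns * nt) - c * mu_t / nt**2)
    gs = np.broadcast_to(dmu_s / wFs.shape[0], wFs.shape).copy()
    gt = np.broadcast_to(dmu_t / wFt.shape[0], wFt.shape).copy()
    return loss, gs, gt


def domain_adaptation_loss(
    wFs: np.ndarray,
    wFt: np.ndarray,
    mode: str = "discriminator",
    discriminator: DomainDiscriminator | None = None,
    lambda_grl: float = 0.3,
) -> float:
    """Scalar domain-adaptation loss on attention-weighted features.

    ``discriminator`` mode: binary cross-entropy of a 2-layer domain
    classifier (source label 0, target label 1); during training a
    gradient-reversal layer sits between encoder and classifier.
    ``cosine`` mode: 1 - cosine of the two domain prototype means.
    """
    wFs = np.atleast_2d(np.asarray(wFs, dtype=float))
    wFt = np.atleast_2d(np.asarray(wFt, dtype=float))
    if mode == "cosine":
        return float(_cosine_da(wFs, wFt, with_grad=False))
    if mode == "discriminator":
        if discriminator is None:
            discriminator = DomainDiscriminator(wFs.shape[1])
        z = np.vstack([wFs, wFt])
        labels = np.concatenate([np.zeros(len(wFs)), np.ones(len(wFt))])
        p = _sigmoid(discriminator(z)[:, 0])
        return _bce(p, labels)
    raise ValueError(f"unknown domain adaptation mode {mode!r}")


def composite_loss(l_mse: float, l_da: float,
                   lambda1: float = 1.0, lambda2: float = 0.3) -> float:
    """The stage-2 objective: lambda1 * L_MSE + lambda2 * L_DA."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    return lambda1 * l_mse + lambda2 * l_da


# ---------------------------------------------------------------------------
# fitted model bundle


@dataclass
class FittedTraitModel:
    """Encoder + head plus the target scaler that maps head outputs back to
    trait units."""

    net: TraitNet
    scaler: TraitScaler
    encoder_cfg: EncoderConfig

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Reflectance matrix (n x b) -> trait predictions (n x 3)."""
        self.net.eval()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        preds = []
        for start in range(0, X.shape[0], batch_size):
            images = spectra_to_images(
                X[start : start + batch_size], self.net.cfg.side,
                mode=self.encoder_cfg.reshape_mode,
            )
            preds.append(self.net(images))
        return self.scaler.inverse_transform(np.vstack(preds))


# ---------------------------------------------------------------------------
# stage 1: physics pretraining


def _lr_schedule(epoch: int, epochs: int, lr0: float, lr1: float) -> float:
    if epochs <= 1:
        return lr0
    frac = epoch / (epochs - 1)
    return lr0 + frac * (lr1 - lr0)


def _train_val_split(n: int, val_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    if n - n_val < 1:
        n_val = 0
    return idx[n_val:], idx[:n_val]


def pretrain(
    corpus: SpectraTable,
    cfg: TrainConfig = TrainConfig(),
    encoder_cfg: EncoderConfig | None = None,
    model: FittedTraitModel | None = None,
    patience: int | None = None,
):
    """Stage-1 supervised training on a fully labeled (simulated) corpus.

    Minimizes the summed per-trait MSE on min-max scaled targets with Adam
    and a linearly decaying learning rate.  Returns the fitted model and a
    history dict with per-epoch training and validation loss.  When
    ``patience`` is set, training stops after that many epochs without
    validation improvement and the best-validation parameters are restored.
    """
    if len(corpus) == 0:
        raise ValueError("pretraining corpus is empty")
    if not corpus.labeled_mask.all():
        raise ValueError("pretraining corpus must be fully labeled")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        encoder_cfg = encoder_cfg or EncoderConfig(seed=int(rng.integers(2**31)))
        net = TraitNet(encoder_cfg)
        scaler = TraitScaler().fit(corpus.traits)
        model = FittedTraitModel(net, scaler, encoder_cfg)
    net, scaler = model.net, model.scaler

    tr_idx, val_idx = _train_val_split(len(corpus), cfg.val_fraction, rng)
    side = net.cfg.side
    images = spectra_to_images(corpus.reflectance, side,
                               mode=model.encoder_cfg.reshape_mode)
    Y = scaler.transform(corpus.traits)

    opt = Adam(net.params(), lr=cfg.stage1_lr)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(cfg.stage1_epochs):
        lr = _lr_schedule(epoch, cfg.stage1_epochs, cfg.stage1_lr, cfg.stage1_lr_final)
        net.train()
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, order.size, cfg.stage1_batch):
            batch = order[start : start + cfg.stage1_batch]
            net.zero_grad()
            yhat = net(images[batch])
            total, _ = mse_loss(Y[batch], yhat)
            net.backward(_mse_grad(Y[batch], yhat))
            opt.step(lr)
            losses.append(total)
        history["train_loss"].append(float(np.mean(losses)))
        if val_idx.size:
            net.eval()
            val_loss, _ = mse_loss(Y[val_idx], net(images[val_idx]))
        else:
            val_loss = float("nan")
        history["val_loss"].append(float(val_loss))
        if patience is not None and val_idx.size:
            if val_loss < best_val - 1e-12:
                best_val, best_state, since_best = val_loss, net.state(), 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
    if patience is not None and best_state is not None:
        net.load_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# stage 2: adversarial adaptation


def adapt(
    model: FittedTraitModel | None,
    source: SpectraTable,
    target: SpectraTable,
    cfg: TrainConfig = TrainConfig(),
    encoder_cfg: EncoderConfig | None = None,
):
    """Stage-2 fine-tuning with domain alignment.

    The MSE term sees labeled source rows plus the target rows flagged in
    ``target.fewshot_mask``; the domain-adaptation term sees all rows of
    both domains.  ``model=None`` starts from random initialization (the
    GRL-only ablation); ``cfg.lambda2 = 0`` disables alignment entirely
    (supervised fine-tuning, the physics-only ablation).
    """
    if len(target) == 0:
        raise ValueError("no target rows")
    if len(source) == 0 and cfg.lambda2 > 0:
        raise ValueError("domain alignment requires rows from both domains")
    rng = np.random.default_rng(cfg.seed)

    if model is None:
        encoder_cfg = encoder_cfg or EncoderConfig(seed=int(rng.integers(2**31)))
        net = TraitNet(encoder_cfg)
        model = FittedTraitModel(net, TraitScaler(), encoder_cfg)
        scaler_needs_fit = True
    else:
        net = model.net
        scaler_needs_fit = not hasattr(model.scaler, "lo_")

    few = target.fewshot_mask & target.labeled_mask
    src_lab = source.labeled_mask
    if scaler_needs_fit:
        pool = [source.traits[src_lab]]
        if few.any():
            pool.append(target.traits[few])
        model.scaler.fit(np.vstack(pool))
    scaler = model.scaler

    side = net.cfg.side
    img_s = spectra_to_images(source.reflectance, side,
                              mode=model.encoder_cfg.reshape_mode)
    img_t = spectra_to_images(target.reflectance, side,
                              mode=model.encoder_cfg.reshape_mode)
    Ys = scaler.transform(source.traits)
    Yt = scaler.transform(np.where(np.isnan(target.traits), 0.0, target.traits))

    use_da = cfg.lambda2 > 0
    params = net.params()
    grl = disc = None
    if use_da and cfg.da_mode == "discriminator":
        grl = GradientReversal(cfg.lambda_grl)
        disc = DomainDiscriminator(net.encoder.feature_dim,
                                   seed=int(rng.integers(2**31)))
        params = params + disc.params()
    opt = Adam(params, lr=cfg.stage2_lr)

    half = max(cfg.stage2_batch // 2, 1)
    steps = max(int(np.ceil(len(source) / half)), 1)
    history = {"mse_loss": [], "da_loss": []}
    for _ in range(cfg.stage2_epochs):
        net.train()
        s_order = rng.permutation(len(source))
        t_order = rng.permutation(len(target))
        ep_mse, ep_da = [], []
        for step in range(steps):
            sb = s_order[np.arange(step * half, (step + 1) * half) % len(source)]
            tb = t_order[np.arange(step * half, (step + 1) * half) % len(target)]
            images = np.vstack([img_s[sb], img_t[tb]])
            n_s = sb.size

            net.zero_grad()
            if disc is not None:
                disc.zero_grad()
            feats = net.encoder(images)
            dfeats = np.zeros_like(feats)

            # trait regression on the labeled rows of the joint batch
            lab_rows = np.concatenate([
                np.flatnonzero(src_lab[sb]),
                n_s + np.flatnonzero(few[tb]),
            ])
            l_mse = 0.0
            if lab_rows.size:
                y_true = np.vstack([Ys[sb][src_lab[sb]], Yt[tb][few[tb]]])
                yhat = net.head(feats[lab_rows])
                l_mse, _ = mse_loss(y_true, yhat)
                dlab = net.head.backward(_mse_grad(y_true, yhat))
                dfeats[lab_rows] += cfg.lambda1 * dlab

            # domain alignment on all rows of the joint batch
            l_da = 0.0
            if use_da:
                Fs, Ft = feats[:n_s], feats[n_s:]
                wFs, wFt, ws, wt = contrastive_attention(Fs, Ft)
                if cfg.da_mode == "discriminator":
                    z = np.vstack([wFs, wFt])
                    labels = np.concatenate(
                        [np.zeros(n_s), np.ones(len(images) - n_s)]
                    )
                    logits = disc(grl.forward(z))[:, 0]
                    p = _sigmoid(logits)
                    l_da = _bce(p, labels)
                    dlogits = ((p - labels) / len(labels))[:, None]
                    dz = grl.backward(disc.backward(cfg.lambda2 * dlogits))
                    # attention weights treated as constants
                    dfeats[:n_s] += dz[:n_s] * ws[:, None]
                    dfeats[n_s:] += dz[n_s:] * wt[:, None]
                else:
                    l_da, gs, gt = _cosine_da(wFs, wFt, with_grad=True)
                    dfeats[:n_s] += cfg.lambda2 * gs * ws[:, None]
                    dfeats[n_s:] += cfg.lambda2 * gt * wt[:, None]

            net.encoder.backward(dfeats)
            opt.step()
            ep_mse.append(l_mse)
            ep_da.append(l_da)
        history["mse_loss"].append(float(np.mean(ep_mse)))
        history["da_loss"].append(float(np.mean(ep_da)))
    return model, history
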