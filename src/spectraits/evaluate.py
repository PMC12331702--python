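"""Metrics, validation protocols and the model benchmark harness.

Metrics: the coefficient of determination

    R^2 = 1 - sum_i (yhat_i - y_i)^2 / sum_i (y_i - ybar)^2

and the normalized root-mean-square error nRMSE = RMSE / ybar.

Protocols: dataset-stratified k-fold cross-validation on the pooled rows,
leave-one-dataset-out (and its ordered pairwise variant), and a fixed
train-on-many / test-on-one holdout.  Standardization, target scaling and
early stopping only ever see training rows — held-out statistics never
leak into a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adapt import FittedTraitModel, TrainConfig, adapt, pretrain
from .models import EncoderConfig, PLSTraitRegressor
from .prospect import TRAIT_NAMES
from .spectra import SpectraTable, concat_tables, fit_band_stats, standardize
from .synth import ParamRanges, generate_corpus

__all__ = [
    "r_squared",
    "nrmse",
    "EvalReport",
    "stratified_kfold",
    "run_kfold",
    "leave_one_dataset_out",
    "benchmark",
    "sweep_pretrain_size",
    "MODEL_NAMES",
    "build_model",
    "OracleModel",
    "PLSRModelAdapter",
    "DeepModelAdapter",
]


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size < 2 or y.shape != yhat.shape:
        raise ValueError("need matched vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant observations")
    ss_res = float(np.sum((yhat - y) ** 2))
    return 1.0 - ss_res / ss_tot


def nrmse(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("shape mismatch")
    ybar = float(y.mean())
    if ybar == 0:
        raise ValueError("nRMSE undefined when the observed mean is zero")
    return float(np.sqrt(np.mean((yhat - y) ** 2)) / ybar)


@dataclass
class EvalReport:
    """Per-trait, per-trial metrics with protocol provenance."""

    records: list = field(default_factory=list)

    def add(self, *, protocol: str, model: str, trial: str, trait: str,
            r2: float, nrmse_value: float, seed: int, n_test: int) -> None:
        self.records.append(dict(
            protocol=protocol, model=model, trial=trial, trait=trait,
            r2=r2, nrmse=nrmse_value, seed=seed, n_test=n_test,
        ))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def aggregate(self, by=("protocol", "model", "trait")) -> pd.DataFrame:
        df = self.frame()
        return (
            df.groupby(list(by))[["r2", "nrmse"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def extend(self, other: "EvalReport") -> None:
        self.records.extend(other.records)


def _score(report: EvalReport, table: SpectraTable, preds: np.ndarray, *,
           protocol: str, model: str, trial: str, seed: int) -> None:
    for j, trait in enumerate(TRAIT_NAMES):
        report.add(
            protocol=protocol, model=model, trial=trial, trait=trait,
            r2=r_squared(table.traits[:, j], preds[:, j]),
            nrmse_value=nrmse(table.traits[:, j], preds[:, j]),
            seed=seed, n_test=len(table),
        )


# ---------------------------------------------------------------------------
# model adapters: a uniform fit/predict surface over SpectraTables


class TableModel:
    """Protocol: fit on a training table (optionally with an unlabeled or
    few-shot-labeled target table) and predict traits for any table."""

    name = "model"

    def fit(self, train: SpectraTable,
            target: SpectraTable | None = None) -> "TableModel":
        raise NotImplementedError

    def predict_table(self, table: SpectraTable) -> np.ndarray:
        raise NotImplementedError


class OracleModel(TableModel):
    """Returns the true traits — the protocol-engine sanity check."""

    name = "oracle"

    def fit(self, train, target=None):
        return self

    def predict_table(self, table):
        return table.traits.copy()


class PLSRModelAdapter(TableModel):
    """PLSR on per-band standardized reflectance (train statistics only)."""

    name = "PLSR"

    def __init__(self, n_components="cv", seed: int = 0) -> None:
        self.est = PLSTraitRegressor(n_components=n_components, seed=seed)

    def fit(self, train, target=None):
        self.stats_ = fit_band_stats(train)
        z = standardize(train, self.stats_)
        self.est.fit(z.reflectance, train.traits)
        return self

    def predict_table(self, table):
        z = standardize(table, self.stats_)
        return self.est.predict(z.reflectance)


class DeepModelAdapter(TableModel):
    """The residual-encoder family: plain, physics-pretrained, adversarial,
    and the combined two-stage variant.

    ``pretrain_corpus`` enables physics pretraining; ``use_da`` enables the
    adversarial alignment stage against the provided target table.  The four
    deep benchmark entries are configurations of this one adapter:

    - ResNet            — no pretraining, no alignment
    - ResNet-PROSPECT   — pretraining, no alignment (lambda2 = 0)
    - ResNet-GRL        — no pretraining, alignment
    - the full model    — pretraining + alignment
    """

    def __init__(self, name: str, cfg: TrainConfig,
                 encoder_cfg: EncoderConfig | None = None,
                 pretrain_corpus: SpectraTable | None = None,
                 use_da: bool = True, patience: int | None = None) -> None:
        self.name = name
        self.cfg = cfg
        self.encoder_cfg = encoder_cfg or EncoderConfig(seed=cfg.seed)
        self.pretrain_corpus = pretrain_corpus
        self.use_da = use_da
        self.patience = patience
        self.model_: FittedTraitModel | None = None

    def fit(self, train, target=None):
        model = None
        if self.pretrain_corpus is not None:
            model, self.pretrain_history_ = pretrain(
                self.pretrain_corpus, self.cfg, encoder_cfg=self.encoder_cfg,
                patience=self.patience,
            )
        stage2 = self.cfg if self.use_da else _no_da(self.cfg)
        if target is None:
            # no separate target domain: plain supervised (fine-)tuning on
            # the training rows using the stage-2 budget
            sup = TrainConfig(
                stage1_epochs=self.cfg.stage2_epochs,
                stage1_batch=self.cfg.stage2_batch,
                stage1_lr=self.cfg.stage2_lr,
                stage1_lr_final=self.cfg.stage2_lr,
                val_fraction=self.cfg.val_fraction,
                seed=self.cfg.seed,
            )
            self.model_, self.history_ = pretrain(
                train, sup, encoder_cfg=self.encoder_cfg, model=model,
                patience=self.patience,
            )
        else:
            self.model_, self.history_ = adapt(
                model, train, target, stage2, encoder_cfg=self.encoder_cfg
            )
        return self

    def predict_table(self, table):
        return self.model_.predict(table.reflectance)


def _no_da(cfg: TrainConfig) -> TrainConfig:
    kwargs = {f: getattr(cfg, f) for f in TrainConfig.__dataclass_fields__}
    kwargs["lambda2"] = 0.0
    return TrainConfig(**kwargs)


MODEL_NAMES = ("PLSR", "ResNet", "ResNet-PROSPECT", "ResNet-GRL", "PPADA-Net")


def build_model(
    name: str,
    cfg: TrainConfig = TrainConfig(),
    encoder_cfg: EncoderConfig | None = None,
    pretrain_corpus: SpectraTable | None = None,
    pretrain_n: int = 2000,
    constants=None,
    patience: int | None = None,
) -> TableModel:
    """Instantiate a benchmark model by name with shared seeds/configs.

    The physics-pretrained variants simulate their own corpus (size
    ``pretrain_n``) when none is passed.
    """
    if name == "PLSR":
        return PLSRModelAdapter(seed=cfg.seed)
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    needs_corpus = name in ("ResNet-PROSPECT", "PPADA-Net")
    corpus = pretrain_corpus
    if needs_corpus and corpus is None:
        corpus = generate_corpus(ParamRanges(), pretrain_n, constants,
                                 seed=cfg.seed)
    return DeepModelAdapter(
        name=name, cfg=cfg, encoder_cfg=encoder_cfg,
        pretrain_corpus=corpus if needs_corpus else None,
        use_da=name in ("ResNet-GRL", "PPADA-Net"),
        patience=patience,
    )


# ---------------------------------------------------------------------------
# protocols


def stratified_kfold(tables, k: int = 5, seed: int = 0,
                     val_fraction: float = 0.15):
    """Dataset-stratified k-fold split of the pooled rows.

    Returns ``(pooled, folds)`` where each fold is a dict with disjoint
    ``train``/``val``/``test`` index arrays into the pooled table; within
    each test fold every dataset is represented proportionally (counts per
    dataset differ by at most 1 across folds), and ``val`` reserves
    ``val_fraction`` of the training rows for early stopping.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pooled = concat_tables(list(tables)) if not isinstance(tables, SpectraTable) \
        else tables
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(pooled), dtype=int)
    for label in np.unique(pooled.domain):
        rows = np.flatnonzero(pooled.domain == label)
        if rows.size < k:
            raise ValueError(
                f"dataset {label!r} has {rows.size} rows, fewer than k={k}"
            )
        rows = rng.permutation(rows)
        fold_of[rows] = np.arange(rows.size) % k
    folds = []
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        rest = np.flatnonzero(fold_of != f)
        rest = rng.permutation(rest)
        n_val = int(round(val_fraction * rest.size))
        folds.append(dict(train=np.sort(rest[n_val:]), val=np.sort(rest[:n_val]),
                          test=np.sort(test)))
    return pooled, folds


def run_kfold(tables, model_factory, k: int = 5, seed: int = 0,
              protocol_name: str = "kfold") -> EvalReport:
    """Fit/score a model on each stratified fold.

    ``model_factory(fold_index) -> TableModel`` builds a fresh model per
    fold so no state crosses folds.
    """
    pooled, folds = stratified_kfold(tables, k=k, seed=seed)
    report = EvalReport()
    for f, fold in enumerate(folds):
        train = pooled.subset(np.concatenate([fold["train"], fold["val"]]))
        test = pooled.subset(fold["test"])
        model = model_factory(f)
        model.fit(train)
        preds = model.predict_table(test)
        _score(report, test, preds, protocol=protocol_name, model=model.name,
               trial=f"fold{f}", seed=seed)
    return report


def _mask_target(table: SpectraTable, fewshot_fraction: float,
                 seed: int) -> SpectraTable:
    """Flag a seeded few-shot subset of a held-out table; the rest of the
    rows keep their labels only for scoring, never for fitting."""
    n = len(table)
    n_few = int(round(fewshot_fraction * n))
    fewshot = np.zeros(n, dtype=bool)
    if n_few:
        idx = np.random.default_rng(seed).choice(n, size=n_few, replace=False)
        fewshot[idx] = True
    out = table.subset(np.arange(n))
    out.fewshot_mask = fewshot
    return out


def leave_one_dataset_out(tables, model_factory, pairwise: bool = False,
                          seed: int = 0,
                          fewshot_fraction: float = 0.10) -> EvalReport:
    """Dataset-level transfer validation.

    Default: one trial per held-out dataset, training on all others pooled.
    ``pairwise``: one trial per ordered (train, test) dataset pair.  The
    held-out table is passed to the model as the adaptation target with a
    seeded few-shot labeled subset flagged; metrics are computed on the
    non-few-shot rows only, identically for every model.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least two datasets")
    names = [str(t.domain[0]) for t in tables]
    if pairwise:
        trials = [([i], j) for i in range(len(tables))
                  for j in range(len(tables)) if i != j]
    else:
        trials = [([i for i in range(len(tables)) if i != j], j)
                  for j in range(len(tables))]
    report = EvalReport()
    for train_ids, test_id in trials:
        train = concat_tables([tables[i] for i in train_ids])
        held = _mask_target(tables[test_id], fewshot_fraction, seed)
        trial = f"{'+'.join(names[i] for i in train_ids)}-{names[test_id]}"
        model = model_factory(trial)
        model.fit(train, target=held)
        eval_rows = np.flatnonzero(~held.fewshot_mask)
        test = held.subset(eval_rows)
        preds = model.predict_table(test)
        _score(report, test, preds,
               protocol="pairwise" if pairwise else "lodo",
               model=model.name, trial=trial, seed=seed)
    return report


def holdout(train_tables, test_table, model_factory, seed: int = 0,
            fewshot_fraction: float = 0.10) -> EvalReport:
    """Train on a fixed pool of datasets, test on one independent dataset."""
    train = concat_tables(list(train_tables))
    held = _mask_target(test_table, fewshot_fraction, seed)
    model = model_factory("holdout")
    model.fit(train, target=held)
    test = held.subset(np.flatnonzero(~held.fewshot_mask))
    preds = model.predict_table(test)
    report = EvalReport()
    _score(report, test, preds, protocol="holdout", model=model.name,
           trial=f"train-{'+'.join(str(t.domain[0]) for t in train_tables)}"
                 f"-test-{test_table.domain[0]}",
           seed=seed)
    return report


# ---------------------------------------------------------------------------
# benchmarks


def benchmark(source: SpectraTable, target: SpectraTable, models=MODEL_NAMES,
              cfg: TrainConfig = TrainConfig(), seeds=(0, 1, 2),
              encoder_cfg: EncoderConfig | None = None,
              pretrain_n: int = 2000, constants=None) -> EvalReport:
    """Run the model zoo on one source/target scenario with shared seeds.

    Every model sees the identical source table, target table and few-shot
    flags per seed; metrics are computed on the non-few-shot target rows.
    """
    report = EvalReport()
    eval_rows = np.flatnonzero(~target.fewshot_mask)
    test = target.subset(eval_rows)
    for seed in seeds:
        scfg = _reseed(cfg, seed)
        for name in models:
            model = build_model(name, scfg, encoder_cfg=encoder_cfg,
                                pretrain_n=pretrain_n, constants=constants)
            model.fit(source, target=target)
            preds = model.predict_table(test)
            _score(report, test, preds, protocol="benchmark", model=name,
                   trial="scenario", seed=seed)
    return report


def _reseed(cfg: TrainConfig, seed: int) -> TrainConfig:
    kwargs = {f: getattr(cfg, f) for f in TrainConfig.__dataclass_fields__}
    kwargs["seed"] = seed
    return TrainConfig(**kwargs)


def sweep_pretrain_size(sizes, source: SpectraTable, target: SpectraTable,
                        cfg: TrainConfig = TrainConfig(),
                        encoder_cfg: EncoderConfig | None = None,
                        constants=None, seed: int = 0) -> EvalReport:
    """Pretraining-corpus-size sweep: one benchmark row per corpus size."""
    report = EvalReport()
    eval_rows = np.flatnonzero(~target.fewshot_mask)
    test = target.subset(eval_rows)
    scfg = _reseed(cfg, seed)
    for n in sizes:
        model = build_model("PPADA-Net", scfg, encoder_cfg=encoder_cfg,
                            pretrain_n=int(n), constants=constants)
        model.fit(source, target=target)
        preds = model.predict_table(test)
        _score(report, test, preds, protocol="sweep", model="PPADA-Net",
               trial=f"n{n}", seed=seed)
    return report
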