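"""Training pipeline: stratified splitting, the optimisation loop, baselines,
and reduced-scale ablation / hyperparameter-sweep harnesses.

Training is transductive: the four relationship graphs are built once over
the whole cohort from features only (labels never enter edge construction),
message passing runs over the full graph, and the loss at each step is
evaluated on a mini-batch of training students. Early stopping watches the
validation total loss; the returned parameters are from the best validation
epoch. Everything is a pure function of (cohort, config), so a fixed seed
reproduces the run bit for bit.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from . import autodiff as ad
from .cohort import CohortTable, scale_features
from .graphs import PermaPriorMap, TopologySet, build_topology_set, default_prior
from .metrics import DEFAULT_EPSILON, DEFAULT_PCE_WEIGHTS, MetricReport, evaluate
from .perma_transformer import (
    DEFAULT_LAMBDAS,
    EncoderDims,
    ForwardResult,
    GnnDims,
    ModelParams,
    PredictionBundle,
    forward_full,
    init_model_params,
    loss_total,
)

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class RunConfig:
    """Hyperparameters of a training run (defaults = reference configuration)."""

    seed: int = 0
    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    strata_keys: tuple[str, ...] = ("learning_style", "stress_level")
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    weight_decay: float = 1e-5
    min_lr: float = 1e-6
    warmup_steps: int = 500
    epochs: int = 100
    batch_size: int = 32
    grad_clip: float = 1.0
    early_stop_patience: int = 15
    lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS
    dropout: float = 0.1
    graph_threshold: float = 0.3
    # architecture
    encoder_layers: int = 6
    width: int = 256
    heads: int = 5
    head_width: int = 64
    ffn_width: int = 1024
    token_width: int = 128
    gcn_layers: int = 3
    gcn_width: int = 128
    gat_heads: int = 8
    gat_head_width: int = 32
    prior_strength: float = 0.5
    use_gnn: bool = True
    use_encoder: bool = True
    use_culture_embedding: bool = False
    # evaluation
    pce_weights: tuple[float, float, float] = DEFAULT_PCE_WEIGHTS
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if min(self.epochs, self.batch_size, self.warmup_steps + 1, self.width) <= 0:
            raise ValueError("counts must be positive")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambdas must be nonnegative")

    def encoder_dims(self) -> EncoderDims:
        return EncoderDims(
            layers=self.encoder_layers, width=self.width, heads=self.heads,
            head_width=self.head_width, ffn_width=self.ffn_width, dropout=self.dropout,
        )

    def gnn_dims(self) -> GnnDims:
        return GnnDims(
            gcn_layers=self.gcn_layers, gcn_width=self.gcn_width,
            gat_heads=self.gat_heads, gat_head_width=self.gat_head_width,
        )


def reduced_config(seed: int = 0, **overrides) -> RunConfig:
    """Desk-scale configuration used by the ablation/sweep harnesses and the
    quick-run paths: a narrower 2-layer model with a shorter schedule whose
    learning rate and warmup are matched to the ~100-step budget."""
    base = dict(
        seed=seed,
        learning_rate=1e-3,
        warmup_steps=20,
        epochs=30,
        batch_size=128,
        encoder_layers=2,
        width=64,
        heads=5,
        head_width=16,
        ffn_width=128,
        token_width=32,
        gcn_layers=2,
        gcn_width=64,
        gat_heads=4,
        gat_head_width=16,
    )
    base.update(overrides)
    return RunConfig(**base)


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray

    def __iter__(self):
        return iter((self.train, self.valid, self.test))


def _stratum_labels(cohort: CohortTable, keys: Sequence[str]) -> np.ndarray:
    parts = []
    for key in keys:
        if key == "learning_style":
            parts.append(cohort.learning_styles)
        elif key == "stress_level":
            parts.append(cohort.stress_levels)
        elif key == "culture":
            parts.append(cohort.cultures)
        else:
            raise ValueError(f"unknown stratification key {key!r}")
    return np.array(["|".join(p) for p in zip(*parts)])


def _student_key(cohort: CohortTable, i: int, seed: int) -> int:
    """Permutation-invariant pseudo-random ordering key for one student."""
    h = hashlib.blake2b(digest_size=8)
    h.update(seed.to_bytes(8, "little", signed=True))
    h.update(np.ascontiguousarray(cohort.features[i]).tobytes())
    h.update(str(cohort.cultures[i]).encode())
    h.update(str(cohort.learning_styles[i]).encode())
    h.update(str(cohort.stress_levels[i]).encode())
    return int.from_bytes(h.digest(), "little")


def _apportion_split(n: int, ratios: Sequence[float]) -> list[int]:
    exact = [r * n for r in ratios]
    counts = [math.floor(e) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    order = sorted(range(len(ratios)), key=lambda k: (-remainders[k], k))
    for j in range(n - sum(counts)):
        counts[order[j % len(counts)]] += 1
    return counts


def stratified_split(cohort: CohortTable, config: RunConfig) -> Split:
    """Deterministic stratified train/valid/test split (default 7:2:1).

    Within each stratum the split counts are within +-1 of the exact
    proportions. Strata with fewer than 3 students are merged into the
    largest stratum (with a warning). Students are ordered inside a stratum
    by a hash of their content and the seed, so permuting the cohort permutes
    the partition identically.
    """
    keys = list(config.strata_keys)
    if "culture" not in keys and len(np.unique(cohort.cultures)) > 1:
        keys.append("culture")
    labels = _stratum_labels(cohort, keys)
    values, counts = np.unique(labels, return_counts=True)
    if counts.max() < 3:
        logger.warning("all strata smaller than 3; collapsing to a single stratum")
        labels = np.full(cohort.n, "all")
    else:
        small = values[counts < 3]
        if small.size:
            biggest = values[np.argmax(counts)]
            logger.warning(
                "merging %d strata smaller than 3 into %r", small.size, biggest
            )
            labels = np.where(np.isin(labels, small), biggest, labels)

    train, valid, test = [], [], []
    for stratum in np.unique(labels):
        idx = np.flatnonzero(labels == stratum)
        keys_ = [_student_key(cohort, int(i), config.seed) for i in idx]
        idx = idx[np.argsort(keys_, kind="stable")]
        n_tr, n_va, n_te = _apportion_split(len(idx), config.split_ratios)
        train.extend(idx[:n_tr])
        valid.extend(idx[n_tr:n_tr + n_va])
        test.extend(idx[n_tr + n_va:])
    return Split(
        train=np.sort(np.array(train, dtype=int)),
        valid=np.sort(np.array(valid, dtype=int)),
        test=np.sort(np.array(test, dtype=int)),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""
    split: Split | None = None

    def validation_mae(self) -> list[float]:
        return [e["valid_mae"] for e in self.epochs]


@dataclass
class PreparedData:
    """Deterministic preprocessing shared by train and evaluation."""

    cohort: CohortTable         # scaled
    prior: PermaPriorMap
    topologies: TopologySet
    split: Split


def prepare_inputs(cohort: CohortTable, config: RunConfig) -> PreparedData:
    scaled = scale_features(cohort)
    prior = default_prior(scaled.schema)
    topologies = build_topology_set(scaled, prior, config.graph_threshold)
    split = stratified_split(scaled, config)
    return PreparedData(cohort=scaled, prior=prior, topologies=topologies, split=split)


def lr_schedule(step: int, total_steps: int, config: RunConfig) -> float:
    """Linear warmup to ``learning_rate`` then cosine annealing to ``min_lr``."""
    if step <= config.warmup_steps:
        return config.learning_rate * step / config.warmup_steps
    span = max(1, total_steps - config.warmup_steps)
    progress = min(1.0, (step - config.warmup_steps) / span)
    return config.min_lr + 0.5 * (config.learning_rate - config.min_lr) * (
        1.0 + math.cos(math.pi * progress)
    )


def _build_model(cohort: CohortTable, prior, config: RunConfig) -> ModelParams:
    cultures = tuple(sorted(np.unique(cohort.cultures))) if config.use_culture_embedding else ()
    return init_model_params(
        d=cohort.schema.d,
        style_names=sorted(np.unique(cohort.learning_styles)),
        prior=prior,
        prior_strength=config.prior_strength,
        seed=config.seed,
        token_width=config.token_width,
        encoder_dims=config.encoder_dims(),
        gnn_dims=config.gnn_dims(),
        use_gnn=config.use_gnn,
        use_encoder=config.use_encoder,
        culture_names=cultures,
    )


def train(
    cohort: CohortTable,
    config: RunConfig,
    prepared: PreparedData | None = None,
) -> tuple[ModelParams, TrainingHistory]:
    """Fit the model; returns parameters from the best validation epoch.

    Mini-batches index students for the loss while message passing always
    runs over the full cohort graph. Early stopping on validation total loss
    with the configured patience. Raises :class:`DivergenceError` if the
    loss becomes non-finite.
    """
    if not (cohort.has_wellbeing and cohort.has_perma):
        raise ValueError("training requires wellbeing and PERMA labels")
    data = prepared or prepare_inputs(cohort, config)
    scaled, split = data.cohort, data.split
    params = _build_model(scaled, data.prior, config)
    opt = ad.AdamW(
        params.parameters(), lr=config.learning_rate, betas=config.betas,
        eps=config.adam_eps, weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    topologies = data.topologies if config.use_gnn else None

    train_idx = split.train
    steps_per_epoch = max(1, math.ceil(len(train_idx) / config.batch_size))
    total_steps = config.epochs * steps_per_epoch

    history = TrainingHistory(split=split)
    best_val = math.inf
    best_state = params.copy_state()
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        for b in range(steps_per_epoch):
            batch = train_idx[order[b * config.batch_size:(b + 1) * config.batch_size]]
            if batch.size == 0:
                continue
            step += 1
            opt.lr = lr_schedule(step, total_steps, config)
            history.lr_trace.append(opt.lr)
            result = forward_full(scaled, topologies, params, train_mode=True, rng=rng)
            loss = loss_total(
                result.wellbeing[batch], result.perma[batch],
                scaled.wellbeing[batch], scaled.perma_labels[batch],
                lambdas=config.lambdas,
            )
            if not np.isfinite(float(loss.l_total)):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"{loss.as_floats()}"
                )
            opt.zero_grad()
            loss.l_total.backward()
            ad.clip_grad_norm(params.parameters(), config.grad_clip)
            opt.step()

        # end-of-epoch evaluation (dropout off)
        result = forward_full(scaled, topologies, params, train_mode=False)
        record: dict = {"epoch": epoch, "lr": opt.lr, "step": step}
        for name, idx in (("train", split.train), ("valid", split.valid)):
            part = loss_total(
                result.wellbeing[idx], result.perma[idx],
                scaled.wellbeing[idx], scaled.perma_labels[idx],
                lambdas=config.lambdas,
            )
            record[f"{name}_loss"] = part.as_floats()
            record[f"{name}_mae"] = float(
                np.mean(np.abs(result.bundle.wellbeing_pred[idx] - scaled.wellbeing[idx]))
            )
        history.epochs.append(record)
        val_total = record["valid_loss"]["total"]
        if not np.isfinite(val_total):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        if val_total < best_val:
            best_val = val_total
            history.best_epoch = epoch
            best_state = params.copy_state()
        elif epoch - history.best_epoch > config.early_stop_patience:
            history.stop_reason = "early_stopping"
            break
    else:
        history.stop_reason = "max_epochs"

    params.load_state(best_state)
    return params, history


def predict(
    cohort_scaled: CohortTable,
    params: ModelParams,
    topologies: TopologySet | None,
) -> ForwardResult:
    """Deterministic full-cohort forward pass (evaluation mode)."""
    return forward_full(cohort_scaled, topologies, params, train_mode=False)


def evaluate_split(
    data: PreparedData,
    params: ModelParams,
    config: RunConfig,
    which: str = "test",
    strata: Mapping[str, Sequence] | None = None,
) -> tuple[MetricReport, np.ndarray]:
    """Metric report on one split plus the per-student absolute errors."""
    idx = getattr(data.split, which)
    result = predict(data.cohort, params, data.topologies if config.use_gnn else None)
    bundle = PredictionBundle(
        wellbeing_pred=result.bundle.wellbeing_pred[idx],
        perma_pred=result.bundle.perma_pred[idx],
    )
    sub_strata = None
    if strata is not None:
        sub_strata = {k: np.asarray(v)[idx] for k, v in strata.items()}
    report = evaluate(
        bundle, data.cohort.wellbeing[idx], data.cohort.perma_labels[idx],
        epsilon=config.epsilon, pce_weights=config.pce_weights, strata=sub_strata,
    )
    abs_errors = np.abs(bundle.wellbeing_pred - data.cohort.wellbeing[idx])
    return report, abs_errors


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def mean_baseline(data: PreparedData, which: str = "test") -> tuple[PredictionBundle, np.ndarray]:
    """Predict the training-set means for every student."""
    cohort, split = data.cohort, data.split
    idx = getattr(split, which)
    y_mean = float(cohort.wellbeing[split.train].mean())
    perma_mean = cohort.perma_labels[split.train].mean(axis=0)
    bundle = PredictionBundle(
        wellbeing_pred=np.full(len(idx), y_mean),
        perma_pred=np.tile(perma_mean, (len(idx), 1)),
    )
    return bundle, np.abs(bundle.wellbeing_pred - cohort.wellbeing[idx])


def ridge_baseline(
    data: PreparedData, alpha: float = 1.0, which: str = "test"
) -> tuple[PredictionBundle, np.ndarray]:
    """Ridge regression on the scaled features, predictions clipped to [0, 1]."""
    cohort, split = data.cohort, data.split
    idx = getattr(split, which)
    X_tr = cohort.features[split.train]
    reg_y = Ridge(alpha=alpha).fit(X_tr, cohort.wellbeing[split.train])
    reg_p = Ridge(alpha=alpha).fit(X_tr, cohort.perma_labels[split.train])
    bundle = PredictionBundle(
        wellbeing_pred=np.clip(reg_y.predict(cohort.features[idx]), 0.0, 1.0),
        perma_pred=np.clip(reg_p.predict(cohort.features[idx]), 0.0, 1.0),
    )
    return bundle, np.abs(bundle.wellbeing_pred - cohort.wellbeing[idx])


# ---------------------------------------------------------------------------
# Ablation and sweep harnesses
# ---------------------------------------------------------------------------

#: stepwise variants: flags overriding the base config
ABLATION_VARIANTS: tuple[tuple[str, dict], ...] = (
    ("mlp_heads", dict(use_gnn=False, use_encoder=False, prior_strength=0.0, lambda3=0.0)),
    ("+perma_prior", dict(use_gnn=False, use_encoder=False, lambda3=0.0)),
    ("+multi_graph", dict(use_encoder=False, lambda3=0.0)),
    ("+aligned_attention", dict(lambda3=0.0)),
    ("full_consistency", dict()),
)


def _variant_config(base: RunConfig, overrides: Mapping, seed: int) -> RunConfig:
    overrides = dict(overrides)
    lambdas = base.lambdas
    if "lambda3" in overrides:
        lambdas = (lambdas[0], lambdas[1], overrides.pop("lambda3"))
    return replace(base, seed=seed, lambdas=lambdas, **overrides)


def run_ablation(
    cohort: CohortTable,
    config: RunConfig | None = None,
    seeds: Sequence[int] = (0, 1, 2),
    variants: Sequence[tuple[str, Mapping]] = ABLATION_VARIANTS,
) -> pd.DataFrame:
    """Train each stepwise variant over several seeds at reduced scale.

    Returns mean +- sd of test MAE / PDA / PCI / PCE per variant.
    """
    names = [name for name, _ in variants]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variant labels")
    config = config or reduced_config()
    rows = []
    for name, overrides in variants:
        per_seed = []
        for seed in seeds:
            cfg = _variant_config(config, overrides, seed)
            data = prepare_inputs(cohort, cfg)
            params, _ = train(cohort, cfg, prepared=data)
            report, _ = evaluate_split(data, params, cfg)
            per_seed.append(report)
        row = {"variant": name, "seeds": len(list(seeds))}
        for metric in ("mae", "pda", "pci", "pce"):
            vals = np.array([getattr(r, metric) for r in per_seed])
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_sweep(
    cohort: CohortTable,
    grid: Mapping[str, Sequence],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """One reduced-scale train + evaluate per grid point.

    Grid keys are scalar :class:`RunConfig` fields. Divergent runs are
    reported with ``diverged=True`` instead of metrics (never silent NaN).
    """
    config = config or reduced_config()
    valid_fields = {f.name for f in fields(RunConfig)}
    bad = set(grid) - valid_fields
    if bad:
        raise ValueError(f"unknown config fields in grid: {sorted(bad)}")
    rows = []
    for combo in itertools.product(*grid.values()):
        overrides = dict(zip(grid.keys(), combo))
        cfg = replace(config, **overrides)
        row = dict(overrides)
        try:
            data = prepare_inputs(cohort, cfg)
            params, history = train(cohort, cfg, prepared=data)
            report, _ = evaluate_split(data, params, cfg)
            row.update(
                mae=report.mae, rmse=report.rmse, pda=report.pda,
                pci=report.pci, pce=report.pce,
                best_epoch=history.best_epoch, diverged=False,
            )
        except DivergenceError as exc:
            logger.warning("grid point %s diverged: %s", overrides, exc)
            row.update(
                mae=None, rmse=None, pda=None, pci=None, pce=None,
                best_epoch=None, diverged=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
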