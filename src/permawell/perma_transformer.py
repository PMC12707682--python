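"""Dimension-aligned transformer encoder, prediction heads and the loss.

The encoder runs on each student's sequence of five PERMA tokens. Five
attention heads (one per dimension by design, the count is configurable for
sensitivity studies) attend over the five tokens; head outputs are
concatenated and projected back to the model width. Blocks are pre-norm
residual: ``x + Attn(LN(x))`` then ``x + FFN(LN(x))`` with a GELU
feed-forward; dropout is active only in training mode.

Prediction pools the encoded tokens by global average and applies two
sigmoid heads: overall well-being (scalar) and the five-dimension
decomposition. The multi-task loss is

    L_total = l1 * MSE(y_hat, y) + l2 * MSE(Y_hat, Y)
            + l3 * MSE(y_hat, rowmean(Y_hat))

whose last term is the consistency penalty tying the overall prediction to
the mean of its own PERMA decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DEFAULT_LAMBDAS = (1.0, 0.8, 0.5)


@dataclass(frozen=True)
class EncoderDims:
    """Encoder architecture; defaults follow the reference configuration."""

    layers: int = 6
    width: int = 256
    heads: int = 5
    head_width: int = 64
    ffn_width: int = 1024
    dropout: float = 0.1


@dataclass
class EncoderLayerParams:
    w_q: list[Tensor]
    w_k: list[Tensor]
    w_v: list[Tensor]
    w_o: Tensor                      # (heads * head_width, width)
    ffn_in: Tensor                   # (width, ffn_width)
    ffn_in_bias: Tensor
    ffn_out: Tensor                  # (ffn_width, width)
    ffn_out_bias: Tensor
    ln1_gain: Tensor
    ln1_bias: Tensor
    ln2_gain: Tensor
    ln2_bias: Tensor

    def parameters(self) -> list[Tensor]:
        return [
            *self.w_q, *self.w_k, *self.w_v, self.w_o,
            self.ffn_in, self.ffn_in_bias, self.ffn_out, self.ffn_out_bias,
            self.ln1_gain, self.ln1_bias, self.ln2_gain, self.ln2_bias,
        ]


@dataclass
class EncoderParams:
    layers: list[EncoderLayerParams]
    dims: EncoderDims

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


@dataclass
class HeadParams:
    """Sigmoid affine heads on the pooled representation."""

    w_wellbeing: Tensor  # (width, 1)
    b_wellbeing: Tensor  # (1,)
    w_perma: Tensor      # (width, 5)
    b_perma: Tensor      # (5,)

    def parameters(self) -> list[Tensor]:
        return [self.w_wellbeing, self.b_wellbeing, self.w_perma, self.b_perma]


@dataclass
class PredictionBundle:
    """Per-student predictions, both strictly inside (0, 1)."""

    wellbeing_pred: np.ndarray   # (n,)
    perma_pred: np.ndarray       # (n, 5)

    @property
    def n(self) -> int:
        return len(self.wellbeing_pred)

    def consistency_gap(self) -> np.ndarray:
        return np.abs(self.wellbeing_pred - self.perma_pred.mean(axis=1))


@dataclass
class LossBreakdown:
    """Components of the multi-task objective (held as 0-d tensors so the
    total can be back-propagated; ``float()`` them for reporting)."""

    l_wellbeing: Tensor
    l_perma: Tensor
    l_consistency: Tensor
    l_total: Tensor
    lambdas: tuple[float, float, float]

    def as_floats(self) -> dict[str, float]:
        return {
            "wellbeing": float(self.l_wellbeing),
            "perma": float(self.l_perma),
            "consistency": float(self.l_consistency),
            "total": float(self.l_total),
        }


@dataclass
class AttentionProfile:
    """Batch-averaged attention: (layers, heads, 5, 5); rows sum to 1."""

    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("attention profile must be (layers, heads, q, k)")


def init_encoder_params(dims: EncoderDims = EncoderDims(), seed: int = 0) -> EncoderParams:
    rng = np.random.default_rng(seed)
    w = dims.width
    concat = dims.heads * dims.head_width

    def xavier(shape):
        return Tensor(ad.xavier_uniform(shape, rng), requires_grad=True)

    layers = []
    for _ in range(dims.layers):
        layers.append(
            EncoderLayerParams(
                w_q=[xavier((w, dims.head_width)) for _ in range(dims.heads)],
                w_k=[xavier((w, dims.head_width)) for _ in range(dims.heads)],
                w_v=[xavier((w, dims.head_width)) for _ in range(dims.heads)],
                w_o=xavier((concat, w)),
                ffn_in=xavier((w, dims.ffn_width)),
                ffn_in_bias=Tensor(np.zeros(dims.ffn_width), requires_grad=True),
                ffn_out=xavier((dims.ffn_width, w)),
                ffn_out_bias=Tensor(np.zeros(w), requires_grad=True),
                ln1_gain=Tensor(np.ones(w), requires_grad=True),
                ln1_bias=Tensor(np.zeros(w), requires_grad=True),
                ln2_gain=Tensor(np.ones(w), requires_grad=True),
                ln2_bias=Tensor(np.zeros(w), requires_grad=True),
            )
        )
    return EncoderParams(layers=layers, dims=dims)


def init_head_params(width: int = 256, seed: int = 0) -> HeadParams:
    rng = np.random.default_rng(seed)
    return HeadParams(
        w_wellbeing=Tensor(ad.xavier_uniform((width, 1), rng), requires_grad=True),
        b_wellbeing=Tensor(np.zeros(1), requires_grad=True),
        w_perma=Tensor(ad.xavier_uniform((width, 5), rng), requires_grad=True),
        b_perma=Tensor(np.zeros(5), requires_grad=True),
    )


def encoder_forward(
    tokens,
    params: EncoderParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, AttentionProfile]:
    """Run the pre-norm encoder; returns encoded tokens and the attention
    profile (per-layer, per-head query-to-token maps averaged over students)."""
    x = ad.as_tensor(tokens)
    n, t, w = x.shape
    if t != 5:
        raise ValueError(f"expected 5 PERMA tokens per student, got {t}")
    if train_mode and params.dims.dropout > 0 and rng is None:
        raise ValueError("training mode with dropout requires an rng")
    scale = 1.0 / np.sqrt(params.dims.head_width)
    profile = []
    for layer in params.layers:
        normed = ad.layer_norm(x, layer.ln1_gain, layer.ln1_bias)
        heads, head_maps = [], []
        for w_q, w_k, w_v in zip(layer.w_q, layer.w_k, layer.w_v):
            q = normed @ w_q
            k = normed @ w_k
            v = normed @ w_v
            attn = ad.softmax((q @ k.swapaxes(-1, -2)) * scale, axis=-1)  # (n, 5, 5)
            heads.append(attn @ v)
            head_maps.append(attn.data.mean(axis=0))
        update = ad.concatenate(heads, axis=-1) @ layer.w_o
        if train_mode:
            update = ad.dropout(update, params.dims.dropout, rng)
        x = x + update
        profile.append(np.stack(head_maps))

        normed = ad.layer_norm(x, layer.ln2_gain, layer.ln2_bias)
        hidden = ad.gelu(normed @ layer.ffn_in + layer.ffn_in_bias)
        out = hidden @ layer.ffn_out + layer.ffn_out_bias
        if train_mode:
            out = ad.dropout(out, params.dims.dropout, rng)
        x = x + out
    return x, AttentionProfile(np.stack(profile))


def predict_heads(encoded, params: HeadParams) -> tuple[PredictionBundle, Tensor, Tensor]:
    """Pool tokens (global average) and apply the two sigmoid heads.

    Returns the numeric bundle plus the differentiable wellbeing (n,) and
    PERMA (n, 5) prediction tensors for loss computation.
    """
    encoded = ad.as_tensor(encoded)
    n = encoded.shape[0]
    pooled = encoded.mean(axis=1)  # (n, width)
    wellbeing = ad.sigmoid(pooled @ params.w_wellbeing + params.b_wellbeing).reshape(n)
    perma = ad.sigmoid(pooled @ params.w_perma + params.b_perma)
    bundle = PredictionBundle(wellbeing_pred=wellbeing.data.copy(), perma_pred=perma.data.copy())
    return bundle, wellbeing, perma


def loss_total(
    wellbeing_pred,
    perma_pred,
    wellbeing_labels,
    perma_labels,
    lambdas: tuple[float, float, float] = DEFAULT_LAMBDAS,
) -> LossBreakdown:
    """Multi-task loss with the prediction-consistency penalty.

    Accepts tensors (for training) or arrays (for reporting); labels are
    required for every student.
    """
    y_hat = ad.as_tensor(wellbeing_pred)
    perma_hat = ad.as_tensor(perma_pred)
    if wellbeing_labels is None or perma_labels is None:
        raise ValueError("loss_total requires both label types for all students")
    y = np.asarray(wellbeing_labels, dtype=float)
    perma = np.asarray(perma_labels, dtype=float)
    if y.shape != y_hat.shape or perma.shape != perma_hat.shape:
        raise ValueError("label shapes do not match predictions")

    l_wb = ((y_hat - y) ** 2).mean()
    l_perma = ((perma_hat - perma) ** 2).mean()
    l_cons = ((y_hat - perma_hat.mean(axis=1)) ** 2).mean()
    l1, l2, l3 = lambdas
    total = l1 * l_wb + l2 * l_perma + l3 * l_cons
    return LossBreakdown(
        l_wellbeing=l_wb, l_perma=l_perma, l_consistency=l_cons,
        l_total=total, lambdas=tuple(lambdas),
    )


def alignment_matrix(profile: AttentionProfile) -> np.ndarray:
    """Head-to-dimension alignment: entry (h, p) is the mean attention mass
    head ``h`` assigns to token ``p``, averaged over layers, students and
    query positions. Rows sum to 1."""
    # maps: (layers, heads, query, key) already averaged over students
    return profile.maps.mean(axis=(0, 2))


# ---------------------------------------------------------------------------
# Full-model assembly
# ---------------------------------------------------------------------------

from .cohort import CohortTable                      # noqa: E402
from .graphs import TopologySet                      # noqa: E402
from .perma_features import (                        # noqa: E402
    CrossAttnParams,
    PermaEmbedParams,
    cross_modal_enhance,
    init_cross_attn,
    init_from_prior,
    tokenize,
)
from .relational_gnn import (                        # noqa: E402
    GnnDims,
    GnnParams,
    encode_relations,
    init_gnn_params,
)


@dataclass
class ModelParams:
    """Every trainable parameter of the full predictor.

    ``gnn``/``encoder`` may be None (ablation variants: tokens-only MLP,
    no-relational, no-encoder models). ``culture_table`` is the optional
    learned per-culture token offset (off by default; culture is otherwise
    used only for stratified evaluation).
    """

    embed: PermaEmbedParams
    heads: HeadParams
    cross: CrossAttnParams | None = None
    gnn: GnnParams | None = None
    encoder: EncoderParams | None = None
    culture_table: Tensor | None = None
    culture_names: tuple[str, ...] = ()

    def parameters(self) -> list[Tensor]:
        out = self.embed.parameters() + self.heads.parameters()
        if self.gnn is not None:
            out += self.gnn.parameters()
            if self.cross is not None:
                out += self.cross.parameters()
        if self.encoder is not None:
            out += self.encoder.parameters()
        if self.culture_table is not None:
            out.append(self.culture_table)
        return out

    def copy_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, data in zip(self.parameters(), state):
            p.data = data.copy()


def init_model_params(
    d: int,
    style_names,
    prior,
    prior_strength: float = 0.5,
    seed: int = 0,
    token_width: int = 128,
    encoder_dims: EncoderDims = EncoderDims(),
    gnn_dims: GnnDims = GnnDims(),
    use_gnn: bool = True,
    use_encoder: bool = True,
    culture_names: tuple[str, ...] = (),
) -> ModelParams:
    """Initialise all components consistently (one seed fans out per part)."""
    width = encoder_dims.width
    if use_gnn and gnn_dims.out_width != width:
        raise ValueError(
            f"GAT output width {gnn_dims.out_width} must equal model width {width}"
        )
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    embed = init_from_prior(
        prior, strength=prior_strength, seed=int(seeds[0]),
        token_width=token_width, model_width=width,
    )
    params = ModelParams(
        embed=embed,
        heads=init_head_params(width=width, seed=int(seeds[1])),
    )
    if use_gnn:
        params.gnn = init_gnn_params(d, style_names, dims=gnn_dims, seed=int(seeds[2]))
        params.cross = init_cross_attn(seed=int(seeds[3]), model_width=width)
    if use_encoder:
        params.encoder = init_encoder_params(dims=encoder_dims, seed=int(seeds[4]))
    if culture_names:
        crng = np.random.default_rng(int(seeds[1]) + 1)
        params.culture_table = Tensor(
            crng.normal(0, 0.02, (len(culture_names), width)), requires_grad=True
        )
        params.culture_names = tuple(culture_names)
    return params


@dataclass
class ForwardResult:
    """Everything a full forward pass produces."""

    bundle: PredictionBundle
    wellbeing: Tensor                 # (n,) differentiable
    perma: Tensor                     # (n, 5) differentiable
    fusion_weights: Tensor | None     # (n, 4) rows sum to 1, None without GNN
    attention: AttentionProfile | None
    gat_attention: dict[str, np.ndarray] | None


def forward_full(
    cohort: CohortTable,
    topologies: TopologySet | None,
    params: ModelParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> ForwardResult:
    """tokenize -> relational encoding -> cross-modal enhancement ->
    dimension-aligned encoder -> dual heads. Deterministic when
    ``train_mode`` is off."""
    tokens = tokenize(cohort.features, params.embed)
    if params.culture_table is not None:
        index = {c: i for i, c in enumerate(params.culture_names)}
        idx = np.array([index[c] for c in cohort.cultures])
        n = cohort.n
        tokens = tokens + params.culture_table[idx].reshape(n, 1, params.embed.model_width)

    fusion_weights, gat_maps = None, None
    if params.gnn is not None:
        if topologies is None:
            raise ValueError("model has a relational branch but no topologies given")
        h_graph, fusion_weights, gat_maps = encode_relations(cohort, topologies, params.gnn)
        tokens = cross_modal_enhance(tokens, h_graph, params.cross)

    profile = None
    if params.encoder is not None:
        tokens, profile = encoder_forward(tokens, params.encoder, train_mode=train_mode, rng=rng)

    bundle, wellbeing, perma = predict_heads(tokens, params.heads)
    return ForwardResult(
        bundle=bundle, wellbeing=wellbeing, perma=perma,
        fusion_weights=fusion_weights, attention=profile, gat_attention=gat_maps,
    )
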