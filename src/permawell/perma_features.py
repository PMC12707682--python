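"""PERMA-grounded feature embedding.

Two representations are produced from the raw feature matrix:

* an interpretable n x 5 PERMA *score* map ``X @ W_perma + b`` whose weight
  matrix can be initialised from the psychological prior, and
* a per-student sequence of five *tokens* (one per PERMA dimension,
  ``token_p = lift(GELU(x @ U_p + dim_embed_p))``) that feeds the
  dimension-aligned transformer encoder.

Tokens can be enhanced with the student's fused graph representation through
single-head cross-modal attention with a residual connection, so graph
information never overwrites the theory-grounded tokens, it only refines
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graphs import PermaPriorMap

DEFAULT_TOKEN_WIDTH = 128
DEFAULT_MODEL_WIDTH = 256


@dataclass
class PermaEmbedParams:
    """Parameters of the score map and the five-token embedding."""

    score_map: Tensor        # (d, 5)
    score_bias: Tensor       # (5,)
    token_proj: list[Tensor]  # five (d, token_width)
    dim_embed: Tensor        # (5, token_width)
    lift: Tensor             # (token_width, model_width)

    def parameters(self) -> list[Tensor]:
        return [self.score_map, self.score_bias, *self.token_proj, self.dim_embed, self.lift]

    @property
    def d(self) -> int:
        return self.score_map.shape[0]

    @property
    def token_width(self) -> int:
        return self.token_proj[0].shape[1]

    @property
    def model_width(self) -> int:
        return self.lift.shape[1]


@dataclass
class CrossAttnParams:
    """Single-head cross-modal attention (tokens attend to the graph vector)."""

    w_q: Tensor  # (model_width, model_width)
    w_k: Tensor
    w_v: Tensor
    w_o: Tensor

    def parameters(self) -> list[Tensor]:
        return [self.w_q, self.w_k, self.w_v, self.w_o]


def init_from_prior(
    prior: PermaPriorMap,
    strength: float = 0.5,
    seed: int = 0,
    token_width: int = DEFAULT_TOKEN_WIDTH,
    model_width: int = DEFAULT_MODEL_WIDTH,
) -> PermaEmbedParams:
    """Prior-informed initialisation.

    ``score_map`` is the convex combination ``strength * prior + (1 -
    strength) * XavierUniform``; each token projection ``U_p`` has its
    feature rows rescaled toward the (mean-one normalised) relevance of that
    feature to dimension ``p``, so dimension-relevant features dominate the
    token. ``strength`` in [0, 1] interpolates between a purely random and a
    purely prior-shaped start; deterministic given ``seed``.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must be in [0, 1], got {strength}")
    rng = np.random.default_rng(seed)
    d = prior.d
    random_map = ad.xavier_uniform((d, 5), rng)
    score_map = strength * prior.weights + (1.0 - strength) * random_map

    token_proj = []
    for p in range(5):
        u = ad.xavier_uniform((d, token_width), rng)
        relevance = prior.weights[:, p]
        scale = relevance * d / relevance.sum()  # mean-one relevance
        row_scale = (1.0 - strength) + strength * scale
        token_proj.append(Tensor(u * row_scale[:, None], requires_grad=True))

    return PermaEmbedParams(
        score_map=Tensor(score_map, requires_grad=True),
        score_bias=Tensor(np.zeros(5), requires_grad=True),
        token_proj=token_proj,
        dim_embed=Tensor(ad.xavier_uniform((5, token_width), rng), requires_grad=True),
        lift=Tensor(ad.xavier_uniform((token_width, model_width), rng), requires_grad=True),
    )


def init_cross_attn(
    seed: int = 0, model_width: int = DEFAULT_MODEL_WIDTH
) -> CrossAttnParams:
    rng = np.random.default_rng(seed)
    make = lambda: Tensor(ad.xavier_uniform((model_width, model_width), rng), requires_grad=True)
    return CrossAttnParams(w_q=make(), w_k=make(), w_v=make(), w_o=make())


def score_perma(X, params: PermaEmbedParams) -> Tensor:
    """Linear PERMA scores ``X @ W_perma + b`` (n x 5)."""
    X = ad.as_tensor(X)
    if X.shape[-1] != params.d:
        raise ValueError(f"X has d={X.shape[-1]}, params expect {params.d}")
    return X @ params.score_map + params.score_bias


def tokenize(X, params: PermaEmbedParams) -> Tensor:
    """Five tokens per student, ordered (P, E, R, M, A); shape (n, 5, width).

    ``token_p = lift(GELU(x @ U_p + dim_embed_p))``.
    """
    X = ad.as_tensor(X)
    if X.shape[-1] != params.d:
        raise ValueError(f"X has d={X.shape[-1]}, params expect {params.d}")
    n = X.shape[0]
    tokens = []
    for p in range(5):
        h = ad.gelu(X @ params.token_proj[p] + params.dim_embed[p])
        tokens.append((h @ params.lift).reshape(n, 1, params.model_width))
    return ad.concatenate(tokens, axis=1)


def cross_modal_enhance(tokens, h_graph, params: CrossAttnParams) -> Tensor:
    """Residual single-head cross attention from tokens onto the graph vector.

    Each student contributes one key/value (their fused graph representation),
    so the softmax over keys is a singleton and the attention weight is
    exactly 1; what is learned is the value/output projection of the graph
    information added onto each token.
    """
    tokens = ad.as_tensor(tokens)
    h_graph = ad.as_tensor(h_graph)
    n, t, w = tokens.shape
    if h_graph.shape != (n, w):
        raise ValueError(f"h_graph shape {h_graph.shape} incompatible with tokens {tokens.shape}")
    h = h_graph.reshape(n, 1, w)
    q = tokens @ params.w_q
    k = h @ params.w_k
    v = h @ params.w_v
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(w))  # (n, t, 1)
    attn = ad.softmax(scores, axis=-1)  # singleton key -> exactly 1
    update = (attn @ v) @ params.w_o
    return tokens + update
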