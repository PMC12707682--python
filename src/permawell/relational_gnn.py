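"""Multi-topology relational encoder: per-graph GCN + GAT, attention fusion.

Each of the four student-relationship graphs is encoded independently —
three symmetric-normalised graph-convolution layers followed by one
multi-head graph-attention layer — and the four branch outputs are combined
per student by a learned convex weighting ("graph-level attention fusion")
conditioned only on the student's learning style and stress level:

    score_k(i) = v_k^T tanh(W_g [e_style(i) || e_stress(i)] + b_g)
    beta(i)    = softmax_k(score_k(i)),   H_final(i) = sum_k beta_k(i) H^(k)(i)

The fusion scoring vectors ``v_k`` are zero-initialised so every student
starts at the uniform weighting (0.25, 0.25, 0.25, 0.25); training moves the
weights away from uniform only where style/stress conditioning warrants it.
The per-student ``beta`` is returned for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cohort import CohortTable, STRESS_LEVELS
from .graphs import Topology, TopologySet, normalize_adjacency

LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class GnnDims:
    """Architecture widths for the relational encoder."""

    gcn_layers: int = 3
    gcn_width: int = 128
    gat_heads: int = 8
    gat_head_width: int = 32

    @property
    def out_width(self) -> int:
        return self.gat_heads * self.gat_head_width


@dataclass
class GnnParams:
    """Per-topology GCN/GAT weights plus the style/stress fusion scorer."""

    gcn_weights: list[list[Tensor]]   # [topology][layer] (w_in, w_out)
    gat_weights: list[list[Tensor]]   # [topology][head] (gcn_width, head_width)
    gat_attn: list[list[Tensor]]      # [topology][head] (2 * head_width, 1)
    style_table: Tensor               # (n_styles, 32)
    stress_table: Tensor              # (3, 32)
    w_g: Tensor                       # (64, 32)
    b_g: Tensor                       # (32,)
    fusion_v: Tensor                  # (4, 32), zero-initialised
    style_names: tuple[str, ...]
    dims: GnnDims

    def parameters(self) -> list[Tensor]:
        out = [self.style_table, self.stress_table, self.w_g, self.b_g, self.fusion_v]
        for branch in self.gcn_weights:
            out.extend(branch)
        for branch in self.gat_weights:
            out.extend(branch)
        for branch in self.gat_attn:
            out.extend(branch)
        return out


def init_gnn_params(
    d: int,
    style_names,
    dims: GnnDims = GnnDims(),
    seed: int = 0,
    embed_width: int = 32,
) -> GnnParams:
    """Kaiming-normal GNN weights; zero fusion scorers (uniform 0.25 start)."""
    rng = np.random.default_rng(seed)
    gcn_weights, gat_weights, gat_attn = [], [], []
    for _ in range(4):
        widths = [d] + [dims.gcn_width] * dims.gcn_layers
        gcn_weights.append(
            [
                Tensor(ad.kaiming_normal((w_in, w_out), rng), requires_grad=True)
                for w_in, w_out in zip(widths[:-1], widths[1:])
            ]
        )
        gat_weights.append(
            [
                Tensor(ad.kaiming_normal((dims.gcn_width, dims.gat_head_width), rng), requires_grad=True)
                for _ in range(dims.gat_heads)
            ]
        )
        gat_attn.append(
            [
                Tensor(ad.kaiming_normal((2 * dims.gat_head_width, 1), rng), requires_grad=True)
                for _ in range(dims.gat_heads)
            ]
        )
    style_names = tuple(style_names)
    return GnnParams(
        gcn_weights=gcn_weights,
        gat_weights=gat_weights,
        gat_attn=gat_attn,
        style_table=Tensor(rng.normal(0, 0.1, (len(style_names), embed_width)), requires_grad=True),
        stress_table=Tensor(rng.normal(0, 0.1, (3, embed_width)), requires_grad=True),
        w_g=Tensor(ad.xavier_uniform((2 * embed_width, embed_width), rng), requires_grad=True),
        b_g=Tensor(np.zeros(embed_width), requires_grad=True),
        fusion_v=Tensor(np.zeros((4, embed_width)), requires_grad=True),
        style_names=style_names,
        dims=dims,
    )


def gcn_layer(H, A_norm, W) -> Tensor:
    """One graph convolution: ``ReLU(A_norm @ H @ W)``."""
    H = ad.as_tensor(H)
    A_norm = ad.as_tensor(A_norm)
    W = ad.as_tensor(W)
    if A_norm.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: A_norm {A_norm.shape}, H {H.shape}, W {W.shape}"
        )
    return ad.relu(A_norm @ H @ W)


def gat_layer(H, adjacency, weights, attn_vectors) -> tuple[Tensor, np.ndarray]:
    """Multi-head graph attention over ``N_i = {j : a_ij > 0} ∪ {i}``.

    Per head: ``alpha_ij = softmax_{j in N_i}(LeakyReLU(a^T [W h_i || W h_j]))``
    and ``h'_i = ELU(sum_j alpha_ij W h_j)``; heads are concatenated.

    Returns the (n, heads * head_width) output and the per-head attention
    maps as an (heads, n, n) array (rows sum to 1 over each neighbourhood).
    """
    H = ad.as_tensor(H)
    adjacency = np.asarray(adjacency, dtype=float)
    n = H.shape[0]
    if adjacency.shape != (n, n):
        raise ValueError("adjacency does not match H")
    mask = (adjacency > 0) | np.eye(n, dtype=bool)
    neg_inf = np.where(mask, 0.0, -1e9)

    outputs, maps = [], []
    for W, a in zip(weights, attn_vectors):
        Wh = H @ W  # (n, head_width)
        hw = W.shape[1] if isinstance(W, Tensor) else np.asarray(W).shape[1]
        a_src = a[:hw, :]  # split a^T [u || v] = a_src . u + a_dst . v
        a_dst = a[hw:, :]
        src = (Wh @ a_src).reshape(n, 1)
        dst = (Wh @ a_dst).reshape(1, n)
        logits = ad.leaky_relu(src + dst, LEAKY_SLOPE) + neg_inf
        alpha = ad.softmax(logits, axis=-1)
        outputs.append(ad.elu(alpha @ Wh))
        maps.append(alpha.data * mask)
    return ad.concatenate(outputs, axis=-1), np.stack(maps)


def fuse_topologies(
    H_set, styles, stresses, params: GnnParams
) -> tuple[Tensor, Tensor]:
    """Convex combination of the four branch outputs per student.

    Returns ``(H_final, beta)`` where ``beta`` is the (n, 4) fusion-weight
    matrix (rows sum to 1).
    """
    styles = np.asarray(styles)
    stresses = np.asarray(stresses)
    style_index = {s: i for i, s in enumerate(params.style_names)}
    unknown = [s for s in np.unique(styles) if s not in style_index]
    if unknown:
        raise ValueError(f"unknown learning styles {unknown}")
    bad = [s for s in np.unique(stresses) if s not in STRESS_LEVELS]
    if bad:
        raise ValueError(f"unknown stress levels {bad}")
    style_idx = np.array([style_index[s] for s in styles])
    stress_idx = np.array([STRESS_LEVELS.index(s) for s in stresses])

    cond = ad.concatenate(
        [params.style_table[style_idx], params.stress_table[stress_idx]], axis=-1
    )  # (n, 64)
    hidden = ad.tanh(cond @ params.w_g + params.b_g)  # (n, 32)
    scores = hidden @ params.fusion_v.swapaxes(0, 1)  # (n, 4)
    beta = ad.softmax(scores, axis=-1)
    n = len(styles)
    stacked = ad.concatenate(
        [h.reshape(n, 1, h.shape[-1]) for h in map(ad.as_tensor, H_set)], axis=1
    )  # (n, 4, w)
    h_final = (beta.reshape(n, 1, 4) @ stacked).reshape(n, stacked.shape[-1])
    return h_final, beta


def encode_relations(
    cohort: CohortTable,
    topologies: TopologySet,
    params: GnnParams,
) -> tuple[Tensor, Tensor, dict[str, np.ndarray]]:
    """Full relational encoding of a cohort.

    Per topology: 3 GCN layers on the normalised adjacency, then one GAT
    layer on the raw thresholded adjacency; branch outputs fused per student.
    Returns ``(H_graph, beta, attention_maps)`` with one (heads, n, n)
    attention array per topology kind.
    """
    if topologies.n != cohort.n:
        raise ValueError("topologies and cohort sizes differ")
    X = cohort.features
    branch_outputs, attn_maps = [], {}
    for k, topology in enumerate(topologies):
        a_norm = normalize_adjacency(topology)
        h = ad.as_tensor(X)
        for W in params.gcn_weights[k]:
            h = gcn_layer(h, a_norm, W)
        out, maps = gat_layer(h, topology.adjacency, params.gat_weights[k], params.gat_attn[k])
        branch_outputs.append(out)
        attn_maps[topology.kind] = maps
    h_final, beta = fuse_topologies(
        branch_outputs, cohort.learning_styles, cohort.stress_levels, params
    )
    return h_final, beta, attn_maps
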