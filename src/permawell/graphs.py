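"""Student-relationship graph construction.

Four adjacency matrices are built over the same cohort ordering:

* ``cosine`` — clipped cosine similarity of feature vectors,
* ``euclidean`` — Gaussian kernel of pairwise distances with median bandwidth,
* ``learning`` — binary shared-learning-style graph,
* ``perma`` — a theory-weighted sum of per-dimension cosine similarities,
  ``a_ij = sum_p w_p * sim_p(x_i^(p), x_j^(p))`` where ``x^(p)`` masks the
  features by their relevance to PERMA dimension ``p``.

All graphs are symmetric with zero diagonal; entries below the shared edge
threshold (default 0.3, closed at the threshold) are removed so edge weights
live on a comparable [threshold, 1] scale across topologies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse
from scipy.spatial.distance import pdist, squareform

from .cohort import CohortTable, PERMA_DIMS, BLOCK_DOMINANT_DIM, FeatureSchema

logger = logging.getLogger(__name__)

TOPOLOGY_KINDS = ("cosine", "euclidean", "learning", "perma")
DEFAULT_THRESHOLD = 0.3

#: tolerance so entries analytically equal to the threshold survive round-off
_THRESHOLD_EPS = 1e-12


class GraphError(ValueError):
    """Raised for invalid graph inputs."""


@dataclass(frozen=True)
class Topology:
    """One thresholded student-relationship graph."""

    kind: str
    adjacency: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.kind not in TOPOLOGY_KINDS:
            raise GraphError(f"unknown topology kind {self.kind!r}")
        a = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise GraphError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise GraphError("adjacency must have zero diagonal")
        nz = a[a > 0]
        if nz.size and (np.any(nz < self.threshold - 1e-9) or np.any(nz > 1 + 1e-9)):
            raise GraphError("nonzero entries must lie in [threshold, 1]")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def edge_list(self) -> np.ndarray:
        """(m, 3) array of (i, j, weight), 0-based, i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j, self.adjacency[i, j]])


@dataclass(frozen=True)
class TopologySet:
    """Exactly one topology per kind, in fixed order, over one cohort."""

    topologies: tuple[Topology, Topology, Topology, Topology]

    def __post_init__(self):
        kinds = tuple(t.kind for t in self.topologies)
        if kinds != TOPOLOGY_KINDS:
            raise GraphError(f"topologies must be ordered {TOPOLOGY_KINDS}, got {kinds}")
        sizes = {t.n for t in self.topologies}
        if len(sizes) != 1:
            raise GraphError("all topologies must share n")

    @property
    def n(self) -> int:
        return self.topologies[0].n

    def __iter__(self):
        return iter(self.topologies)

    def __getitem__(self, kind: str) -> Topology:
        for t in self.topologies:
            if t.kind == kind:
                return t
        raise KeyError(kind)


@dataclass(frozen=True)
class PermaPriorMap:
    """Feature-to-PERMA relevance: row-stochastic d x 5 weights plus the
    theoretical per-dimension weights ``w_p`` (sum to 1)."""

    weights: np.ndarray
    dim_weights: np.ndarray = field(
        default_factory=lambda: np.full(5, 0.2)
    )

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        dw = np.asarray(self.dim_weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "dim_weights", dw)
        if w.ndim != 2 or w.shape[1] != 5:
            raise GraphError("prior weights must be (d, 5)")
        if np.any(w < 0):
            raise GraphError("prior weights must be nonnegative")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-9):
            raise GraphError("each prior row must sum to 1")
        if dw.shape != (5,) or np.any(dw < 0) or abs(dw.sum() - 1.0) > 1e-9:
            raise GraphError("dim_weights must be a nonnegative 5-vector summing to 1")

    @property
    def d(self) -> int:
        return self.weights.shape[0]

    def to_json(self, path, feature_names: Sequence[str]) -> None:
        payload = {
            "dim_weights": {p: float(v) for p, v in zip(PERMA_DIMS, self.dim_weights)},
            "weights": {
                name: {p: float(v) for p, v in zip(PERMA_DIMS, row)}
                for name, row in zip(feature_names, self.weights)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path, feature_names: Sequence[str]) -> "PermaPriorMap":
        payload = json.loads(Path(path).read_text())
        weights = np.array(
            [[payload["weights"][n][p] for p in PERMA_DIMS] for n in feature_names]
        )
        dim_weights = np.array([payload["dim_weights"][p] for p in PERMA_DIMS])
        return cls(weights=weights, dim_weights=dim_weights)


def default_prior(schema: FeatureSchema, dominant: float = 0.6, other: float = 0.1) -> PermaPriorMap:
    """Block-aligned prior: 0.6 on the block's dominant dimension, 0.1 elsewhere.

    This allocation is a configurable convention, not a canonical psychometric
    mapping; dimension weights default to uniform 0.2.
    """
    weights = np.full((schema.d, 5), other, dtype=float)
    dim_index = {p: k for k, p in enumerate(PERMA_DIMS)}
    for i, name in enumerate(schema.feature_names):
        weights[i, dim_index[BLOCK_DOMINANT_DIM[schema.block_of[name]]]] = dominant
    weights /= weights.sum(axis=1, keepdims=True)
    return PermaPriorMap(weights=weights)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _apply_threshold(raw: np.ndarray, threshold: float) -> np.ndarray:
    a = np.where(raw >= threshold - _THRESHOLD_EPS, raw, 0.0)
    np.fill_diagonal(a, 0.0)
    return np.clip((a + a.T) / 2.0, 0.0, 1.0)  # symmetrise against round-off


def _clipped_cosine(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-norm feature rows; their similarities set to 0", zero.sum())
    safe = np.where(zero, 1.0, norms)
    unit = X / safe[:, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    return sim


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise GraphError("need an (n >= 2, d) feature matrix")
    if not np.all(np.isfinite(X)):
        raise GraphError("feature matrix must be finite")
    return X


def build_cosine_graph(X, threshold: float = DEFAULT_THRESHOLD) -> Topology:
    """Thresholded clipped-cosine similarity graph."""
    X = _check_features(X)
    return Topology("cosine", _apply_threshold(_clipped_cosine(X), threshold), threshold)


def build_euclidean_graph(X, threshold: float = DEFAULT_THRESHOLD) -> Topology:
    """Gaussian kernel graph, bandwidth = median nonzero pairwise distance."""
    X = _check_features(X)
    dist = squareform(pdist(X))
    nonzero = dist[np.triu_indices_from(dist, k=1)]
    nonzero = nonzero[nonzero > 0]
    if nonzero.size == 0:
        logger.warning("all pairwise distances zero; returning complete unit graph")
        raw = np.ones_like(dist)
    else:
        sigma = float(np.median(nonzero))
        raw = np.exp(-(dist**2) / (2.0 * sigma**2))
    return Topology("euclidean", _apply_threshold(raw, threshold), threshold)


def build_style_graph(styles, threshold: float = DEFAULT_THRESHOLD) -> Topology:
    """Binary graph connecting students with identical learning styles."""
    styles = np.asarray(styles)
    if styles.ndim != 1 or styles.size < 2:
        raise GraphError("need a length-n (n >= 2) style vector")
    same = (styles[:, None] == styles[None, :]).astype(float)
    return Topology("learning", _apply_threshold(same, threshold), threshold)


def build_perma_graph(
    X, prior: PermaPriorMap, threshold: float = DEFAULT_THRESHOLD
) -> Topology:
    """Theory-weighted graph: sum_p w_p * cosine on prior-masked features."""
    X = _check_features(X)
    if prior.d != X.shape[1]:
        raise GraphError(f"prior has d={prior.d} but features have d={X.shape[1]}")
    raw = np.zeros((X.shape[0], X.shape[0]))
    for p in range(5):
        raw += prior.dim_weights[p] * _clipped_cosine(X * prior.weights[:, p])
    return Topology("perma", _apply_threshold(raw, threshold), threshold)


def build_topology_set(
    cohort: CohortTable,
    prior: PermaPriorMap,
    threshold: float = DEFAULT_THRESHOLD,
) -> TopologySet:
    """All four graphs over a [0, 1]-scaled cohort with one shared threshold."""
    X = cohort.features
    if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
        raise GraphError("cohort features must be scaled to [0, 1] first")
    return TopologySet((
        build_cosine_graph(X, threshold),
        build_euclidean_graph(X, threshold),
        build_style_graph(cohort.learning_styles, threshold),
        build_perma_graph(X, prior, threshold),
    ))


def normalize_adjacency(topology: Topology) -> np.ndarray:
    """Symmetric renormalisation D^{-1/2} (A + I) D^{-1/2}.

    Self-loops guarantee every degree is >= 1, so the result is well defined
    and its spectrum lies in [-1, 1].
    """
    a_tilde = topology.adjacency + np.eye(topology.n)
    inv_sqrt_deg = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * inv_sqrt_deg[:, None] * inv_sqrt_deg[None, :]


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_edge_list(topology: Topology, path) -> None:
    """TSV of (i, j, weight) with 0-based indices, i < j."""
    edges = topology.edge_list()
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in edges:
            fh.write(f"{int(i)}\t{int(j)}\t{w:.12g}\n")


def export_normalized_mtx(topology: Topology, path) -> None:
    """MatrixMarket export of the normalised adjacency."""
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(normalize_adjacency(topology)))
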