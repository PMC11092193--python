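"""Network and sequence similarity matrices and their weighted fusion.

Two complementary views of the same protein set are turned into n-by-n
similarity matrices:

* **network view** — the Gaussian interaction-profile (GIP) kernel
  ``S_network(i, j) = exp(-gamma_r * ||A(i) - A(j)||^2)`` over rows of the
  binary adjacency, with bandwidth ``gamma_r`` set to the reciprocal of the
  mean squared profile norm, ``gamma_r = n / sum_i ||A(i)||^2``;
* **sequence view** — a Levenshtein-distance similarity, by default
  ``S_seq(i, j) = 1 - LD(s_i, s_j) / max(|s_i|, |s_j|)``.

The fusion (initial information) matrix is the convex combination
``M = alpha * S_network + (1 - alpha) * S_seq``; each protein's feature
vector is its row of ``M``.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import InteractionNetwork, ProteinSet

#: Supported Levenshtein-to-similarity conversions.
SEQ_NORMALIZATIONS = ("max", "sum", "exp")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric n-by-n similarity with unit diagonal and entries in [0, 1]."""

    values: np.ndarray
    kind: str  # "network" | "sequence" | "fused"
    alpha: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.kind not in ("network", "sequence", "fused"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if (self.kind == "fused") != (self.alpha is not None):
            raise ValueError("alpha is present exactly when kind='fused'")
        if not np.isfinite(v).all():
            raise ValueError("similarity entries must be finite")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("similarity matrix must be symmetric within 1e-12")
        if v.size and (np.abs(np.diag(v) - 1.0).max() > 1e-12):
            raise ValueError("similarity diagonal must equal 1")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GipBandwidth:
    """Gaussian interaction-profile kernel bandwidth gamma_r."""

    gamma_r: float

    def __post_init__(self) -> None:
        if not (self.gamma_r > 0 and np.isfinite(self.gamma_r)):
            raise ValueError("gamma_r must be positive and finite")


def gip_bandwidth(network: InteractionNetwork) -> GipBandwidth:
    """Bandwidth gamma_r = n / sum_i ||A(i)||^2 (reciprocal mean squared row norm).

    For a binary adjacency the squared row norms are the node degrees, so
    gamma_r = n / (2 * |E|).  Undefined (error) on an edgeless graph.
    """
    a = network.adjacency.astype(float)
    total = float((a**2).sum())
    if total == 0:
        raise ValueError("GIP bandwidth undefined for an edgeless network")
    return GipBandwidth(gamma_r=network.n / total)


def gip_similarity(network: InteractionNetwork) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over adjacency rows."""
    gamma = gip_bandwidth(network).gamma_r
    a = network.adjacency.astype(float)
    sq = squareform(pdist(a, metric="sqeuclidean"))
    values = np.exp(-gamma * sq)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values=values, kind="network")


def levenshtein_distance(s: str, t: str) -> int:
    """Minimum number of single-character edits (insert/delete/substitute)
    transforming ``s`` into ``t``."""
    if not s or not t:
        return len(s) + len(t)
    return edlib.align(s, t, mode="NW", task="distance")["editDistance"]


def _to_similarity(d: int, len_s: int, len_t: int, normalization: str) -> float:
    if normalization == "max":
        m = max(len_s, len_t)
        return 1.0 - d / m if m else 1.0
    if normalization == "sum":
        m = len_s + len_t
        return 1.0 - d / m if m else 1.0
    if normalization == "exp":
        return float(np.exp(-d))
    raise ValueError(f"unknown normalization {normalization!r}; choose from {SEQ_NORMALIZATIONS}")


def sequence_similarity_matrix(
    proteins: ProteinSet, normalization: str = "max"
) -> SimilarityMatrix:
    """Pairwise Levenshtein similarity over the protein set.

    ``normalization`` selects the distance-to-similarity conversion:
    ``"max"`` (default) 1 - d/max(|s|,|t|); ``"sum"`` 1 - d/(|s|+|t|);
    ``"exp"`` exp(-d).
    """
    if normalization not in SEQ_NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}; choose from {SEQ_NORMALIZATIONS}")
    seqs = proteins.sequence_list()
    n = len(seqs)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein_distance(seqs[i], seqs[j])
            values[i, j] = values[j, i] = _to_similarity(
                d, len(seqs[i]), len(seqs[j]), normalization
            )
    return SimilarityMatrix(values=values, kind="sequence")


def fuse(
    s_net: SimilarityMatrix, s_seq: SimilarityMatrix, alpha: float
) -> SimilarityMatrix:
    """Initial information matrix M = alpha * S_network + (1 - alpha) * S_seq.

    At alpha=0 the fusion contains only sequence information, at alpha=1 only
    network information.
    """
    if s_net.kind != "network" or s_seq.kind != "sequence":
        raise ValueError("fuse expects a network and a sequence similarity matrix")
    if s_net.values.shape != s_seq.values.shape:
        raise ValueError("shape mismatch between similarity matrices")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        values = s_seq.values.copy()
    elif alpha == 1.0:
        values = s_net.values.copy()
    else:
        values = alpha * s_net.values + (1.0 - alpha) * s_seq.values
    return SimilarityMatrix(values=values, kind="fused", alpha=float(alpha))
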