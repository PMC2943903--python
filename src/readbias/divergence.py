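"""Kullback-Leibler divergence between per-position k-mer distributions.

For each read offset i let P_i be the distribution of k-mers observed
there. Comparing P_i against P_j for every ordered pair of offsets gives
a matrix of divergences

    KL(P_i ‖ P_j) = Σ_w P_i(w) · log2( P_i(w) / P_j(w) )   [bits]

whose structure localises bias: an unbiased read set yields a flat plain
of small values, while a biased start offset lights up its whole row and
column. KL is asymmetric and requires Q(w) > 0 wherever P(w) > 0, so the
per-position distributions are additively smoothed (pseudo-count alpha,
default 0.5) before comparison; alpha = 0 disables smoothing and then a
zero in Q under the support of P is an error rather than a silent skip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import kmer_to_index
from .kmers import PositionalKmerTable

DEFAULT_ALPHA = 0.5


@dataclass
class PositionDistribution:
    """Smoothed k-mer distribution at one read offset (1-based position)."""

    position: int
    k: int
    prob: np.ndarray
    support_size: int
    smoothing_alpha: float

    def probability(self, kmer: str) -> float:
        return float(self.prob[kmer_to_index(kmer)])


@dataclass
class KLMatrix:
    """Pairwise positional KL divergences, in bits.

    ``values[a, b]`` is KL(P_i ‖ P_j) for positions i = positions[a],
    j = positions[b]; the diagonal is zero and the matrix is generally
    not symmetric. ``dropped`` lists 1-based positions excluded for
    insufficient valid-window coverage.
    """

    k: int
    positions: np.ndarray
    values: np.ndarray
    dropped: list[int]

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.positions, columns=self.positions)


def position_distribution(
    table: PositionalKmerTable, position: int, alpha: float = DEFAULT_ALPHA
) -> PositionDistribution:
    """k-mer distribution at a 1-based read position with additive smoothing.

    prob[w] = (count[w] + alpha) / (total_valid + alpha · 4^k).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    row = table.counts[position - 1].astype(float)
    total = row.sum()
    if total == 0:
        raise ValueError(f"no valid windows at position {position}")
    prob = (row + alpha) / (total + alpha * len(row))
    return PositionDistribution(
        position=position, k=table.k, prob=prob,
        support_size=int((row > 0).sum()), smoothing_alpha=alpha,
    )


def kl_divergence(P: PositionDistribution, Q: PositionDistribution) -> float:
    """KL(P ‖ Q) in bits; terms with P(w) = 0 contribute nothing."""
    if P.k != Q.k:
        raise ValueError("distributions have different k")
    p, q = P.prob, Q.prob
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("unsmoothed zero in Q under the support of P")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def kl_matrix(
    table: PositionalKmerTable,
    alpha: float = DEFAULT_ALPHA,
    min_coverage: int = 1,
) -> KLMatrix:
    """KL divergence between every ordered pair of read positions.

    Positions with fewer than ``min_coverage`` valid windows are dropped
    (and reported): late offsets of a variable-length read set are
    covered by few reads and their distributions are noise-dominated.
    """
    valid_counts = table.n_windows - table.skipped
    keep = np.flatnonzero(valid_counts >= max(min_coverage, 1))
    dropped = [int(i) + 1 for i in np.flatnonzero(valid_counts < max(min_coverage, 1))]
    if len(keep) < 2:
        raise ValueError("fewer than 2 positions with sufficient coverage")

    counts = table.counts[keep].astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + alpha) / (totals + alpha * counts.shape[1])

    if alpha > 0:
        logp = np.log2(probs)
        # KL[a,b] = Σ_w probs[a]·(logp[a] − logp[b])
        self_ent = np.sum(probs * logp, axis=1)
        cross = probs @ logp.T
        values = self_ent[:, None] - cross
    else:
        n = len(keep)
        values = np.zeros((n, n))
        dists = [
            PositionDistribution(
                position=int(i) + 1, k=table.k, prob=probs[a],
                support_size=int((counts[a] > 0).sum()), smoothing_alpha=0.0,
            )
            for a, i in enumerate(keep)
        ]
        for a in range(n):
            for b in range(n):
                if a != b:
                    values[a, b] = kl_divergence(dists[a], dists[b])
    np.fill_diagonal(values, 0.0)
    values = np.maximum(values, 0.0)  # clip −0.0 / rounding dust
    return KLMatrix(k=table.k, positions=keep + 1, values=values, dropped=dropped)


def first_position_excess(matrix: KLMatrix) -> float:
    """Mean of row 1 + column 1 divided by the interior grand mean.

    A ratio well above 1 reproduces the hallmark of start-site bias:
    the first position's distribution diverges from every other.
    """
    v = matrix.values
    n = matrix.n_positions
    if n < 3:
        raise ValueError("need at least 3 positions")
    edge = np.concatenate((v[0, 1:], v[1:, 0]))
    interior = v[1:, 1:]
    off_diag = interior[~np.eye(n - 1, dtype=bool)]
    grand = float(off_diag.mean())
    if grand == 0:
        return float("inf") if edge.mean() > 0 else 1.0
    return float(edge.mean()) / grand
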