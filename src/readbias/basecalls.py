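"""Per-position base-call counts and quality profiles.

The simplest bias screen: count how many times each of the five symbols
A, C, G, T, N was called at each read position. With unbiased data the
per-position fractions of a fixed base are flat across positions, and the
complementary pairs A/T and C/G are balanced (no strand preference), so
deviations — in particular non-zero A−T or C−G differences — localise
where in the reads a problem sits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import BASES, encode
from .io import Read


@dataclass
class BaseCountMatrix:
    """Per-position counts of A, C, G, T, N calls.

    ``counts`` has shape (max_length, 5) with columns ordered A,C,G,T,N;
    row i (0-based) covers read position i+1. ``coverage[i]`` is the
    number of reads of length > i; the five counts at each position sum
    to the coverage there.
    """

    counts: np.ndarray
    coverage: np.ndarray

    @property
    def max_length(self) -> int:
        return self.counts.shape[0]

    def validate(self) -> None:
        if not np.array_equal(self.counts.sum(axis=1), self.coverage):
            raise ValueError("base counts do not sum to coverage at every position")
        if np.any(np.diff(self.coverage) > 0):
            raise ValueError("coverage must be non-increasing with position")


@dataclass
class QualityProfile:
    """Per-position mean Phred quality and mean error probability.

    ``mean_error_prob`` averages the probabilities 10^(−Q/10), not the
    qualities: the mean of transformed qualities is a biased (Jensen)
    estimate of the error rate, and the simulator needs the unbiased one.
    """

    mean_q: np.ndarray
    n: np.ndarray
    mean_error_prob: np.ndarray


def count_basecalls(reads: Iterable[Read]) -> BaseCountMatrix:
    """Count each symbol at each position over a stream of reads.

    Reads of different lengths are allowed; a read only contributes to
    positions it covers.
    """
    counts = np.zeros((0, 5), dtype=np.int64)
    n_reads = 0
    for read in reads:
        codes = encode(read.seq)
        if len(codes) > counts.shape[0]:
            grown = np.zeros((len(codes), 5), dtype=np.int64)
            grown[: counts.shape[0]] = counts
            counts = grown
        counts[np.arange(len(codes)), codes] += 1
        n_reads += 1
    if n_reads == 0:
        raise ValueError("empty read stream")
    matrix = BaseCountMatrix(counts=counts, coverage=counts.sum(axis=1))
    matrix.validate()
    return matrix


def quality_profile(reads: Iterable[Read]) -> QualityProfile:
    """Mean Phred score and mean error probability at each position."""
    q_sum = np.zeros(0)
    p_sum = np.zeros(0)
    n = np.zeros(0, dtype=np.int64)
    n_reads = 0
    for read in reads:
        quals = np.asarray(read.quals, dtype=np.float64)
        if len(quals) > len(n):
            q_sum = np.pad(q_sum, (0, len(quals) - len(q_sum)))
            p_sum = np.pad(p_sum, (0, len(quals) - len(p_sum)))
            n = np.pad(n, (0, len(quals) - len(n)))
        q_sum[: len(quals)] += quals
        p_sum[: len(quals)] += 10.0 ** (-quals / 10.0)
        n[: len(quals)] += 1
        n_reads += 1
    if n_reads == 0:
        raise ValueError("empty read stream")
    return QualityProfile(mean_q=q_sum / n, n=n, mean_error_prob=p_sum / n)


def basecall_fractions(matrix: BaseCountMatrix) -> pd.DataFrame:
    """Per-position base fractions plus strand-symmetry diagnostics.

    Returns a DataFrame indexed by 1-based position with the five counts,
    coverage, fractions, and the A−T and C−G fraction differences (zero
    under strand-symmetric sampling).
    """
    cov = matrix.coverage.astype(float)
    frac = np.divide(
        matrix.counts, cov[:, None], out=np.zeros_like(matrix.counts, dtype=float),
        where=cov[:, None] > 0,
    )
    df = pd.DataFrame(
        matrix.counts, columns=list(BASES),
        index=pd.RangeIndex(1, matrix.max_length + 1, name="position"),
    )
    df["coverage"] = matrix.coverage
    for i, b in enumerate(BASES):
        df[f"frac_{b}"] = frac[:, i]
    df["AT_diff"] = frac[:, 0] - frac[:, 3]
    df["CG_diff"] = frac[:, 1] - frac[:, 2]
    return df
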