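"""Positional k-mer counting and binomial over/under-representation tests.

Under uniform sampling of read start sites, a k-mer w occupying fraction
p_w of genome windows appears at any fixed read offset with probability
p_w independently per read, so its positional count is Binomial(n, p_w).
This module counts k-mers at every read offset, builds background models
from a reference or from the read pool, and computes one-sided binomial
tail p-values on the log10 scale, using a Stirling-series log-factorial
so that tests remain well-defined for counts far beyond floating range.

The positional counts can also be regressed against read offset: under
position independence a k-mer's frequency is flat in the offset, so a
significant (typically cubic) trend is itself a bias signal — the
homopolymer runs rising toward read ends are the canonical example.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from ._seq import _ENCODE as _ENCODE_TABLE
from ._seq import all_kmers, encode, kmer_to_index, revcomp_codes, window_codes
from .io import Read, ReferenceSequence

LOG10E = math.log10(math.e)

# ---------------------------------------------------------------------------
# log-factorials: exact cumulative sums for small n, Stirling series above

_EXACT_LIMIT = 20
_EXACT_LF = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, _EXACT_LIMIT + 1)))))
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


def stirling_log_factorial(n: float) -> float:
    """Stirling-series approximation of ln(n!).

    n ln n − n + ½ ln(2πn) plus the 1/(12n) − 1/(360n³) correction terms;
    the truncation error is below 1/(1260 n⁵), far inside the 1/(12n)
    envelope of the leading-order formula.
    """
    if n <= 0:
        return 0.0
    return (
        n * math.log(n) - n + _HALF_LOG_2PI + 0.5 * math.log(n)
        + 1.0 / (12.0 * n) - 1.0 / (360.0 * n**3)
    )


def log_factorial(n: int) -> float:
    """ln(n!): exact summation for n ≤ 20, Stirling series beyond."""
    if n < 0:
        raise ValueError("factorial of negative number")
    if n <= _EXACT_LIMIT:
        return float(_EXACT_LF[n])
    return stirling_log_factorial(n)


def _log_binom_pmf(x: int, n: int, log_p: float, log_q: float) -> float:
    return (
        log_factorial(n) - log_factorial(x) - log_factorial(n - x)
        + x * log_p + (n - x) * log_q
    )


def binomial_log10_pvalue(
    observed: int, n: int, p: float
) -> tuple[float, Literal["over", "under"]]:
    """One-sided binomial tail probability on the log10 scale.

    The tail is taken in the direction of the deviation from the mean np:
    P(X ≥ observed) when observed ≥ np (direction "over"), else
    P(X ≤ observed) ("under"). The sum runs outward from the observed
    value entirely in log space; once the next term can no longer move
    the accumulated log-sum, the remaining mass is bounded by a geometric
    series with ratio r = p(n−x)/((x+1)(1−p)) (or its lower-tail mirror)
    and added in closed form.

    Returns ``(log10_pvalue, direction)``; log10_pvalue is ≤ 0 and may be
    −inf in degenerate zero-probability cases.
    """
    if not 0 <= observed <= n:
        raise ValueError(f"observed={observed} outside [0, n={n}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    if p == 0.0:
        return (0.0, "over") if observed == 0 else (-math.inf, "over")
    if p == 1.0:
        return (0.0, "under") if observed == n else (-math.inf, "under")

    mean = n * p
    direction: Literal["over", "under"] = "over" if observed >= mean else "under"
    log_p, log_q = math.log(p), math.log1p(-p)

    log_term = _log_binom_pmf(observed, n, log_p, log_q)
    log_sum = log_term
    x = observed
    # run far enough past the mode that truncation is controlled by the
    # geometric remainder, not the gaussian bulk
    sd = math.sqrt(max(mean * (1.0 - p), 1.0))
    max_terms = int(min((n + 1), 30.0 * sd + 200.0))

    for _ in range(max_terms):
        if direction == "over":
            if x >= n:
                return (min(0.0, log_sum * LOG10E), direction)
            log_ratio = math.log(n - x) - math.log(x + 1) + log_p - log_q
            x += 1
        else:
            if x <= 0:
                return (min(0.0, log_sum * LOG10E), direction)
            log_ratio = math.log(x) - math.log(n - x + 1) + log_q - log_p
            x -= 1
        log_term += log_ratio
        if log_term < log_sum - 40.0:
            log_sum = np.logaddexp(log_sum, log_term)
            break
        log_sum = np.logaddexp(log_sum, log_term)
    else:
        # truncated: bound the remainder by Σ term·r^j = term·r/(1−r)
        if direction == "over":
            r = math.exp(log_p - log_q) * (n - x) / (x + 1)
        else:
            r = math.exp(log_q - log_p) * x / (n - x + 1)
        if 0.0 < r < 1.0:
            log_sum = np.logaddexp(log_sum, log_term + math.log(r) - math.log1p(-r))
    return (min(0.0, float(log_sum) * LOG10E), direction)


# ---------------------------------------------------------------------------
# positional k-mer tables


@dataclass
class PositionalKmerTable:
    """Counts of every k-mer at every read offset.

    ``counts[i, w]`` (0-based offset i, packed k-mer index w) is the
    number of reads whose window [i, i+k−1] equals w; windows containing
    an N are tallied per offset in ``skipped``. ``n_windows[i]`` counts
    reads long enough to have a window at offset i, so at every offset
    counts + skipped = n_windows.
    """

    k: int
    counts: np.ndarray
    skipped: np.ndarray
    n_windows: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    def validate(self) -> None:
        if not np.array_equal(self.counts.sum(axis=1) + self.skipped, self.n_windows):
            raise ValueError("window counts + skipped != n_windows at some offset")

    def count(self, position: int, kmer: str) -> int:
        """Count of ``kmer`` at 1-based read position."""
        return int(self.counts[position - 1, kmer_to_index(kmer)])


def _accumulate_code_block(
    codes: np.ndarray, k: int,
    counts: np.ndarray, skipped: np.ndarray, n_windows: np.ndarray,
) -> None:
    """Tally the windows of one (n_reads, length) code block in place."""
    n_reads, length = codes.shape
    np_local = length - k + 1
    idx = np.zeros((n_reads, np_local), dtype=np.int64)
    valid = np.ones((n_reads, np_local), dtype=bool)
    c = codes.astype(np.int64)
    for j in range(k):
        col = c[:, j : j + np_local]
        valid &= col != 4
        idx = idx * 4 + np.where(col == 4, 0, col)
    n_windows[:np_local] += n_reads
    for i in range(np_local):
        v = valid[:, i]
        skipped[i] += int((~v).sum())
        counts[i] += np.bincount(idx[v, i], minlength=counts.shape[1])


def count_kmers_from_matrix(codes: np.ndarray, k: int) -> PositionalKmerTable:
    """Positional k-mer table from an (n_reads, length) base-code matrix."""
    if codes.ndim != 2 or codes.shape[1] < k:
        raise ValueError("code matrix narrower than k")
    n_pos = codes.shape[1] - k + 1
    counts = np.zeros((n_pos, 4**k), dtype=np.int64)
    skipped = np.zeros(n_pos, dtype=np.int64)
    n_windows = np.zeros(n_pos, dtype=np.int64)
    _accumulate_code_block(codes, k, counts, skipped, n_windows)
    return PositionalKmerTable(k=k, counts=counts, skipped=skipped, n_windows=n_windows)


def count_kmers_by_position(reads: Iterable[Read], k: int) -> PositionalKmerTable:
    """Tally k-mer occurrences at every read offset.

    Reads are batched by length and counted with vectorised window
    encoding; variable-length read sets are fine (shorter reads simply
    stop contributing at their last full window).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_length: dict[int, list[str]] = {}
    for read in reads:
        by_length.setdefault(len(read.seq), []).append(read.seq)
    if not by_length:
        raise ValueError("empty read stream")
    max_len = max(by_length)
    if k > max_len:
        raise ValueError(f"k={k} exceeds the longest read ({max_len})")

    n_pos = max_len - k + 1
    counts = np.zeros((n_pos, 4**k), dtype=np.int64)
    skipped = np.zeros(n_pos, dtype=np.int64)
    n_windows = np.zeros(n_pos, dtype=np.int64)

    for length, seqs in by_length.items():
        if length < k:
            continue
        block = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        codes = _ENCODE_TABLE[block].reshape(len(seqs), length)
        _accumulate_code_block(codes, k, counts, skipped, n_windows)

    table = PositionalKmerTable(k=k, counts=counts, skipped=skipped, n_windows=n_windows)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# background models


@dataclass
class BackgroundModel:
    """Probability of each k-mer under a reference or read-pool background."""

    k: int
    source: Literal["reference", "read_pool"]
    prob: np.ndarray
    n_sites: int
    genome_occurrences: np.ndarray | None = None

    def probability(self, kmer: str) -> float:
        return float(self.prob[kmer_to_index(kmer)])


def background_from_reference(
    ref: ReferenceSequence, k: int, both_strands: bool = True
) -> BackgroundModel:
    """k-mer window frequencies of a reference sequence.

    Counts every length-k window (windows containing N are skipped); with
    ``both_strands`` the reverse-complement windows are added, doubling
    the site denominator. prob[w] = occurrences[w] / n_sites.
    """
    if len(ref) < k:
        raise ValueError(f"reference length {len(ref)} < k={k}")
    codes = encode(ref.seq)
    occ = np.zeros(4**k, dtype=np.int64)
    for strand in ([codes, revcomp_codes(codes)] if both_strands else [codes]):
        idx, valid = window_codes(strand, k)
        occ += np.bincount(idx[valid], minlength=4**k)
    n_sites = int(occ.sum())
    if n_sites == 0:
        raise ValueError("no valid windows in reference (all N?)")
    return BackgroundModel(
        k=k, source="reference", prob=occ / n_sites,
        n_sites=n_sites, genome_occurrences=occ,
    )


def background_from_reads(table: PositionalKmerTable) -> BackgroundModel:
    """Pooled-read background: prob[w] ∝ Σ_i counts[i, w]."""
    pooled = table.counts.sum(axis=0)
    total = int(pooled.sum())
    if total == 0:
        raise ValueError("positional table contains no valid windows")
    return BackgroundModel(
        k=table.k, source="read_pool", prob=pooled / total, n_sites=total
    )


# ---------------------------------------------------------------------------
# the positional test


@dataclass
class KmerTestResult:
    kmer: str
    position: int
    observed: int
    expected: float
    log10_pvalue: float
    direction: Literal["over", "under"]
    bonferroni_log10: float


def test_positional_kmers(
    table: PositionalKmerTable,
    background: BackgroundModel,
    positions: Sequence[int] | Literal["start", "all"] = "start",
) -> list[KmerTestResult]:
    """Binomial test of every k-mer's count at the requested read positions.

    Positions are 1-based; "start" tests position 1 only, "all" tests
    every offset. At each position the number of trials is the N-free
    window count there. Background probabilities of exactly zero are
    floored at 1/(2·n_sites) — a pseudo-count of half an observation —
    so an observed k-mer absent from the background is reported as the
    extreme outlier it is instead of breaking the logarithm. Both raw
    and Bonferroni-adjusted (over all tests emitted) log10 p-values are
    returned.
    """
    if table.k != background.k:
        raise ValueError(f"table k={table.k} != background k={background.k}")
    if positions == "start":
        pos_list = [1]
    elif positions == "all":
        pos_list = list(range(1, table.n_positions + 1))
    else:
        pos_list = sorted(set(int(p) for p in positions))
        for pos in pos_list:
            if not 1 <= pos <= table.n_positions:
                raise ValueError(f"position {pos} outside [1, {table.n_positions}]")

    floor = 1.0 / (2.0 * background.n_sites)
    results: list[KmerTestResult] = []
    names = all_kmers(table.k)
    for pos in pos_list:
        row = table.counts[pos - 1]
        n = int(table.n_windows[pos - 1] - table.skipped[pos - 1])
        if n == 0:
            continue
        for w in range(4**table.k):
            p_w = float(background.prob[w])
            obs = int(row[w])
            if p_w == 0.0 and obs == 0:
                continue
            p_w = max(p_w, floor)
            log10_p, direction = binomial_log10_pvalue(obs, n, p_w)
            results.append(
                KmerTestResult(
                    kmer=names[w], position=pos, observed=obs,
                    expected=n * p_w, log10_pvalue=log10_p,
                    direction=direction, bonferroni_log10=log10_p,  # adjusted below
                )
            )
    m = len(results)
    if m:
        log10_m = math.log10(m)
        for res in results:
            res.bonferroni_log10 = min(0.0, res.log10_pvalue + log10_m)
    return results


def results_to_frame(results: list[KmerTestResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df = df.sort_values("log10_pvalue").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# position-frequency trend


@dataclass
class PositionTrendFit:
    kmer: str
    degree: int
    r2: float
    pvalue: float
    coefficients: np.ndarray
    adjusted_r2: float = float("nan")
    degenerate: bool = False


def position_trend_fit(
    table: PositionalKmerTable,
    kmer: str,
    degree: int | Literal["auto"] = 3,
) -> PositionTrendFit:
    """OLS polynomial fit of a k-mer's count against read position.

    Under position independence the counts are flat, so the regression
    F-test doubles as a per-k-mer bias test. degree is 1, 3 or "auto"
    (both fitted, better adjusted R² wins). Constant counts are returned
    with r2 = 0, pvalue = 1 and the degenerate flag set.
    """
    w = kmer_to_index(kmer)
    y = table.counts[:, w].astype(float)
    x = np.arange(1, table.n_positions + 1, dtype=float)

    if degree == "auto":
        fits = [_fit_poly(x, y, d, kmer) for d in (1, 3) if len(x) >= d + 2]
        if not fits:
            raise ValueError("too few positions for any fit")
        return max(fits, key=lambda f: -math.inf if f.degenerate else f.adjusted_r2)
    degree = int(degree)
    if degree not in (1, 3):
        raise ValueError("degree must be 1, 3 or 'auto'")
    if len(x) < degree + 2:
        raise ValueError(f"need >= {degree + 2} positions for degree {degree}")
    return _fit_poly(x, y, degree, kmer)


def _fit_poly(x: np.ndarray, y: np.ndarray, degree: int, kmer: str) -> PositionTrendFit:
    n = len(x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return PositionTrendFit(
            kmer=kmer, degree=degree, r2=0.0, pvalue=1.0,
            coefficients=np.concatenate((np.zeros(degree), [y.mean()])),
            adjusted_r2=0.0, degenerate=True,
        )
    coef = np.polyfit(x, y, degree)
    resid = y - np.polyval(coef, x)
    ss_res = float((resid**2).sum())
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    df_reg, df_res = degree, n - degree - 1
    if ss_res <= 1e-12 * ss_tot:
        pvalue = 0.0
        r2 = 1.0
    else:
        f_stat = (ss_tot - ss_res) / df_reg / (ss_res / df_res)
        pvalue = float(_stats.f.sf(f_stat, df_reg, df_res))
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_res if df_res > 0 else -math.inf
    return PositionTrendFit(
        kmer=kmer, degree=degree, r2=r2, pvalue=pvalue,
        coefficients=coef, adjusted_r2=adj,
    )
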