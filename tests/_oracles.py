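"""Independent oracles used by the test suite.

These deliberately avoid the production code paths: exact log-space
binomial summation built on lgamma (no Stirling series), and direct
two-distribution KL evaluation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp


def exact_binomial_log10_tail(observed: int, n: int, p: float, direction: str) -> float:
    """log10 of the exact one-sided binomial tail by full log-space summation."""
    if p <= 0.0 or p >= 1.0:
        raise ValueError("oracle handles 0 < p < 1 only")
    xs = (
        np.arange(observed, n + 1) if direction == "over" else np.arange(0, observed + 1)
    )
    log_pmf = (
        gammaln(n + 1) - gammaln(xs + 1) - gammaln(n - xs + 1)
        + xs * math.log(p) + (n - xs) * math.log1p(-p)
    )
    return float(logsumexp(log_pmf)) / math.log(10)


def exact_log_factorial(n: int) -> float:
    """Σ_{i=1..n} ln i by direct summation."""
    return float(np.log(np.arange(1, n + 1)).sum())


def direct_kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    """Term-by-term KL divergence in bits, skipping P(w) = 0 terms."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * math.log2(pi / qi)
    return total
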