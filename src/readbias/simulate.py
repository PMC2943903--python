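"""Read simulation under the uniform-sampling null, and bootstrap calibration.

The simulator draws read start sites uniformly over the reference (both
strands equally), then applies context-free substitution errors at a
per-position rate taken from an empirical quality profile — exactly the
null model against which observed data are judged. Repeating the
simulation gives the null mean and standard deviation of every cell of
the positional KL matrix, so observed divergences can be reported as
effect sizes (multiples of the null standard deviation) instead of
p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._seq import decode, encode
from .basecalls import QualityProfile
from .divergence import DEFAULT_ALPHA, KLMatrix, kl_matrix
from .io import MAX_PHRED, Read, ReferenceSequence
from .kmers import count_kmers_from_matrix

DEFAULT_REPLICATES = 100  # replicate read sets per calibration


@dataclass
class ErrorProfile:
    """Per-position substitution error probabilities for the simulator."""

    per_position_error: np.ndarray

    def __post_init__(self) -> None:
        self.per_position_error = np.asarray(self.per_position_error, dtype=float)
        if np.any((self.per_position_error < 0) | (self.per_position_error > 1)):
            raise ValueError("error probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.per_position_error)

    @classmethod
    def from_quality_profile(cls, profile: QualityProfile) -> "ErrorProfile":
        """Train on observed data: the per-position mean error probability."""
        return cls(per_position_error=np.asarray(profile.mean_error_prob, dtype=float))

    @classmethod
    def constant(cls, rate: float, length: int) -> "ErrorProfile":
        return cls(per_position_error=np.full(length, rate))

    @classmethod
    def linear(cls, start_rate: float, end_rate: float, length: int) -> "ErrorProfile":
        return cls(per_position_error=np.linspace(start_rate, end_rate, length))

    def phred(self) -> np.ndarray:
        """Rounded Phred score at each position (capped at 93 for p = 0)."""
        p = np.maximum(self.per_position_error, 10 ** (-MAX_PHRED / 10))
        return np.minimum(np.round(-10.0 * np.log10(p)), MAX_PHRED).astype(int)


def _simulate_code_matrix(
    ref_codes: np.ndarray,
    n: int,
    length: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, length) base-code matrix of reads sampled under H1 + H3."""
    G = len(ref_codes)
    if G < length:
        raise ValueError(f"reference length {G} < read length {length}")
    if len(profile) != length:
        raise ValueError("error profile length != read length")
    starts = rng.integers(0, G - length + 1, size=n)
    codes = ref_codes[starts[:, None] + np.arange(length)]
    minus = rng.random(n) < 0.5
    # reverse complement the minus-strand rows (N = 4 is self-complementary here)
    rc = codes[minus][:, ::-1]
    rc = np.where(rc == 4, 4, 3 - rc)
    codes = codes.copy()
    codes[minus] = rc
    # context-free substitutions: replace with one of the other 3 bases uniformly
    err_mask = rng.random((n, length)) < profile.per_position_error[None, :]
    err_mask &= codes != 4
    n_err = int(err_mask.sum())
    if n_err:
        shift = rng.integers(1, 4, size=n_err)
        codes[err_mask] = (codes[err_mask] + shift) % 4
    return codes


def simulate_reads(
    ref: ReferenceSequence,
    n: int,
    length: int,
    profile: ErrorProfile,
    seed: int,
) -> Iterator[Read]:
    """Simulate ``n`` reads of fixed ``length`` from a reference.

    Start sites are uniform over [0, G−length], strands equiprobable,
    substitution errors independent per position at the profile's rate.
    Emitted qualities are the Phred values of the profile's error rates.
    Identical seeds give identical read sets.
    """
    rng = np.random.default_rng(seed)
    codes = _simulate_code_matrix(encode(ref.seq), n, length, profile, rng)
    quals = [int(q) for q in profile.phred()]
    for i in range(n):
        yield Read(id=f"sim_{i}", seq=decode(codes[i]), quals=list(quals))


@dataclass
class NullCalibration:
    """Per-cell null mean and sd of the KL matrix across replicates."""

    replicates: int
    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    avg_sd: float
    avg_sd_ci95: tuple[float, float]


@dataclass
class EffectSizeMatrix:
    """Observed KL cells expressed in null standard deviations."""

    z: np.ndarray
    degenerate_cells: list[tuple[int, int]]

    def max_abs(self) -> tuple[float, tuple[int, int]]:
        finite = np.where(np.isfinite(self.z), np.abs(self.z), -np.inf)
        flat = int(np.argmax(finite))
        ij = np.unravel_index(flat, self.z.shape)
        return float(finite[ij]), (int(ij[0]), int(ij[1]))


def calibrate_null(
    ref: ReferenceSequence,
    n: int,
    length: int,
    profile: ErrorProfile,
    replicates: int = DEFAULT_REPLICATES,
    k: int = 6,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> NullCalibration:
    """Bootstrap the null distribution of the positional KL matrix.

    Simulates ``replicates`` read sets under uniform sampling with the
    given error profile, computes each one's KL matrix, and returns the
    per-cell mean and (ddof = 1) standard deviation. ``avg_sd`` averages
    the sd over off-diagonal cells (the diagonal is identically zero)
    with a 95% normal-approximation confidence interval across cells.
    Replicate r uses seed + r, so calibrations are reproducible and
    individual replicates can be regenerated.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates to estimate a standard deviation")
    ref_codes = encode(ref.seq)
    stack = []
    positions = None
    for r in range(replicates):
        rng = np.random.default_rng(seed + r)
        codes = _simulate_code_matrix(ref_codes, n, length, profile, rng)
        table = count_kmers_from_matrix(codes, k)
        km = kl_matrix(table, alpha=alpha)
        if positions is None:
            positions = km.positions
        elif not np.array_equal(positions, km.positions):
            raise RuntimeError("replicates produced different position sets")
        stack.append(km.values)
    cube = np.stack(stack)
    mean = cube.mean(axis=0)
    sd = cube.std(axis=0, ddof=1)
    off = ~np.eye(mean.shape[0], dtype=bool)
    cells = sd[off]
    avg_sd = float(cells.mean())
    half = 1.96 * float(cells.std(ddof=1)) / math.sqrt(cells.size) if cells.size > 1 else 0.0
    return NullCalibration(
        replicates=replicates, positions=positions, mean=mean, sd=sd,
        avg_sd=avg_sd, avg_sd_ci95=(avg_sd - half, avg_sd + half),
    )


def effect_sizes(observed: KLMatrix, calibration: NullCalibration) -> EffectSizeMatrix:
    """z[i,j] = (observed − null mean) / null sd, cellwise.

    Cells with zero null sd are listed as degenerate (z = NaN there);
    no number is fabricated for them.
    """
    if observed.values.shape != calibration.mean.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.values.shape} vs "
            f"calibration {calibration.mean.shape}"
        )
    sd = calibration.sd
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed.values - calibration.mean) / sd
    degenerate = [(int(i), int(j)) for i, j in zip(*np.nonzero(sd == 0))]
    z[sd == 0] = np.nan
    return EffectSizeMatrix(z=z, degenerate_cells=degenerate)
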