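"""Synthetic genomes and read sets with known, injectable biases.

Every detector in this package is validated against data whose biases
are planted by construction: a start-site motif forced into a fraction
of reads, a k-mer enriched at one interior offset, near-homopolymer
windows in read tails converted into true runs (emulating the
systematic errors that manufacture poly-G), and a linear error-rate
gradient along the read. Biases are applied by overwriting bases after
uniform sampling, so the genome composition stays clean and every
injected effect size is exactly computable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._seq import decode, encode
from .io import MAX_PHRED, Read, ReferenceSequence
from .simulate import ErrorProfile, _simulate_code_matrix


@dataclass
class BiasSpec:
    """Which biases to inject into a simulated read set.

    start_motif: (motif, fraction) — that fraction of reads has its first
        len(motif) bases overwritten by the motif.
    position_enrichment: (kmer, position, fold) — the k-mer is planted at
        the 1-based position in enough extra reads to multiply its
        expected occurrence rate there by ``fold``.
    polyrun_error: (base, tail_length, conversion_prob) — within the last
        ``tail_length`` window offsets, each window differing from a pure
        run of ``base`` by exactly one base is converted to the pure run
        with the given probability (run length fixed by ``polyrun_k``).
    error_gradient: (start_rate, end_rate) — linear per-position
        substitution error rates.
    """

    start_motif: tuple[str, float] | None = None
    position_enrichment: tuple[str, int, float] | None = None
    polyrun_error: tuple[str, int, float] | None = None
    error_gradient: tuple[float, float] | None = None
    polyrun_k: int = 6

    def __post_init__(self) -> None:
        if self.start_motif is not None and not 0 <= self.start_motif[1] <= 1:
            raise ValueError("start_motif fraction outside [0, 1]")
        if self.position_enrichment is not None and self.position_enrichment[2] <= 0:
            raise ValueError("position_enrichment fold must be > 0")
        if self.polyrun_error is not None and not 0 <= self.polyrun_error[2] <= 1:
            raise ValueError("polyrun conversion probability outside [0, 1]")


def generate_genome(length: int, gc: float = 0.5, seed: int = 0) -> ReferenceSequence:
    """i.i.d. random genome with the given GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc outside [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    codes = rng.choice(4, size=length, p=probs)
    return ReferenceSequence(id=f"synthetic_g{length}_gc{gc:g}", seq=decode(codes))


def _generate_code_matrix(
    ref: ReferenceSequence, n: int, length: int, spec: BiasSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    if spec.error_gradient is not None:
        profile = ErrorProfile.linear(*spec.error_gradient, length)
    else:
        profile = ErrorProfile.constant(0.0, length)
    codes = _simulate_code_matrix(encode(ref.seq), n, length, profile, rng)

    if spec.start_motif is not None:
        motif, fraction = spec.start_motif
        mcodes = encode(motif)
        if len(mcodes) > length:
            raise ValueError("start motif longer than read")
        chosen = rng.random(n) < fraction
        codes[chosen, : len(mcodes)] = mcodes

    if spec.position_enrichment is not None:
        kmer, position, fold = spec.position_enrichment
        kcodes = encode(kmer)
        if position - 1 + len(kcodes) > length:
            raise ValueError("enriched k-mer does not fit at that position")
        sl = slice(position - 1, position - 1 + len(kcodes))
        has = np.all(codes[:, sl] == kcodes, axis=1)
        base_rate = max(has.mean(), 1.0 / n)
        extra = min(max((fold - 1.0) * base_rate, 0.0), 1.0)
        chosen = (rng.random(n) < extra) & ~has
        codes[chosen, sl] = kcodes

    if spec.polyrun_error is not None:
        base, tail_length, conv = spec.polyrun_error
        k = spec.polyrun_k
        bcode = encode(base)[0]
        n_pos = length - k + 1
        first_tail = max(0, n_pos - tail_length)
        for i in range(first_tail, n_pos):
            window = codes[:, i : i + k]
            mismatches = (window != bcode).sum(axis=1)
            near = mismatches == 1
            convert = near & (rng.random(n) < conv)
            codes[convert, i : i + k] = bcode
    return codes, profile.phred()


def generate_reads(
    ref: ReferenceSequence,
    n: int,
    length: int,
    spec: BiasSpec | None = None,
    seed: int = 0,
) -> Iterator[Read]:
    """Simulate ``n`` reads from ``ref`` with the biases of ``spec`` injected.

    With an empty spec this is exactly uniform sampling with zero error:
    every read is a substring of the reference or its reverse complement.
    """
    spec = spec or BiasSpec()
    codes, quals = _generate_code_matrix(ref, n, length, spec, seed)
    qual_list = [int(q) for q in quals]
    for i in range(n):
        yield Read(id=f"synth_{i}", seq=decode(codes[i]), quals=list(qual_list))
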