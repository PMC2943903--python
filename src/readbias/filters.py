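"""Pre-analysis artefact filters: poly-A fragments and primer prefixes.

Poly-A fragments (flow-cell reflection artefacts) and residual
sequencing primers inject artificial positional bias, so they are
removed before any profiling. Removed reads are returned alongside the
kept ones — never discarded silently — so filtering claims are
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import Read


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_removed_polyA: int = 0
    n_removed_primer: int = 0
    primer: str = ""

    def validate(self) -> None:
        if self.n_input != self.n_kept + self.n_removed_polyA + self.n_removed_primer:
            raise ValueError("filter report does not partition the input")


def is_polyA(read: Read, max_nonA: int | None = None) -> bool:
    """True if the read has at most ``max_nonA`` non-A bases.

    Default threshold: 5% of the read length (rounded down) — removes
    reflection artefacts without touching genuinely A-rich reads.
    """
    if max_nonA is None:
        max_nonA = int(0.05 * len(read.seq))
    return sum(1 for b in read.seq if b != "A") <= max_nonA


def matches_primer_prefix(read: Read, primer: str, max_mismatch: int = 1) -> bool:
    """True if the read starts with the primer up to ``max_mismatch`` mismatches.

    N counts as a mismatch. Reads shorter than the primer are compared
    over their full length with a proportionally scaled mismatch budget.
    """
    m = min(len(primer), len(read.seq))
    budget = max_mismatch if m == len(primer) else int(max_mismatch * m / len(primer))
    mismatches = sum(1 for a, b in zip(read.seq[:m], primer[:m]) if a != b)
    return mismatches <= budget


def filter_polyA(
    reads: Iterable[Read], max_nonA: int | None = None
) -> tuple[list[Read], list[Read], FilterReport]:
    """Split reads into (kept, removed) by the poly-A criterion."""
    kept: list[Read] = []
    removed: list[Read] = []
    for read in reads:
        (removed if is_polyA(read, max_nonA) else kept).append(read)
    report = FilterReport(
        n_input=len(kept) + len(removed), n_kept=len(kept),
        n_removed_polyA=len(removed),
    )
    report.validate()
    return kept, removed, report


def filter_primer_prefix(
    reads: Iterable[Read], primer: str, max_mismatch: int = 1
) -> tuple[list[Read], list[Read], FilterReport]:
    """Split reads into (kept, removed) by primer-prefix match."""
    if not primer or any(b not in "ACGT" for b in primer):
        raise ValueError("primer must be non-empty over {A,C,G,T}")
    kept: list[Read] = []
    removed: list[Read] = []
    for read in reads:
        (removed if matches_primer_prefix(read, primer, max_mismatch) else kept).append(read)
    report = FilterReport(
        n_input=len(kept) + len(removed), n_kept=len(kept),
        n_removed_primer=len(removed), primer=primer,
    )
    report.validate()
    return kept, removed, report


def filter_artefacts(
    reads: Iterable[Read],
    primer: str | None = None,
    max_mismatch: int = 1,
    max_nonA: int | None = None,
) -> tuple[list[Read], list[Read], FilterReport]:
    """Apply the poly-A filter, then (optionally) the primer filter.

    A pure poly-A read that also matches an A-rich primer is attributed
    to the poly-A filter, which runs first.
    """
    kept, removed_polyA, _ = filter_polyA(reads, max_nonA)
    removed_primer: list[Read] = []
    if primer:
        kept, removed_primer, _ = filter_primer_prefix(kept, primer, max_mismatch)
    report = FilterReport(
        n_input=len(kept) + len(removed_polyA) + len(removed_primer),
        n_kept=len(kept),
        n_removed_polyA=len(removed_polyA),
        n_removed_primer=len(removed_primer),
        primer=primer or "",
    )
    report.validate()
    return kept, removed_polyA + removed_primer, report
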