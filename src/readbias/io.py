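"""FASTQ / FASTA input and output with quality-offset handling.

Reads are modelled as a sequence over {A,C,G,T,N} plus per-base Phred
qualities; any lowercase or IUPAC-ambiguity character other than N is
mapped to N on input. Quality encodings Phred+33 and Phred+64 are both
supported, with auto-detection from the quality strings.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from ._seq import sanitize

MAX_PHRED = 93


@dataclass
class Read:
    """One sequencing read: id, sequence and per-base Phred qualities."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.seq)} bases but {len(self.quals)} qualities"
            )
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceSequence:
    """A reference (genome) sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadSetSummary:
    """Counts accumulated while streaming a read set."""

    n_reads: int = 0
    max_length: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def observe(self, read: Read) -> None:
        self.n_reads += 1
        length = len(read)
        self.max_length = max(self.max_length, length)
        self.length_histogram[length] = self.length_histogram.get(length, 0) + 1


class FastqFormatError(ValueError):
    pass


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if path.suffix == ".gz" or magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def detect_quality_offset(sample: Iterable[str]) -> tuple[int, bool]:
    """Infer the Phred ASCII offset (33 or 64) from quality strings.

    Returns ``(offset, ambiguous)``. Any character below ASCII 59 forces
    offset 33 (those codes are impossible under Phred+64). A sample whose
    codes all sit at or above 64 with at least one above 74 indicates
    Phred+64 ('K'..'Z' would mean Q > 41 under +33, rare; codes above 74
    would mean Q > 93's window under the old scale). Samples confined to
    the overlap window [59, 74] are undecidable; we fall back to 33 —
    modern data is overwhelmingly Phred+33 and a wrong 64 would silently
    produce negative qualities — and flag the ambiguity.
    """
    lo, hi = 255, 0
    seen = False
    for qs in sample:
        for ch in qs:
            code = ord(ch)
            seen = True
            lo = min(lo, code)
            hi = max(hi, code)
    if not seen:
        raise ValueError("empty quality sample")
    if lo < 59:
        return 33, False
    if lo >= 64 and hi > 74:
        return 64, False
    warnings.warn(
        "quality encoding ambiguous (all ASCII codes in [59,74]); assuming Phred+33",
        stacklevel=2,
    )
    return 33, True


def _decode_quals(qual: str, offset: int, ordinal: int) -> list[int]:
    quals = [ord(c) - offset for c in qual]
    for q in quals:
        if q < 0:
            raise FastqFormatError(
                f"record {ordinal}: quality character below offset {offset}"
            )
        if q > MAX_PHRED:
            raise FastqFormatError(
                f"record {ordinal}: quality {q} exceeds Phred maximum {MAX_PHRED}"
            )
    return quals


def read_fastq(
    path: str | Path,
    offset: int | str = "auto",
    summary: ReadSetSummary | None = None,
) -> Iterator[Read]:
    """Stream reads from a 4-line FASTQ file (plain or gzip).

    ``offset`` is 33, 64 or "auto" (sniffed from the first 100 records).
    Pass a :class:`ReadSetSummary` to have it filled in while streaming.
    Malformed records raise :class:`FastqFormatError` naming the record
    ordinal (1-based).
    """
    if offset == "auto":
        with _open_text(path) as fh:
            quals = []
            for i, line in enumerate(fh):
                if i % 4 == 3:
                    quals.append(line.rstrip("\n"))
                if len(quals) >= 100:
                    break
        if not quals:  # empty file: offset irrelevant
            offset = 33
        else:
            offset, _ = detect_quality_offset(quals)
    offset = int(offset)

    with _open_text(path) as fh:
        ordinal = 0
        while True:
            header = fh.readline()
            if not header:
                break
            ordinal += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqFormatError(f"record {ordinal}: header does not start with '@'")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FastqFormatError(f"record {ordinal}: separator line missing '+'")
            if len(seq) != len(qual):
                raise FastqFormatError(f"length mismatch at record {ordinal}")
            if not seq:
                raise FastqFormatError(f"record {ordinal}: empty sequence")
            read = Read(
                id=header[1:].split()[0] if len(header) > 1 else "",
                seq=sanitize(seq),
                quals=_decode_quals(qual, offset, ordinal),
            )
            if summary is not None:
                summary.observe(read)
            yield read


def write_fastq(reads: Iterable[Read], path: str | Path, offset: int = 33) -> int:
    """Write reads as 4-line FASTQ; returns number of records written."""
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + offset) for q in read.quals)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Parse a (multi-)FASTA file; lowercase uppercased, non-ACGTN -> N."""
    records: list[ReferenceSequence] = []
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            seq = sanitize("".join(chunks))
            if not seq:
                raise ValueError(f"FASTA record {name!r} has an empty sequence")
            records.append(ReferenceSequence(id=name, seq=seq))

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            else:
                if name is None:
                    raise ValueError("FASTA file does not start with a '>' header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError("empty FASTA file")
    return records


def write_fasta(records: Iterable[ReferenceSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
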