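"""Sequence and interval primitives plus the FASTA/BED plumbing used by the scanner.

Internal coordinates are 0-based half-open throughout.  Printed genome-browser
style coordinates (1-based inclusive) only enter via :func:`interval_from_printed`.
Soft-masking is carried as a per-position boolean flag; residues themselves are
stored uppercase.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence as PySequence, TextIO, Union

import numpy as np

__all__ = [
    "Sequence",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "interval_from_printed",
    "write_predictions",
]

_VALID = set("ACGTNacgtn")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Sequence:
    """A nucleotide sequence with a per-position soft-mask flag.

    Residues are uppercase over the alphabet ``{A, C, G, T, N}``; case
    information from the source FASTA lives only in :attr:`mask`
    (``True`` = soft-masked, i.e. lowercase in the input).
    """

    id: str
    residues: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal symbols: {sorted(bad)}"
            )
        if self.mask is None:
            self.mask = np.zeros(len(self.residues), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.residues):
            raise ValueError("mask length does not match residue count")

    @classmethod
    def from_raw(cls, seq_id: str, raw: str) -> "Sequence":
        """Build from raw (possibly lowercase) residue text."""
        bad = set(raw) - _VALID
        if bad:
            raise ValueError(
                f"sequence {seq_id!r} contains illegal symbols: {sorted(bad)}"
            )
        mask = np.fromiter((c.islower() for c in raw), dtype=bool, count=len(raw))
        return cls(id=seq_id, residues=raw.upper(), mask=mask)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def to_raw(self) -> str:
        """Residues with soft-masked positions re-lowered (FASTA round-trip)."""
        chars = list(self.residues)
        for i in np.flatnonzero(self.mask):
            chars[i] = chars[i].lower()
        return "".join(chars)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def center(self) -> float:
        return (self.start + self.end) / 2.0


def interval_from_printed(
    chrom: str, start_1based: int, end_1based: int, strand: str = "+"
) -> GenomicInterval:
    """Convert printed 1-based inclusive coordinates to an internal interval.

    ``length() == end_1based - start_1based + 1`` by construction.
    """
    if start_1based < 1:
        raise ValueError("printed coordinates are 1-based; start must be >= 1")
    if start_1based > end_1based:
        raise ValueError(
            f"printed start {start_1based} exceeds end {end_1based}"
        )
    return GenomicInterval(chrom, start_1based - 1, end_1based, strand)


def _iter_fasta_records(handle: TextIO):
    header = None
    chunks: List[str] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0] if line[1:].strip() else None
            if header is None:
                raise ValueError(f"empty FASTA header at line {lineno}")
            chunks = []
        else:
            if header is None:
                raise ValueError(
                    f"FASTA line {lineno} precedes any '>' header: {line[:40]!r}"
                )
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: Union[str, Path, TextIO]) -> List[Sequence]:
    """Read a FASTA file into :class:`Sequence` records, in file order.

    Lowercase residues set the soft-mask flag and are uppercased.  Characters
    outside ``{A,C,G,T,N}`` (either case) are rejected.
    """
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            records = list(_iter_fasta_records(fh))
    else:
        records = list(_iter_fasta_records(path))
    if not records:
        raise ValueError("FASTA input contains no records")
    out = []
    for seq_id, raw in records:
        if not raw:
            raise ValueError(f"FASTA record {seq_id!r} has no residues")
        out.append(Sequence.from_raw(seq_id, raw))
    return out


def write_fasta(seqs: Iterable[Sequence], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            raw = s.to_raw()
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + "\n")


def reverse_complement(s: Sequence) -> Sequence:
    """Reverse complement with N self-complementary; mask flags reversed too."""
    return Sequence(
        id=s.id,
        residues=s.residues.translate(_COMPLEMENT)[::-1],
        mask=s.mask[::-1].copy(),
    )


def write_predictions(regions: PySequence, path: Union[str, Path]) -> None:
    """Write predicted regions as BED6 plus a full-precision sidecar TSV.

    BED name column is ``<query_id>.<rank>``; score column is the region score
    rounded to the nearest integer; strand is always ``+``.  The sidecar file
    ``<path>.tsv`` carries exact scores and the score-type label.
    """
    path = Path(path)
    with open(path, "w") as bed, open(path.with_suffix(path.suffix + ".tsv"), "w") as tsv:
        tsv.write(
            "query_id\trank\tscore_type\tseq_id\tstart\tend\tregion_score\t"
            "peak_start\tpeak_end\n"
        )
        for r in regions:
            iv = r.interval
            bed.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{r.query_id}.{r.rank}\t"
                f"{round(r.region_score)}\t+\n"
            )
            tsv.write(
                f"{r.query_id}\t{r.rank}\t{r.score_type}\t{iv.seq_id}\t"
                f"{iv.start}\t{iv.end}\t{r.region_score!r}\t"
                f"{r.peak_window.start}\t{r.peak_window.end}\n"
            )


def read_fasta_str(text: str) -> List[Sequence]:
    """Convenience wrapper used by tests: parse FASTA from a string."""
    return read_fasta(io.StringIO(text))
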