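"""Alphabet-safe sequence primitives and I/O for the standard formats the pipeline touches.

Every sequence entering the pipeline is normalized to the RNA alphabet
(uppercase, T mapped to U) so that DNA-alphabet transcriptome assemblies and
RNA-alphabet mature-miRNA inputs interoperate.  The only ambiguity code kept
is N, which is treated as unpairable in folding and never matching in scans;
all other IUPAC codes are rejected because the downstream filters are
base-exact.

Coordinates throughout the package are 0-based half-open, composing with BED
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "NucSequence",
    "RegionAnnotation",
    "FastaFormatError",
    "RegionValidationError",
    "read_fasta",
    "write_fasta",
    "read_regions",
    "write_regions",
    "gc_percent",
    "au_percent",
    "reverse_complement",
]

_ALLOWED = set("ACGUN")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA records (bad characters, empty sequences)."""


class RegionValidationError(ValueError):
    """Raised for invalid region annotations (overlap, inverted coordinates)."""


def _normalize(raw: str, record: str) -> str:
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - _ALLOWED
    if bad:
        raise FastaFormatError(
            f"record {record!r}: illegal character(s) {sorted(bad)} "
            "(expected A/C/G/T/U, or N)"
        )
    if not seq:
        raise FastaFormatError(f"record {record!r}: empty sequence")
    return seq


@dataclass(frozen=True)
class NucSequence:
    """An identified nucleotide sequence over the normalized RNA alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _normalize(self.seq, self.id))

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "NucSequence":
        return NucSequence(new_id or f"{self.id}|rc", reverse_complement(self.seq))

    def subseq(self, start: int, end: int, new_id: str | None = None) -> "NucSequence":
        if not (0 <= start < end <= len(self.seq)):
            raise ValueError(f"bad slice [{start},{end}) for {self.id!r} of length {len(self.seq)}")
        return NucSequence(new_id or f"{self.id}:{start}-{end}", self.seq[start:end])


def reverse_complement(seq: str) -> str:
    """Reverse complement on the RNA alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(s: NucSequence | str) -> float:
    """G+C content in percent; N counts in the denominator only."""
    seq = s.seq if isinstance(s, NucSequence) else s
    if not seq:
        raise ValueError("gc_percent of empty sequence is undefined")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def au_percent(s: NucSequence | str) -> float:
    """A+U content in percent; N counts in the denominator only."""
    seq = s.seq if isinstance(s, NucSequence) else s
    if not seq:
        raise ValueError("au_percent of empty sequence is undefined")
    return 100.0 * (seq.count("A") + seq.count("U")) / len(seq)


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a (multi-line, mixed-case, DNA or RNA) FASTA file.

    Returns one normalized :class:`NucSequence` per record, order preserved.
    Raises :class:`FastaFormatError` naming the offending record on illegal
    characters or empty sequences.
    """
    out: list[NucSequence] = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            out.append(NucSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA (UTF-8)."""
    with open(path, "w") as handle:
        for s in seqs:
            handle.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                handle.write(s.seq[i : i + width] + "\n")


@dataclass(frozen=True)
class RegionAnnotation:
    """A labeled half-open interval on a named reference (e.g. 18S on pre-rRNA)."""

    reference_id: str
    start: int
    end: int
    region_name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionValidationError(
                f"region {self.region_name!r}: need 0 <= start < end, got [{self.start},{self.end})"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def validate_regions(regions: Iterable[RegionAnnotation]) -> list[RegionAnnotation]:
    """Sort regions by (reference, start) and reject overlaps within a reference."""
    ordered = sorted(regions, key=lambda r: (r.reference_id, r.start))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.reference_id == prev.reference_id and cur.start < prev.end:
            raise RegionValidationError(
                f"regions {prev.region_name!r} and {cur.region_name!r} overlap "
                f"on {cur.reference_id!r}: [{prev.start},{prev.end}) vs [{cur.start},{cur.end})"
            )
    return ordered


def read_regions(path: str | Path) -> list[RegionAnnotation]:
    """Read BED-like 4-column TSV (reference, start, end, name; 0-based half-open).

    Regions are returned sorted by start; overlapping rows raise
    :class:`RegionValidationError` with the line number.
    """
    rows: list[tuple[int, RegionAnnotation]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise RegionValidationError(f"line {lineno}: expected >=4 tab-separated columns")
            ref, start, end, name = fields[0], fields[1], fields[2], fields[3]
            try:
                region = RegionAnnotation(ref, int(start), int(end), name)
            except (ValueError, RegionValidationError) as exc:
                raise RegionValidationError(f"line {lineno}: {exc}") from exc
            rows.append((lineno, region))
    rows.sort(key=lambda item: (item[1].reference_id, item[1].start))
    for (ln_a, a), (ln_b, b) in zip(rows, rows[1:]):
        if b.reference_id == a.reference_id and b.start < a.end:
            raise RegionValidationError(
                f"lines {ln_a} and {ln_b}: regions {a.region_name!r} and "
                f"{b.region_name!r} overlap on {b.reference_id!r}"
            )
    return [region for _, region in rows]


def write_regions(regions: Iterable[RegionAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in validate_regions(regions):
            handle.write(f"{r.reference_id}\t{r.start}\t{r.end}\t{r.region_name}\n")
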