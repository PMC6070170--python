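"""Deterministic homology scans replacing heuristic local alignment.

Mature queries are matched by an exhaustive full-length Hamming scan of every
transcript window (both strands by default).  For 17-25 nt queries with at
most 2 mismatches this finds a superset of what a seeded word-match search
can find, and it is exactly reproducible.  Known precursors are matched by an
ungapped seed-and-extend scan: every exact shared 28-mer is extended to the
full precursor length and kept when the identity reaches 90 %.

N never matches anything, on either side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .seqio import NucSequence, reverse_complement

__all__ = [
    "SearchConfig",
    "MatureHit",
    "scan_mature",
    "scan_precursor",
    "extract_window",
    "hits_to_tsv",
]

log = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_N = 4


@dataclass(frozen=True)
class SearchConfig:
    """Scan parameters.

    ``max_mismatches`` bounds the Hamming distance for mature scans;
    ``flank`` is the number of nucleotides cut upstream and downstream of a
    hit when extracting the candidate precursor window; ``seed_word`` and
    ``min_precursor_identity`` drive the known-precursor mode.
    """

    max_mismatches: int = 2
    min_mature_len: int = 17
    max_mature_len: int = 25
    flank: int = 150
    seed_word: int = 28
    min_precursor_identity: float = 0.90
    scan_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_mature_len > self.max_mature_len:
            raise ValueError("min_mature_len > max_mature_len")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


DEFAULT_SEARCH = SearchConfig()


@dataclass(frozen=True)
class MatureHit:
    """A query occurrence on a transcript (0-based half-open, transcript strand)."""

    query_id: str
    transcript_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_LUT = np.full(256, _N, dtype=np.uint8)
for _base, _code in _CODE.items():
    _LUT[ord(_base)] = _code


def _codes(seq: str) -> np.ndarray:
    return _LUT[_encode(seq)]


def _hamming_scan(query: np.ndarray, subject: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All (start, mismatches) with mismatches <= max_mm; N never matches."""
    L, n = len(query), len(subject)
    if n < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(subject, L)
    mm = ((windows != query) | (windows == _N) | (query == _N)).sum(axis=1)
    starts = np.flatnonzero(mm <= max_mm)
    return [(int(s), int(mm[s])) for s in starts]


def scan_mature(
    query: NucSequence, transcript: NucSequence, cfg: SearchConfig | None = None
) -> list[MatureHit]:
    """Every full-length transcript window within ``max_mismatches`` of the
    query, on both strands when enabled, in coordinate order.

    Queries outside the allowed mature length range are skipped with a logged
    warning (the mature-length rule applied at scan time).  A transcript
    shorter than the query yields an empty result.
    """
    cfg = cfg or DEFAULT_SEARCH
    if not cfg.min_mature_len <= query.length <= cfg.max_mature_len:
        log.warning(
            "query %s skipped: length %d outside [%d,%d]",
            query.id,
            query.length,
            cfg.min_mature_len,
            cfg.max_mature_len,
        )
        return []
    q = _codes(query.seq)
    t = _codes(transcript.seq)
    n, L = len(t), len(q)
    hits = [
        MatureHit(query.id, transcript.id, s, s + L, "+", mm)
        for s, mm in _hamming_scan(q, t, cfg.max_mismatches)
    ]
    if cfg.scan_reverse_complement:
        rc = _codes(reverse_complement(transcript.seq))
        for s, mm in _hamming_scan(q, rc, cfg.max_mismatches):
            # [s, s+L) on the reverse complement maps to [n-s-L, n-s) forward
            hits.append(MatureHit(query.id, transcript.id, n - s - L, n - s, "-", mm))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def extract_window(
    transcript: NucSequence, hit: MatureHit, cfg: SearchConfig | None = None
) -> tuple[NucSequence, tuple[int, int]]:
    """Cut the candidate precursor window around a hit: ``flank`` nt upstream
    and downstream, silently clipped at the transcript edges.

    Minus-strand hits are returned reverse-complemented so downstream folding
    always sees the mature sense strand.  Returns the window (its id records
    the source transcript, coordinates and strand) and the mature span
    re-expressed on the returned sequence.
    """
    cfg = cfg or DEFAULT_SEARCH
    n = transcript.length
    if not (0 <= hit.start < hit.end <= n):
        raise ValueError(f"hit [{hit.start},{hit.end}) outside transcript of length {n}")
    a = max(0, hit.start - cfg.flank)
    b = min(n, hit.end + cfg.flank)
    if a > hit.start - cfg.flank or b < hit.end + cfg.flank:
        log.debug("window for %s clipped to [%d,%d)", hit.query_id, a, b)
    raw = transcript.seq[a:b]
    wid = f"{transcript.id}:{a}-{b}({hit.strand})"
    if hit.strand == "+":
        return NucSequence(wid, raw), (hit.start - a, hit.end - a)
    window = NucSequence(wid, reverse_complement(raw))
    # on the reverse-complemented window, the mature occupies the mirror span
    return window, (b - hit.end, b - hit.start)


def scan_precursor(
    known: NucSequence, transcript: NucSequence, cfg: SearchConfig | None = None
) -> list[MatureHit]:
    """Ungapped seed-and-extend scan for a known precursor.

    Every exact shared ``seed_word``-mer anchors a full-length ungapped
    alignment; loci reaching ``min_precursor_identity`` are reported,
    deduplicated per locus (highest identity, then leftmost).  The
    ``mismatches`` field carries the number of non-identical positions.
    """
    cfg = cfg or DEFAULT_SEARCH
    w = cfg.seed_word
    if known.length < w:
        raise ValueError(f"known precursor {known.id!r} shorter than seed word ({w} nt)")

    def _scan_strand(subject: str) -> dict[int, int]:
        # offset -> mismatches, for candidate placements of the full query
        qseq = known.seq
        L = len(qseq)
        index: dict[str, list[int]] = {}
        for qpos in range(L - w + 1):
            word = qseq[qpos : qpos + w]
            if "N" in word:
                continue
            index.setdefault(word, []).append(qpos)
        offsets: set[int] = set()
        for tpos in range(len(subject) - w + 1):
            word = subject[tpos : tpos + w]
            for qpos in index.get(word, ()):  # exact shared seed
                off = tpos - qpos
                if 0 <= off <= len(subject) - L:
                    offsets.add(off)
        out: dict[int, int] = {}
        for off in offsets:
            seg = subject[off : off + L]
            mm = sum(1 for a, b in zip(seg, qseq) if a != b or a == "N" or b == "N")
            if L - mm >= cfg.min_precursor_identity * L:
                out[off] = mm
        return out

    L, n = known.length, transcript.length
    hits: list[MatureHit] = []
    for off, mm in _scan_strand(transcript.seq).items():
        hits.append(MatureHit(known.id, transcript.id, off, off + L, "+", mm))
    if cfg.scan_reverse_complement:
        for off, mm in _scan_strand(reverse_complement(transcript.seq)).items():
            hits.append(MatureHit(known.id, transcript.id, n - off - L, n - off, "-", mm))
    # deduplicate overlapping loci: highest identity (fewest mismatches), then leftmost
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    kept: list[MatureHit] = []
    for h in hits:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.strand))
    return kept


def hits_to_tsv(hits: Iterable[MatureHit], path) -> None:
    """Export hits as 6-column TSV (query, transcript, start, end, strand, mismatches)."""
    with open(path, "w") as fh:
        fh.write("query\ttranscript\tstart\tend\tstrand\tmismatches\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.transcript_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.mismatches}\n"
            )
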