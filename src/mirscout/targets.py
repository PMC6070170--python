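"""Position-weighted complementarity scoring of candidate target sites.

The scorer follows the standard plant-miRNA penalty scheme: a candidate site
on the mRNA sense strand is aligned (ungapped) against the reverse complement
of the miRNA, and penalties accumulate per position counted from the miRNA 5'
end — 1.0 per mismatch, 0.5 per G:U wobble, doubled inside the functionally
critical positions 2-13.  The resulting "expectation" is 0 for a perfect
complement and grows with divergence; sites at or below a cutoff (default
5.0) are reported.  A mismatch at any of positions 9-11 (the cleavage site)
marks the interaction as translational rather than cleavage-guided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .seqio import NucSequence

__all__ = ["TargetHit", "score_site", "scan_targets", "targets_to_tsv"]

_WOBBLE = {("G", "U"), ("U", "G")}
_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

#: positions (1-based from the miRNA 5' end) with doubled penalties
CORE_START, CORE_END = 2, 13
#: positions whose mismatch switches the predicted mode to translational
CLEAVAGE_SITE = (9, 10, 11)

DEFAULT_CUTOFF = 5.0


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int
    end: int
    expectation: float
    mode: Literal["cleavage", "translational"]


def score_site(mirna: NucSequence, site: NucSequence) -> tuple[float, str]:
    """Score one site (mRNA sense strand) against a miRNA.

    Returns (expectation, mode).  Raises ``ValueError`` on length mismatch;
    gapped (bulged) sites are out of scope for this scorer.
    """
    if mirna.length != site.length:
        raise ValueError(
            f"site length {site.length} != miRNA length {mirna.length} (ungapped scorer)"
        )
    L = mirna.length
    total = 0.0
    mode = "cleavage"
    for p in range(1, L + 1):  # position from the miRNA 5' end
        m = mirna.seq[p - 1]
        s = site.seq[L - p]  # miRNA 5' end pairs the site 3' end
        if (m, s) in _PAIR:
            continue
        penalty = 0.5 if (m, s) in _WOBBLE else 1.0
        if CORE_START <= p <= CORE_END:
            penalty *= 2.0
        total += penalty
        if (m, s) not in _WOBBLE and p in CLEAVAGE_SITE:
            mode = "translational"
    return total, mode


def scan_targets(
    mirna: NucSequence,
    transcripts: Iterable[NucSequence],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetHit]:
    """All sites with expectation <= cutoff across the transcripts.

    Overlapping windows on one transcript are deduplicated to the best
    (lowest-expectation, then leftmost) site; output is sorted by
    (expectation, transcript, start).
    """
    L = mirna.length
    hits: list[TargetHit] = []
    for tr in transcripts:
        raw: list[TargetHit] = []
        for start in range(tr.length - L + 1):
            site = NucSequence(f"{tr.id}:{start}", tr.seq[start : start + L])
            e, mode = score_site(mirna, site)
            if e <= cutoff:
                raw.append(TargetHit(mirna.id, tr.id, start, start + L, e, mode))
        raw.sort(key=lambda h: (h.expectation, h.start))
        kept: list[TargetHit] = []
        for h in raw:
            if all(h.end <= k.start or h.start >= k.end for k in kept):
                kept.append(h)
        hits.extend(kept)
    hits.sort(key=lambda h: (h.expectation, h.transcript_id, h.start))
    return hits


def targets_to_tsv(hits: Iterable[TargetHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\ttranscript\tstart\tend\texpectation\tmode\n")
        for h in hits:
            fh.write(
                f"{h.mirna_id}\t{h.transcript_id}\t{h.start}\t{h.end}\t{h.expectation:g}\t{h.mode}\n"
            )
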