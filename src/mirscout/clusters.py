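"""Detection of miRNA clusters and assignment to annotated reference regions.

A cluster is two or more accepted precursors co-located on one transcript
unit.  The defining example in this package is a polycistronic ribosomal RNA
precursor (ETS-18S-ITS1-5.8S-ITS2-28S) carrying several miRNA hairpins, so
the default gap limit is unlimited: everything on one reference forms one
cluster.  A finite ``max_gap`` makes the grouping genomic-style.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

from .seqio import RegionAnnotation, validate_regions

__all__ = [
    "PrecursorLocus",
    "RegionAssignment",
    "ClusterCall",
    "detect_clusters",
    "assign_region",
    "clusters_to_tsv",
    "clusters_to_json",
]


@dataclass(frozen=True)
class PrecursorLocus:
    """An accepted precursor placed on a reference (0-based half-open)."""

    id: str
    reference_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad locus span [{self.start},{self.end}) for {self.id!r}")


@dataclass(frozen=True)
class RegionAssignment:
    region_name: str  # "unannotated" when outside every region
    straddles_boundary: bool = False


@dataclass(frozen=True)
class ClusterCall:
    """Two or more precursors on one reference, sorted by start."""

    reference_id: str
    members: tuple[PrecursorLocus, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")
        if any(m.reference_id != self.reference_id for m in self.members):
            raise ValueError("cluster members must share one reference")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].start, self.members[-1].end)


def detect_clusters(
    loci: Iterable[PrecursorLocus], max_gap: int | None = None
) -> list[ClusterCall]:
    """Group precursors per reference; successive spans at most ``max_gap``
    apart chain into one cluster (``None`` = unlimited, one cluster per
    reference).  Singletons are not clusters.  Input order is irrelevant."""
    ordered = sorted(loci, key=lambda p: (p.reference_id, p.start, p.end, p.id))
    calls: list[ClusterCall] = []
    for ref, group_iter in groupby(ordered, key=lambda p: p.reference_id):
        group = list(group_iter)
        chain: list[PrecursorLocus] = []
        for locus in group:
            if chain and max_gap is not None and locus.start - chain[-1].end > max_gap:
                if len(chain) >= 2:
                    calls.append(ClusterCall(ref, tuple(chain)))
                chain = []
            chain.append(locus)
        if len(chain) >= 2:
            calls.append(ClusterCall(ref, tuple(chain)))
    return calls


def assign_region(
    span: tuple[int, int], regions: Sequence[RegionAnnotation]
) -> RegionAssignment:
    """Label a span by the region containing its midpoint.

    A span straddling a region boundary keeps the midpoint label but is
    flagged; a midpoint outside every region is "unannotated".
    """
    regions = validate_regions(regions)
    start, end = span
    mid = (start + end) // 2
    name = "unannotated"
    for r in regions:
        if r.start <= mid < r.end:
            name = r.region_name
            break
    contained = any(r.start <= start and end <= r.end for r in regions)
    overlaps = sum(1 for r in regions if start < r.end and r.start < end)
    straddles = (not contained) and overlaps >= 1
    return RegionAssignment(name, straddles)


def clusters_to_tsv(
    clusters: Iterable[ClusterCall],
    regions: Sequence[RegionAnnotation] | None,
    path,
) -> None:
    """Export clusters as a GFF3-like TSV (reference, start, end, member, region)."""
    with open(path, "w") as fh:
        fh.write("reference\tstart\tend\tmember\tregion\n")
        for c in clusters:
            for m in c.members:
                region = (
                    assign_region((m.start, m.end), regions).region_name
                    if regions
                    else "unannotated"
                )
                fh.write(f"{c.reference_id}\t{m.start}\t{m.end}\t{m.id}\t{region}\n")


def clusters_to_json(
    clusters: Iterable[ClusterCall], regions: Sequence[RegionAnnotation] | None
) -> str:
    payload = []
    for c in clusters:
        members = []
        for m in c.members:
            assignment = (
                assign_region((m.start, m.end), regions)
                if regions
                else RegionAssignment("unannotated")
            )
            members.append(
                {
                    "id": m.id,
                    "start": m.start,
                    "end": m.end,
                    "region": assignment.region_name,
                    "straddles_boundary": assignment.straddles_boundary,
                }
            )
        payload.append(
            {"reference": c.reference_id, "size": c.size, "members": members}
        )
    return json.dumps(payload)
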