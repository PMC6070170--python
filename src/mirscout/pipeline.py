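"""End-to-end orchestration: scan -> window -> fold/trim -> filter -> clusters.

:func:`discover` is the in-memory pipeline over already-loaded sequences;
:func:`run_pipeline` wraps it with file I/O, stage logging, Table-style TSV
reporting and a JSON run summary.

Candidates are deduplicated per locus: overlapping extraction windows on one
transcript (e.g. the same hairpin found through the mature on the plus strand
and through the star on the minus strand, or through two homologous queries)
collapse to a single call — accepted over rejected, then best (most negative)
MFEI, then leftmost.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import yaml

from . import __version__
from .clusters import (
    ClusterCall,
    PrecursorLocus,
    assign_region,
    clusters_to_json,
    clusters_to_tsv,
    detect_clusters,
)
from .filtering import (
    FilterCriteria,
    WindowAssessment,
    assess_window,
    round2,
)
from .folding import FoldModel, HairpinStructure
from .homology import MatureHit, SearchConfig, extract_window, scan_mature
from .seqio import (
    NucSequence,
    RegionAnnotation,
    au_percent,
    gc_percent,
    read_fasta,
    read_regions,
)
from .targets import scan_targets, targets_to_tsv

__all__ = [
    "PipelineConfig",
    "CandidateCall",
    "DiscoveryResult",
    "discover",
    "run_pipeline",
    "command_line_folder",
]

log = logging.getLogger(__name__)


def command_line_folder(command: str) -> Callable[[NucSequence], HairpinStructure]:
    """Adapt an external folding engine via a simple text contract.

    The command receives the sequence on stdin and must print a dot-bracket
    string followed by whitespace and the energy (kcal/mol) — optionally in
    parentheses — on the last non-empty output line.
    """

    def _fold(s: NucSequence) -> HairpinStructure:
        proc = subprocess.run(
            shlex.split(command),
            input=s.seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
        if not lines:
            raise RuntimeError(f"external folder produced no output for {s.id}")
        fields = lines[-1].split()
        db = fields[0]
        energy = float(fields[-1].strip("()"))
        return HairpinStructure.from_dotbracket(s, db, energy)

    return _fold


@dataclass(frozen=True)
class CandidateCall:
    """One deduplicated candidate locus with its full assessment."""

    candidate_id: str
    query_id: str
    transcript_id: str
    window_span: tuple[int, int]  # on the transcript, forward coordinates
    strand: str
    hit_mismatches: int
    assessment: WindowAssessment

    @property
    def accepted(self) -> bool:
        return self.assessment.report.accepted

    @property
    def locus_span(self) -> tuple[int, int]:
        """Trimmed precursor span in forward transcript coordinates."""
        a, b = self.assessment.precursor_span
        w0, w1 = self.window_span
        if self.strand == "+":
            return (w0 + a, w0 + b)
        return (w1 - b, w1 - a)


@dataclass
class DiscoveryResult:
    candidates: list[CandidateCall]
    clusters: list[ClusterCall]
    regions: list[RegionAnnotation]
    counts: dict[str, int]

    @property
    def accepted(self) -> list[CandidateCall]:
        return [c for c in self.candidates if c.accepted]

    @property
    def rejected(self) -> list[CandidateCall]:
        return [c for c in self.candidates if not c.accepted]

    def region_of(self, call: CandidateCall) -> str:
        if not self.regions:
            return "unannotated"
        return assign_region(call.locus_span, self.regions).region_name


def _dedup(calls: list[CandidateCall]) -> list[CandidateCall]:
    """Collapse transitively-overlapping windows per transcript to one call."""

    def mfei_key(c: CandidateCall) -> float:
        m = c.assessment.report.stats.get("MFEI")
        return float(m) if m is not None else float("inf")

    out: list[CandidateCall] = []
    by_tx: dict[str, list[CandidateCall]] = {}
    for c in calls:
        by_tx.setdefault(c.transcript_id, []).append(c)
    for tx_calls in by_tx.values():
        tx_calls.sort(key=lambda c: c.window_span)
        group: list[CandidateCall] = []
        group_end = -1
        for c in tx_calls + [None]:  # type: ignore[list-item]
            if c is not None and (not group or c.window_span[0] < group_end):
                group.append(c)
                group_end = max(group_end, c.window_span[1])
                continue
            if group:
                best = sorted(
                    group,
                    key=lambda g: (not g.accepted, mfei_key(g), g.window_span[0]),
                )[0]
                out.append(best)
            if c is not None:
                group, group_end = [c], c.window_span[1]
    out.sort(key=lambda c: (c.transcript_id, c.window_span))
    return out


def discover(
    matures: Sequence[NucSequence],
    transcripts: Sequence[NucSequence],
    search: SearchConfig | None = None,
    criteria: FilterCriteria | None = None,
    model: FoldModel | None = None,
    regions: Sequence[RegionAnnotation] | None = None,
    max_gap: int | None = None,
    fold_fn: Callable[[NucSequence], HairpinStructure] | None = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline in memory.

    Stage counts are monotone non-increasing (hits >= windows >= deduplicated
    candidates >= accepted) and every deduplicated candidate is accounted for
    as accepted or rejected-with-reasons.
    """
    search = search or SearchConfig()
    tx_by_id = {t.id: t for t in transcripts}

    hits: list[MatureHit] = []
    for q in matures:
        for t in transcripts:
            hits.extend(scan_mature(q, t, search))
    log.info("scan: %d hits from %d queries x %d transcripts", len(hits), len(matures), len(transcripts))

    mature_by_id = {m.id: m for m in matures}
    raw_calls: list[CandidateCall] = []
    for k, hit in enumerate(hits):
        transcript = tx_by_id[hit.transcript_id]
        window, m_span = extract_window(transcript, hit, search)
        assessment = assess_window(
            window,
            mature_by_id[hit.query_id],
            criteria,
            model,
            scan_mismatches=search.max_mismatches,
            fold_fn=fold_fn,
        )
        a = max(0, hit.start - search.flank)
        b = min(transcript.length, hit.end + search.flank)
        raw_calls.append(
            CandidateCall(
                candidate_id=f"cand_{k}",
                query_id=hit.query_id,
                transcript_id=hit.transcript_id,
                window_span=(a, b),
                strand=hit.strand,
                hit_mismatches=hit.mismatches,
                assessment=assessment,
            )
        )
    candidates = _dedup(raw_calls)
    accepted = [c for c in candidates if c.accepted]
    log.info(
        "filter: %d windows -> %d candidate loci -> %d accepted",
        len(raw_calls),
        len(candidates),
        len(accepted),
    )

    loci = [
        PrecursorLocus(c.candidate_id, c.transcript_id, *c.locus_span)
        for c in accepted
    ]
    clusters = detect_clusters(loci, max_gap=max_gap)
    counts = {
        "queries": len(matures),
        "transcripts": len(transcripts),
        "hits": len(hits),
        "windows": len(raw_calls),
        "candidates": len(candidates),
        "accepted": len(accepted),
        "rejected": len(candidates) - len(accepted),
        "clusters": len(clusters),
    }
    return DiscoveryResult(
        candidates=candidates,
        clusters=clusters,
        regions=list(regions or []),
        counts=counts,
    )


@dataclass
class PipelineConfig:
    """File-level pipeline configuration (YAML-loadable)."""

    matures: str
    transcriptome: str
    outdir: str
    regions: str | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    external_folder: str | None = None
    max_gap: int | None = None
    run_targets: bool = False
    target_cutoff: float = 5.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "search" in raw:
            raw["search"] = SearchConfig(**raw["search"])
        if "criteria" in raw:
            raw["criteria"] = FilterCriteria(**raw["criteria"])
        return cls(**raw)


_TABLE_COLUMNS = (
    "candidate",
    "query",
    "transcript",
    "start",
    "end",
    "strand",
    "mature_seq",
    "au_pct",
    "gc_pct",
    "lp",
    "mfe",
    "mfei",
    "arm",
    "accepted",
    "failed_criteria",
)


def _candidate_rows(result: DiscoveryResult, matures: Sequence[NucSequence]) -> list[dict]:
    mature_by_id = {m.id: m for m in matures}
    rows = []
    for c in result.candidates:
        stats = c.assessment.report.stats
        prec = c.assessment.precursor
        mfei = stats["MFEI"]
        rows.append(
            {
                "candidate": c.candidate_id,
                "query": c.query_id,
                "transcript": c.transcript_id,
                "start": c.locus_span[0],
                "end": c.locus_span[1],
                "strand": c.strand,
                "mature_seq": mature_by_id[c.query_id].seq,
                "au_pct": round(au_percent(prec), 2),
                "gc_pct": round(gc_percent(prec), 2),
                "lp": stats["LP"],
                "mfe": stats["MFE"],
                "mfei": None if mfei is None else round2(mfei),
                "arm": stats["arm"],
                "accepted": c.accepted,
                "failed_criteria": ";".join(c.assessment.report.failed),
            }
        )
    return rows


def _write_tsv(rows: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join("" if row[c] is None else str(row[c]) for c in _TABLE_COLUMNS) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline and write reports.

    Outputs under ``cfg.outdir``: candidates.tsv (accepted calls in a
    Table-style schema), rejected.tsv (with per-criterion reasons),
    clusters.tsv/.json, optional targets.tsv, and summary.json (stage counts,
    config echo, seed, version).  Zero passing candidates is still a success.
    """
    for label, path in (("matures", cfg.matures), ("transcriptome", cfg.transcriptome)):
        if not Path(path).is_file():
            raise FileNotFoundError(f"{label} file not found: {path}")
    if cfg.regions and not Path(cfg.regions).is_file():
        raise FileNotFoundError(f"regions file not found: {cfg.regions}")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matures = read_fasta(cfg.matures)
    transcripts = read_fasta(cfg.transcriptome)
    regions = read_regions(cfg.regions) if cfg.regions else []
    fold_fn = command_line_folder(cfg.external_folder) if cfg.external_folder else None

    result = discover(
        matures,
        transcripts,
        search=cfg.search,
        criteria=cfg.criteria,
        regions=regions,
        max_gap=cfg.max_gap,
        fold_fn=fold_fn,
    )

    rows = _candidate_rows(result, matures)
    _write_tsv([r for r in rows if r["accepted"]], outdir / "candidates.tsv")
    _write_tsv([r for r in rows if not r["accepted"]], outdir / "rejected.tsv")
    clusters_to_tsv(result.clusters, regions or None, outdir / "clusters.tsv")
    (outdir / "clusters.json").write_text(clusters_to_json(result.clusters, regions or None))

    if cfg.run_targets:
        hits = []
        accepted_queries = sorted({c.query_id for c in result.accepted})
        mature_by_id = {m.id: m for m in matures}
        for qid in accepted_queries:
            hits.extend(scan_targets(mature_by_id[qid], transcripts, cfg.target_cutoff))
        targets_to_tsv(hits, outdir / "targets.tsv")

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "counts": result.counts,
        "config": {
            "matures": str(cfg.matures),
            "transcriptome": str(cfg.transcriptome),
            "regions": str(cfg.regions) if cfg.regions else None,
            "search": asdict(cfg.search),
            "criteria": asdict(cfg.criteria),
            "max_gap": cfg.max_gap,
            "external_folder": cfg.external_folder,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline summary: %s", result.counts)
    return summary
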