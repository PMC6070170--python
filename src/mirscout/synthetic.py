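"""Ground-truthed synthetic inputs for every pipeline stage.

The generators build transcript collections with planted precursor hairpins,
decoys that violate one named filter criterion each, and a long polycistronic
ribosomal-RNA-like reference carrying a cluster of planted precursors — so
the whole analysis is testable without any download.

Construction notes
------------------
A planted precursor is ``[mature][loop][star]`` (mirrored for 3p), where the
star is the reverse complement of the mature with a chosen number of
mismatch mutations; each mutation sets the star base equal to the mature
base it opposes, which is unpairable in both orientations (no accidental
GU wobble on either strand).  Flanks and embedding pads are runs of N:
under the bundled additive per-pair energy model N is unpairable, so pads
are energetically inert and the planted hairpin is exactly recoverable.
Real-base flanks would tie with stem pairs of the same type and could steal
them in the traceback — the pads deliberately sidestep that degeneracy.

Every generator is a pure function of (spec, seed): one named pseudo-random
stream per generator call, no global state.  Generation ends with a
self-check through the real filter: a clean precursor must be accepted, a
decoy must fail its designated criterion.  When the bundled fold model
produces an unintended alternative structure for a random draw, the mature
is redrawn from the same seeded stream (bounded), keeping generation
deterministic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .filtering import (
    DEFAULT_CRITERIA,
    FilterCriteria,
    assess_window,
    evaluate,
)
from .folding import FoldModel, fold
from .homology import SearchConfig, extract_window, scan_mature
from .seqio import NucSequence, RegionAnnotation, reverse_complement, write_fasta, write_regions

__all__ = [
    "GenerationError",
    "TruthRecord",
    "PlantedSpec",
    "SyntheticTranscriptome",
    "PreRrnaScenario",
    "make_precursor",
    "make_transcriptome",
    "make_pre_rrna",
    "default_planted_specs",
    "DEFAULT_DECOYS",
    "DEFAULT_RRNA_REGIONS",
    "DEFAULT_RRNA_ASSIGNMENTS",
]

#: pads around planted precursors exceed the default extraction flank, so
#: every extraction window stays inside inert sequence
EMBED_PAD = 160

_BASES = np.array(list("ACGU"))


class GenerationError(RuntimeError):
    """A requested synthetic construct cannot be realized."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _random_bases(rng: np.random.Generator, n: int, p: Sequence[float] | None = None) -> str:
    return "".join(rng.choice(_BASES, size=n, p=p))


@dataclass(frozen=True)
class TruthRecord:
    """What was planted where, and which criterion (if any) it violates."""

    planted_id: str
    transcript_id: str | None
    mature_span: tuple[int, int]
    arm: str
    violated_criterion: str = "none"  # "none" or a criterion label
    precursor_span: tuple[int, int] | None = None
    region: str | None = None
    mature_seq: str = ""


# ---------------------------------------------------------------------------
# single planted precursor
# ---------------------------------------------------------------------------

_LOOP_CYCLE = "CAA"  # A/C loops cannot pair with each other or with the N flanks


def _mismatch_base(opposite: str) -> str:
    # the least reactive base that cannot pair the opposite one: A pairs only
    # U (and weakly), so use A unless the opposite IS U, then C (C:U nonpair)
    return "C" if opposite == "U" else "A"


def _build_hairpin(
    mature: str, star_mut_positions: Sequence[int], loop_len: int, arm: str
) -> tuple[str, int]:
    """Return (core sequence, mature offset within core)."""
    L = len(mature)
    star = list(reverse_complement(mature))
    for k in star_mut_positions:
        star[k] = _mismatch_base(mature[L - 1 - k])
    star_s = "".join(star)
    loop = (_LOOP_CYCLE * (loop_len // len(_LOOP_CYCLE) + 1))[:loop_len]
    if arm == "5p":
        return mature + loop + star_s, 0
    return star_s + loop + mature, L + loop_len


def make_precursor(
    mature: NucSequence,
    star_mutations: int = 0,
    loop_len: int = 6,
    arm: str = "5p",
    seed: int = 0,
    planted_id: str | None = None,
    criteria: FilterCriteria | None = None,
    model: FoldModel | None = None,
) -> tuple[NucSequence, TruthRecord]:
    """Build a criterion-clean precursor around a mature sequence.

    The hairpin is ``[mature][loop][star]`` for the 5p arm (mirrored for 3p),
    with ``star_mutations`` mismatches placed pseudo-randomly in the star,
    never within 2 nt of either stem end, then N-extended to the minimum
    precursor length.  Generation re-folds the result with the bundled model
    and asserts the truth record (accepted under default criteria, correct
    arm); an unrealizable request raises :class:`GenerationError`.
    """
    c = criteria or DEFAULT_CRITERIA
    L = mature.length
    if not c.min_mature_len <= L <= c.max_mature_len:
        raise GenerationError(
            f"mature length {L} outside [{c.min_mature_len},{c.max_mature_len}]"
        )
    if loop_len < 3:
        raise GenerationError("loop_len must be >= 3")
    if star_mutations >= c.max_duplex_mismatches + 1:
        raise GenerationError(
            f"{star_mutations} star mutations exceed the duplex mismatch bound"
        )
    if L - star_mutations < c.min_duplex_pairs:
        raise GenerationError(
            f"{star_mutations} mutations drop the duplex below "
            f"{c.min_duplex_pairs} pairs"
        )
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    rng = _rng(seed, f"precursor:{mature.seq}:{star_mutations}:{loop_len}:{arm}")
    # interior star positions only (never within 2 nt of either stem end),
    # preferring sites opposite weak (A/U) mature bases: the lost pair is
    # cheap and the freed mature base is the least reactive
    interior = list(range(2, L - 2))
    weak = [k for k in interior if mature.seq[L - 1 - k] in "AU"]
    strong = [k for k in interior if k not in weak]
    rng.shuffle(weak)
    rng.shuffle(strong)
    positions = sorted((weak + strong)[:star_mutations])
    core, m_off = _build_hairpin(mature.seq, positions, loop_len, arm)
    target_len = max(c.min_precursor_len, len(core) + 8)
    pad = target_len - len(core)
    left, right = pad // 2, pad - pad // 2
    seq = "N" * left + core + "N" * right
    pid = planted_id or f"planted_{arm}_{mature.id}"
    precursor = NucSequence(pid, seq)
    m_span = (left + m_off, left + m_off + L)

    h = fold(precursor, model)
    report = evaluate(precursor, mature, h, c, mature_span=m_span)
    if not report.accepted:
        raise GenerationError(
            f"self-check failed for {pid}: criteria {report.failed} "
            f"(stats {report.stats})"
        )
    if report.stats["arm"] != arm:
        raise GenerationError(
            f"self-check failed for {pid}: arm {report.stats['arm']} != {arm}"
        )
    truth = TruthRecord(
        planted_id=pid,
        transcript_id=None,
        mature_span=m_span,
        arm=arm,
        violated_criterion="none",
        precursor_span=(0, len(seq)),
        mature_seq=mature.seq,
    )
    return precursor, truth


# ---------------------------------------------------------------------------
# transcript collections with planted precursors and decoys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSpec:
    """Recipe for one criterion-clean planted precursor."""

    mature_len: int = 21
    star_mutations: int = 0
    arm: str = "5p"
    loop_len: int = 6


def default_planted_specs(n: int) -> list[PlantedSpec]:
    """n recipes cycling over arms and 0-3 star mismatches."""
    return [
        PlantedSpec(
            mature_len=21 + (i % 2),
            star_mutations=i % 4,
            arm="5p" if i % 2 == 0 else "3p",
        )
        for i in range(n)
    ]


#: one decoy per individually violated criterion
DEFAULT_DECOYS = (
    "gc_content",
    "mfe",
    "single_hairpin",
    "duplex_mismatches",
    "precursor_length",
)


@dataclass
class SyntheticTranscriptome:
    """Transcript collection + the mature queries + the truth table."""

    transcripts: list[NucSequence]
    matures: list[NucSequence]
    truth: list[TruthRecord]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        write_fasta(self.matures, outdir / "matures.fasta")
        write_truth(self.truth, outdir / "truth.tsv")


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "planted_id\ttranscript_id\tmature_start\tmature_end\tarm\t"
            "violated_criterion\tregion\tmature_seq\n"
        )
        for t in truth:
            fh.write(
                f"{t.planted_id}\t{t.transcript_id or ''}\t{t.mature_span[0]}\t"
                f"{t.mature_span[1]}\t{t.arm}\t{t.violated_criterion}\t"
                f"{t.region or ''}\t{t.mature_seq}\n"
            )


def _draw_mature(rng: np.random.Generator, length: int) -> NucSequence:
    """A GC-balanced random mature (GC fraction kept in [0.4, 0.65])."""
    for _ in range(100):
        seq = _random_bases(rng, length)
        gc = (seq.count("G") + seq.count("C")) / length
        if 0.4 <= gc <= 0.65:
            return NucSequence("draw", seq)
    raise GenerationError("could not draw a GC-balanced mature")  # pragma: no cover


def _embed(precursor: NucSequence, tid: str) -> tuple[NucSequence, int]:
    seq = "N" * EMBED_PAD + precursor.seq + "N" * EMBED_PAD
    return NucSequence(tid, seq), EMBED_PAD


def _make_clean_planted(
    idx: int, spec: PlantedSpec, seed: int, criteria: FilterCriteria, model: FoldModel | None
) -> tuple[NucSequence, NucSequence, TruthRecord]:
    rng = _rng(seed, f"planted_mature:{idx}")
    last_err: GenerationError | None = None
    for attempt in range(50):
        mature = NucSequence(f"mat_{idx}", _draw_mature(rng, spec.mature_len).seq)
        try:
            precursor, truth = make_precursor(
                mature,
                star_mutations=spec.star_mutations,
                loop_len=spec.loop_len,
                arm=spec.arm,
                seed=seed + attempt,
                planted_id=f"planted_{idx}",
                criteria=criteria,
                model=model,
            )
        except GenerationError as exc:
            last_err = exc
            continue
        tid = f"planted_tx_{idx}"
        transcript, off = _embed(precursor, tid)
        truth = replace(
            truth,
            transcript_id=tid,
            mature_span=(truth.mature_span[0] + off, truth.mature_span[1] + off),
            precursor_span=(off, off + precursor.length),
        )
        return transcript, mature, truth
    raise GenerationError(f"planted precursor {idx} unrealizable: {last_err}")


def _decoy_self_check(
    transcript: NucSequence,
    mature: NucSequence,
    designated: str,
    criteria: FilterCriteria,
    model: FoldModel | None,
) -> bool:
    """Run the per-candidate pipeline core; the designated criterion must fail."""
    cfg = SearchConfig()
    hits = scan_mature(mature, transcript, cfg)
    plus = [h for h in hits if h.strand == "+"]
    if not plus:
        return False
    window, m_span = extract_window(transcript, plus[0], cfg)
    assessment = assess_window(window, mature, criteria, model)
    return designated in assessment.report.failed


def _build_decoy(
    idx: int,
    designated: str,
    seed: int,
    criteria: FilterCriteria,
    model: FoldModel | None,
) -> tuple[NucSequence, NucSequence, TruthRecord]:
    rng = _rng(seed, f"decoy:{idx}:{designated}")
    tid = f"decoy_tx_{idx}"
    last = "no attempt"
    for attempt in range(50):
        if designated == "gc_content":
            # AU-extreme hairpin: GC far below the 24% floor, everything else clean
            L = 21
            au = "".join(rng.choice(np.array(list("AU")), size=L))
            pos = sorted(rng.choice(np.arange(2, L - 2), size=3, replace=False))
            chars = list(au)
            for p, b in zip(pos, "GCG"):
                chars[p] = b
            mature = NucSequence(f"decoy_mat_{idx}", "".join(chars))
            core, _ = _build_hairpin(mature.seq, [], 6, "5p")
            precursor = NucSequence(f"decoy_{idx}", "N" * 6 + core + "N" * 6)
            transcript, off = _embed(precursor, tid)
            m_span = (off + 6, off + 6 + L)
        elif designated == "mfe":
            # no legal base pair anywhere near the mature: folding energy ~0
            mature = NucSequence(
                f"decoy_mat_{idx}", "".join(rng.choice(np.array(list("AC")), size=21))
            )
            transcript, off = _embed(NucSequence(f"decoy_{idx}", mature.seq), tid)
            m_span = (off, off + 21)
        elif designated == "single_hairpin":
            # a GC clamp enclosing TWO stem-loops: not a single hairpin
            mature = _draw_mature(rng, 21)
            mature = NucSequence(f"decoy_mat_{idx}", mature.seq)
            hp_a, _ = _build_hairpin(mature.seq, [], 4, "5p")
            b_stem = _draw_mature(rng, 12).seq
            hp_b, _ = _build_hairpin(b_stem, [], 4, "5p")
            core = "G" * 6 + hp_a + "NN" + hp_b + "C" * 6
            precursor = NucSequence(f"decoy_{idx}", "N" * 4 + core + "N" * 4)
            transcript, off = _embed(precursor, tid)
            m_span = (off + 10, off + 10 + 21)
        elif designated == "duplex_mismatches":
            # star with 8 mismatch mutations: duplex pairs fine, mismatches not
            mature = NucSequence(f"decoy_mat_{idx}", _draw_mature(rng, 25).seq)
            pos = sorted(rng.choice(np.arange(2, 23), size=8, replace=False))
            core, _ = _build_hairpin(mature.seq, pos, 6, "5p")
            precursor = NucSequence(f"decoy_{idx}", "N" * 4 + core + "N" * 4)
            transcript, off = _embed(precursor, tid)
            m_span = (off + 4, off + 4 + 25)
        elif designated == "precursor_length":
            # transcript shorter than the minimum precursor: window clips to <60 nt
            mature = NucSequence(f"decoy_mat_{idx}", _draw_mature(rng, 21).seq)
            transcript = NucSequence(tid, "N" * 10 + mature.seq + "N" * 9)
            m_span = (10, 31)
        else:
            raise ValueError(f"no decoy construction for criterion {designated!r}")
        if _decoy_self_check(transcript, mature, designated, criteria, model):
            truth = TruthRecord(
                planted_id=f"decoy_{idx}",
                transcript_id=tid,
                mature_span=m_span,
                arm="ambiguous",
                violated_criterion=designated,
                mature_seq=mature.seq,
            )
            return transcript, mature, truth
        last = f"attempt {attempt}: designated criterion did not fail"
    raise GenerationError(f"decoy for {designated!r} unrealizable ({last})")


def make_transcriptome(
    n_background: int,
    planted: int | Sequence[PlantedSpec],
    decoy_specs: Sequence[str] | None = None,
    seed: int = 0,
    background_len: tuple[int, int] = (300, 2000),
    background_gc: float | None = None,
    criteria: FilterCriteria | None = None,
    model: FoldModel | None = None,
) -> SyntheticTranscriptome:
    """Background transcripts + planted criterion-clean precursors + decoys.

    ``planted`` is a count (default recipes) or explicit
    :class:`PlantedSpec` list; ``decoy_specs`` names the criterion each decoy
    must violate.  Background transcripts draw uniform bases (or GC-skewed
    when ``background_gc`` is set) with lengths in ``background_len``.
    Byte-identical output for identical arguments and seed.
    """
    c = criteria or DEFAULT_CRITERIA
    specs = default_planted_specs(planted) if isinstance(planted, int) else list(planted)
    decoys = list(DEFAULT_DECOYS if decoy_specs is None else decoy_specs)

    rng_bg = _rng(seed, "background")
    p = None
    if background_gc is not None:
        g = background_gc / 2
        a = (1 - background_gc) / 2
        p = [a, g, g, a]
    transcripts: list[NucSequence] = []
    for i in range(n_background):
        n = int(rng_bg.integers(background_len[0], background_len[1] + 1))
        transcripts.append(NucSequence(f"background_{i}", _random_bases(rng_bg, n, p)))

    matures: list[NucSequence] = []
    truth: list[TruthRecord] = []
    for i, spec in enumerate(specs):
        tr, mat, t = _make_clean_planted(i, spec, seed, c, model)
        transcripts.append(tr)
        matures.append(mat)
        truth.append(t)
    for i, designated in enumerate(decoys):
        tr, mat, t = _build_decoy(i, designated, seed, c, model)
        transcripts.append(tr)
        matures.append(mat)
        truth.append(t)
    return SyntheticTranscriptome(transcripts=transcripts, matures=matures, truth=truth)


# ---------------------------------------------------------------------------
# polycistronic pre-rRNA-like reference with a planted cluster
# ---------------------------------------------------------------------------

_RRNA_ID = "pre_rRNA_synthetic"

#: ETS-18S-ITS1-5.8S-ITS2-28S layout with field-realistic span sizes (nt)
DEFAULT_RRNA_REGIONS = (
    RegionAnnotation(_RRNA_ID, 0, 700, "ETS"),
    RegionAnnotation(_RRNA_ID, 700, 2500, "18S"),
    RegionAnnotation(_RRNA_ID, 2500, 2800, "ITS1"),
    RegionAnnotation(_RRNA_ID, 2800, 2960, "5.8S"),
    RegionAnnotation(_RRNA_ID, 2960, 3260, "ITS2"),
    RegionAnnotation(_RRNA_ID, 3260, 6700, "28S"),
)

#: the default scenario: three precursors in the small-subunit region, two in
#: the large-subunit region — a five-member polycistronic cluster
DEFAULT_RRNA_ASSIGNMENTS = {
    "miR2914": "18S",
    "miR2916": "18S",
    "miR2910": "18S",
    "miR1310": "28S",
    "miR2911": "28S",
}


@dataclass
class PreRrnaScenario:
    """A synthetic polycistron: reference + regions + queries + truth."""

    reference: NucSequence
    regions: list[RegionAnnotation]
    matures: list[NucSequence]
    truth: list[TruthRecord]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.reference], outdir / "reference.fasta")
        write_regions(self.regions, outdir / "regions.bed")
        write_fasta(self.matures, outdir / "matures.fasta")
        write_truth(self.truth, outdir / "truth.tsv")


def _catalog_matures(names: Iterable[str]) -> dict[str, str]:
    from .filtering import load_catalog

    df = load_catalog()
    out = {}
    for name in names:
        rows = df[df["name"].str.contains(name, regex=False)]
        if len(rows):
            out[name] = rows.iloc[0]["mature_seq"]
    return out


def make_pre_rrna(
    regions: Sequence[RegionAnnotation] | None = None,
    assignments: dict[str, str] | None = None,
    seed: int = 0,
    criteria: FilterCriteria | None = None,
    model: FoldModel | None = None,
) -> PreRrnaScenario:
    """One long reference with precursors planted wholly inside assigned regions.

    The default scenario plants the five catalogued Papaver cluster miRNAs —
    miR2914, miR2916, miR2910 inside "18S" and miR1310, miR2911 inside "28S".
    When a catalogue mature cannot be realized as a clean hairpin under the
    bundled fold model, a synthetic mature of the same length stands in
    (planted id is kept; the truth table carries the actual sequence).
    """
    c = criteria or DEFAULT_CRITERIA
    regions = list(DEFAULT_RRNA_REGIONS) if regions is None else list(regions)
    assignments = (
        dict(DEFAULT_RRNA_ASSIGNMENTS) if assignments is None else dict(assignments)
    )
    region_by_name = {r.region_name: r for r in regions}
    for pid, rname in assignments.items():
        if rname not in region_by_name:
            raise GenerationError(f"{pid}: assigned region {rname!r} does not exist")
    ref_id = regions[0].reference_id
    total = max(r.end for r in regions)
    rng_fill = _rng(seed, "rrna_fill")
    sequence = list(_random_bases(rng_fill, total))

    catalog = _catalog_matures(assignments)
    matures: list[NucSequence] = []
    truth: list[TruthRecord] = []
    cursors = {r.region_name: r.start + 10 for r in regions}
    for pid, rname in assignments.items():
        rng_p = _rng(seed, f"rrna_mature:{pid}")
        precursor = None
        candidates: list[str] = []
        if pid in catalog:
            candidates.append(catalog[pid])
        candidates.extend(_draw_mature(rng_p, 21).seq for _ in range(30))
        last_err: Exception | None = None
        for mseq in candidates:
            try:
                precursor, p_truth = make_precursor(
                    NucSequence(pid, mseq),
                    star_mutations=0,
                    loop_len=6,
                    arm="5p",
                    seed=seed,
                    planted_id=pid,
                    criteria=c,
                    model=model,
                )
                mature = NucSequence(pid, mseq)
                break
            except GenerationError as exc:
                last_err = exc
        if precursor is None:
            raise GenerationError(f"{pid}: unrealizable ({last_err})")
        region = region_by_name[rname]
        start = cursors[rname] + EMBED_PAD
        end = start + precursor.length
        if end + EMBED_PAD > region.end:
            raise GenerationError(
                f"{pid}: precursor does not fit inside region {rname!r}"
            )
        sequence[start - EMBED_PAD : end + EMBED_PAD] = list(
            "N" * EMBED_PAD + precursor.seq + "N" * EMBED_PAD
        )
        cursors[rname] = end + EMBED_PAD
        m0, m1 = p_truth.mature_span
        matures.append(mature)
        truth.append(
            TruthRecord(
                planted_id=pid,
                transcript_id=ref_id,
                mature_span=(start + m0, start + m1),
                arm=p_truth.arm,
                violated_criterion="none",
                precursor_span=(start, end),
                region=rname,
                mature_seq=mature.seq,
            )
        )
    reference = NucSequence(ref_id, "".join(sequence))
    return PreRrnaScenario(
        reference=reference, regions=regions, matures=matures, truth=truth
    )
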