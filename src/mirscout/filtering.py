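"""Criterion-by-criterion evaluation of folded precursor candidates.

A candidate window is judged against the structural and thermodynamic rules
used for conserved plant pre-miRNA screening:

* precursor length between 60 and 400 nt, mature length 17-25 nt;
* the window folds into a single stem-loop;
* the mature sits entirely on one arm (5p or 3p) and forms a duplex with the
  star strand on the opposite arm with fewer than 6 unpaired (mismatched)
  mature positions and at least 16 base pairs;
* bulges within the duplex are at most 3 nt long with per-internal-loop
  asymmetry at most 2 nt;
* MFE <= -15 kcal/mol, MFEI <= -0.49, and G+C content within 24-71 %.

MFEI is the minimal-folding-free-energy index: AMFE / GC%, where
AMFE = 100 * MFE / precursor_length is the folding energy per 100 nt.  A
"mismatch" in the duplex is operationalized as a mature position with no
pairing partner; the GU wobble counts as paired, consistent with plant miRNA
practice.

Failures are verdicts, not exceptions: :func:`evaluate` always returns a full
:class:`FilterReport` whose per-criterion verdicts carry the measured values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import pandas as pd

from .folding import FoldModel, HairpinStructure, fold, is_single_hairpin
from .seqio import NucSequence, gc_percent

__all__ = [
    "FilterCriteria",
    "DuplexAlignment",
    "DuplexUndefinedError",
    "MatureNotFoundError",
    "CriterionVerdict",
    "FilterReport",
    "CRITERION_ORDER",
    "amfe",
    "compute_mfei",
    "round2",
    "locate_mature",
    "extract_duplex",
    "arm_of",
    "evaluate",
    "trim_to_hairpin",
    "assess_window",
    "load_catalog",
    "recompute_catalog_mfei",
]

Arm = Literal["5p", "3p", "ambiguous"]

#: evaluation order; labels name what each criterion measures
CRITERION_ORDER = (
    "precursor_length",
    "mature_length",
    "single_hairpin",
    "duplex_mismatches",
    "arm",
    "mfei",
    "mfe",
    "bulge_asymmetry",
    "gc_content",
    "duplex_pairs",
)


class DuplexUndefinedError(ValueError):
    """The mature has no pairing partners or straddles the terminal loop."""


class MatureNotFoundError(ValueError):
    """No window of the precursor matches the mature within tolerance."""


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the precursor screen.  ``max_duplex_mismatches`` is an
    exclusive bound (mismatches must be strictly below it)."""

    min_mature_len: int = 17
    max_mature_len: int = 25
    max_duplex_mismatches: int = 6
    min_duplex_pairs: int = 16
    max_mfe: float = -15.0
    max_mfei: float = -0.49
    gc_min: float = 24.0
    gc_max: float = 71.0
    max_bulge: int = 3
    max_asymmetry: int = 2
    min_precursor_len: int = 60
    max_precursor_len: int = 400

    def __post_init__(self) -> None:
        if self.min_mature_len > self.max_mature_len:
            raise ValueError("min_mature_len > max_mature_len")
        if self.min_precursor_len > self.max_precursor_len:
            raise ValueError("min_precursor_len > max_precursor_len")
        if self.gc_min >= self.gc_max:
            raise ValueError("gc_min >= gc_max")


DEFAULT_CRITERIA = FilterCriteria()


def amfe(mfe: float, lp: int) -> float:
    """Adjusted MFE: folding energy per 100 nt of precursor."""
    if lp < 1:
        raise ValueError("precursor length must be >= 1")
    return 100.0 * mfe / lp


def compute_mfei(mfe: float, lp: int, gc: float) -> float:
    """MFEI = AMFE / GC% = (100 * MFE / LP) / GC%.

    ``gc`` is a percentage (0-100].  A GC of zero leaves the index undefined
    and raises ``ValueError``.
    """
    if gc <= 0:
        raise ValueError("MFEI is undefined for GC% <= 0")
    return amfe(mfe, lp) / gc


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (reporting convention)."""
    import math

    return math.copysign(math.floor(abs(x) * 100 + 0.5) / 100, x)


def locate_mature(
    precursor: NucSequence, mature: NucSequence, max_mismatches: int = 2
) -> tuple[int, int]:
    """Best (fewest-mismatch, then leftmost) window of ``precursor`` matching
    ``mature``; N never matches.  Raises :class:`MatureNotFoundError` if the
    best window exceeds ``max_mismatches``."""
    p, m = precursor.seq, mature.seq
    L = len(m)
    if L > len(p):
        raise MatureNotFoundError(
            f"mature {mature.id!r} ({L} nt) longer than precursor ({len(p)} nt)"
        )
    best_mm, best_start = L + 1, -1
    for start in range(len(p) - L + 1):
        mm = sum(
            1
            for a, b in zip(p[start : start + L], m)
            if a != b or a == "N" or b == "N"
        )
        if mm < best_mm:
            best_mm, best_start = mm, start
            if mm == 0:
                break
    if best_mm > max_mismatches:
        raise MatureNotFoundError(
            f"mature {mature.id!r} not found in {precursor.id!r} "
            f"within {max_mismatches} mismatches (best: {best_mm})"
        )
    return (best_start, best_start + L)


@dataclass(frozen=True)
class DuplexAlignment:
    """The mature:star duplex read off a hairpin's pairing table.

    ``bulges`` lists maximal unpaired runs strictly interior to the duplex as
    (side, length); ``asymmetries`` carries |unpaired_mature - unpaired_star|
    per internal loop.
    """

    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    paired_count: int
    mismatches: int
    bulges: tuple[tuple[str, int], ...]
    asymmetries: tuple[int, ...]

    def __post_init__(self) -> None:
        m0, m1 = self.mature_span
        if self.paired_count + self.mismatches != m1 - m0:
            raise ValueError("paired_count + mismatches must equal mature length")


def extract_duplex(h: HairpinStructure, mature_span: tuple[int, int]) -> DuplexAlignment:
    """Read the mature:star duplex off the pairing table.

    The star span is the minimal contiguous interval containing all partners
    of paired mature positions.  Raises :class:`DuplexUndefinedError` when no
    mature position is paired, when the mature straddles a terminal loop, or
    when the pairing partners are not arranged as a single opposite-arm run
    (a "break" in the duplex).
    """
    m0, m1 = mature_span
    if not (0 <= m0 < m1 <= len(h.seq)):
        raise ValueError(f"mature span [{m0},{m1}) outside structure of length {len(h.seq)}")
    for l0, l1 in h.terminal_loops():
        if m0 < l1 and l0 < m1:  # mature overlaps a hairpin loop
            raise DuplexUndefinedError(
                f"mature [{m0},{m1}) straddles the terminal loop [{l0},{l1})"
            )
    paired = [(p, h.partner(p)) for p in range(m0, m1) if h.partner(p) is not None]
    if not paired:
        raise DuplexUndefinedError("no mature position is paired")
    partners = [q for _, q in paired]
    if any(m0 <= q < m1 for q in partners):
        raise DuplexUndefinedError("mature pairs with itself")
    # partners must descend strictly as mature positions ascend (opposite arm)
    if any(b >= a for a, b in zip(partners, partners[1:])):
        raise DuplexUndefinedError("duplex is broken: partners are not a single run")
    star_span = (min(partners), max(partners) + 1)
    mismatches = (m1 - m0) - len(paired)
    bulges: list[tuple[str, int]] = []
    asymmetries: list[int] = []
    for (p_a, q_a), (p_b, q_b) in zip(paired, paired[1:]):
        um = p_b - p_a - 1
        us = q_a - q_b - 1
        if um == 0 and us == 0:
            continue
        if um:
            bulges.append(("mature", um))
        if us:
            bulges.append(("star", us))
        asymmetries.append(abs(um - us))
    return DuplexAlignment(
        mature_span=(m0, m1),
        star_span=star_span,
        paired_count=len(paired),
        mismatches=mismatches,
        bulges=tuple(bulges),
        asymmetries=tuple(asymmetries),
    )


def arm_of(h: HairpinStructure, mature_span: tuple[int, int]) -> Arm:
    """Which arm of the stem-loop carries the mature sequence.

    5p if the mature ends at or before the terminal-loop start, 3p if it
    begins at or after the loop end; anything else (straddling the loop, or a
    structure without exactly one terminal loop) is ambiguous.
    """
    loops = h.terminal_loops()
    if len(loops) != 1:
        return "ambiguous"
    l0, l1 = loops[0]
    m0, m1 = mature_span
    if m1 <= l0:
        return "5p"
    if m0 >= l1:
        return "3p"
    return "ambiguous"


@dataclass(frozen=True)
class CriterionVerdict:
    name: str
    passed: bool
    value: object = None
    detail: str = ""


@dataclass
class FilterReport:
    """Per-criterion verdicts plus the summary statistics of a candidate."""

    verdicts: dict[str, CriterionVerdict]
    stats: dict[str, object]

    @property
    def accepted(self) -> bool:
        return all(v.passed for v in self.verdicts.values())

    @property
    def failed(self) -> list[str]:
        return [name for name, v in self.verdicts.items() if not v.passed]

    def to_json(self) -> str:
        payload = {
            "verdicts": {
                name: {"passed": v.passed, "value": v.value, "detail": v.detail}
                for name, v in self.verdicts.items()
            },
            "stats": self.stats,
            "accepted": self.accepted,
        }
        return json.dumps(payload, indent=None, sort_keys=False)

    @classmethod
    def from_json(cls, payload: str) -> "FilterReport":
        data = json.loads(payload)
        verdicts = {
            name: CriterionVerdict(name, d["passed"], d["value"], d.get("detail", ""))
            for name, d in data["verdicts"].items()
        }
        return cls(verdicts=verdicts, stats=data["stats"])


def evaluate(
    precursor: NucSequence,
    mature: NucSequence,
    h: HairpinStructure,
    criteria: FilterCriteria | None = None,
    mature_span: tuple[int, int] | None = None,
) -> FilterReport:
    """Judge a folded precursor candidate criterion by criterion.

    ``h`` must be a fold of ``precursor``; the mature site is located within
    the precursor (<=2 scan-level mismatches) unless ``mature_span`` is given.
    Statistics (LP, GC%, MFE, AMFE, MFEI, arm) are always populated; a mature
    that cannot be located or a duplex that cannot be read produce failing
    verdicts, never exceptions.
    """
    c = criteria or DEFAULT_CRITERIA
    if h.seq != precursor.seq:
        raise ValueError("structure does not fold the given precursor")
    lp = precursor.length
    gc = gc_percent(precursor)
    mfe = h.energy
    a = amfe(mfe, lp)
    mfei = compute_mfei(mfe, lp, gc) if gc > 0 else None

    verdicts: dict[str, CriterionVerdict] = {}

    def add(name: str, passed: bool, value: object, detail: str = "") -> None:
        verdicts[name] = CriterionVerdict(name, bool(passed), value, detail)

    add(
        "precursor_length",
        c.min_precursor_len <= lp <= c.max_precursor_len,
        lp,
        f"allowed [{c.min_precursor_len},{c.max_precursor_len}]",
    )
    add(
        "mature_length",
        c.min_mature_len <= mature.length <= c.max_mature_len,
        mature.length,
        f"allowed [{c.min_mature_len},{c.max_mature_len}]",
    )
    add("single_hairpin", is_single_hairpin(h), is_single_hairpin(h))

    if mature_span is None:
        try:
            mature_span = locate_mature(precursor, mature)
        except MatureNotFoundError as exc:
            mature_span = None
            locate_err = str(exc)
    duplex: DuplexAlignment | None = None
    duplex_err = ""
    if mature_span is not None:
        try:
            duplex = extract_duplex(h, mature_span)
        except DuplexUndefinedError as exc:
            duplex_err = str(exc)
    else:
        duplex_err = f"mature not located: {locate_err}"

    if duplex is not None:
        add(
            "duplex_mismatches",
            duplex.mismatches < c.max_duplex_mismatches,
            duplex.mismatches,
            f"must be < {c.max_duplex_mismatches}",
        )
        add(
            "duplex_pairs",
            duplex.paired_count >= c.min_duplex_pairs,
            duplex.paired_count,
            f"must be >= {c.min_duplex_pairs}",
        )
        worst_bulge = max((ln for _, ln in duplex.bulges), default=0)
        worst_asym = max(duplex.asymmetries, default=0)
        add(
            "bulge_asymmetry",
            worst_bulge <= c.max_bulge and worst_asym <= c.max_asymmetry,
            {"max_bulge": worst_bulge, "max_asymmetry": worst_asym},
            f"bulge <= {c.max_bulge} nt, asymmetry <= {c.max_asymmetry} nt",
        )
    else:
        add("duplex_mismatches", False, None, duplex_err)
        add("duplex_pairs", False, None, duplex_err)
        add("bulge_asymmetry", False, None, duplex_err)

    arm: Arm = arm_of(h, mature_span) if mature_span is not None else "ambiguous"
    add("arm", arm in ("5p", "3p"), arm)
    add(
        "mfei",
        mfei is not None and mfei <= c.max_mfei,
        None if mfei is None else round(mfei, 4),
        f"must be <= {c.max_mfei}",
    )
    add("mfe", mfe <= c.max_mfe, mfe, f"must be <= {c.max_mfe} kcal/mol")
    add(
        "gc_content",
        c.gc_min <= gc <= c.gc_max,
        round(gc, 2),
        f"allowed [{c.gc_min},{c.gc_max}] %",
    )

    ordered = {name: verdicts[name] for name in CRITERION_ORDER}
    stats = {
        "LP": lp,
        "GC": round(gc, 2),
        "MFE": round(mfe, 2),
        "AMFE": round(a, 2),
        "MFEI": None if mfei is None else round(mfei, 2),
        "arm": arm,
        "mature_span": list(mature_span) if mature_span is not None else None,
        "duplex_pairs": duplex.paired_count if duplex else None,
        "duplex_mismatches": duplex.mismatches if duplex else None,
    }
    return FilterReport(verdicts=ordered, stats=stats)


def trim_to_hairpin(
    window: NucSequence,
    h: HairpinStructure,
    mature_span: tuple[int, int],
    pad: int = 8,
    min_len: int = 60,
) -> tuple[int, int]:
    """Cut an extraction window down to its precursor: the span of the
    outermost base pair enclosing the mature site, plus short tails.

    Extraction windows carry up to 150 nt of flank on each side of the mature
    hit; the precursor proper is the stem-loop around it.  The trimmed span is
    extended by ``pad`` nt per side and symmetrically widened to ``min_len``
    (clipped at the window edges).  If no pair encloses the mature, the mature
    span itself is padded — downstream criteria will then reject the window on
    structural grounds.

    Returns the half-open span on ``window``.
    """
    m0, m1 = mature_span
    enclosing = [(i, j) for i, j in h.pairs if i <= m0 and j >= m1 - 1]
    if enclosing:
        a = min(i for i, _ in enclosing)
        b = max(j for _, j in enclosing) + 1
    else:
        a, b = m0, m1
    a = max(0, a - pad)
    b = min(len(window.seq), b + pad)
    while b - a < min_len and (a > 0 or b < len(window.seq)):
        if a > 0:
            a -= 1
        if b < len(window.seq) and b - a < min_len:
            b += 1
    return (a, b)


@dataclass(frozen=True)
class WindowAssessment:
    """Everything learned about one extraction window."""

    precursor: NucSequence
    precursor_span: tuple[int, int]  # on the window
    structure: HairpinStructure
    mature_span: tuple[int, int] | None  # on the trimmed precursor
    report: FilterReport


def assess_window(
    window: NucSequence,
    mature: NucSequence,
    criteria: FilterCriteria | None = None,
    model: FoldModel | None = None,
    scan_mismatches: int = 2,
    fold_fn=None,
) -> WindowAssessment:
    """Fold an extraction window, trim it to the enclosed hairpin, refold the
    trimmed precursor and evaluate it.  This is the per-candidate core of the
    discovery pipeline.

    ``fold_fn`` swaps in an alternative folding backend (any callable mapping
    a :class:`NucSequence` to a :class:`HairpinStructure`); by default the
    bundled model is used.
    """
    c = criteria or DEFAULT_CRITERIA
    do_fold = fold_fn if fold_fn is not None else (lambda s: fold(s, model))
    full = do_fold(window)
    try:
        w_span = locate_mature(window, mature, scan_mismatches)
    except MatureNotFoundError:
        # no usable mature site: evaluate the raw window, which will fail
        report = evaluate(window, mature, full, c, mature_span=None)
        return WindowAssessment(window, (0, len(window.seq)), full, None, report)
    a, b = trim_to_hairpin(window, full, w_span, min_len=c.min_precursor_len)
    precursor = window.subseq(a, b, new_id=f"{window.id}|hairpin")
    m_span = (w_span[0] - a, w_span[1] - a)
    structure = do_fold(precursor)
    report = evaluate(precursor, mature, structure, c, mature_span=m_span)
    return WindowAssessment(precursor, (a, b), structure, m_span, report)


# ---------------------------------------------------------------------------
# Reference catalogue of reported Papaver precursor statistics
# ---------------------------------------------------------------------------

def load_catalog() -> pd.DataFrame:
    """Load the bundled catalogue of conserved Papaver miRNA precursors.

    Columns: name, mature_seq, in_somniferum, in_bracteatum, au_pct, gc_pct,
    lp (precursor length, nt), mfe (kcal/mol), mfei_printed (the index as
    reported, which mixes rounding conventions — see
    :func:`recompute_catalog_mfei`).
    """
    with resources.files("mirscout.data").joinpath("papaver_mirna_catalog.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def recompute_catalog_mfei(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute AMFE and MFEI from the catalogue's MFE/LP/GC columns.

    Adds ``amfe``, ``mfei_recomputed`` (2 dp, half away from zero) and
    ``consistent`` — whether the recomputed index reproduces the printed one
    within 0.01 (the catalogue mixes rounding and truncation; inconsistent
    rows are flagged, not forced).
    """
    df = (df if df is not None else load_catalog()).copy()
    df["amfe"] = [amfe(m, lp) for m, lp in zip(df["mfe"], df["lp"])]
    df["mfei_recomputed"] = [
        round2(compute_mfei(m, lp, gc))
        for m, lp, gc in zip(df["mfe"], df["lp"], df["gc_pct"])
    ]
    df["consistent"] = (df["mfei_recomputed"] - df["mfei_printed"]).abs() <= 0.01 + 1e-9
    return df
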