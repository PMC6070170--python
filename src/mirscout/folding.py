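"""Secondary-structure prediction for candidate precursor windows.

The bundled model is an additive per-pair energy model (a weighted variant of
the classic nested base-pair maximization dynamic program): each GC/CG pair
contributes -3.0 kcal/mol, AU/UA -2.0, and the GU/UG wobble -1.0, with a
minimum hairpin loop of 3 unpaired nucleotides and no pseudoknots.  It is
deliberately not a nearest-neighbor thermodynamic model: it is deterministic,
dependency-free, and small enough that its optima can be verified by
exhaustive enumeration, while every downstream filter is agnostic to where
the energy came from.  A thermodynamic engine (e.g. RNAfold) can be plugged
in behind the same contract by supplying dot-bracket + energy through
:meth:`HairpinStructure.from_dotbracket` or the pipeline's external-folder
hook.

Traceback is fully specified so the dot-bracket output is bit-stable: at each
interval, pairing the two endpoints is preferred when optimal; otherwise the
interval is split at the leftmost optimal point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .seqio import NucSequence

__all__ = [
    "FoldModel",
    "HairpinStructure",
    "DotBracketError",
    "fold",
    "parse_dotbracket",
    "is_single_hairpin",
]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

#: canonical pairs (incl. GU wobble); N is unpairable
_DEFAULT_WEIGHTS = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

_TOL = 1e-9


class DotBracketError(ValueError):
    """Raised for unbalanced or otherwise invalid dot-bracket strings."""


@dataclass(frozen=True)
class FoldModel:
    """Additive per-pair energies (kcal/mol) and the minimum hairpin loop size."""

    pair_weights: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.min_loop < 1:
            raise ValueError("min_loop must be >= 1")
        if any(w >= 0 for w in self.pair_weights.values()):
            raise ValueError("pair weights must be negative (stabilizing)")

    def weight_matrix(self) -> np.ndarray:
        """5x5 matrix over A,C,G,U,N codes; +inf marks an illegal pair."""
        mat = np.full((5, 5), np.inf)
        for (a, b), w in self.pair_weights.items():
            mat[_CODE[a], _CODE[b]] = w
        return mat

    def can_pair(self, a: str, b: str) -> bool:
        return (a, b) in self.pair_weights


DEFAULT_MODEL = FoldModel()


def parse_dotbracket(db: str, min_loop: int | None = None) -> dict[int, int]:
    """Parse a dot-bracket string into a position->partner map.

    ``min_loop`` enables hairpin-loop size enforcement at parse time; when
    disabled (default), undersized loops only emit a validation warning.
    Unbalanced strings raise :class:`DotBracketError` with the offending index.
    """
    if set(db) - set("()."):
        bad = next(i for i, c in enumerate(db) if c not in "().")
        raise DotBracketError(f"illegal character {db[bad]!r} at index {bad}")
    stack: list[int] = []
    table: dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at index {i}")
            j = stack.pop()
            loop = i - j - 1
            if min_loop is not None and loop < min_loop:
                raise DotBracketError(
                    f"pair ({j},{i}) encloses a loop of {loop} < {min_loop} nt"
                )
            if min_loop is None and loop < 3 and _innermost(db, j, i):
                warnings.warn(
                    f"pair ({j},{i}) encloses a hairpin loop of {loop} < 3 nt",
                    stacklevel=2,
                )
            table[j] = i
            table[i] = j
    if stack:
        raise DotBracketError(f"unmatched '(' at index {stack[-1]}")
    return table


def _innermost(db: str, j: int, i: int) -> bool:
    return all(c == "." for c in db[j + 1 : i])


@dataclass(frozen=True)
class HairpinStructure:
    """A sequence with a nested secondary structure and its total energy.

    Invariants checked at construction: balanced dot-bracket of equal length,
    every pair canonical (AU/UA/GC/CG/GU/UG), non-positive energy which is
    zero iff the structure has no pairs.
    """

    seq: str
    dotbracket: str
    energy: float

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")
        table = parse_dotbracket(self.dotbracket)
        for i, j in table.items():
            if i < j and (self.seq[i], self.seq[j]) not in _DEFAULT_WEIGHTS:
                raise ValueError(
                    f"illegal pair {self.seq[i]}:{self.seq[j]} at ({i},{j})"
                )
        if self.energy > _TOL:
            raise ValueError(f"energy must be <= 0, got {self.energy}")
        if not table and abs(self.energy) > _TOL:
            raise ValueError("structure without pairs must have energy 0")
        object.__setattr__(self, "_table", table)

    @classmethod
    def from_dotbracket(
        cls, seq: NucSequence | str, db: str, energy: float
    ) -> "HairpinStructure":
        """Build (and validate) a structure produced by an external folder."""
        s = seq.seq if isinstance(seq, NucSequence) else seq
        return cls(s, db, energy)

    @property
    def pair_table(self) -> dict[int, int]:
        return dict(self._table)  # type: ignore[attr-defined]

    def partner(self, i: int) -> int | None:
        return self._table.get(i)  # type: ignore[attr-defined]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Pairs (i, j) with i < j, sorted by i."""
        t = self._table  # type: ignore[attr-defined]
        return sorted((i, j) for i, j in t.items() if i < j)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def terminal_loops(self) -> list[tuple[int, int]]:
        """Half-open spans of hairpin (terminal) loops, one per innermost pair."""
        loops = []
        for i, j in self.pairs:
            if all(self.partner(k) is None for k in range(i + 1, j)):
                loops.append((i + 1, j))
        return loops

    def to_vienna(self, header: str | None = None) -> str:
        """Serialize as a Vienna-style 3-line record."""
        name = header if header is not None else "structure"
        return f">{name}\n{self.seq}\n{self.dotbracket} ({self.energy:.2f})\n"


def is_single_hairpin(h: HairpinStructure) -> bool:
    """True iff the structure is one stem-loop: at least one pair and exactly
    one transition from an "(" run to a ")" run."""
    brackets = [c for c in h.dotbracket if c in "()"]
    if not brackets:
        return False
    transitions = sum(
        1 for a, b in zip(brackets, brackets[1:]) if a == "(" and b == ")"
    )
    return transitions == 1


def _fill(codes: np.ndarray, pair_e: np.ndarray, min_loop: int) -> np.ndarray:
    """O(n^3) interval DP. E[i, j] = optimal energy of codes[i..j] inclusive."""
    n = len(codes)
    # one padding row so that the column slice E[k+1, j] is defined for k = j
    E = np.zeros((n + 1, max(n, 1)))
    P = pair_e[codes[:, None], codes[None, :]] if n else np.empty((0, 0))
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = float(np.min(E[i, i:j] + E[i + 1 : j + 1, j]))
            pe = P[i, j]
            if np.isfinite(pe):
                v = pe + E[i + 1, j - 1]
                if v < best:
                    best = v
            E[i, j] = best
    return E


def _traceback(
    codes: np.ndarray, pair_e: np.ndarray, E: np.ndarray, min_loop: int
) -> list[tuple[int, int]]:
    n = len(codes)
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        e = E[i, j]
        pe = pair_e[codes[i], codes[j]]
        if np.isfinite(pe) and abs(pe + E[i + 1, j - 1] - e) <= _TOL:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if abs(E[i, k] + E[k + 1, j] - e) <= _TOL:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - would indicate a DP/traceback inconsistency
            raise RuntimeError(f"traceback failed at interval ({i},{j})")
    return pairs


def fold(s: NucSequence | str, model: FoldModel | None = None) -> HairpinStructure:
    """Predict the minimum-energy nested structure of ``s`` under ``model``.

    Deterministic: ties are resolved by preferring the endpoint pair of each
    interval and otherwise splitting at the leftmost optimal point, so the
    returned dot-bracket is identical across runs and platforms.
    """
    model = model or DEFAULT_MODEL
    seq = s.seq if isinstance(s, NucSequence) else s
    n = len(seq)
    if not 1 <= n <= 10_000:
        raise ValueError(f"fold expects 1..10000 nt, got {n}")
    codes = np.array([_CODE[c] for c in seq], dtype=np.int8)
    pair_e = model.weight_matrix()
    E = _fill(codes, pair_e, model.min_loop)
    pairs = _traceback(codes, pair_e, E, model.min_loop)
    db = ["."] * n
    energy = 0.0
    for i, j in pairs:
        db[i], db[j] = "(", ")"
        energy += pair_e[codes[i], codes[j]]
    return HairpinStructure(seq, "".join(db), energy)
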