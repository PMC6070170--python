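"""The bundled folding model against exhaustive enumeration, plus structure
parsing and the single-hairpin predicate."""

import pytest

from conftest import enumerated_min_energy, random_rna
from mirscout.folding import (
    DotBracketError,
    FoldModel,
    HairpinStructure,
    fold,
    is_single_hairpin,
    parse_dotbracket,
)


class TestFoldExamples:
    @pytest.mark.parametrize(
        "seq,db,energy",
        [
            ("GGGAAACCC", "(((...)))", -9.0),
            ("AAAAA", ".....", 0.0),
            ("GAAAC", "(...)", -3.0),
        ],
    )
    def test_small_sequences(self, seq, db, energy):
        h = fold(seq)
        assert h.dotbracket == db
        assert h.energy == pytest.approx(energy)

    def test_n_is_unpairable(self):
        h = fold("GAAAN")
        assert h.dotbracket == "....."

    def test_pure_and_deterministic(self, rng):
        seq = random_rna(rng, 80)
        a, b = fold(seq), fold(seq)
        assert a.dotbracket == b.dotbracket and a.energy == b.energy

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold("")


class TestFoldOracle:
    def test_matches_exhaustive_enumeration(self, rng):
        """The DP optimum equals the brute-force optimum over all nested
        structures with loop >= 3, across random short sequences."""
        for _ in range(60):
            n = int(rng.integers(4, 13))
            seq = random_rna(rng, n)
            h = fold(seq)
            assert h.energy == pytest.approx(enumerated_min_energy(seq)), seq

    def test_energy_consistent_with_structure(self, rng):
        w = FoldModel().pair_weights
        for _ in range(20):
            seq = random_rna(rng, 40)
            h = fold(seq)
            assert h.energy == pytest.approx(
                sum(w[(seq[i], seq[j])] for i, j in h.pairs)
            )

    def test_appending_never_raises_energy(self, rng):
        for _ in range(25):
            seq = random_rna(rng, int(rng.integers(5, 30)))
            extended = seq + random_rna(rng, 3)
            assert fold(extended).energy <= fold(seq).energy + 1e-9


class TestHairpinStructure:
    def test_pair_table_is_symmetric_involution(self, rng):
        seq = random_rna(rng, 60)
        h = fold(seq)
        for i, j in h.pair_table.items():
            assert h.pair_table[j] == i

    def test_rejects_illegal_pair(self):
        with pytest.raises(ValueError, match="illegal pair"):
            HairpinStructure("AAAAA", "(...)", -2.0)

    def test_rejects_positive_energy(self):
        with pytest.raises(ValueError):
            HairpinStructure("GAAAC", "(...)", 1.0)

    def test_no_pairs_requires_zero_energy(self):
        with pytest.raises(ValueError):
            HairpinStructure("AAAA", "....", -1.0)

    def test_vienna_serialization(self):
        h = fold("GGGAAACCC")
        text = h.to_vienna("hp")
        assert text.splitlines() == [">hp", "GGGAAACCC", "(((...))) (-9.00)"]


class TestSingleHairpin:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("(((...)))", True),
            ("(((...)))(((...)))", False),
            (".........", False),
            ("..((..(((...)))..))..", True),
            ("((..((...))..((...))..))", False),  # two terminal loops
        ],
    )
    def test_transition_counting(self, db, expected):
        seq = _seq_for(db)
        h = HairpinStructure(seq, db, -2.0 * sum(1 for c in db if c == "(") or 0.0)
        assert is_single_hairpin(h) is expected


def _seq_for(db: str) -> str:
    """A sequence realizing the given dot-bracket with A:U pairs."""
    chars = []
    for c in db:
        chars.append({"(": "A", ")": "U", ".": "C"}[c])
    return "".join(chars)


class TestParseDotBracket:
    def test_simple(self):
        assert parse_dotbracket("(...)") == {0: 4, 4: 0}

    def test_tight_loop_warns_without_enforcement(self):
        with pytest.warns(UserWarning):
            assert parse_dotbracket("()") == {0: 1, 1: 0}

    def test_tight_loop_rejected_with_enforcement(self):
        with pytest.raises(DotBracketError):
            parse_dotbracket("()", min_loop=3)

    @pytest.mark.parametrize("db,idx", [(")(", 0), ("(()", 0), ("(.))", 3)])
    def test_unbalanced_reports_index(self, db, idx):
        with pytest.raises(DotBracketError, match=f"index {idx}"):
            parse_dotbracket(db)
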