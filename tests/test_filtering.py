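"""MFEI arithmetic, duplex extraction, arm calls and the seven-criterion filter."""

import dataclasses

import pytest

from mirscout.filtering import (
    DuplexUndefinedError,
    FilterCriteria,
    FilterReport,
    MatureNotFoundError,
    amfe,
    arm_of,
    compute_mfei,
    evaluate,
    extract_duplex,
    load_catalog,
    locate_mature,
    recompute_catalog_mfei,
    round2,
    trim_to_hairpin,
)
from mirscout.folding import HairpinStructure, fold
from mirscout.seqio import NucSequence
from mirscout.synthetic import make_precursor


class TestMfei:
    @pytest.mark.parametrize(
        "mfe,lp,gc,expected",
        [
            (-62.80, 95, 72.63, -0.91),
            (-15.51, 59, 47.46, -0.55),
            (-19.20, 63, 52.38, -0.58),
            (-20.60, 85, 30.59, -0.79),
            (-44.30, 92, 46.74, -1.03),
            (-10.0, 100, 50.0, -0.20),
        ],
    )
    def test_reported_and_constructed_values(self, mfe, lp, gc, expected):
        assert round2(compute_mfei(mfe, lp, gc)) == pytest.approx(expected)

    def test_amfe_is_energy_per_100nt(self):
        assert amfe(-10.0, 100) == pytest.approx(-10.0)
        assert amfe(-10.0, 50) == pytest.approx(-20.0)

    def test_gc_zero_is_domain_error(self):
        with pytest.raises(ValueError):
            compute_mfei(-20.0, 80, 0.0)

    def test_scale_consistency(self):
        """Doubling LP at fixed MFE halves the index."""
        one = compute_mfei(-30.0, 70, 40.0)
        two = compute_mfei(-30.0, 140, 40.0)
        assert two == pytest.approx(one / 2)


class TestCatalog:
    CONSISTENT = [
        "pso-miR2911",
        "pso-miR2910",
        "pso-miR2914",
        "pso-miR156h",
        "pso-miRf12412-akr",
        "pso-miR1122",
        "pso-miR415",
    ]

    def test_recomputation_reproduces_consistent_rows(self):
        df = recompute_catalog_mfei()
        sub = df[df["name"].isin(self.CONSISTENT)]
        assert len(sub) == len(self.CONSISTENT)
        assert (sub["mfei_recomputed"] == sub["mfei_printed"]).all()

    def test_inconsistent_rows_are_flagged_not_forced(self):
        df = recompute_catalog_mfei().set_index("name")
        for name in ("pso-miR414", "pso-miR5023", "pso-miR1134"):
            assert not df.loc[name, "consistent"]

    def test_catalog_shape(self):
        df = load_catalog()
        assert len(df) == 22
        assert df["mature_seq"].str.fullmatch("[ACGU]+").all()


class TestLocateMature:
    def test_planted_copy_found(self, rng):
        from conftest import random_rna

        mature = NucSequence("m", random_rna(rng, 23))
        window = NucSequence("w", random_rna(rng, 150) + mature.seq + random_rna(rng, 127))
        assert locate_mature(window, mature) == (150, 173)

    def test_leftmost_of_two_exact_copies(self):
        m = NucSequence("m", "ACGUACGUACGUACGUA")
        p = NucSequence("p", "CC" + m.seq + "CC" + m.seq)
        assert locate_mature(p, m)[0] == 2

    def test_not_found_beyond_tolerance(self):
        m = NucSequence("m", "A" * 17)
        p = NucSequence("p", "C" * 60)
        with pytest.raises(MatureNotFoundError):
            locate_mature(p, m)


class TestDuplexAndArm:
    def _perfect(self):
        # 22-bp GC/AU stem with a 4-nt loop; mature is the full 5' arm
        mature = "GCGCGCGCAUAUAUGCGCGCAU"
        from mirscout.seqio import reverse_complement

        seq = mature + "CAAC" + reverse_complement(mature)
        h = fold(seq)
        return h, (0, 22)

    def test_perfect_stem(self):
        h, span = self._perfect()
        d = extract_duplex(h, span)
        assert d.mismatches == 0
        assert d.paired_count == 22
        assert d.bulges == ()

    def test_star_side_bulge(self):
        # hand-built: 5' arm 8 pairs, a 2-nt bulge on the star side
        seq = "GGGGGGGG" + "AAAC" + "CCCC" + "AA" + "CCCC"
        db = "((((((((" + "...." + "))))" + ".." + "))))"
        h = HairpinStructure(seq, db, -24.0)
        d = extract_duplex(h, (0, 8))
        assert d.bulges == (("star", 2),)
        assert d.asymmetries == (2,)

    def test_mature_spanning_loop_is_undefined(self):
        h, _ = self._perfect()
        with pytest.raises(DuplexUndefinedError):
            extract_duplex(h, (18, 30))

    def test_unpaired_mature_is_undefined(self):
        h = HairpinStructure("GGGGAAAACCCCAAAAA", "((((....)))).....", -12.0)
        with pytest.raises(DuplexUndefinedError):
            extract_duplex(h, (13, 17))

    @pytest.mark.parametrize(
        "span,expected",
        [((0, 6), "5p"), ((10, 16), "3p"), ((4, 12), "ambiguous")],
    )
    def test_arm_assignment(self, span, expected):
        h = HairpinStructure("GGGGGGAAAACCCCCC", "((((((....))))))", -18.0)
        assert arm_of(h, span) == expected


@pytest.fixture(scope="module")
def clean():
    mature = NucSequence("m", "GCAUGCAUGGCAUCCGAUGCAG")
    precursor, truth = make_precursor(mature, star_mutations=0, loop_len=6, arm="5p", seed=1)
    h = fold(precursor)
    return precursor, mature, h, truth


class TestEvaluate:

    def test_clean_precursor_accepted_criterion_by_criterion(self, clean):
        precursor, mature, h, truth = clean
        report = evaluate(precursor, mature, h, mature_span=truth.mature_span)
        assert report.accepted
        assert report.failed == []
        assert report.stats["arm"] == "5p"
        assert report.stats["duplex_pairs"] == 22

    def test_weak_energy_fails_mfe_criterion(self, clean):
        """A structure whose energy is above -15 kcal/mol fails, whatever its shape."""
        precursor, mature, h, truth = clean
        weak = HairpinStructure(h.seq, h.dotbracket, -14.2)  # e.g. an external backend
        report = evaluate(precursor, mature, weak, mature_span=truth.mature_span)
        assert "mfe" in report.failed

    def test_low_gc_fails_gc_criterion(self):
        # AU-only hairpin: GC far below the 24% floor
        mature = NucSequence("m", "AUAUAUAUAAUUAUAUAUAUA")
        from mirscout.seqio import reverse_complement

        seq = "NNNNNNNNN" + mature.seq + "CAACAA" + reverse_complement(mature.seq) + "NNNNNNNNN"
        p = NucSequence("p", seq)
        report = evaluate(p, mature, fold(p), mature_span=(9, 30))
        assert "gc_content" in report.failed

    def test_verdict_values_follow_thresholds(self, clean):
        precursor, mature, h, truth = clean
        report = evaluate(precursor, mature, h, mature_span=truth.mature_span)
        assert report.verdicts["mfe"].value == pytest.approx(h.energy)
        assert report.verdicts["precursor_length"].value == precursor.length

    def test_monotone_in_thresholds(self, clean):
        """Relaxing any single bound never turns accepted into rejected."""
        precursor, mature, h, truth = clean
        base = FilterCriteria()
        assert evaluate(precursor, mature, h, base, truth.mature_span).accepted
        relaxed = [
            dataclasses.replace(base, max_mfe=base.max_mfe + 5),
            dataclasses.replace(base, max_mfei=base.max_mfei + 0.2),
            dataclasses.replace(base, gc_min=base.gc_min - 10),
            dataclasses.replace(base, gc_max=base.gc_max + 10),
            dataclasses.replace(base, max_duplex_mismatches=base.max_duplex_mismatches + 2),
            dataclasses.replace(base, min_duplex_pairs=base.min_duplex_pairs - 4),
            dataclasses.replace(base, max_bulge=base.max_bulge + 2),
            dataclasses.replace(base, min_precursor_len=base.min_precursor_len - 10),
            dataclasses.replace(base, max_precursor_len=base.max_precursor_len + 100),
        ]
        for crit in relaxed:
            assert evaluate(precursor, mature, h, crit, truth.mature_span).accepted

    def test_report_json_round_trip(self, clean):
        precursor, mature, h, truth = clean
        report = evaluate(precursor, mature, h, mature_span=truth.mature_span)
        back = FilterReport.from_json(report.to_json())
        assert back.accepted == report.accepted
        assert back.stats == report.stats
        assert list(back.verdicts) == list(report.verdicts)


class TestTrim:
    def test_trim_recovers_planted_hairpin(self):
        mature = NucSequence("m", "GCAUGCAUGGCAUCCGAUGCAG")
        precursor, truth = make_precursor(mature, seed=3)
        window = NucSequence("w", "N" * 140 + precursor.seq + "N" * 140)
        h = fold(window)
        m0 = 140 + truth.mature_span[0]
        a, b = trim_to_hairpin(window, h, (m0, m0 + mature.length))
        assert b - a >= 60
        # the trimmed span contains the full planted hairpin core
        assert a <= 140 + truth.mature_span[0]
        assert b >= 140 + precursor.length - 4
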