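"""Mature/precursor homology scans against brute-force enumeration."""

import pytest

from conftest import hamming_all_windows, random_rna
from mirscout.homology import SearchConfig, scan_mature, scan_precursor, extract_window
from mirscout.seqio import NucSequence, reverse_complement

CFG = SearchConfig()
PLUS_ONLY = SearchConfig(scan_reverse_complement=False)

_SUB = {"A": "C", "C": "A", "G": "U", "U": "G"}


def _mutate(seq: str, positions) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = _SUB[chars[p]]
    return "".join(chars)


class TestScanMature:
    def _planted(self, rng, n_sub):
        query = random_rna(rng, 17)
        bg = random_rna(rng, 60)
        planted = _mutate(query, range(n_sub))
        return NucSequence("q", query), NucSequence("t", bg[:10] + planted + bg[27:])

    def test_exact_plant_found_at_offset(self, rng):
        q, t = self._planted(rng, 0)
        hits = [h for h in scan_mature(q, t, PLUS_ONLY) if h.start == 10]
        assert hits and hits[0].mismatches == 0
        assert hits[0].end - hits[0].start == q.length

    def test_two_substitutions_still_found(self, rng):
        q, t = self._planted(rng, 2)
        assert any(h.start == 10 and h.mismatches == 2 for h in scan_mature(q, t, PLUS_ONLY))

    def test_three_substitutions_not_found_at_locus(self, rng):
        q, t = self._planted(rng, 3)
        assert not any(h.start == 10 for h in scan_mature(q, t, PLUS_ONLY))

    def test_transcript_shorter_than_query_is_empty(self):
        q = NucSequence("q", "ACGUACGUACGUACGUA")
        assert scan_mature(q, NucSequence("t", "ACGU"), CFG) == []

    def test_query_outside_length_range_is_skipped(self):
        q = NucSequence("q", "ACGUACGUACGU")  # 12 nt < 17
        t = NucSequence("t", "ACGUACGUACGU" * 4)
        assert scan_mature(q, t, CFG) == []

    def test_n_never_matches(self):
        q = NucSequence("q", "A" * 17)
        t = NucSequence("t", "A" * 5 + "NNN" + "A" * 12)
        hits = scan_mature(q, t, SearchConfig(scan_reverse_complement=False))
        # every window covering the NNN block pays 3 mismatches
        assert all(h.mismatches > 2 for h in hits) or hits == []

    def test_oracle_equivalence_both_strands(self, rng):
        """scan_mature equals the all-windows Hamming enumeration, forward and
        reverse-complement, over random query/transcript pairs."""
        for _ in range(30):
            q = random_rna(rng, 20)
            t = random_rna(rng, 100)
            hits = scan_mature(NucSequence("q", q), NucSequence("t", t), CFG)
            fwd = hamming_all_windows(q, t, CFG.max_mismatches)
            rev = hamming_all_windows(q, reverse_complement(t), CFG.max_mismatches)
            expected_plus = {(s, mm) for s, mm in fwd}
            expected_minus = {(len(t) - s - 20, mm) for s, mm in rev}
            got_plus = {(h.start, h.mismatches) for h in hits if h.strand == "+"}
            got_minus = {(h.start, h.mismatches) for h in hits if h.strand == "-"}
            assert got_plus == expected_plus
            assert got_minus == expected_minus

    def test_strand_symmetry(self, rng):
        """Hits on the reverse complement mirror the minus-strand hits."""
        q = NucSequence("q", random_rna(rng, 18))
        t = NucSequence("t", random_rna(rng, 150))
        rc = t.reverse_complement("t")
        direct = {(h.strand, h.start, h.end) for h in scan_mature(q, t, CFG)}
        mirrored = {
            ({"+": "-", "-": "+"}[h.strand], t.length - h.end, t.length - h.start)
            for h in scan_mature(q, rc, CFG)
        }
        assert direct == mirrored


class TestExtractWindow:
    def _hit(self, start, end, strand="+"):
        from mirscout.homology import MatureHit

        return MatureHit("q", "t", start, end, strand, 0)

    def test_interior_hit_full_window(self, rng):
        t = NucSequence("t", random_rna(rng, 1000))
        window, span = extract_window(t, self._hit(200, 221), CFG)
        assert window.length == 321  # 150 + 21 + 150
        assert window.seq == t.seq[50:371]
        assert span == (150, 171)

    def test_edge_hit_clipped(self, rng):
        t = NucSequence("t", random_rna(rng, 1000))
        window, span = extract_window(t, self._hit(20, 41), CFG)
        assert window.seq == t.seq[0:191]
        assert span == (20, 41)

    def test_zero_flank_returns_the_mature(self, rng):
        t = NucSequence("t", random_rna(rng, 100))
        window, span = extract_window(t, self._hit(30, 50), SearchConfig(flank=0))
        assert window.seq == t.seq[30:50]
        assert span == (0, 20)

    def test_minus_strand_reorients_to_mature_sense(self, rng):
        q = random_rna(rng, 20)
        t = NucSequence("t", random_rna(rng, 100) + reverse_complement(q) + random_rna(rng, 100))
        (hit,) = [h for h in scan_mature(NucSequence("q", q), t, CFG) if h.strand == "-"]
        window, span = extract_window(t, hit, CFG)
        assert window.seq[span[0] : span[1]] == q

    def test_window_length_bound(self, rng):
        t = NucSequence("t", random_rna(rng, 500))
        for start in (0, 10, 240, 470):
            window, _ = extract_window(t, self._hit(start, start + 20), CFG)
            assert window.length <= 150 + 20 + 150


class TestScanPrecursor:
    def test_verbatim_plant(self, rng):
        known = NucSequence("k", random_rna(rng, 90))
        t = NucSequence("t", random_rna(rng, 100) + known.seq + random_rna(rng, 100))
        (hit,) = [h for h in scan_precursor(known, t, CFG) if h.strand == "+"]
        assert (hit.start, hit.end, hit.mismatches) == (100, 190, 0)

    def test_ninety_percent_identity_with_intact_seed(self, rng):
        known = NucSequence("k", random_rna(rng, 90))
        # 9 substitutions, none inside the 28-mer block [10, 38)
        mutated = _mutate(known.seq, [0, 3, 7, 40, 50, 60, 70, 80, 88])
        t = NucSequence("t", random_rna(rng, 50) + mutated + random_rna(rng, 50))
        hits = [h for h in scan_precursor(known, t, CFG) if h.strand == "+"]
        assert hits and hits[0].mismatches == 9  # identity exactly 0.90

    def test_no_exact_seed_no_hit(self, rng):
        known = NucSequence("k", random_rna(rng, 90))
        mutated = _mutate(known.seq, range(0, 90, 20))  # breaks every 28-mer
        t = NucSequence("t", random_rna(rng, 50) + mutated + random_rna(rng, 50))
        assert [h for h in scan_precursor(known, t, PLUS_ONLY)] == []

    def test_short_known_rejected(self):
        with pytest.raises(ValueError):
            scan_precursor(NucSequence("k", "ACGU" * 5), NucSequence("t", "ACGU" * 30), CFG)
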