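"""Pairing classification, weighted mismatch counting, filters, and transcript scanning."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptarget.duplex import (
    DuplexError,
    FilterCriteria,
    MatureMiRNA,
    MismatchWeights,
    align_duplex,
    check_criteria,
    classify_pair,
    normalize_rna,
    perfect_complement,
    scan_transcript,
    weighted_mismatch,
)
from conftest import random_rna

WEIGHT = {"|": 0.0, "o": 0.5, "x": 1.0}

rna_base = st.sampled_from("ACGU")
rna_seq = st.text(alphabet="ACGU", min_size=1, max_size=30)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "m, t, symbol",
        [
            ("U", "A", "|"), ("A", "U", "|"), ("G", "C", "|"), ("C", "G", "|"),
            ("G", "U", "o"), ("U", "G", "o"),
            ("G", "G", "x"), ("A", "A", "x"), ("C", "U", "x"), ("A", "C", "x"),
        ],
    )
    def test_pair_vocabulary(self, m, t, symbol):
        assert classify_pair(m, t) == symbol

    def test_rejects_non_rna(self):
        with pytest.raises(DuplexError, match="T"):
            classify_pair("T", "A")

    @given(m=rna_base, t=rna_base)
    @settings(derandomize=True)
    def test_symmetric_for_paired_classes(self, m, t):
        # Watson-Crick and wobble pairs survive a strand swap; mismatch class too
        assert classify_pair(m, t) == classify_pair(t, m)


class TestAlignDuplex:
    def test_published_row(self, mirna):
        d = align_duplex(mirna, "AGGUGGGGCCGGAAGUACCU")
        assert d.pairing == "||||x||||||x||x||||x"

    def test_perfect_complement_is_all_watson_crick(self, mirna):
        d = align_duplex(mirna, "AGGUCGGGCCGCAACUACCG")
        assert d.pairing == "|" * 20
        assert perfect_complement(mirna.seq) == "AGGUCGGGCCGCAACUACCG"

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_mixed_example(self):
        mi = MatureMiRNA("mini", "UCGA")
        assert align_duplex(mi, "AGUU").pairing == "||o|"

    def test_unequal_lengths_rejected(self, mirna):
        with pytest.raises(DuplexError, match="equal lengths"):
            align_duplex(mirna, "AGGU")

    def test_site_orientation_roundtrip(self, mirna):
        d = align_duplex(mirna, "AGGUGGGGCCGGAAGUACCU")
        assert d.site_5to3 == "UCCAUGAAGGCCGGGGUGGA"
        assert d.site_5to3[::-1] == d.site_3to5

    def test_dna_input_normalized(self):
        mi = MatureMiRNA("dna", "tccagcccggcgttgatggc")
        assert mi.seq == "UCCAGCCCGGCGUUGAUGGC"
        assert normalize_rna("ACGT") == "ACGU"


class TestWeightedMismatch:
    def test_five_prime_window_of_published_row(self, mirna):
        d = align_duplex(mirna, "GGGCGGGGCCGCAGCUACCG")  # pairing o||xx||||||||o||||||
        assert weighted_mismatch(d, (1, 12)) == 2.5

    def test_full_window_of_published_row(self, mirna):
        d = align_duplex(mirna, "AGGUCGUGCCGCAACAACGA")  # ||||||x||||||||x||xx
        assert weighted_mismatch(d, (1, 20)) == 4.0

    def test_perfect_duplex_scores_zero(self, mirna):
        d = align_duplex(mirna, perfect_complement(mirna.seq))
        assert weighted_mismatch(d) == 0.0

    def test_inverted_window_rejected(self, mirna):
        d = align_duplex(mirna, perfect_complement(mirna.seq))
        with pytest.raises(DuplexError, match="inverted"):
            weighted_mismatch(d, (5, 3))
        with pytest.raises(DuplexError, match="outside"):
            weighted_mismatch(d, (1, 25))

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @given(seq=st.text(alphabet="ACGU", min_size=2, max_size=25), data=st.data())
    @settings(derandomize=True, max_examples=60)
    def test_additive_over_disjoint_windows(self, seq, data):
        mi = MatureMiRNA("h", seq)
        site = data.draw(st.text(alphabet="ACGU", min_size=len(seq), max_size=len(seq)))
        d = align_duplex(mi, site)
        n = len(seq)
        cut = data.draw(st.integers(min_value=1, max_value=n - 1))
        left = weighted_mismatch(d, (1, cut))
        right = weighted_mismatch(d, (cut + 1, n))
        total = weighted_mismatch(d, (1, n))
        assert total == pytest.approx(left + right)
        # monotone non-decreasing in window size
        assert total >= left and total >= right


class TestCheckCriteria:
    def test_published_row_with_adequate_energy_passes(self, mirna):
        d = align_duplex(mirna, "AGGUGGGGCCGGAAGUACCU")  # 4 x, clean 10-11, 2.0 in 1-12
        v = check_criteria(d, energy_ratio=0.80)
        assert (v.total_ok, v.forbidden_ok, v.five_prime_ok, v.energy_ok) == (True,) * 4
        assert v.passes

    def test_mismatch_in_forbidden_window_fails(self, mirna):
        site = list(perfect_complement(mirna.seq))
        site[9] = "A"  # position 10: miRNA G vs A = x
        v = check_criteria(align_duplex(mirna, "".join(site)), energy_ratio=1.0)
        assert not v.forbidden_ok and not v.passes

    def test_five_mismatches_fail_total(self, mirna):
        site = list(perfect_complement(mirna.seq))
        for i in (0, 2, 4, 6, 8):
            site[i] = {"A": "A", "U": "U", "G": "G", "C": "C"}[mirna.seq[i]]
        v = check_criteria(align_duplex(mirna, "".join(site)), energy_ratio=1.0)
        assert not v.total_ok and not v.passes

    def test_wobble_in_forbidden_window_configurable(self, mirna):
        site = list(perfect_complement(mirna.seq))
        assert mirna.seq[9] == "G"
        site[9] = "U"  # G:U wobble at position 10
        d = align_duplex(mirna, "".join(site))
        strict = check_criteria(d, energy_ratio=1.0)
        lenient = check_criteria(
            d, energy_ratio=1.0, criteria=FilterCriteria(wobble_fails_forbidden=False)
        )
        assert not strict.forbidden_ok
        assert lenient.forbidden_ok and lenient.passes

    def test_criteria_toggles(self, mirna):
        d = align_duplex(mirna, "AGGUGGGGCCGGAAGUACCU")
        v = check_criteria(d, energy_ratio=0.1, criteria=FilterCriteria(check_energy=False))
        assert v.passes  # energy disabled, mismatch criteria pass

    def test_energy_required_when_enabled(self, mirna):
        d = align_duplex(mirna, perfect_complement(mirna.seq))
        with pytest.raises(DuplexError, match="energy"):
            check_criteria(d, energy_ratio=None)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(DuplexError):
            FilterCriteria(max_total_mismatch=-1)
        with pytest.raises(DuplexError):
            FilterCriteria(forbidden_window=(11, 10))

    def test_invalid_weights_rejected(self):
        with pytest.raises(DuplexError):
            MismatchWeights(gu_wobble=2.0, other=1.0)


def brute_force_scan(mirna, transcript, criteria):
    """Independent oracle: re-derive pairing and criteria per offset from the raw rules."""
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "U"), ("U", "G")}
    hits = []
    m = len(mirna.seq)
    for start in range(len(transcript) - m + 1):
        site = transcript[start : start + m][::-1]
        w = [
            0.0 if (a, b) in wc else (0.5 if (a, b) in wob else 1.0)
            for a, b in zip(mirna.seq, site)
        ]
        total = sum(w)
        ok = (
            total <= criteria.max_total_mismatch
            and w[9] + w[10] == 0
            and sum(w[:12]) <= criteria.max_five_prime_mismatch
        )
        if ok:
            hits.append((start, total))
    return sorted(hits, key=lambda h: (h[1], h[0]))


class TestScanTranscript:
    CRIT = FilterCriteria(check_energy=False)

    def test_planted_perfect_site_found(self, mirna, rng):
        planted = perfect_complement(mirna.seq)[::-1]
        tx = random_rna(rng, 137) + planted + random_rna(rng, 343)
        # drop coincidental hits by construction check: compare against oracle
        sites = scan_transcript(mirna, tx, self.CRIT)
        assert [(s.start, s.total_mismatch) for s in sites] == brute_force_scan(
            mirna, tx, self.CRIT
        )
        assert any(s.start == 137 and s.total_mismatch == 0.0 for s in sites)

    def test_short_transcript_returns_empty(self, mirna):
        assert scan_transcript(mirna, "ACGUACGU", self.CRIT) == []

    def test_empty_mirna_rejected(self):
        with pytest.raises(DuplexError):
            MatureMiRNA("empty", "")

    def test_matches_brute_force_on_random_transcripts(self, mirna, rng):
        for _ in range(30):
            tx = random_rna(rng, 200)
            got = [(s.start, s.total_mismatch) for s in scan_transcript(mirna, tx, self.CRIT)]
            assert got == brute_force_scan(mirna, tx, self.CRIT)

    def test_best_per_transcript_takes_min_then_smallest_start(self, mirna, rng):
        planted = perfect_complement(mirna.seq)[::-1]
        tx = random_rna(rng, 50) + planted + random_rna(rng, 30) + planted + random_rna(rng, 50)
        best = scan_transcript(mirna, tx, self.CRIT, best_per_transcript=True)
        assert len(best) == 1 and best[0].start == 50

    def test_length_warning_outside_18_30(self):
        with pytest.warns(UserWarning, match="outside"):
            MatureMiRNA("short", "ACGUACGU")
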