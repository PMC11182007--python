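import numpy as np
import pytest

from thermoscan.descriptor import parse_descriptor, sample_instance
from thermoscan.scanner import (
    ElementSpan,
    InvalidMatchError,
    InvalidSequenceError,
    MotifMatch,
    ScanConfig,
    brute_force_scan,
    revcomp,
    scan_sequence,
    verify_match,
)

from _fuzz import random_descriptor, random_sequence


def match_tuple(m):
    return (m.strand, m.start, m.end,
            tuple((sp.element_id, sp.start, sp.end, sp.realized) for sp in m.spans))


class TestBasics:
    def test_single_n_element(self):
        d = parse_descriptor("s1\ns1 0 N")
        ms = scan_sequence("ACGU", d, ScanConfig(strand_mode="forward"))
        assert len(ms) == 4
        assert [m.start for m in ms] == [0, 1, 2, 3]

    def test_all_a_sequence_no_fouru_match(self, fouru):
        assert scan_sequence("A" * 120, fouru) == []

    def test_sequence_shorter_than_min_span(self, fouru):
        assert scan_sequence("ACGU" * 9, fouru) == []  # 36 < 40

    def test_invalid_characters_rejected(self, fouru):
        with pytest.raises(InvalidSequenceError):
            scan_sequence("ACGU!!", fouru)

    def test_empty_sequence_rejected(self, fouru):
        with pytest.raises(InvalidSequenceError):
            scan_sequence("", fouru)

    def test_dna_input_accepted(self):
        d = parse_descriptor("s1\ns1 0 AUG")
        ms = scan_sequence("catgc", d, ScanConfig(strand_mode="forward"))
        assert len(ms) == 1 and ms[0].spans[0].realized == "AUG"

    def test_subject_ambiguity_codes(self):
        d = parse_descriptor("s1 s2\ns1 0 A\ns2 0 N")
        # subject N matches pattern N but never a literal
        assert scan_sequence("NN", d, ScanConfig(strand_mode="forward")) == []
        ms = scan_sequence("AN", d, ScanConfig(strand_mode="forward"))
        assert len(ms) == 1

    def test_mismatch_allowance(self):
        d = parse_descriptor("s1\ns1 1 AAAA")
        ms = scan_sequence("AAGA", d, ScanConfig(strand_mode="forward"))
        assert len(ms) == 1
        d0 = parse_descriptor("s1\ns1 0 AAAA")
        assert scan_sequence("AAGA", d0, ScanConfig(strand_mode="forward")) == []

    def test_max_matches_cap(self):
        d = parse_descriptor("s1\ns1 0 N")
        ms = scan_sequence("ACGU", d, ScanConfig(strand_mode="forward", max_matches=2))
        assert len(ms) == 2

    def test_leftmost_shortest_per_start(self):
        d = parse_descriptor("s1\ns1 0 A*")
        ms = scan_sequence("AAA", d, ScanConfig(strand_mode="forward",
                                                overlap_policy="leftmost_shortest_per_start"))
        assert [(m.start, m.end) for m in ms] == [(0, 1), (1, 2), (2, 3)]


class TestPlantAndRecover:
    def test_planted_instance_recovered_with_truth_spans(self, fouru, rng):
        seq, truth = sample_instance(fouru, rng)
        bg = random_sequence(rng, 30)
        s = bg + seq + random_sequence(rng, 40)
        ms = scan_sequence(s, fouru)
        want = tuple((t, a + 30, b + 30, r) for t, (a, b, r) in truth.items())
        got = {tuple((sp.element_id, sp.start, sp.end, sp.realized) for sp in m.spans)
               for m in ms if m.strand == "+"}
        assert want in got

    def test_recall_over_many_seeded_plants(self, fouru):
        rng = np.random.default_rng(11)
        n, found = 1000, 0
        for _ in range(n):
            seq, truth = sample_instance(fouru, rng)
            s = random_sequence(rng, 10) + seq + random_sequence(rng, 10)
            ms = scan_sequence(s, fouru, ScanConfig(strand_mode="forward"))
            want = tuple((t, a + 10, b + 10, r) for t, (a, b, r) in truth.items())
            if any(tuple((sp.element_id, sp.start, sp.end, sp.realized)
                         for sp in m.spans) == want for m in ms):
                found += 1
        assert found == n


class TestOracleEquivalence:
    def test_fouru_descriptor_case(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        s = random_sequence(rng, 25) + seq + random_sequence(rng, 25)
        assert scan_sequence(s, fouru) == brute_force_scan(s, fouru)

    def test_fuzzed_cases(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            d = random_descriptor(rng)
            s = random_sequence(rng, int(rng.integers(20, 200)))
            assert scan_sequence(s, d) == brute_force_scan(s, d)

    def test_fuzzed_with_planted_instance(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            d = random_descriptor(rng)
            inst, _ = sample_instance(d, rng)
            s = random_sequence(rng, 40) + inst + random_sequence(rng, 40)
            fast, slow = scan_sequence(s, d), brute_force_scan(s, d)
            assert fast == slow
            assert len(fast) >= 1


class TestStrandSymmetry:
    def test_minus_matches_equal_forward_on_revcomp(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        s = random_sequence(rng, 20) + revcomp(seq) + random_sequence(rng, 20)
        L = len(s)
        minus = [m for m in scan_sequence(s, fouru) if m.strand == "-"]
        fwd_rc = scan_sequence(revcomp(s), fouru, ScanConfig(strand_mode="forward"))
        assert len(minus) == len(fwd_rc) > 0
        mapped = sorted((L - m.end, L - m.start,
                         tuple((sp.element_id, L - sp.end, L - sp.start, sp.realized)
                               for sp in m.spans)) for m in minus)
        orig = sorted((m.start, m.end,
                       tuple((sp.element_id, sp.start, sp.end, sp.realized)
                             for sp in m.spans)) for m in fwd_rc)
        assert mapped == orig

    def test_forward_mode_reports_no_minus(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        ms = scan_sequence(revcomp(seq), fouru, ScanConfig(strand_mode="forward"))
        assert all(m.strand == "+" for m in ms)
        both = scan_sequence(revcomp(seq), fouru)
        assert any(m.strand == "-" for m in both)


class TestDeterminism:
    def test_repeated_scans_identical(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        s = random_sequence(rng, 30) + seq + random_sequence(rng, 30)
        assert scan_sequence(s, fouru) == scan_sequence(s, fouru)

    def test_order_contract(self):
        d = parse_descriptor("s1\ns1 0 N*")
        ms = scan_sequence("ACG", d, ScanConfig(strand_mode="forward"))
        keys = [m.sort_key() for m in ms]
        assert keys == sorted(keys)


class TestVerifyMatch:
    def test_emitted_matches_verify(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        s = random_sequence(rng, 15) + seq + random_sequence(rng, 15)
        ms = scan_sequence(s, fouru)
        assert ms and all(verify_match(s, fouru, m) for m in ms)

    def test_broken_pairing_fails(self, fouru, rng):
        seq, truth = sample_instance(fouru, rng)
        ms = scan_sequence(seq, fouru, ScanConfig(strand_mode="forward"))
        m = ms[0]
        # flip one base inside the h2 5' strand to violate pairing, keeping
        # the stored spans as they were
        sp5 = m.span_for("h2")
        sp3 = m.span_for("h2'")
        L = len(sp5.realized)
        i = next(i for i in range(L)
                 if not fouru.pairing.allows("G", sp3.realized[L - 1 - i])
                 or sp5.realized[i] != "G")
        mutated = None
        for b in "ACGU":
            if b != sp5.realized[i] and not fouru.pairing.allows(b, sp3.realized[L - 1 - i]):
                mutated = sp5.realized[:i] + b + sp5.realized[i + 1:]
                break
        assert mutated is not None
        seq2 = seq[:sp5.start] + mutated + seq[sp5.end:]
        spans2 = tuple(
            ElementSpan(sp.element_id, sp.start, sp.end,
                        mutated if sp.element_id == "h2" else sp.realized, sp.mask)
            for sp in m.spans)
        m2 = MotifMatch(m.sequence_id, m.strand, m.start, m.end, spans2)
        assert verify_match(seq2, fouru, m2) is False

    def test_reordered_spans_error(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        m = scan_sequence(seq, fouru, ScanConfig(strand_mode="forward"))[0]
        spans = list(m.spans)
        spans[0], spans[1] = spans[1], spans[0]
        bad = MotifMatch(m.sequence_id, m.strand, m.start, m.end, tuple(spans))
        with pytest.raises(InvalidMatchError):
            verify_match(seq, fouru, bad)

    def test_out_of_bounds_error(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        m = scan_sequence(seq, fouru, ScanConfig(strand_mode="forward"))[0]
        bad = MotifMatch(m.sequence_id, m.strand, m.start, len(seq) + 10, m.spans)
        with pytest.raises(InvalidMatchError):
            verify_match(seq, fouru, bad)

    def test_minus_strand_matches_verify(self, fouru, rng):
        seq, _ = sample_instance(fouru, rng)
        s = random_sequence(rng, 10) + revcomp(seq) + random_sequence(rng, 10)
        minus = [m for m in scan_sequence(s, fouru) if m.strand == "-"]
        assert minus and all(verify_match(s, fouru, m) for m in minus)
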