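import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from natpipe import nat_discovery as nd
from natpipe.io_formats import GenomeInterval

from conftest import make_transcript, random_seq

PARAMS = nd.AlignmentParams()


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_best_blocks(seq_a: str, seq_b: str, params: nd.AlignmentParams):
    """All-diagonals complementarity scan, written with numpy prefix sums
    (independent of the seeded Kadane scan in the implementation)."""
    rc_b = nd.reverse_complement(seq_b)
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(rc_b.encode(), dtype=np.uint8)
    blocks = []
    for diag in range(-(len(b) - 1), len(a)):
        i_lo, i_hi = max(0, diag), min(len(a), len(b) + diag)
        if i_hi - i_lo < 1:
            continue
        match = (a[i_lo:i_hi] == b[i_lo - diag:i_hi - diag]) \
            & (a[i_lo:i_hi] != ord("N"))
        steps = np.where(match, params.match_score, params.mismatch_penalty)
        prefix = np.concatenate([[0], np.cumsum(steps)])
        run_min = np.minimum.accumulate(prefix[:-1])
        gains = prefix[1:] - run_min
        if gains.max() <= 0:
            continue
        end_rel = int(np.argmax(gains))  # earliest maximal end
        start_rel = int(np.argmin(prefix[:end_rel + 1]))  # earliest minimum
        score = int(gains[end_rel])
        a_start, a_end = i_lo + start_rel, i_lo + end_rel + 1
        matches = int(match[start_rel:end_rel + 1].sum())
        length = a_end - a_start
        if length < params.min_overlap or matches / length < params.min_identity:
            continue
        j_start, j_end = a_start - diag, a_end - diag
        blocks.append((a_start, a_end, len(seq_b) - j_end, len(seq_b) - j_start,
                       matches, length, score))
    blocks.sort(key=lambda t: (-t[6], t[0], t[2]))
    return blocks


def oracle_call_pairs(transcripts, params: nd.AlignmentParams):
    """Brute-force all-pairs scan at identical thresholds."""
    out = []
    for i in range(len(transcripts)):
        for j in range(i + 1, len(transcripts)):
            ta, tb = sorted((transcripts[i], transcripts[j]),
                            key=lambda t: t.transcript_id)
            blocks = oracle_best_blocks(ta.sequence, tb.sequence, params)
            if not blocks:
                continue
            a0, a1, b0, b1, matches, length, score = blocks[0]
            ev = params.k * len(ta) * len(tb) * math.exp(-params.lambda_ * score)
            if ev > params.evalue_max:
                continue
            out.append((ta.transcript_id, tb.transcript_id,
                        (a0, a1), (b0, b1), length, score))
    return sorted(out)


def oracle_locus_class(a: GenomeInterval, b: GenomeInterval) -> str:
    same_chrom = a.chromosome == b.chromosome
    overlap = max(0, min(a.end, b.end) - max(a.start, b.start)) > 0
    opposite = a.strand != b.strand
    return "cis" if (same_chrom and overlap and opposite) else "trans"


def oracle_orientation(a: GenomeInterval, b: GenomeInterval) -> str:
    if (a.start <= b.start and b.end <= a.end) or \
       (b.start <= a.start and a.end <= b.end):
        return "enclosed"
    plus = a if a.strand == "+" else b
    minus = b if a.strand == "+" else a
    return "convergent" if plus.start < minus.start else "divergent"


# ---------------------------------------------------------------------------
# reverse_complement
# ---------------------------------------------------------------------------

class TestReverseComplement:
    def test_palindrome(self):
        assert nd.reverse_complement("ACGT") == "ACGT"

    def test_simple(self):
        assert nd.reverse_complement("AAAC") == "GTTT"

    def test_n_maps_to_n(self):
        assert nd.reverse_complement("ANT") == "ANT"

    def test_illegal(self):
        with pytest.raises(ValueError):
            nd.reverse_complement("ACGU")

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=200))
    def test_involution(self, s):
        assert nd.reverse_complement(nd.reverse_complement(s)) == s


# ---------------------------------------------------------------------------
# find_antisense_blocks
# ---------------------------------------------------------------------------

class TestFindAntisenseBlocks:
    def test_perfect_antisense(self, rng):
        s = random_seq(rng, 100)
        blocks = nd.find_antisense_blocks(s, nd.reverse_complement(s), PARAMS)
        assert blocks[0].on_a == (0, 100)
        assert blocks[0].on_b == (0, 100)
        assert blocks[0].identity == 1.0

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(25):
            sa, sb = random_seq(rng, 200), random_seq(rng, 200)
            got = [(b.on_a, b.on_b, b.matches, b.length, b.score)
                   for b in nd.find_antisense_blocks(sa, sb, PARAMS)]
            want = [((a0, a1), (b0, b1), m, ln, sc)
                    for a0, a1, b0, b1, m, ln, sc in oracle_best_blocks(sa, sb, PARAMS)]
            assert got == want

    def test_identity_invisible(self, rng):
        s = random_seq(rng, 200)
        assert nd.find_antisense_blocks(s, s, PARAMS) == []

    def test_planted_block_in_background(self, rng):
        block = random_seq(rng, 60)
        sa = random_seq(rng, 70) + block + random_seq(rng, 70)
        sb = random_seq(rng, 30) + nd.reverse_complement(block) + random_seq(rng, 50)
        blocks = nd.find_antisense_blocks(sa, sb, PARAMS)
        assert blocks
        best = blocks[0]
        assert best.on_a[0] <= 70 and best.on_a[1] >= 130
        assert best.identity >= 0.95


class TestEvalue:
    def test_score_zero_closed_form(self):
        e = nd.karlin_altschul_evalue(0, 100, 200, PARAMS)
        assert e == pytest.approx(PARAMS.k * 100 * 200)

    def test_length_linearity(self):
        e1 = nd.karlin_altschul_evalue(10, 100, 100, PARAMS)
        e2 = nd.karlin_altschul_evalue(10, 200, 100, PARAMS)
        assert e2 == pytest.approx(2 * e1)

    def test_hand_computation(self):
        # independent closed-form evaluation, frozen
        e = nd.karlin_altschul_evalue(30, 1000, 1000, PARAMS)
        assert e == pytest.approx(0.621 * 1e6 * math.exp(-1.33 * 30), rel=1e-12)
        assert e == pytest.approx(2.8316e-12, rel=1e-3)

    def test_monotone_in_score(self):
        evs = [nd.karlin_altschul_evalue(s, 500, 500, PARAMS) for s in range(50)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            nd.karlin_altschul_evalue(-1, 10, 10, PARAMS)


# ---------------------------------------------------------------------------
# call_nat_pairs
# ---------------------------------------------------------------------------

class TestCallNatPairs:
    def test_exact_antisense_pair(self, rng):
        s = random_seq(rng, 500)
        ts = [make_transcript("x", s), make_transcript("y", nd.reverse_complement(s))]
        pairs = nd.call_nat_pairs(ts, PARAMS)
        assert len(pairs) == 1
        assert pairs[0].overlap_length == 500

    def test_shared_antisense_partner(self, rng):
        core = random_seq(rng, 120)
        partner = make_transcript("partner", random_seq(rng, 40)
                                  + nd.reverse_complement(core) + random_seq(rng, 40))
        family = [make_transcript(f"para{i}",
                                  random_seq(rng, 30) + core + random_seq(rng, 30))
                  for i in range(3)]
        pairs = nd.call_nat_pairs(family + [partner], PARAMS)
        assert len(pairs) == 3
        assert all("partner" in (p.id_a, p.id_b) for p in pairs)

    def test_random_transcripts_no_pairs(self, rng):
        ts = [make_transcript(f"t{i}", random_seq(rng, 300)) for i in range(50)]
        assert nd.call_nat_pairs(ts, PARAMS) == []

    def test_oracle_equivalence_small(self, rng):
        for _ in range(5):
            ts = [make_transcript(f"t{i}", random_seq(rng, 150)) for i in range(6)]
            block = random_seq(rng, 50)
            ts.append(make_transcript("p1", random_seq(rng, 40) + block
                                      + random_seq(rng, 40)))
            ts.append(make_transcript("p2", random_seq(rng, 20)
                                      + nd.reverse_complement(block)
                                      + random_seq(rng, 60)))
            got = sorted((p.id_a, p.id_b, p.overlap_on_a, p.overlap_on_b,
                          p.overlap_length, p.alignment_score)
                         for p in nd.call_nat_pairs(ts, PARAMS))
            assert got == oracle_call_pairs(ts, PARAMS)

    def test_input_order_invariance(self, rng):
        block = random_seq(rng, 80)
        ts = [make_transcript("a", block + random_seq(rng, 100)),
              make_transcript("b", nd.reverse_complement(block) + random_seq(rng, 50)),
              make_transcript("c", random_seq(rng, 150))]
        forward = nd.call_nat_pairs(ts, PARAMS)
        backward = nd.call_nat_pairs(ts[::-1], PARAMS)
        assert forward == backward

    def test_threshold_monotonicity(self, rng):
        blocks = [random_seq(rng, ln) for ln in (40, 60, 120)]
        ts = []
        for i, b in enumerate(blocks):
            ts.append(make_transcript(f"s{i}", random_seq(rng, 50) + b
                                      + random_seq(rng, 50)))
            ts.append(make_transcript(f"t{i}", random_seq(rng, 30)
                                      + nd.reverse_complement(b)
                                      + random_seq(rng, 70)))
        base = {(p.id_a, p.id_b) for p in nd.call_nat_pairs(ts, PARAMS)}
        import dataclasses
        stricter_e = dataclasses.replace(PARAMS, evalue_max=1e-30)
        stricter_o = dataclasses.replace(PARAMS, min_overlap=100)
        assert {(p.id_a, p.id_b)
                for p in nd.call_nat_pairs(ts, stricter_e)} <= base
        assert {(p.id_a, p.id_b)
                for p in nd.call_nat_pairs(ts, stricter_o)} <= base


# ---------------------------------------------------------------------------
# locus classification
# ---------------------------------------------------------------------------

def _dummy_pair(ida="a", idb="b", cls="unset"):
    return nd.NATPair(ida, idb, (0, 50), (0, 50), 50, 50, 1e-20,
                      locus_class=cls)


class TestClassifyLocus:
    def test_cis(self):
        ann = {"a": GenomeInterval("chr1", 100, 600, "+"),
               "b": GenomeInterval("chr1", 400, 900, "-")}
        assert nd.classify_locus(_dummy_pair(), ann) == "cis"

    def test_different_chromosomes(self):
        ann = {"a": GenomeInterval("chr1", 100, 600, "+"),
               "b": GenomeInterval("chr2", 400, 900, "-")}
        assert nd.classify_locus(_dummy_pair(), ann) == "trans"

    def test_same_strand_overlap_is_trans(self):
        ann = {"a": GenomeInterval("chr1", 100, 600, "+"),
               "b": GenomeInterval("chr1", 400, 900, "+")}
        assert nd.classify_locus(_dummy_pair(), ann) == "trans"

    def test_missing_annotation(self):
        with pytest.raises(KeyError, match="'b'"):
            nd.classify_locus(_dummy_pair(),
                              {"a": GenomeInterval("chr1", 0, 10, "+")})

    def test_decision_table(self):
        cases = []
        for chrom_b in ("chr1", "chr2"):
            for b_span in ((400, 900), (700, 900)):
                for strand_b in "+-":
                    cases.append(GenomeInterval(chrom_b, *b_span, strand_b))
        a = GenomeInterval("chr1", 100, 600, "+")
        for b in cases:
            ann = {"a": a, "b": b}
            assert nd.classify_locus(_dummy_pair(), ann) == oracle_locus_class(a, b)


class TestCisOrientation:
    def _classify(self, a, b):
        ann = {"a": a, "b": b}
        pair = _dummy_pair(cls="cis")
        return nd.classify_cis_orientation(pair, ann)

    def test_convergent(self):
        assert self._classify(GenomeInterval("c", 100, 500, "+"),
                              GenomeInterval("c", 400, 700, "-")) == "convergent"

    def test_divergent(self):
        assert self._classify(GenomeInterval("c", 100, 500, "-"),
                              GenomeInterval("c", 400, 700, "+")) == "divergent"

    def test_enclosed(self):
        assert self._classify(GenomeInterval("c", 100, 900, "+"),
                              GenomeInterval("c", 300, 500, "-")) == "enclosed"

    def test_trans_pair_rejected(self):
        with pytest.raises(ValueError):
            nd.classify_cis_orientation(_dummy_pair(cls="trans"), {})

    def test_randomized_against_oracle(self):
        rnd = random.Random(7)
        for _ in range(2000):
            s1 = rnd.randrange(1000)
            e1 = s1 + 1 + rnd.randrange(500)
            s2 = rnd.randrange(max(s1 - 100, 0), e1)  # force overlap
            e2 = s2 + 1 + rnd.randrange(500)
            if min(e1, e2) <= max(s1, s2):
                continue
            strand_a = rnd.choice("+-")
            a = GenomeInterval("c", s1, e1, strand_a)
            b = GenomeInterval("c", s2, e2, "-" if strand_a == "+" else "+")
            assert self._classify(a, b) == oracle_orientation(a, b)


class TestDegreeAndMembership:
    def test_degree_simple(self):
        pairs = [_dummy_pair("a", "b"), _dummy_pair("a", "c")]
        got = {d.transcript_id: d.n_antisense_partners
               for d in nd.antisense_degree(pairs)}
        assert got == {"a": 2, "b": 1, "c": 1}

    def test_degree_empty(self):
        assert nd.antisense_degree([]) == []

    def test_degree_random_matches_naive(self, rng):
        names = [f"t{i}" for i in range(20)]
        pairs = []
        seen = set()
        for _ in range(40):
            x, y = sorted(rng.sample(names, 2))
            if (x, y) in seen:
                continue
            seen.add((x, y))
            pairs.append(_dummy_pair(x, y))
        naive = {}
        for x, y in seen:
            naive.setdefault(x, set()).add(y)
            naive.setdefault(y, set()).add(x)
        got = {d.transcript_id: d.n_antisense_partners
               for d in nd.antisense_degree(pairs)}
        assert got == {k: len(v) for k, v in naive.items()}

    def test_membership(self):
        pairs = [_dummy_pair("a", "b", cls="cis"),
                 _dummy_pair("a", "c", cls="trans"),
                 _dummy_pair("d", "e", cls="trans")]
        part = nd.cross_class_membership(pairs)
        assert part["both"] == {"a"}
        assert part["cis_only"] == {"b"}
        assert part["trans_only"] == {"c", "d", "e"}
        universe = part["both"] | part["cis_only"] | part["trans_only"]
        assert universe == {"a", "b", "c", "d", "e"}

    def test_membership_disjoint(self):
        pairs = [_dummy_pair("a", "b", cls="cis"),
                 _dummy_pair("c", "d", cls="trans")]
        assert nd.cross_class_membership(pairs)["both"] == set()

    def test_membership_requires_class(self):
        with pytest.raises(ValueError):
            nd.cross_class_membership([_dummy_pair("a", "b")])
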