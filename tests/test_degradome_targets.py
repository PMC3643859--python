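import itertools

import pytest

from natpipe import degradome_targets as dt
from natpipe.io_formats import AbundanceRead
from natpipe.nat_discovery import NATPair, reverse_complement

from conftest import make_transcript, random_seq


def oracle_rule(positions):
    """The three-clause predicate, written independently."""
    in_seed = [p for p in positions if 1 <= p <= 9]
    in_cleavage = [p for p in positions if p in (10, 11)]
    after = [p for p in positions if p >= 12]
    return (len(in_seed) < 2) and (len(in_cleavage) == 0) and (len(after) < 3)


class TestMapDegradome:
    def test_exact_placement(self, rng):
        t = make_transcript("t1", random_seq(rng, 200))
        tag = AbundanceRead("g", t.sequence[50:70], 3)
        hits = dt.map_degradome([tag], [t])
        assert [(h.transcript_id, h.position) for h in hits] == [("t1", 50)]

    def test_one_mismatch_no_hit(self, rng):
        t = make_transcript("t1", random_seq(rng, 200))
        seq = t.sequence[50:70]
        bad = ("A" if seq[5] != "A" else "C")
        tag = AbundanceRead("g", seq[:5] + bad + seq[6:], 3)
        assert dt.map_degradome([tag], [t]) == []

    def test_random_against_naive(self, rng):
        transcripts = [make_transcript(f"t{i}", random_seq(rng, 150))
                       for i in range(10)]
        tags = []
        for i in range(100):
            if rng.random() < 0.5:
                t = transcripts[rng.randrange(10)]
                s = rng.randrange(len(t.sequence) - 20)
                tags.append(AbundanceRead(f"g{i}", t.sequence[s:s + 20], 1))
            else:
                tags.append(AbundanceRead(f"g{i}", random_seq(rng, 20), 1))
        got = {(h.transcript_id, h.position, h.sequence)
               for h in dt.map_degradome(tags, transcripts)}
        want = set()
        for tag in tags:
            for t in transcripts:
                start = t.sequence.find(tag.sequence)
                while start != -1:
                    want.add((t.transcript_id, start, tag.sequence))
                    start = t.sequence.find(tag.sequence, start + 1)
        assert got == want


class TestLongDegradome:
    def test_interior_window(self, rng):
        t = make_transcript("t1", random_seq(rng, 1000))
        hit = dt.DegradomeHit(t.sequence[100:120], 1, "t1", 100)
        ld = dt.extract_long_degradome(t, hit)
        assert ld.window == (80, 140)
        assert ld.anchor == 100

    def test_left_clipped(self, rng):
        t = make_transcript("t1", random_seq(rng, 1000))
        hit = dt.DegradomeHit(t.sequence[5:25], 1, "t1", 5)
        ld = dt.extract_long_degradome(t, hit)
        assert ld.window == (0, 45)

    def test_right_clipped(self, rng):
        t = make_transcript("t1", random_seq(rng, 100))
        hit = dt.DegradomeHit(t.sequence[75:95], 1, "t1", 75)
        ld = dt.extract_long_degradome(t, hit)
        assert ld.window == (55, 100)

    def test_slice_identity(self, rng):
        t = make_transcript("t1", random_seq(rng, 500))
        for _ in range(30):
            pos = rng.randrange(480)
            hit = dt.DegradomeHit(t.sequence[pos:pos + 20], 1, "t1", pos)
            ld = dt.extract_long_degradome(t, hit)
            assert ld.sequence == t.sequence[ld.window[0]:ld.window[1]]


class TestScanCandidateSites:
    def _window(self, seq, start=0, tid="t1"):
        return dt.LongDegradome(tid, (start, start + len(seq)), seq, start)

    def test_perfect_site(self, rng):
        sirna = random_seq(rng, 21)
        flank_l, flank_r = random_seq(rng, 15), random_seq(rng, 15)
        window = self._window(flank_l + reverse_complement(sirna) + flank_r)
        exact = [s for s in dt.scan_candidate_sites(sirna, window)
                 if s.mismatch_positions == ()]
        assert len(exact) == 1
        assert exact[0].site == (15, 36)

    def test_position_ten_coordinate(self, rng):
        sirna = random_seq(rng, 21)
        site = list(reverse_complement(sirna))
        j = 21 - 10  # pairs siRNA position 10
        site[j] = next(b for b in "ACGT" if b != site[j])
        window = self._window("".join(site))
        sites = dt.scan_candidate_sites(sirna, window)
        assert [s.mismatch_positions for s in sites] == [(10,)]

    def test_exhaustive_substitution_variants(self, rng):
        sirna = random_seq(rng, 21)
        perfect = reverse_complement(sirna)
        for k in (1, 2, 3):
            for combo in itertools.combinations(range(21), k):
                site = list(perfect)
                for j in combo:
                    site[j] = "ACGT"[(("ACGT".index(site[j])) + 1) % 4]
                window = self._window("".join(site))
                sites = dt.scan_candidate_sites(sirna, window)
                planted = tuple(sorted(21 - j for j in combo))
                assert any(s.mismatch_positions == planted for s in sites)

    def test_four_mismatches_rejected(self, rng):
        sirna = random_seq(rng, 21)
        site = list(reverse_complement(sirna))
        for j in (0, 5, 10, 15):
            site[j] = "ACGT"[("ACGT".index(site[j]) + 1) % 4]
        window = self._window("".join(site))
        assert dt.scan_candidate_sites(sirna, window) == []

    def test_too_long_sirna(self):
        window = self._window("ACGTACGT")
        assert dt.scan_candidate_sites("A" * 20, window) == []


class TestSchwabFilter:
    def test_perfect(self):
        assert dt.schwab_filter(()) is True

    def test_position_ten_rejected(self):
        assert dt.schwab_filter((10,)) is False

    def test_two_seed_mismatches_rejected(self):
        assert dt.schwab_filter((1, 2)) is False

    def test_mixed_accept(self):
        assert dt.schwab_filter((3, 14, 20)) is True

    def test_truth_table(self):
        for k in range(4):
            for combo in itertools.combinations(range(1, 25), k):
                assert dt.schwab_filter(combo) == oracle_rule(combo), combo

    def test_position_beyond_length(self):
        with pytest.raises(ValueError):
            dt.schwab_filter((22,), sirna_len=21)


def _pair(ida, idb):
    a, b = sorted((ida, idb))
    return NATPair(a, b, (0, 50), (0, 50), 50, 50, 1e-20)


class TestClassifyOrigin:
    def test_antisense_origin(self):
        origin, multiple = dt.classify_origin(
            "X", "A", [_pair("A", "B")], {"X": {"B"}})
        assert origin == "a" and multiple is False

    def test_sense_origin(self):
        origin, _ = dt.classify_origin("X", "A", [_pair("A", "B")], {"X": {"A"}})
        assert origin == "s"

    def test_other_origin(self):
        origin, _ = dt.classify_origin("X", "A", [_pair("A", "B")], {"X": {"C"}})
        assert origin == "o"

    def test_multiple_flag(self):
        sources = {f"t{i}" for i in range(7)}
        _, multiple = dt.classify_origin("X", "A", [], {"X": sources})
        assert multiple is True
        _, multiple = dt.classify_origin("X", "A", [], {"X": set(list(sources)[:5])})
        assert multiple is False

    def test_no_source_error(self):
        with pytest.raises(ValueError):
            dt.classify_origin("X", "A", [], {})


def _planted_scenario(rng, mismatch_positions=()):
    """Source transcript carries the siRNA; target carries a complementary
    site (with planted mismatches) plus a tag anchored inside the window."""
    sirna = random_seq(rng, 21)
    source = make_transcript("src", random_seq(rng, 100) + sirna
                             + random_seq(rng, 100))
    site = list(reverse_complement(sirna))
    for p in mismatch_positions:
        j = 21 - p
        site[j] = next(b for b in "ACGT" if b != site[j])
    site_start = 150
    target_seq = (random_seq(rng, site_start) + "".join(site)
                  + random_seq(rng, 150))
    target = make_transcript("tgt", target_seq)
    tag5 = site_start + 11  # opposite siRNA positions 10/11
    tag = AbundanceRead("tag1", target_seq[tag5:tag5 + 20], 4)
    pair = _pair("src", "tgt")
    sirnas = [AbundanceRead("s1", sirna, 9)]
    dhits = dt.map_degradome([tag], [target])
    return sirna, site_start, sirnas, dhits, [pair], [source, target]


class TestCallTargets:
    def test_planted_call(self, rng):
        sirna, s0, sirnas, dhits, pairs, ts = _planted_scenario(rng)
        calls = dt.call_targets(sirnas, dhits, pairs, ts)
        assert len(calls) == 1
        call = calls[0]
        assert call.site == (s0, s0 + 21)
        assert call.origin == "a"
        assert call.mismatch_positions == ()
        assert call.sirna_abundance == 9
        assert call.tag_support == 4

    def test_mismatch_at_eleven_blocks(self, rng):
        *_, sirnas, dhits, pairs, ts = _planted_scenario(rng, (11,))
        assert dt.call_targets(sirnas, dhits, pairs, ts) == []

    def test_compliant_mismatches_pass(self, rng):
        sirna, s0, sirnas, dhits, pairs, ts = _planted_scenario(rng, (4, 15))
        calls = dt.call_targets(sirnas, dhits, pairs, ts)
        assert len(calls) == 1
        assert calls[0].mismatch_positions == (4, 15)

    def test_accepted_calls_self_verify(self, rng):
        sirna, s0, sirnas, dhits, pairs, ts = _planted_scenario(rng, (4, 15))
        seqs = {t.transcript_id: t.sequence for t in ts}
        for call in dt.call_targets(sirnas, dhits, pairs, ts):
            site = seqs[call.target_id][call.site[0]:call.site[1]]
            rc = reverse_complement(call.sirna)
            diffs = tuple(sorted(len(call.sirna) - j
                                 for j in range(len(site)) if site[j] != rc[j]))
            assert diffs == call.mismatch_positions

    def test_flank_monotonicity(self, rng):
        # a smaller window can only lose candidate sites
        for flank in (0, 5, 10, 20):
            sirna, s0, sirnas, dhits, pairs, ts = _planted_scenario(rng)
            small = dt.call_targets(sirnas, dhits, pairs, ts, flank=flank)
            full = dt.call_targets(sirnas, dhits, pairs, ts, flank=20)
            keys = lambda calls: {(c.sirna, c.target_id, c.site) for c in calls}
            assert keys(small) <= keys(full)

    def test_dedup_sums_tag_support(self, rng):
        sirna, s0, sirnas, dhits, pairs, ts = _planted_scenario(rng)
        # second distinct tag one base downstream still exposes the site
        target = ts[1]
        tag2 = AbundanceRead("tag2", target.sequence[s0 + 12:s0 + 32], 2)
        dhits2 = dhits + dt.map_degradome([tag2], [target])
        calls = dt.call_targets(sirnas, dhits2, pairs, ts)
        assert len(calls) == 1
        assert calls[0].tag_support == 6
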