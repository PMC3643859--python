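"""Seedable synthetic genomes, small RNA and degradome libraries.

The generator plants every feature the pipeline is supposed to find — NAT
pairs of all orientations, overlap-concentrated small RNA clouds with
controlled strand bias, rule-compliant and rule-violating degradome target
sites, and inverted-repeat precursors — and records the ground truth in a
manifest so downstream recovery can be scored exactly.

Every NAT transcript carries a 3' "reserved zone" of random sequence that
small RNA sampling never touches; target sites and their supporting
degradome tags are planted inside it, which keeps planted positives and
decoys free of accidental cross-talk with the sampled read cloud.

All generation draws integers from a single ``random.Random`` stream, so a
seed fixes every emitted byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AbundanceRead,
    TranscriptRecord,
    write_abundance_reads,
    write_fasta,
    write_gene_table,
)
from .nat_discovery import reverse_complement
from .sirna_profiling import EnrichmentResult, enrichment

__all__ = [
    "SimConfig",
    "SmallRNAConfig",
    "DegradomeConfig",
    "HairpinConfig",
    "SimState",
    "simulate_genome",
    "plant_hairpins",
    "simulate_smallrnas",
    "simulate_degradome",
    "simulate_all",
    "write_outputs",
    "simulate_enrichment_cohort",
]

RESERVED_LEN = 90
_SITE_ZONE_OFFSET = 30   # site start within the reserved zone

# mismatch sets planted into compliant sites / rule-violating decoys
COMPLIANT_MISMATCH_SETS = [(), (5,), (14,), (3, 15), (7, 13, 20), (12, 18)]
DECOY_MISMATCH_SETS = [(10,), (11,), (1, 5), (10, 15), (2, 8, 14), (12, 15, 11)]


@dataclass(frozen=True)
class SmallRNAConfig:
    reads_per_pair: int = 12
    length_weights: tuple[tuple[int, int], ...] = (
        (20, 1), (21, 6), (22, 4), (23, 1), (24, 6), (25, 2),
    )
    overlap_concentration: int = 5  # per-base rate multiplier inside overlaps
    bias_mix: tuple[tuple[str, int], ...] = (("One", 2), ("Equal", 1), ("Bias", 1))
    n_excluded_reads: int = 10
    abundance_continue_permille: int = 600  # geometric tail parameter


@dataclass(frozen=True)
class DegradomeConfig:
    n_targets: int = 4
    n_decoys: int = 4
    tags_per_target: int = 2
    tag_length: int = 20
    n_noise_tags: int = 15
    sirna_length: int = 21


@dataclass(frozen=True)
class HairpinConfig:
    n_planted: int = 2
    arm_length: int = 25
    loop_length: int = 10
    mature_length: int = 21


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_background_genes: int = 30
    n_cis_convergent: int = 2
    n_cis_divergent: int = 2
    n_cis_enclosed: int = 2
    n_trans_families: int = 2
    trans_family_size: int = 3
    overlap_range: tuple[int, int] = (31, 200)
    gene_length_range: tuple[int, int] = (400, 800)
    gc_permille: int = 350
    smallrna: SmallRNAConfig = field(default_factory=SmallRNAConfig)
    degradome: DegradomeConfig = field(default_factory=DegradomeConfig)
    hairpins: HairpinConfig = field(default_factory=HairpinConfig)

    def __post_init__(self) -> None:
        if self.overlap_range[0] < 31:
            raise ValueError("minimum overlap must be >= 31")
        if self.overlap_range[0] >= self.gene_length_range[0]:
            raise ValueError(
                "infeasible geometry: minimum overlap must be smaller than "
                "the minimum gene length"
            )


@dataclass
class _SimTranscript:
    transcript_id: str
    chromosome: str
    strand: str
    genomic_start: int
    genomic_end: int
    sequence: str
    is_nat: bool = False
    has_hairpin: bool = False
    source_used: bool = False
    target_used: bool = False

    def to_record(self) -> TranscriptRecord:
        return TranscriptRecord(
            self.transcript_id, self.transcript_id, self.chromosome,
            self.strand, self.genomic_start, self.genomic_end, self.sequence,
        )


@dataclass
class SimState:
    config: SimConfig
    rng: random.Random
    transcripts: dict[str, _SimTranscript] = field(default_factory=dict)
    # manifest pieces
    pairs: list[dict] = field(default_factory=list)
    strand_bias: dict[str, dict] = field(default_factory=dict)
    targets: list[dict] = field(default_factory=list)
    hairpins: list[dict] = field(default_factory=list)
    srna_reads: list[AbundanceRead] = field(default_factory=list)
    degradome_tags: list[AbundanceRead] = field(default_factory=list)
    exclusion_records: list[tuple[str, str]] = field(default_factory=list)
    excluded_read_seqs: list[str] = field(default_factory=list)

    def records(self) -> list[TranscriptRecord]:
        return [t.to_record() for t in self.transcripts.values()]

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "pairs": self.pairs,
            "strand_bias": self.strand_bias,
            "targets": self.targets,
            "hairpins": self.hairpins,
            "excluded_read_seqs": self.excluded_read_seqs,
        }


def _random_seq(rng: random.Random, n: int, gc_permille: int) -> str:
    half_gc = gc_permille // 2
    half_at = (1000 - gc_permille) // 2
    out = []
    for _ in range(n):
        r = rng.randrange(1000)
        if r < half_gc:
            out.append("G")
        elif r < 2 * half_gc:
            out.append("C")
        elif r < 2 * half_gc + half_at:
            out.append("A")
        else:
            out.append("T")
    return "".join(out)


def _log_uniform(rng: random.Random, lo: int, hi: int) -> int:
    """Integer draw, roughly uniform on a log scale over [lo, hi]."""
    if hi <= lo:
        return lo
    octaves = []
    cur = lo
    while cur <= hi:
        octaves.append((cur, min(hi, cur * 2 - 1)))
        cur *= 2
    a, b = octaves[rng.randrange(len(octaves))]
    return a + rng.randrange(b - a + 1)


def _draw_weighted(rng: random.Random, weights: tuple[tuple[int, int], ...]) -> int:
    total = sum(w for _, w in weights)
    r = rng.randrange(total)
    for value, w in weights:
        if r < w:
            return value
        r -= w
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> SimState:
    """Build the transcript set: cis pairs of each orientation, trans
    families sharing one antisense partner, and random background genes."""
    rng = random.Random(config.seed)
    state = SimState(config=config, rng=rng)
    gc = config.gc_permille
    glo, ghi = config.gene_length_range
    olo, ohi = config.overlap_range

    def gene_len() -> int:
        return glo + rng.randrange(ghi - glo + 1)

    def add(t: _SimTranscript) -> None:
        if t.is_nat:
            t.sequence += _random_seq(rng, RESERVED_LEN, gc)
        state.transcripts[t.transcript_id] = t

    offset = 1000  # genomic placement offset, cosmetic
    cis_specs = (
        [("convergent", i) for i in range(config.n_cis_convergent)]
        + [("divergent", i) for i in range(config.n_cis_divergent)]
        + [("enclosed", i) for i in range(config.n_cis_enclosed)]
    )
    for orientation, i in cis_specs:
        ga, gb = gene_len(), gene_len()
        overlap = min(_log_uniform(rng, olo, ohi), ga - 1, gb - 1)
        chrom = f"chr_cis_{orientation}_{i}"
        ida = f"cis_{orientation}_{i}_a"
        idb = f"cis_{orientation}_{i}_b"
        if orientation == "convergent":
            # + gene first, 3' ends overlap
            locus = _random_seq(rng, ga - overlap + gb, gc)
            a_span = (0, ga)
            b_span = (ga - overlap, ga - overlap + gb)
            ov_a = (ga - overlap, ga)
            ov_b = (gb - overlap, gb)
        elif orientation == "divergent":
            locus = _random_seq(rng, gb - overlap + ga, gc)
            b_span = (0, gb)
            a_span = (gb - overlap, gb - overlap + ga)
            ov_a = (0, overlap)
            ov_b = (0, overlap)
        else:  # enclosed: the minus gene is exactly the overlap, inside +
            gb = overlap
            locus = _random_seq(rng, ga, gc)
            a_span = (0, ga)
            s = 1 + rng.randrange(max(1, ga - overlap - 1))
            b_span = (s, s + overlap)
            ov_a = (s, s + overlap)
            ov_b = (0, overlap)
        seq_a = locus[a_span[0]:a_span[1]]
        seq_b = reverse_complement(locus[b_span[0]:b_span[1]])
        add(_SimTranscript(ida, chrom, "+", offset + a_span[0],
                           offset + a_span[1], seq_a, is_nat=True))
        add(_SimTranscript(idb, chrom, "-", offset + b_span[0],
                           offset + b_span[1], seq_b, is_nat=True))
        first, second = sorted((ida, idb))
        ov_first, ov_second = (ov_a, ov_b) if first == ida else (ov_b, ov_a)
        state.pairs.append({
            "id_a": first, "id_b": second, "locus_class": "cis",
            "orientation": orientation, "overlap_length": overlap,
            "overlap_on_a": list(ov_first), "overlap_on_b": list(ov_second),
        })

    for fam in range(config.n_trans_families):
        overlap = min(_log_uniform(rng, olo, ohi), glo - 1)
        block = _random_seq(rng, overlap, gc)
        partner_id = f"trans_{fam}_antisense"
        plen = gene_len()
        p_pos = rng.randrange(plen - overlap + 1)
        pseq = _random_seq(rng, plen, gc)
        pseq = pseq[:p_pos] + reverse_complement(block) + pseq[p_pos + overlap:]
        add(_SimTranscript(partner_id, f"chr_trans_{fam}_p", "+", offset,
                           offset + plen, pseq, is_nat=True))
        for j in range(config.trans_family_size):
            sid = f"trans_{fam}_sense_{j}"
            slen = gene_len()
            s_pos = rng.randrange(slen - overlap + 1)
            sseq = _random_seq(rng, slen, gc)
            sseq = sseq[:s_pos] + block + sseq[s_pos + overlap:]
            add(_SimTranscript(sid, f"chr_trans_{fam}_s{j}", "+", offset,
                               offset + slen, sseq, is_nat=True))
            first, second = sorted((partner_id, sid))
            ovp = (p_pos, p_pos + overlap)
            ovs = (s_pos, s_pos + overlap)
            ov_first, ov_second = (ovp, ovs) if first == partner_id else (ovs, ovp)
            state.pairs.append({
                "id_a": first, "id_b": second, "locus_class": "trans",
                "orientation": "not_applicable", "overlap_length": overlap,
                "overlap_on_a": list(ov_first), "overlap_on_b": list(ov_second),
            })

    for i in range(config.n_background_genes):
        length = gene_len()
        start = offset + i * (ghi + 500)
        add(_SimTranscript(f"bg_{i}", "chr_bg", "+", start, start + length,
                           _random_seq(rng, length, gc)))
    return state


# ---------------------------------------------------------------------------
# Hairpins
# ---------------------------------------------------------------------------

def plant_hairpins(state: SimState) -> SimState:
    """Overwrite a segment of selected NAT transcripts with an
    inverted-repeat precursor carrying a designated mature small RNA."""
    cfg = state.config.hairpins
    rng = state.rng
    arm, loop, mlen = cfg.arm_length, cfg.loop_length, cfg.mature_length
    if mlen > arm:
        raise ValueError("mature length cannot exceed the arm length")
    hp_len = 2 * arm + loop
    candidates = _hairpin_hosts(state, hp_len)
    if len(candidates) < cfg.n_planted:
        raise ValueError("not enough NAT transcripts to host hairpins")
    for n in range(cfg.n_planted):
        tid, lo, hi = candidates[n]
        t = state.transcripts[tid]
        arm_seq = _random_seq(rng, arm, state.config.gc_permille)
        loop_seq = _random_seq(rng, loop, state.config.gc_permille)
        precursor = arm_seq + loop_seq + reverse_complement(arm_seq)
        pos = lo + rng.randrange(hi - lo - hp_len + 1)
        t.sequence = t.sequence[:pos] + precursor + t.sequence[pos + hp_len:]
        t.has_hairpin = True
        mature_off = rng.randrange(arm - mlen + 1)
        mature_start = pos + mature_off
        state.hairpins.append({
            "transcript_id": tid,
            "hairpin_start": pos,
            "hairpin_end": pos + hp_len,
            "mature_start": mature_start,
            "mature_length": mlen,
            "mature_sequence": t.sequence[mature_start:mature_start + mlen],
        })
    return state


def _overlap_intervals(state: SimState, tid: str) -> list[tuple[int, int]]:
    out = []
    for p in state.pairs:
        if p["id_a"] == tid:
            out.append(tuple(p["overlap_on_a"]))
        elif p["id_b"] == tid:
            out.append(tuple(p["overlap_on_b"]))
    return out


def _free_segments(state: SimState, tid: str, pad: int = 0) -> list[tuple[int, int]]:
    """Segments of a NAT transcript outside overlap regions, hairpins and
    the reserved zone, shrunk by ``pad`` on each side."""
    t = state.transcripts[tid]
    avail = len(t.sequence) - (RESERVED_LEN if t.is_nat else 0)
    blocked = [(max(0, a - pad), min(avail, b + pad))
               for a, b in _overlap_intervals(state, tid)]
    for h in state.hairpins:
        if h["transcript_id"] == tid:
            blocked.append((max(0, h["hairpin_start"] - pad),
                            min(avail, h["hairpin_end"] + pad)))
    blocked.sort()
    segments = []
    cur = 0
    for a, b in blocked:
        if a > cur:
            segments.append((cur, a))
        cur = max(cur, b)
    if cur < avail:
        segments.append((cur, avail))
    return segments


def _hairpin_hosts(state: SimState, hp_len: int) -> list[tuple[str, int, int]]:
    hosts = []
    for tid in sorted(state.transcripts):
        t = state.transcripts[tid]
        if not t.is_nat or t.has_hairpin:
            continue
        for lo, hi in _free_segments(state, tid, pad=5):
            if hi - lo >= hp_len + 2:
                hosts.append((tid, lo, hi))
                break
    return hosts


# ---------------------------------------------------------------------------
# Small RNAs
# ---------------------------------------------------------------------------

def _draw_abundance(rng: random.Random, continue_permille: int) -> int:
    count = 1
    while rng.randrange(1000) < continue_permille and count < 500:
        count += 1
    return count


def _sample_read_start(rng: random.Random, avail: int, read_len: int,
                       overlap: tuple[int, int], f: int) -> int:
    """Start position with per-base weight ``f`` inside the overlap."""
    n_pos = avail - read_len + 1
    ov_lo = max(0, overlap[0])
    ov_hi = min(n_pos, overlap[1])
    n_ov = max(0, ov_hi - ov_lo)
    total = f * n_ov + (n_pos - n_ov)
    r = rng.randrange(total)
    if r < f * n_ov:
        return ov_lo + r // f
    r -= f * n_ov
    return r if r < ov_lo else r - ov_lo + ov_hi


def _occurs_in(state: SimState, seq: str) -> set[str]:
    """Independent naive tally of the transcripts carrying ``seq`` exactly."""
    return {tid for tid, t in state.transcripts.items() if seq in t.sequence}


def simulate_smallrnas(state: SimState) -> SimState:
    """Sample reads from NAT transcripts (overlap-concentrated, per-pair
    strand allocation from the bias mix), append planted hairpin matures,
    and emit decoy reads copied into the exclusion set."""
    cfg = state.config.smallrna
    rng = state.rng
    f = cfg.overlap_concentration
    for pair in state.pairs:
        ida, idb = pair["id_a"], pair["id_b"]
        intended = _draw_weighted(
            rng, tuple((i, w) for i, (_, w) in enumerate(cfg.bias_mix)))
        category = cfg.bias_mix[intended][0]
        lone_side = rng.randrange(2)
        for _ in range(cfg.reads_per_pair):
            if category == "One":
                side = lone_side
            elif category == "Equal":
                side = rng.randrange(2)
            else:  # Bias: 5-to-1 allocation toward one side
                side = lone_side if rng.randrange(6) < 5 else 1 - lone_side
            tid = (ida, idb)[side]
            ov = (pair["overlap_on_a"], pair["overlap_on_b"])[side]
            t = state.transcripts[tid]
            avail = len(t.sequence) - RESERVED_LEN
            read_len = _draw_weighted(rng, cfg.length_weights)
            start = _sample_read_start(rng, avail, read_len, tuple(ov), f)
            seq = t.sequence[start:start + read_len]
            count = _draw_abundance(rng, cfg.abundance_continue_permille)
            state.srna_reads.append(
                AbundanceRead(f"sim{len(state.srna_reads)}", seq, count))
    # hairpin matures join the library
    for h in state.hairpins:
        state.srna_reads.append(AbundanceRead(
            f"sim{len(state.srna_reads)}", h["mature_sequence"], 5))
    # decoy reads that the exclusion screen must remove
    if cfg.n_excluded_reads:
        decoy_parent = _random_seq(rng, 300, state.config.gc_permille)
        state.exclusion_records.append(("sim_trna_1", decoy_parent))
        for i in range(cfg.n_excluded_reads):
            start = rng.randrange(300 - 21)
            seq = decoy_parent[start:start + 21]
            state.excluded_read_seqs.append(seq)
            state.srna_reads.append(
                AbundanceRead(f"sim{len(state.srna_reads)}", seq,
                              _draw_abundance(rng, cfg.abundance_continue_permille)))
    return state


# ---------------------------------------------------------------------------
# Degradome
# ---------------------------------------------------------------------------

def _mutate(rng: random.Random, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.randrange(3)]


def simulate_degradome(state: SimState) -> SimState:
    """Plant target sites (compliant and decoy) in reserved zones, emit
    supporting tags anchored opposite small RNA positions 10/11, plus noise
    tags from unconstrained transcript regions."""
    cfg = state.config.degradome
    rng = state.rng
    # hairpin hosts stay eligible: sites live in the reserved zone, far
    # from the planted stem-loop
    nat_ids = [tid for tid in sorted(state.transcripts)
               if state.transcripts[tid].is_nat]
    partners: dict[str, list[str]] = {tid: [] for tid in nat_ids}
    for p in state.pairs:
        if p["id_a"] in partners and p["id_b"] in partners:
            partners[p["id_a"]].append(p["id_b"])
            partners[p["id_b"]].append(p["id_a"])

    origins = ["a", "s", "o"]
    plans = []
    for i in range(cfg.n_targets):
        plans.append((origins[i % 3], COMPLIANT_MISMATCH_SETS[
            i % len(COMPLIANT_MISMATCH_SETS)], False))
    for i in range(cfg.n_decoys):
        plans.append((origins[i % 3],
                      DECOY_MISMATCH_SETS[i % len(DECOY_MISMATCH_SETS)], True))
    # allocate 'a' plans first: they need a pair with both slots free, and
    # 's'/'o' plans are far less constrained
    plans.sort(key=lambda plan: {"a": 0, "s": 1, "o": 2}[plan[0]])

    for origin, mismatches, is_decoy in plans:
        # choose target/source transcripts
        if origin == "a":
            target = None
            for tid in nat_ids:
                t = state.transcripts[tid]
                if t.target_used:
                    continue
                usable = [p for p in partners[tid]
                          if not state.transcripts[p].source_used]
                if usable:
                    target, source = tid, usable[0]
                    break
            if target is None:
                raise ValueError("no free NAT pair for an 'a'-origin target")
        elif origin == "s":
            target = None
            for tid in nat_ids:
                t = state.transcripts[tid]
                if not t.target_used and not t.source_used:
                    target = tid
                    break
            if target is None:
                raise ValueError("no free NAT transcript for an 's'-origin target")
            source = target
        else:
            target = source = None
            for tid in nat_ids:
                if state.transcripts[tid].target_used:
                    continue
                forbidden = set(partners[tid]) | {tid}
                usable = [s for s in nat_ids
                          if not state.transcripts[s].source_used
                          and s not in forbidden]
                if usable:
                    target, source = tid, usable[0]
                    break
            if target is None:
                raise ValueError(
                    "not enough NAT transcripts for an 'o'-origin target")
        t_target = state.transcripts[target]
        t_source = state.transcripts[source]
        t_target.target_used = True
        t_source.source_used = True
        # the siRNA is the leading stretch of the source's reserved zone
        zone = len(t_source.sequence) - RESERVED_LEN
        sirna = t_source.sequence[zone:zone + cfg.sirna_length]
        n = len(sirna)
        site_seq = list(reverse_complement(sirna))
        for p in mismatches:
            j = n - p  # site offset pairing siRNA position p
            site_seq[j] = _mutate(rng, site_seq[j])
        site = "".join(site_seq)
        s0 = len(t_target.sequence) - RESERVED_LEN + _SITE_ZONE_OFFSET
        t_target.sequence = (t_target.sequence[:s0] + site
                             + t_target.sequence[s0 + n:])
        # supporting tags: 5' end opposite siRNA positions 10/11
        tag5 = s0 + (n - 10)
        tag = t_target.sequence[tag5:tag5 + cfg.tag_length]
        for _ in range(cfg.tags_per_target):
            state.degradome_tags.append(AbundanceRead(
                f"tag{len(state.degradome_tags)}", tag,
                1 + rng.randrange(5)))
        state.srna_reads.append(AbundanceRead(
            f"sim{len(state.srna_reads)}", sirna, 1 + rng.randrange(20)))
        state.targets.append({
            "sirna": sirna,
            "source_id": source,
            "target_id": target,
            "site_start": s0,
            "site_end": s0 + n,
            "mismatch_positions": sorted(mismatches),
            "origin": origin,
            "is_decoy": is_decoy,
        })
    # noise tags from free segments, away from overlaps / hairpins / zones
    pad = cfg.tag_length + 2 * 20 + 1
    noise_hosts = []
    for tid in nat_ids:
        for lo, hi in _free_segments(state, tid, pad=pad):
            if hi - lo > cfg.tag_length:
                noise_hosts.append((tid, lo, hi))
    for i in range(cfg.n_noise_tags):
        if not noise_hosts:
            break
        tid, lo, hi = noise_hosts[rng.randrange(len(noise_hosts))]
        start = lo + rng.randrange(hi - lo - cfg.tag_length + 1)
        seq = state.transcripts[tid].sequence[start:start + cfg.tag_length]
        state.degradome_tags.append(
            AbundanceRead(f"tag{len(state.degradome_tags)}", seq,
                          1 + rng.randrange(3)))
    return state


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> SimState:
    state = simulate_genome(config)
    plant_hairpins(state)
    simulate_smallrnas(state)
    simulate_degradome(state)
    _finalize_strand_bias(state)
    _check_manifest(state)
    return state


def _finalize_strand_bias(state: SimState) -> None:
    """Record the realized per-pair strand-bias category over the complete
    read library (including hairpin matures and planted siRNAs), using an
    independent naive substring recount so multi-mapping is honoured."""
    realized: dict[str, dict[str, float]] = {
        f"{p['id_a']}|{p['id_b']}": {p["id_a"]: 0.0, p["id_b"]: 0.0}
        for p in state.pairs
    }
    excluded = set(state.excluded_read_seqs)
    for read in state.srna_reads:
        if read.sequence in excluded:
            continue
        carriers = _occurs_in(state, read.sequence)
        for pair in state.pairs:
            key = f"{pair['id_a']}|{pair['id_b']}"
            for tid in (pair["id_a"], pair["id_b"]):
                if tid in carriers:
                    n_occ = state.transcripts[tid].sequence.count(read.sequence)
                    realized[key][tid] += read.count * n_occ
    for pair in state.pairs:
        key = f"{pair['id_a']}|{pair['id_b']}"
        ca = realized[key][pair["id_a"]]
        cb = realized[key][pair["id_b"]]
        if ca == 0 and cb == 0:
            category = "none"
        elif ca == 0 or cb == 0:
            category = "One"
        else:
            ratio = ca / cb
            category = "Equal" if 0.5 <= ratio <= 2 else "Bias"
        state.strand_bias[key] = {
            "count_a": ca, "count_b": cb, "category": category,
        }


def _check_manifest(state: SimState) -> None:
    """Every planted feature must be re-locatable in the emitted sequences."""
    for h in state.hairpins:
        t = state.transcripts[h["transcript_id"]]
        mature = t.sequence[h["mature_start"]:h["mature_start"] + h["mature_length"]]
        if mature != h["mature_sequence"]:
            raise AssertionError("hairpin manifest inconsistent with sequence")
    for tg in state.targets:
        t = state.transcripts[tg["target_id"]]
        site = t.sequence[tg["site_start"]:tg["site_end"]]
        rc = reverse_complement(tg["sirna"])
        diff = [len(tg["sirna"]) - j
                for j in range(len(site)) if site[j] != rc[j]]
        if sorted(diff) != list(tg["mismatch_positions"]):
            raise AssertionError("target manifest inconsistent with sequence")
        if tg["sirna"] not in state.transcripts[tg["source_id"]].sequence:
            raise AssertionError("planted siRNA missing from source transcript")


def write_outputs(state: SimState, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fa",
        "genes": outdir / "genes.tsv",
        "srna": outdir / "srna.fa",
        "degradome": outdir / "degradome.fa",
        "exclude": outdir / "exclude.fa",
        "truth": outdir / "truth.json",
    }
    records = state.records()
    write_fasta([(r.transcript_id, r.sequence) for r in records],
                paths["transcripts"])
    write_gene_table(records, paths["genes"])
    write_abundance_reads(state.srna_reads, paths["srna"])
    write_abundance_reads(state.degradome_tags, paths["degradome"])
    write_fasta(state.exclusion_records, paths["exclude"])
    with open(paths["truth"], "w") as fh:
        json.dump(state.manifest(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Statistical cohort simulation (enrichment calibration)
# ---------------------------------------------------------------------------

def simulate_enrichment_cohort(
    rng: np.random.Generator,
    n_pairs: int,
    concentration: float = 1.0,
    lo: int = 120,
    lt: int = 2400,
    loci_per_pair: int = 20,
) -> list[EnrichmentResult]:
    """Per-pair enrichment results under the placement model: each locus
    falls in the overlap with probability f*Lo / (f*Lo + (Lt-Lo))."""
    p_in = concentration * lo / (concentration * lo + (lt - lo))
    results = []
    nos = rng.binomial(loci_per_pair, p_in, size=n_pairs)
    for no in nos:
        results.append(enrichment(int(no), loci_per_pair, lo, lt))
    return results
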