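"""Small RNA filtering, exact mapping, strand bias and overlap enrichment.

Reads are screened against optional exclusion sets (structural RNA,
transposable elements), placed on transcripts by exact full-length
sense-orientation matching, and summarised per NAT pair: strand-bias
category (One / Equal / Bias) and overlap-region enrichment with a 1-df
chi-square goodness-of-fit test.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from scipy import stats

from .io_formats import AbundanceRead, TranscriptRecord
from .nat_discovery import NATPair, reverse_complement

__all__ = [
    "SmallRNAHit",
    "StrandBiasCall",
    "EnrichmentResult",
    "filter_excluded",
    "map_exact",
    "size_distribution",
    "strand_bias",
    "enrichment",
    "pair_enrichment",
    "pooled_enrichment",
    "density_ttest",
]

_INDEX_K = 12


@dataclass(frozen=True)
class SmallRNAHit:
    """One exact placement of a read on a transcript (sense orientation)."""

    sequence: str
    count: int
    transcript_id: str
    position: int  # 0-based start on the transcript

    @property
    def end(self) -> int:
        return self.position + len(self.sequence)


@dataclass(frozen=True)
class StrandBiasCall:
    pair_id: str
    count_a: float
    count_b: float
    ratio: float  # may be inf
    category: str  # {One, Equal, Bias}


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap-region enrichment of small RNA loci for one pair or a pool.

    no/nt: unique loci in the overlap / on the whole transcripts.
    lo/lt: overlap / total lengths (nt).  score = (no/lo) / (nt/lt).
    """

    scope: str
    no: int
    nt: int
    lo: int
    lt: int
    score: float
    chi2: float
    p: float

    @property
    def do(self) -> float:
        return self.no / self.lo

    @property
    def dt(self) -> float:
        return self.nt / self.lt


# ---------------------------------------------------------------------------
# Filtering and mapping
# ---------------------------------------------------------------------------

def filter_excluded(
    reads: list[AbundanceRead],
    exclusion_sets: dict[str, list[tuple[str, str]]] | None,
) -> tuple[list[AbundanceRead], list[tuple[str, str]]]:
    """Drop reads occurring (either strand) inside any exclusion sequence.

    ``exclusion_sets`` maps a set label (e.g. "rfam", "te") to FASTA
    records.  Returns (kept_reads, removal_log) where the log lists
    (read_id, set_label) for every removed read.
    """
    if not exclusion_sets:
        return list(reads), []
    kept: list[AbundanceRead] = []
    removed: list[tuple[str, str]] = []
    for read in reads:
        rc = reverse_complement(read.sequence)
        claimed = None
        for label, records in exclusion_sets.items():
            if any(read.sequence in seq or rc in seq for _, seq in records):
                claimed = label
                break
        if claimed is None:
            kept.append(read)
        else:
            removed.append((read.read_id, claimed))
    return kept, removed


def map_exact(reads: list[AbundanceRead],
              transcripts: list[TranscriptRecord]) -> list[SmallRNAHit]:
    """All exact, full-length, sense-orientation placements of each read.

    A k-mer index over transcript prefixes nominates candidate positions;
    every candidate is verified by direct slice comparison, so multi-mapping
    reads yield one hit per placement.  Reads shorter than the index k fall
    back to a direct scan.
    """
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    seqs = {t.transcript_id: t.sequence for t in transcripts}
    for t in transcripts:
        s = t.sequence
        for i in range(len(s) - _INDEX_K + 1):
            index[s[i : i + _INDEX_K]].append((t.transcript_id, i))
    hits: list[SmallRNAHit] = []
    for read in reads:
        rseq = read.sequence
        if "N" in rseq:
            continue  # N never matches
        if len(rseq) >= _INDEX_K:
            for tid, pos in index.get(rseq[:_INDEX_K], ()):
                if seqs[tid][pos : pos + len(rseq)] == rseq:
                    hits.append(SmallRNAHit(rseq, read.count, tid, pos))
        else:
            for tid, s in seqs.items():
                start = s.find(rseq)
                while start != -1:
                    hits.append(SmallRNAHit(rseq, read.count, tid, start))
                    start = s.find(rseq, start + 1)
    hits.sort(key=lambda h: (h.transcript_id, h.position, h.sequence))
    return hits


def size_distribution(hits: list[SmallRNAHit]) -> dict[int, dict[str, int]]:
    """Length table with unique (distinct sequences) and total (abundance)
    tallies.  A sequence placed on several transcripts counts once under
    unique and once under total."""
    unique_seqs: dict[int, set[str]] = defaultdict(set)
    totals: dict[int, int] = defaultdict(int)
    seen: set[str] = set()
    for h in hits:
        unique_seqs[len(h.sequence)].add(h.sequence)
        if h.sequence not in seen:
            seen.add(h.sequence)
            totals[len(h.sequence)] += h.count
    return {
        length: {"unique": len(unique_seqs[length]), "total": totals[length]}
        for length in sorted(unique_seqs)
    }


# ---------------------------------------------------------------------------
# Strand bias
# ---------------------------------------------------------------------------

def strand_bias(pair: NATPair, hits: list[SmallRNAHit],
                weighting: str = "total") -> StrandBiasCall:
    """Classify the pair's small RNA production ratio.

    weighting "total" sums abundances; "unique" counts distinct sequences.
    One: exactly one side produced reads.  Equal: 0.5 <= ratio <= 2.
    Bias: ratio < 0.5 or > 2.
    """
    if weighting not in ("total", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    per_side = {pair.id_a: 0.0, pair.id_b: 0.0}
    uniq: dict[str, set[str]] = {pair.id_a: set(), pair.id_b: set()}
    for h in hits:
        if h.transcript_id not in per_side:
            continue
        per_side[h.transcript_id] += h.count
        uniq[h.transcript_id].add(h.sequence)
    if weighting == "unique":
        count_a = float(len(uniq[pair.id_a]))
        count_b = float(len(uniq[pair.id_b]))
    else:
        count_a, count_b = per_side[pair.id_a], per_side[pair.id_b]
    if count_a == 0 and count_b == 0:
        raise ValueError(f"pair {pair.id_a}/{pair.id_b} has no hits")
    if count_a == 0 or count_b == 0:
        ratio = math.inf if count_b == 0 else 0.0
        category = "One"
    else:
        ratio = count_a / count_b
        category = "Equal" if 0.5 <= ratio <= 2 else "Bias"
    pair_id = f"{pair.id_a}|{pair.id_b}"
    return StrandBiasCall(pair_id, count_a, count_b, ratio, category)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def enrichment(no: int, nt: int, lo: int, lt: int,
               scope: str = "per_pair") -> EnrichmentResult:
    """Density-ratio enrichment with a 1-df chi-square goodness-of-fit test.

    Observed (no, nt-no) against expected (nt*lo/lt, nt*(1-lo/lt)).
    """
    if nt < 1:
        raise ValueError("Nt must be >= 1")
    if lo < 1 or lt <= lo:
        raise ValueError("need 1 <= Lo < Lt")
    if no > nt:
        raise ValueError("No cannot exceed Nt")
    frac = lo / lt
    expected = (nt * frac, nt * (1.0 - frac))
    observed = (no, nt - no)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    score = (no / lo) / (nt / lt)
    return EnrichmentResult(scope, no, nt, lo, lt, score, chi2, p)


def _pair_loci(pair: NATPair, hits: list[SmallRNAHit]) -> tuple[int, int]:
    """(loci in overlap, loci total) for one pair.

    A locus is a distinct (transcript, position, sequence) placement; a hit
    is in the overlap iff its start lies inside the pair's overlap interval
    on that transcript.
    """
    ov = {pair.id_a: pair.overlap_on_a, pair.id_b: pair.overlap_on_b}
    loci: set[tuple[str, int, str]] = set()
    in_ov: set[tuple[str, int, str]] = set()
    for h in hits:
        if h.transcript_id not in ov:
            continue
        key = (h.transcript_id, h.position, h.sequence)
        loci.add(key)
        lo, hi = ov[h.transcript_id]
        if lo <= h.position < hi:
            in_ov.add(key)
    return len(in_ov), len(loci)


def pair_enrichment(pair: NATPair, hits: list[SmallRNAHit],
                    transcript_lengths: dict[str, int]) -> EnrichmentResult:
    """Enrichment over one pair: Lo = overlap on both transcripts,
    Lt = summed transcript lengths."""
    no, nt = _pair_loci(pair, hits)
    lo = 2 * pair.overlap_length
    lt = transcript_lengths[pair.id_a] + transcript_lengths[pair.id_b]
    return enrichment(no, nt, lo, lt, scope="per_pair")


def pooled_enrichment(pairs: list[NATPair], hits: list[SmallRNAHit],
                      transcript_lengths: dict[str, int]) -> EnrichmentResult:
    no = nt = lo = lt = 0
    for pair in pairs:
        pno, pnt = _pair_loci(pair, hits)
        no += pno
        nt += pnt
        lo += 2 * pair.overlap_length
        lt += transcript_lengths[pair.id_a] + transcript_lengths[pair.id_b]
    return enrichment(no, nt, lo, lt, scope="pooled")


def density_ttest(results: list[EnrichmentResult]) -> tuple[float, float, float]:
    """Paired t-test of overlap density against whole-transcript density
    across pairs.  Returns (t, two-sided p, mean Do-Dt difference)."""
    if len(results) < 2:
        raise ValueError("need >= 2 pairs for the t-test")
    do = [r.do for r in results]
    dt = [r.dt for r in results]
    diffs = [a - b for a, b in zip(do, dt)]
    mean_diff = sum(diffs) / len(diffs)
    if all(d == diffs[0] for d in diffs):
        # zero variance: degenerate separation (or exact null)
        if diffs[0] == 0.0:
            return 0.0, 1.0, 0.0
        return math.copysign(math.inf, mean_diff), 0.0, mean_diff
    res = stats.ttest_rel(do, dt)
    return float(res.statistic), float(res.pvalue), mean_diff
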