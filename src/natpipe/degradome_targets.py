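"""Degradome tag mapping and nat-siRNA target calling.

Tags are placed on transcripts by exact sense matching; each placement
yields a "long degradome" window (tag plus 20 nt of context on each side).
Small RNAs are then aligned antisense against those windows allowing up to
three substitutions and no indels, and candidate sites are kept only when
their mismatch positions satisfy the position-specific rule: at most one
mismatch in positions 1-9, none in positions 10-11, at most two after
position 11 (positions counted 1-based from the small RNA 5' end).
Accepted calls carry an origin code: ``a`` (small RNA from the antisense
partner of the target), ``s`` (from the target itself), ``o`` (from another
gene); small RNAs matching more than five transcripts are flagged multiple.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io_formats import AbundanceRead, TranscriptRecord
from .nat_discovery import NATPair, reverse_complement
from .sirna_profiling import map_exact

__all__ = [
    "DegradomeHit",
    "LongDegradome",
    "TargetCall",
    "CandidateSite",
    "map_degradome",
    "extract_long_degradome",
    "scan_candidate_sites",
    "schwab_filter",
    "classify_origin",
    "call_targets",
]

DEFAULT_FLANK = 20
MAX_MISMATCHES = 3


@dataclass(frozen=True)
class DegradomeHit:
    """Exact sense placement of a degradome 5' tag on a transcript."""

    sequence: str
    count: int
    transcript_id: str
    position: int  # 0-based position of the tag's 5' end


@dataclass(frozen=True)
class LongDegradome:
    """Tag context window: the tag plus up to ``flank`` nt on each side."""

    transcript_id: str
    window: tuple[int, int]
    sequence: str
    anchor: int  # tag 5' position on the transcript


@dataclass(frozen=True)
class CandidateSite:
    """One antisense placement of a small RNA inside a window.

    ``site`` is transcript-local; mismatch positions are 1-based from the
    small RNA 5' end (position 1 pairs the 3'-most base of the site).
    """

    sirna: str
    transcript_id: str
    site: tuple[int, int]
    mismatch_positions: tuple[int, ...]


@dataclass(frozen=True)
class TargetCall:
    sirna: str
    sirna_abundance: int
    target_id: str
    site: tuple[int, int]
    mismatch_positions: tuple[int, ...]
    origin: str  # {a, s, o}
    multiple_flag: bool
    tag_support: int

    def __post_init__(self) -> None:
        if len(self.mismatch_positions) > MAX_MISMATCHES:
            raise ValueError("more than three mismatches in an accepted call")
        if any(p in (10, 11) for p in self.mismatch_positions):
            raise ValueError("accepted call has a mismatch at position 10/11")


def map_degradome(tags: list[AbundanceRead],
                  transcripts: list[TranscriptRecord]) -> list[DegradomeHit]:
    """Exact full-length sense placements of every tag (all placements)."""
    hits = map_exact(tags, transcripts)
    return [DegradomeHit(h.sequence, h.count, h.transcript_id, h.position)
            for h in hits]


def extract_long_degradome(transcript: TranscriptRecord, hit: DegradomeHit,
                           flank: int = DEFAULT_FLANK) -> LongDegradome:
    """Window of ``flank`` nt around the tag, clipped at transcript bounds."""
    length = len(transcript.sequence)
    start = max(0, hit.position - flank)
    end = min(length, hit.position + len(hit.sequence) + flank)
    return LongDegradome(
        transcript_id=transcript.transcript_id,
        window=(start, end),
        sequence=transcript.sequence[start:end],
        anchor=hit.position,
    )


def scan_candidate_sites(sirna: str, window: LongDegradome,
                         max_mismatches: int = MAX_MISMATCHES) -> list[CandidateSite]:
    """All antisense placements of the small RNA in the window with at most
    ``max_mismatches`` substitutions and no indels.

    The reverse complement of the small RNA is slid over the window; a
    mismatch at pattern offset j maps to small RNA position len - j
    (1-based from its 5' end).  N never matches.
    """
    pattern = reverse_complement(sirna)
    n = len(pattern)
    wseq = window.sequence
    if n > len(wseq):
        return []
    sites: list[CandidateSite] = []
    for offset in range(len(wseq) - n + 1):
        mismatches: list[int] = []
        ok = True
        for j in range(n):
            a, b = pattern[j], wseq[offset + j]
            if a != b or a == "N" or b == "N":
                mismatches.append(n - j)
                if len(mismatches) > max_mismatches:
                    ok = False
                    break
        if ok:
            start = window.window[0] + offset
            sites.append(CandidateSite(
                sirna=sirna,
                transcript_id=window.transcript_id,
                site=(start, start + n),
                mismatch_positions=tuple(sorted(mismatches)),
            ))
    return sites


def schwab_filter(mismatch_positions: tuple[int, ...] | list[int],
                  sirna_len: int | None = None) -> bool:
    """Position-specific acceptance rule for a candidate mismatch vector.

    Accept iff at most one mismatch at positions 1-9, no mismatch at 10 or
    11, and at most two mismatches at positions >= 12.
    """
    if sirna_len is not None and any(p > sirna_len for p in mismatch_positions):
        raise ValueError("mismatch position beyond the small RNA length")
    seed = sum(1 for p in mismatch_positions if p <= 9)
    cleavage = sum(1 for p in mismatch_positions if p in (10, 11))
    tail = sum(1 for p in mismatch_positions if p >= 12)
    return seed <= 1 and cleavage == 0 and tail <= 2


def classify_origin(sirna: str, target_id: str,
                    nat_pairs: list[NATPair],
                    sirna_source_map: dict[str, set[str]]) -> tuple[str, bool]:
    """Origin code and multiple flag for one accepted call.

    sources = transcripts carrying the small RNA exactly.  ``a`` if the
    target forms a NAT with a source, ``s`` if the small RNA derives from
    the target itself, ``o`` otherwise; multiple iff > 5 source transcripts.
    """
    sources = sirna_source_map.get(sirna)
    if not sources:
        raise ValueError(f"small RNA {sirna!r} has no source transcript")
    multiple = len(sources) > 5
    partners: set[str] = set()
    for p in nat_pairs:
        if p.id_a == target_id:
            partners.add(p.id_b)
        elif p.id_b == target_id:
            partners.add(p.id_a)
    if partners & sources:
        return "a", multiple
    if target_id in sources:
        return "s", multiple
    return "o", multiple


def call_targets(
    sirnas: list[AbundanceRead],
    degradome_hits: list[DegradomeHit],
    nat_pairs: list[NATPair],
    transcripts: list[TranscriptRecord],
    flank: int = DEFAULT_FLANK,
) -> list[TargetCall]:
    """End-to-end target calling.

    Unique small RNA sequences (abundance summed) are scanned against the
    long-degradome window of every tag placement; sites passing the
    position rule are deduplicated on (sirna, transcript, site) with tag
    support summed over the tags whose windows exposed the site.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    # unique query sequences with pooled abundance
    abundance: dict[str, int] = defaultdict(int)
    for r in sirnas:
        abundance[r.sequence] += r.count
    # source map: which transcripts carry each query exactly; only
    # NAT-derived sequences (those with >= 1 source) are used as queries
    query_reads = [AbundanceRead(f"q{i}", seq, 1)
                   for i, seq in enumerate(sorted(abundance))]
    source_map: dict[str, set[str]] = defaultdict(set)
    for h in map_exact(query_reads, transcripts):
        source_map[h.sequence].add(h.transcript_id)
    queries = sorted(source_map)
    accepted: dict[tuple[str, str, tuple[int, int]], dict] = {}
    for dhit in degradome_hits:
        window = extract_long_degradome(by_id[dhit.transcript_id], dhit, flank)
        for sirna in queries:
            for cand in scan_candidate_sites(sirna, window):
                if not schwab_filter(cand.mismatch_positions, len(sirna)):
                    continue
                key = (sirna, cand.transcript_id, cand.site)
                entry = accepted.setdefault(
                    key, {"mismatches": cand.mismatch_positions, "support": 0,
                          "tags": set()})
                tag_key = (dhit.sequence, dhit.position)
                if tag_key not in entry["tags"]:
                    entry["tags"].add(tag_key)
                    entry["support"] += dhit.count
    calls: list[TargetCall] = []
    for (sirna, target_id, site), entry in sorted(accepted.items()):
        if sirna not in source_map:
            continue  # query not derived from any NAT transcript
        origin, multiple = classify_origin(sirna, target_id, nat_pairs, source_map)
        calls.append(TargetCall(
            sirna=sirna,
            sirna_abundance=abundance[sirna],
            target_id=target_id,
            site=site,
            mismatch_positions=entry["mismatches"],
            origin=origin,
            multiple_flag=multiple,
            tag_support=entry["support"],
        ))
    calls.sort(key=lambda c: (c.target_id, c.site[0], c.sirna))
    return calls
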