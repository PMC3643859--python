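"""Calling sense/antisense transcript pairs and classifying their loci.

A pair is called when two transcripts carry a near-identity complementary
block: one transcript is aligned against the reverse complement of the
other with an ungapped seeded scan, and the best block is kept if it clears
the E-value, length and identity thresholds.  Pairs are then classed *cis*
(opposite strands of one overlapping genomic locus) or *trans* (different
loci), and cis pairs are typed convergent / divergent / enclosed from their
genomic span geometry.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace

from .io_formats import GenomeInterval, TranscriptRecord

__all__ = [
    "AlignmentParams",
    "AlignmentBlock",
    "NATPair",
    "AntisenseDegree",
    "reverse_complement",
    "find_antisense_blocks",
    "karlin_altschul_evalue",
    "call_nat_pairs",
    "classify_locus",
    "classify_cis_orientation",
    "classify_pairs",
    "antisense_degree",
    "cross_class_membership",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and threshold parameters for the antisense block scan.

    lambda_ and k are the gapless Karlin-Altschul parameters for the
    match/mismatch score system (defaults fit +1/-2).
    """

    match_score: int = 1
    mismatch_penalty: int = -2
    word_size: int = 11
    lambda_: float = 1.33
    k: float = 0.621
    evalue_max: float = 1e-9
    min_overlap: int = 31
    min_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("lambda_ and k must be positive")
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")
        if self.min_overlap < self.word_size:
            raise ValueError("min_overlap must be >= word_size")


@dataclass(frozen=True)
class AlignmentBlock:
    """One ungapped complementary block between two transcripts.

    ``on_a`` is an interval on transcript a (sense coordinates); ``on_b`` is
    mapped back to transcript b's own sense orientation.  ``length`` counts
    alignment columns; ``matches`` counts identities.
    """

    on_a: tuple[int, int]
    on_b: tuple[int, int]
    matches: int
    length: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.length


@dataclass(frozen=True)
class NATPair:
    id_a: str
    id_b: str
    overlap_on_a: tuple[int, int]
    overlap_on_b: tuple[int, int]
    overlap_length: int
    alignment_score: int
    evalue: float
    locus_class: str = "unset"   # {cis, trans, unset}
    orientation: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("NATPair ids must satisfy id_a < id_b")
        la = self.overlap_on_a[1] - self.overlap_on_a[0]
        lb = self.overlap_on_b[1] - self.overlap_on_b[0]
        if not (la == lb == self.overlap_length):
            raise ValueError("overlap intervals disagree with overlap_length")


@dataclass(frozen=True)
class AntisenseDegree:
    transcript_id: str
    n_antisense_partners: int


def karlin_altschul_evalue(score: int, len_a: int, len_b: int,
                           params: AlignmentParams) -> float:
    """Gapless Karlin-Altschul expectation: E = K * m * n * exp(-lambda*S)."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return params.k * len_a * len_b * math.exp(-params.lambda_ * score)


def _best_segment_on_diagonal(seq_a: str, rc_b: str, diag: int,
                              params: AlignmentParams) -> tuple[int, int, int, int] | None:
    """Maximum-scoring ungapped segment on one diagonal of a vs rc(b).

    Diagonal ``diag`` aligns a[i] with rc_b[i - diag].  Returns
    (a_start, a_end, matches, score) of the best-scoring segment, or None.
    N never matches.  Kadane-style scan; ties resolved leftmost.
    """
    i_lo = max(0, diag)
    i_hi = min(len(seq_a), len(rc_b) + diag)
    if i_hi - i_lo <= 0:
        return None
    best = None  # (score, a_start, a_end, matches)
    run_score = 0
    run_start = i_lo
    run_matches = 0
    for i in range(i_lo, i_hi):
        ca = seq_a[i]
        cb = rc_b[i - diag]
        is_match = ca == cb and ca != "N"
        step = params.match_score if is_match else params.mismatch_penalty
        if run_score < 0:
            # reset only on strictly negative running score, so zero-sum
            # prefixes stay attached and ties resolve to the leftmost start
            run_score = 0
            run_start = i
            run_matches = 0
        run_score += step
        run_matches += 1 if is_match else 0
        if run_score > 0 and (best is None or run_score > best[0]):
            best = (run_score, run_start, i + 1, run_matches)
    if best is None:
        return None
    score, a_start, a_end, matches = best
    return a_start, a_end, matches, score


def find_antisense_blocks(seq_a: str, seq_b: str,
                          params: AlignmentParams | None = None) -> list[AlignmentBlock]:
    """Scored complementary blocks between two transcripts.

    seq_a is scanned against reverse_complement(seq_b): exact word_size
    seeds nominate diagonals and the maximum-scoring ungapped segment on
    each seeded diagonal is kept if it clears min_overlap and min_identity.
    Same-orientation identity is deliberately invisible here.
    """
    params = params or AlignmentParams()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    rc_b = reverse_complement(seq_b)
    w = params.word_size
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(rc_b) - w + 1):
        word = rc_b[j : j + w]
        if "N" not in word:
            index[word].append(j)
    diagonals: set[int] = set()
    for i in range(len(seq_a) - w + 1):
        word = seq_a[i : i + w]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            diagonals.add(i - j)
    blocks: list[AlignmentBlock] = []
    len_b = len(seq_b)
    for diag in sorted(diagonals):
        seg = _best_segment_on_diagonal(seq_a, rc_b, diag, params)
        if seg is None:
            continue
        a_start, a_end, matches, score = seg
        length = a_end - a_start
        if length < params.min_overlap:
            continue
        if matches / length < params.min_identity:
            continue
        # rc_b interval -> b sense interval
        j_start, j_end = a_start - diag, a_end - diag
        b_start, b_end = len_b - j_end, len_b - j_start
        blocks.append(AlignmentBlock(
            on_a=(a_start, a_end), on_b=(b_start, b_end),
            matches=matches, length=length, score=score,
        ))
    blocks.sort(key=lambda b: (-b.score, b.on_a[0], b.on_b[0]))
    return blocks


def _seed_words(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1) if "N" not in seq[i : i + w]}


def call_nat_pairs(transcripts: list[TranscriptRecord],
                   params: AlignmentParams | None = None) -> list[NATPair]:
    """Evaluate all unordered transcript pairs and emit qualifying NAT pairs.

    A seed index over word_size-mers prunes pairs that cannot share an exact
    seed; every surviving pair keeps its single best block (highest score,
    ties leftmost on the lexicographically smaller transcript).  The result
    is sorted by (id_a, id_b) and invariant under input order.
    """
    params = params or AlignmentParams()
    if len(transcripts) < 2:
        return []
    by_id = {t.transcript_id: t for t in transcripts}
    if len(by_id) != len(transcripts):
        raise ValueError("duplicate transcript ids")
    w = params.word_size
    # sense-word index: word -> transcript ids containing it
    sense_index: dict[str, set[str]] = defaultdict(set)
    for t in transcripts:
        for word in _seed_words(t.sequence, w):
            sense_index[word].add(t.transcript_id)
    candidates: set[tuple[str, str]] = set()
    for t in transcripts:
        for word in _seed_words(reverse_complement(t.sequence), w):
            for other_id in sense_index.get(word, ()):
                if other_id == t.transcript_id:
                    continue
                pair = tuple(sorted((t.transcript_id, other_id)))
                candidates.add(pair)  # type: ignore[arg-type]
    pairs: list[NATPair] = []
    for id_a, id_b in sorted(candidates):
        ta, tb = by_id[id_a], by_id[id_b]
        blocks = find_antisense_blocks(ta.sequence, tb.sequence, params)
        if not blocks:
            continue
        best = blocks[0]
        evalue = karlin_altschul_evalue(best.score, len(ta), len(tb), params)
        if evalue > params.evalue_max:
            continue
        pairs.append(NATPair(
            id_a=id_a, id_b=id_b,
            overlap_on_a=best.on_a, overlap_on_b=best.on_b,
            overlap_length=best.length, alignment_score=best.score,
            evalue=evalue,
        ))
    return pairs


def classify_locus(pair: NATPair,
                   annotations: dict[str, GenomeInterval]) -> str:
    """cis iff same chromosome, genomic spans overlap >= 1 bp, and the
    annotated strands are opposite; trans otherwise."""
    for tid in (pair.id_a, pair.id_b):
        if tid not in annotations:
            raise KeyError(f"no genomic annotation for transcript {tid!r}")
    a, b = annotations[pair.id_a], annotations[pair.id_b]
    if a.overlaps(b) and a.strand != b.strand:
        return "cis"
    return "trans"


def classify_cis_orientation(pair: NATPair,
                             annotations: dict[str, GenomeInterval]) -> str:
    """Type a cis pair by span geometry.

    enclosed: one span contains the other.  Otherwise let P be the + strand
    gene and M the - strand gene: convergent when P starts first (the shared
    region covers both 3' ends), divergent when M starts first (both 5'
    ends).
    """
    if pair.locus_class != "cis":
        raise ValueError("orientation is defined only for cis pairs")
    a, b = annotations[pair.id_a], annotations[pair.id_b]
    if (a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end):
        return "enclosed"
    plus, minus = (a, b) if a.strand == "+" else (b, a)
    return "convergent" if plus.start < minus.start else "divergent"


def classify_pairs(pairs: list[NATPair],
                   annotations: dict[str, GenomeInterval]) -> list[NATPair]:
    """Return pairs with locus_class and orientation filled in."""
    out = []
    for pair in pairs:
        cls = classify_locus(pair, annotations)
        pair = replace(pair, locus_class=cls)
        orientation = (classify_cis_orientation(pair, annotations)
                       if cls == "cis" else "not_applicable")
        out.append(replace(pair, orientation=orientation))
    return out


def antisense_degree(pairs: list[NATPair]) -> list[AntisenseDegree]:
    """Per-transcript count of distinct antisense partners."""
    partners: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        partners[p.id_a].add(p.id_b)
        partners[p.id_b].add(p.id_a)
    return [AntisenseDegree(tid, len(ps))
            for tid, ps in sorted(partners.items())]


def cross_class_membership(pairs: list[NATPair]) -> dict[str, set[str]]:
    """Partition transcripts in >= 1 pair into cis-only / trans-only / both."""
    cis: set[str] = set()
    trans: set[str] = set()
    for p in pairs:
        if p.locus_class == "cis":
            cis.update((p.id_a, p.id_b))
        elif p.locus_class == "trans":
            trans.update((p.id_a, p.id_b))
        else:
            raise ValueError(f"pair ({p.id_a},{p.id_b}) has unset locus_class")
    return {
        "cis_only": cis - trans,
        "trans_only": trans - cis,
        "both": cis & trans,
    }
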