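"""Stem-loop screening of transcripts around small RNA loci.

Precursor candidates are 200-nt flanked windows around small RNA
placements.  The default folding engine maximises Watson-Crick + wobble
base pairs (minimum hairpin loop of 3) with a deterministic traceback; a
thermodynamic engine can be plugged in through the ``fold_fn`` seam.  The
hairpin verdict checks that the small RNA sits on one arm of a single
stem-loop with a near-contiguous opposite arm, few unpaired bases, small
bulges, and a duplex that stays clear of the terminal loop.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .io_formats import TranscriptRecord
from .nat_discovery import NATPair
from .sirna_profiling import SmallRNAHit

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn
        return wrap if not args or not callable(args[0]) else args[0]


__all__ = [
    "HairpinCriteria",
    "HairpinCandidate",
    "NATmiRNATarget",
    "FoldTooShortError",
    "extract_precursor",
    "fold",
    "check_hairpin",
    "screen_hairpins",
    "nat_mirna_target_intersect",
    "dinucleotide_shuffle",
    "pair_table",
]

MIN_LOOP = 3
DEFAULT_FLANK = 200
DEFAULT_MIN_FOLD_LEN = 40

# base codes: A=0 C=1 G=2 T=3 N=4; allowed pairs incl. G:U wobble
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_PAIRABLE = np.zeros((5, 5), dtype=np.uint8)
for _x, _y in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRABLE[_x, _y] = 1


class FoldTooShortError(ValueError):
    """Sequence shorter than the folding minimum."""


@dataclass(frozen=True)
class HairpinCriteria:
    """Thresholds for the stem-loop verdict (all configurable)."""

    max_unpaired_in_mir: int = 4
    max_bulge_in_mir: int = 2
    min_stem_pairs: int = 15
    star_span_slack: int = 4


@dataclass
class HairpinCandidate:
    transcript_id: str
    precursor: tuple[int, int]  # transcript-local interval
    sequence: str
    mir_arm: tuple[int, int]  # precursor-local interval of the small RNA
    structure: str = ""
    metrics: dict = field(default_factory=dict)
    verdict: bool = False


@dataclass(frozen=True)
class NATmiRNATarget:
    target_id: str
    mirna: str
    is_nat_member: bool
    validated_flag: bool


def extract_precursor(transcript: TranscriptRecord, hit: SmallRNAHit,
                      flank: int = DEFAULT_FLANK) -> tuple[tuple[int, int], str]:
    """Window of ``flank`` nt around the small RNA, clipped at the ends."""
    length = len(transcript.sequence)
    start = max(0, hit.position - flank)
    end = min(length, hit.position + len(hit.sequence) + flank)
    return (start, end), transcript.sequence[start:end]


@njit(cache=True)
def _fill_nussinov(codes, pairable, min_loop):  # pragma: no cover - numba
    n = codes.shape[0]
    m = np.zeros((n, n), dtype=np.int16)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable[codes[i], codes[k]] == 1:
                    inner = m[i + 1, k - 1] if k - 1 > i else 0
                    outer = m[k + 1, j] if k + 1 <= j else 0
                    cand = inner + outer + 1
                    if cand > best:
                        best = cand
            m[i, j] = best
    return m


def _traceback(codes: np.ndarray, m: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic traceback preferring to pair the 5'-most base, taking
    the outermost partner that achieves the optimum."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, codes.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = m[i, j]
        if target == 0:
            continue
        chosen = -1
        for k in range(j, i + MIN_LOOP, -1):
            if _PAIRABLE[codes[i], codes[k]]:
                inner = m[i + 1, k - 1] if k - 1 > i else 0
                outer = m[k + 1, j] if k + 1 <= j else 0
                if inner + outer + 1 == target:
                    chosen = k
                    break
        if chosen == -1:
            stack.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            if chosen - 1 > i:
                stack.append((i + 1, chosen - 1))
            if chosen + 1 < j:
                stack.append((chosen + 1, j))
    return pairs


def fold(sequence: str, min_length: int = DEFAULT_MIN_FOLD_LEN) -> tuple[str, int]:
    """Pair-maximising pseudoknot-free fold; returns (dot-bracket, n_pairs).

    Allowed pairs: AU, UA, GC, CG, GU, UG; minimum hairpin loop 3; N pairs
    nothing.  Deterministic.  ``min_length`` guards the screening path;
    pass 1 to fold arbitrary short sequences.
    """
    if len(sequence) < min_length:
        raise FoldTooShortError(
            f"sequence of length {len(sequence)} is shorter than {min_length}"
        )
    codes = np.array([_CODE.get(c, 4) for c in sequence], dtype=np.int8)
    if codes.shape[0] <= MIN_LOOP + 1:
        return "." * len(sequence), 0
    m = _fill_nussinov(codes, _PAIRABLE, MIN_LOOP)
    pairs = _traceback(codes, m)
    structure = ["."] * len(sequence)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return "".join(structure), int(m[0, codes.shape[0] - 1])


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 when unpaired); validates balance."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"illegal structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


def check_hairpin(candidate: HairpinCandidate,
                  criteria: HairpinCriteria | None = None) -> HairpinCandidate:
    """Evaluate the stem-loop verdict for a folded candidate.

    Pass requires: (i) every paired base of the small RNA arm partners into
    one contiguous opposite arm on a single side; (ii) unpaired bases in
    the small RNA region <= max_unpaired_in_mir; (iii) longest unpaired run
    in the region <= max_bulge_in_mir; (iv) neither the small RNA nor the
    implied star overlaps the terminal loop; (v) duplex pairs >=
    min_stem_pairs.
    """
    criteria = criteria or HairpinCriteria()
    structure = candidate.structure
    if len(structure) != len(candidate.sequence):
        raise ValueError("structure/sequence length mismatch")
    partner = pair_table(structure)
    mir_start, mir_end = candidate.mir_arm
    mir_len = mir_end - mir_start
    mir_positions = range(mir_start, mir_end)
    partners = sorted(partner[x] for x in mir_positions if partner[x] != -1)
    unpaired = sum(1 for x in mir_positions if partner[x] == -1)
    # longest unpaired run inside the small RNA region
    max_bulge = run = 0
    for x in mir_positions:
        run = run + 1 if partner[x] == -1 else 0
        max_bulge = max(max_bulge, run)
    metrics: dict = {
        "unpaired_in_mir": unpaired,
        "max_bulge_in_mir": max_bulge,
        "stem_pairs": len(partners),
        "arm_side": "na",
        "star_overlap_loop": False,
    }
    if not partners:
        metrics["star_overlap_loop"] = True  # small RNA sits in a loop
        candidate.metrics = metrics
        candidate.verdict = False
        return candidate
    if all(q >= mir_end for q in partners):
        side = "5p"
    elif all(q < mir_start for q in partners):
        side = "3p"
    else:
        side = "mixed"
    metrics["arm_side"] = side
    star_lo, star_hi = partners[0], partners[-1] + 1
    contiguous = (star_hi - star_lo) <= mir_len + criteria.star_span_slack
    # terminal loop bounded by the innermost pair of the small RNA arm
    if side == "5p":
        x_in = max(x for x in mir_positions if partner[x] != -1)
        loop = (x_in + 1, partner[x_in])
    elif side == "3p":
        x_in = min(x for x in mir_positions if partner[x] != -1)
        loop = (partner[x_in] + 1, x_in)
    else:
        loop = (0, 0)
    def overlaps(lo: int, hi: int) -> bool:
        return lo < loop[1] and loop[0] < hi
    star_overlap = overlaps(star_lo, star_hi) or overlaps(mir_start, mir_end)
    metrics["star_overlap_loop"] = star_overlap
    candidate.metrics = metrics
    candidate.verdict = (
        side in ("5p", "3p")
        and contiguous
        and unpaired <= criteria.max_unpaired_in_mir
        and max_bulge <= criteria.max_bulge_in_mir
        and not star_overlap
        and len(partners) >= criteria.min_stem_pairs
    )
    return candidate


def screen_hairpins(
    transcripts: list[TranscriptRecord],
    hits: list[SmallRNAHit],
    flank: int = DEFAULT_FLANK,
    criteria: HairpinCriteria | None = None,
    fold_fn: Callable[[str], tuple[str, int]] | None = None,
) -> list[HairpinCandidate]:
    """Fold and check one candidate per distinct small RNA locus."""
    by_id = {t.transcript_id: t for t in transcripts}
    fold_fn = fold_fn or fold
    seen: set[tuple[str, int, int]] = set()
    out: list[HairpinCandidate] = []
    for hit in sorted(hits, key=lambda h: (h.transcript_id, h.position, h.sequence)):
        key = (hit.transcript_id, hit.position, len(hit.sequence))
        if key in seen:
            continue
        seen.add(key)
        transcript = by_id[hit.transcript_id]
        interval, seq = extract_precursor(transcript, hit, flank)
        if len(seq) < DEFAULT_MIN_FOLD_LEN:
            continue
        structure, _score = fold_fn(seq)
        cand = HairpinCandidate(
            transcript_id=hit.transcript_id,
            precursor=interval,
            sequence=seq,
            mir_arm=(hit.position - interval[0],
                     hit.position - interval[0] + len(hit.sequence)),
            structure=structure,
        )
        out.append(check_hairpin(cand, criteria))
    return out


def nat_mirna_target_intersect(
    mirna_targets: list[tuple[str, str, bool]],
    nat_pairs: list[NATPair],
) -> list[NATmiRNATarget]:
    """Flag each (target_id, mirna, validated) triple by NAT membership."""
    members: set[str] = set()
    for p in nat_pairs:
        members.add(p.id_a)
        members.add(p.id_b)
    return [
        NATmiRNATarget(tid, name, tid in members, validated)
        for tid, name, validated in mirna_targets
    ]


def dinucleotide_shuffle(sequence: str, rng: random.Random) -> str:
    """Altschul-Erikson shuffle preserving dinucleotide composition."""
    if len(sequence) < 4 or len(set(sequence)) < 2:
        return sequence
    first, last = sequence[0], sequence[-1]
    vertices = sorted(set(sequence))
    while True:
        edges: dict[str, list[str]] = defaultdict(list)
        for a, b in zip(sequence, sequence[1:]):
            edges[a].append(b)
        # pick a random terminal edge for every vertex except the last
        terminal: dict[str, str] = {}
        for v in vertices:
            if v == last or not edges[v]:
                continue
            terminal[v] = edges[v].pop(rng.randrange(len(edges[v])))
        # the terminal edges must all lead (transitively) to `last`
        ok = True
        for v in terminal:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in terminal:
                    ok = False
                    break
                seen.add(cur)
                cur = terminal[cur]
            if not ok:
                break
        if not ok:
            continue
        for v in edges:
            rng.shuffle(edges[v])
        for v, w in terminal.items():
            edges[v].append(w)
        out = [first]
        cur = first
        for _ in range(len(sequence) - 1):
            nxt = edges[cur].pop(0)
            out.append(nxt)
            cur = nxt
        return "".join(out)
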