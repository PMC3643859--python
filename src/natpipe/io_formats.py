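"""Readers and writers for the external formats the pipeline touches.

Coordinate convention
---------------------
All in-memory coordinates are 0-based, half-open ``[start, end)``.  Every
emitted table uses 1-based inclusive coordinates; the matching reader
converts back, so a write/read round trip is the identity.

Sequences are normalised on input: ``U`` becomes ``T`` and lowercase is
uppercased.  ``N`` is allowed everywhere but never counts as a match in any
downstream comparison.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "TranscriptRecord",
    "AbundanceRead",
    "GenomeInterval",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "read_abundance_reads",
    "write_abundance_reads",
    "write_nat_table",
    "read_nat_table",
    "write_target_table",
    "read_target_table",
    "write_enrichment_table",
    "read_enrichment_table",
    "normalize_sequence",
    "build_transcripts",
]

NUCLEOTIDES = frozenset("ACGTN")

_NORMALIZE = str.maketrans("acgtunU", "ACGTTNT")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_sequence(raw: str) -> str:
    """Uppercase, convert U to T.  Does not validate the alphabet."""
    return raw.translate(_NORMALIZE)


@dataclass(frozen=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """One spliced transcript in sense orientation with its genomic span."""

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    genomic_start: int
    genomic_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.genomic_end <= self.genomic_start:
            raise ValueError(
                f"{self.transcript_id}: genomic_end must exceed genomic_start"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"{self.transcript_id}: illegal characters {sorted(bad)}"
            )

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chromosome, self.genomic_start, self.genomic_end, self.strand
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AbundanceRead:
    """A read sequence with its total library abundance."""

    read_id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"{self.read_id}: count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet_policy: str = "strict") -> list[tuple[str, str]]:
    """Parse FASTA into ``[(id, normalized_sequence), ...]`` in file order.

    The record id is the first whitespace-delimited token of the header.
    ``alphabet_policy`` is ``strict`` (any character outside ACGTN after
    normalisation is an error, reported with its line number) or ``lenient``
    (offending characters are replaced by N).
    """
    if alphabet_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        records.append((current_id, seq))

    with open(path) as handle:
        any_content = False
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            any_content = True
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if current_id in seen:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate record id {current_id!r}"
                    )
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                norm = normalize_sequence(line)
                bad = set(norm) - NUCLEOTIDES
                if bad:
                    if alphabet_policy == "strict":
                        raise FormatError(
                            f"{path}:{lineno}: illegal character(s) "
                            f"{sorted(bad)} in record {current_id!r}"
                        )
                    norm = "".join(c if c in NUCLEOTIDES else "N" for c in norm)
                chunks.append(norm)
        flush()
    if not any_content:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene coordinate tables
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path, dialect: str = "tsv5") -> dict[str, GenomeInterval]:
    """Read gene coordinates, returning ``{transcript_id: GenomeInterval}``.

    ``tsv5`` columns: transcript_id, chromosome, start (1-based inclusive),
    end (inclusive), strand.  ``gff3``: only rows of type ``mRNA`` are used
    and the id is taken from the ``ID=`` attribute.
    """
    if dialect not in ("tsv5", "gff3"):
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    path = Path(path)
    out: dict[str, GenomeInterval] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "tsv5":
                if len(fields) < 5:
                    fields = line.split()
                if len(fields) < 5:
                    raise FormatError(f"{path}:{lineno}: expected 5 columns")
                tid, chrom, start_s, end_s, strand = fields[:5]
            else:
                if len(fields) < 9:
                    raise FormatError(f"{path}:{lineno}: malformed GFF3 row")
                if fields[2] != "mRNA":
                    continue
                chrom, start_s, end_s, strand = fields[0], fields[3], fields[4], fields[6]
                tid = _gff3_id(fields[8])
                if tid is None:
                    raise FormatError(f"{path}:{lineno}: mRNA row lacks ID attribute")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 > end1:
                raise FormatError(f"{path}:{lineno}: start ({start1}) > end ({end1})")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if tid in out:
                raise FormatError(f"{path}:{lineno}: duplicate transcript id {tid!r}")
            out[tid] = GenomeInterval(chrom, start1 - 1, end1, strand)
    return out


def _gff3_id(attributes: str) -> str | None:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
    return None


def write_gene_table(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Emit a tsv5 gene table (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        for rec in sorted(records, key=lambda r: r.transcript_id):
            handle.write(
                f"{rec.transcript_id}\t{rec.chromosome}\t{rec.genomic_start + 1}"
                f"\t{rec.genomic_end}\t{rec.strand}\n"
            )


def build_transcripts(
    sequences: Sequence[tuple[str, str]],
    intervals: dict[str, GenomeInterval],
    gene_ids: dict[str, str] | None = None,
) -> list[TranscriptRecord]:
    """Join FASTA sequences with coordinate intervals by transcript id."""
    out = []
    for tid, seq in sequences:
        if tid not in intervals:
            raise FormatError(f"transcript {tid!r} has no coordinate annotation")
        iv = intervals[tid]
        gid = (gene_ids or {}).get(tid, tid)
        out.append(
            TranscriptRecord(tid, gid, iv.chromosome, iv.strand, iv.start, iv.end, seq)
        )
    return out


# ---------------------------------------------------------------------------
# Abundance reads
# ---------------------------------------------------------------------------

def sniff_abundance_dialect(path: str | Path) -> str:
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            return "fasta_suffix" if line.startswith(">") else "tsv2"
    raise FormatError(f"{path}: empty abundance file")


def read_abundance_reads(path: str | Path, dialect: str | None = None) -> list[AbundanceRead]:
    """Read abundance-annotated reads.

    Dialects: ``fasta_suffix`` (headers ``>id_COUNT``) or ``tsv2``
    (``sequence<TAB>count``).  ``None`` sniffs from the first record.
    Identical sequences are *not* collapsed here.
    """
    path = Path(path)
    if dialect is None:
        dialect = sniff_abundance_dialect(path)
    if dialect not in ("fasta_suffix", "tsv2"):
        raise ValueError(f"unknown abundance dialect {dialect!r}")
    reads: list[AbundanceRead] = []
    if dialect == "fasta_suffix":
        for rid, seq in read_fasta(path):
            stem, _, count_s = rid.rpartition("_")
            if not stem or not count_s.isdigit():
                raise FormatError(
                    f"{path}: record {rid!r} lacks a '_COUNT' integer suffix"
                )
            reads.append(AbundanceRead(rid, seq, int(count_s)))
    else:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns")
                seq, count_s = fields
                try:
                    count = int(count_s)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {count_s!r}"
                    ) from exc
                reads.append(
                    AbundanceRead(f"read{lineno}", normalize_sequence(seq), count)
                )
    return reads


def write_abundance_reads(reads: Iterable[AbundanceRead], path: str | Path) -> None:
    """Write reads in the fasta_suffix dialect (``>id_COUNT``)."""
    with open(path, "w") as handle:
        for i, read in enumerate(reads, start=1):
            handle.write(f">sr{i}_{read.count}\n{read.sequence}\n")


# ---------------------------------------------------------------------------
# Result tables (TSV, 1-based inclusive coordinates, deterministic order)
# ---------------------------------------------------------------------------

NAT_COLUMNS = [
    "id_a", "id_b", "overlap_len", "evalue", "class", "orientation",
    "a_start", "a_end", "b_start", "b_end",
]

TARGET_COLUMNS = [
    "sirna", "sirna_abundance", "target_id", "site_start", "site_end",
    "mismatches", "origin", "multiple", "tag_support",
]

ENRICHMENT_COLUMNS = [
    "scope", "No", "Nt", "Lo", "Lt", "Do_per_kb", "Dt_per_kb",
    "score", "chi2", "p",
]


def _write_tsv(path: str | Path, columns: list[str], rows: Iterable[Sequence]) -> None:
    try:
        handle = open(path, "w", newline="")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    with handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(rows)


def _read_tsv(path: str | Path, columns: list[str]) -> list[list[str]]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header != columns:
            raise FormatError(f"{path}: unexpected header {header!r}")
        return [row for row in reader if row]


def write_nat_table(pairs, path: str | Path) -> None:
    """NAT pairs as TSV; overlap coordinates 1-based inclusive."""
    rows = []
    for p in sorted(pairs, key=lambda p: (p.id_a, p.id_b)):
        rows.append([
            p.id_a, p.id_b, p.overlap_length, repr(p.evalue),
            p.locus_class, p.orientation,
            p.overlap_on_a[0] + 1, p.overlap_on_a[1],
            p.overlap_on_b[0] + 1, p.overlap_on_b[1],
        ])
    _write_tsv(path, NAT_COLUMNS, rows)


def read_nat_table(path: str | Path):
    from .nat_discovery import NATPair  # deferred: avoid import cycle

    pairs = []
    for row in _read_tsv(path, NAT_COLUMNS):
        (ida, idb, olen, ev, cls, orient, a1, a2, b1, b2) = row
        pairs.append(NATPair(
            id_a=ida, id_b=idb,
            overlap_on_a=(int(a1) - 1, int(a2)),
            overlap_on_b=(int(b1) - 1, int(b2)),
            overlap_length=int(olen),
            alignment_score=0,
            evalue=float(ev),
            locus_class=cls,
            orientation=orient,
        ))
    return pairs


def write_target_table(calls, path: str | Path) -> None:
    rows = []
    order = sorted(calls, key=lambda c: (c.target_id, c.site[0], c.sirna))
    for c in order:
        rows.append([
            c.sirna, c.sirna_abundance, c.target_id,
            c.site[0] + 1, c.site[1],
            ",".join(str(p) for p in c.mismatch_positions) or "-",
            c.origin, "yes" if c.multiple_flag else "no", c.tag_support,
        ])
    _write_tsv(path, TARGET_COLUMNS, rows)


def read_target_table(path: str | Path):
    from .degradome_targets import TargetCall

    calls = []
    for row in _read_tsv(path, TARGET_COLUMNS):
        (sirna, ab, tid, s1, s2, mm, origin, multi, support) = row
        positions = () if mm == "-" else tuple(int(x) for x in mm.split(","))
        calls.append(TargetCall(
            sirna=sirna, sirna_abundance=int(ab), target_id=tid,
            site=(int(s1) - 1, int(s2)), mismatch_positions=positions,
            origin=origin, multiple_flag=(multi == "yes"),
            tag_support=int(support),
        ))
    return calls


def write_enrichment_table(results, path: str | Path) -> None:
    rows = []
    for r in sorted(results, key=lambda r: r.scope):
        rows.append([
            r.scope, r.no, r.nt, r.lo, r.lt,
            repr(r.do * 1000.0), repr(r.dt * 1000.0),
            repr(r.score), repr(r.chi2), repr(r.p),
        ])
    _write_tsv(path, ENRICHMENT_COLUMNS, rows)


def read_enrichment_table(path: str | Path):
    from .sirna_profiling import EnrichmentResult

    results = []
    for row in _read_tsv(path, ENRICHMENT_COLUMNS):
        scope, no, nt, lo, lt, _do, _dt, score, chi2, p = row
        results.append(EnrichmentResult(
            scope=scope, no=int(no), nt=int(nt), lo=int(lo), lt=int(lt),
            score=float(score), chi2=float(chi2), p=float(p),
        ))
    return results
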