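"""Stage orchestration: run the full analysis from a config mapping.

Stages run in a fixed order — predict-nats, map-srna, enrich, targets,
hairpins, mirna-nat — each writing deterministic TSV outputs that the next
stage consumes, so re-running with unchanged inputs reproduces identical
bytes.  ``make_report`` condenses the stage outputs into summary tables.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import degradome_targets as dt
from . import hairpin_mirna as hm
from . import io_formats as io
from . import nat_discovery as nd
from . import sirna_profiling as sp

__all__ = [
    "RunConfig",
    "PipelineError",
    "predict_nats_stage",
    "map_srna_stage",
    "enrich_stage",
    "targets_stage",
    "hairpins_stage",
    "mirna_nat_stage",
    "run_all",
    "make_report",
    "write_hits_table",
    "read_hits_table",
]

logger = logging.getLogger("natpipe")

HITS_COLUMNS = ["transcript_id", "position", "length", "sequence", "count"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    transcripts: Path
    genes: Path
    srna: Path
    degradome: Path
    outdir: Path
    exclude: list[Path] = field(default_factory=list)
    mirna_targets: Path | None = None
    gene_dialect: str = "tsv5"
    evalue_max: float = 1e-9
    min_overlap: int = 31
    min_identity: float = 0.95
    degradome_flank: int = 20
    hairpin_flank: int = 200
    weighting: str = "total"

    def validate(self) -> None:
        required = [self.transcripts, self.genes, self.srna, self.degradome]
        required += list(self.exclude)
        if self.mirna_targets is not None:
            required.append(self.mirna_targets)
        missing = [str(p) for p in required if not Path(p).exists()]
        if missing:
            raise PipelineError("validate", f"missing input files: {missing}")

    def alignment_params(self) -> nd.AlignmentParams:
        return nd.AlignmentParams(
            evalue_max=self.evalue_max,
            min_overlap=self.min_overlap,
            min_identity=self.min_identity,
        )

    @classmethod
    def from_mapping(cls, mapping: dict, base: Path | None = None) -> "RunConfig":
        base = Path(base) if base else Path(".")
        def p(key):
            return base / mapping[key]
        exclude = [base / x for x in mapping.get("exclude", [])]
        mt = mapping.get("mirna_targets")
        return cls(
            transcripts=p("transcripts"), genes=p("genes"), srna=p("srna"),
            degradome=p("degradome"), outdir=base / mapping.get("outdir", "out"),
            exclude=exclude,
            mirna_targets=(base / mt) if mt else None,
            gene_dialect=mapping.get("gene_dialect", "tsv5"),
            evalue_max=float(mapping.get("evalue_max", 1e-9)),
            min_overlap=int(mapping.get("min_overlap", 31)),
            min_identity=float(mapping.get("min_identity", 0.95)),
            degradome_flank=int(mapping.get("degradome_flank", 20)),
            hairpin_flank=int(mapping.get("hairpin_flank", 200)),
            weighting=mapping.get("weighting", "total"),
        )


# ---------------------------------------------------------------------------
# Hits table
# ---------------------------------------------------------------------------

def write_hits_table(hits: list[sp.SmallRNAHit], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HITS_COLUMNS)
        for h in sorted(hits, key=lambda h: (h.transcript_id, h.position, h.sequence)):
            w.writerow([h.transcript_id, h.position + 1, len(h.sequence),
                        h.sequence, h.count])


def read_hits_table(path: Path) -> list[sp.SmallRNAHit]:
    hits = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != HITS_COLUMNS:
            raise io.FormatError(f"{path}: unexpected header {header!r}")
        for tid, pos, _length, seq, count in reader:
            hits.append(sp.SmallRNAHit(seq, int(count), tid, int(pos) - 1))
    return hits


def _load_transcripts(config: RunConfig) -> list[io.TranscriptRecord]:
    seqs = io.read_fasta(config.transcripts)
    intervals = io.read_gene_table(config.genes, config.gene_dialect)
    return io.build_transcripts(seqs, intervals)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def predict_nats_stage(config: RunConfig) -> Path:
    transcripts = _load_transcripts(config)
    params = config.alignment_params()
    pairs = nd.call_nat_pairs(transcripts, params)
    annotations = {t.transcript_id: t.span for t in transcripts}
    pairs = nd.classify_pairs(pairs, annotations)
    out = config.outdir / "nats.tsv"
    io.write_nat_table(pairs, out)
    logger.info("predict-nats: %d transcripts in, %d pairs out",
                len(transcripts), len(pairs))
    return out


def map_srna_stage(config: RunConfig) -> Path:
    transcripts = _load_transcripts(config)
    pairs = io.read_nat_table(config.outdir / "nats.tsv")
    members = {p.id_a for p in pairs} | {p.id_b for p in pairs}
    nat_transcripts = [t for t in transcripts if t.transcript_id in members]
    reads = io.read_abundance_reads(config.srna)
    exclusion = {
        Path(path).stem: io.read_fasta(path) for path in config.exclude
    } or None
    kept, removed = sp.filter_excluded(reads, exclusion)
    hits = sp.map_exact(kept, nat_transcripts)
    out = config.outdir / "hits.tsv"
    write_hits_table(hits, out)
    logger.info("map-srna: %d reads in, %d removed by exclusion, %d hits",
                len(reads), len(removed), len(hits))
    return out


def enrich_stage(config: RunConfig) -> Path:
    transcripts = _load_transcripts(config)
    lengths = {t.transcript_id: len(t.sequence) for t in transcripts}
    pairs = io.read_nat_table(config.outdir / "nats.tsv")
    hits = read_hits_table(config.outdir / "hits.tsv")
    by_tid: dict[str, list[sp.SmallRNAHit]] = {}
    for h in hits:
        by_tid.setdefault(h.transcript_id, []).append(h)
    results = []
    bias_rows = []
    expressed = []
    for pair in pairs:
        pair_hits = by_tid.get(pair.id_a, []) + by_tid.get(pair.id_b, [])
        if not pair_hits:
            continue
        expressed.append(pair)
        try:
            results.append(sp.pair_enrichment(pair, pair_hits, lengths))
        except ValueError:
            pass
        for weighting in ("total", "unique"):
            call = sp.strand_bias(pair, pair_hits, weighting)
            bias_rows.append([call.pair_id, weighting,
                              repr(call.count_a), repr(call.count_b),
                              repr(call.ratio), call.category])
    if expressed:
        results.append(sp.pooled_enrichment(expressed, hits, lengths))
    out = config.outdir / "enrichment.tsv"
    io.write_enrichment_table(results, out)
    with open(config.outdir / "strand_bias.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pair_id", "weighting", "count_a", "count_b", "ratio",
                    "category"])
        w.writerows(bias_rows)
    logger.info("enrich: %d expressed pairs", len(expressed))
    return out


def targets_stage(config: RunConfig) -> Path:
    transcripts = _load_transcripts(config)
    pairs = io.read_nat_table(config.outdir / "nats.tsv")
    members = {p.id_a for p in pairs} | {p.id_b for p in pairs}
    nat_transcripts = [t for t in transcripts if t.transcript_id in members]
    hits = read_hits_table(config.outdir / "hits.tsv")
    sirnas = [io.AbundanceRead(f"h{i}", h.sequence, h.count)
              for i, h in enumerate(hits)]
    tags = io.read_abundance_reads(config.degradome)
    dhits = dt.map_degradome(tags, nat_transcripts)
    calls = dt.call_targets(sirnas, dhits, pairs, nat_transcripts,
                            flank=config.degradome_flank)
    out = config.outdir / "targets.tsv"
    io.write_target_table(calls, out)
    logger.info("targets: %d tags, %d placements, %d calls",
                len(tags), len(dhits), len(calls))
    return out


def hairpins_stage(config: RunConfig) -> Path:
    transcripts = _load_transcripts(config)
    hits = read_hits_table(config.outdir / "hits.tsv")
    candidates = hm.screen_hairpins(transcripts, hits,
                                    flank=config.hairpin_flank)
    out = config.outdir / "hairpins.tsv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "precursor_start", "precursor_end",
                    "mir_start", "mir_end", "verdict", "unpaired_in_mir",
                    "max_bulge_in_mir", "stem_pairs", "arm_side"])
        for c in candidates:
            w.writerow([
                c.transcript_id, c.precursor[0] + 1, c.precursor[1],
                c.precursor[0] + c.mir_arm[0] + 1,
                c.precursor[0] + c.mir_arm[1],
                "pass" if c.verdict else "fail",
                c.metrics.get("unpaired_in_mir", ""),
                c.metrics.get("max_bulge_in_mir", ""),
                c.metrics.get("stem_pairs", ""),
                c.metrics.get("arm_side", ""),
            ])
    with open(config.outdir / "hairpins.structures.txt", "w") as fh:
        for c in candidates:
            fh.write(f">{c.transcript_id}:{c.precursor[0] + 1}-{c.precursor[1]}\n")
            fh.write(c.sequence + "\n")
            fh.write(c.structure + "\n")
    logger.info("hairpins: %d candidates, %d pass",
                len(candidates), sum(c.verdict for c in candidates))
    return out


def mirna_nat_stage(config: RunConfig) -> Path | None:
    if config.mirna_targets is None:
        return None
    pairs = io.read_nat_table(config.outdir / "nats.tsv")
    triples = []
    with open(config.mirna_targets, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            tid, name = row[0], row[1]
            validated = len(row) > 2 and row[2].strip().lower() in ("yes", "1", "true")
            triples.append((tid, name, validated))
    flagged = hm.nat_mirna_target_intersect(triples, pairs)
    out = config.outdir / "nat_mirna.tsv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_id", "mirna", "is_nat_member", "validated"])
        for t in flagged:
            w.writerow([t.target_id, t.mirna,
                        "yes" if t.is_nat_member else "no",
                        "yes" if t.validated_flag else "no"])
    logger.info("mirna-nat: %d targets, %d NAT members",
                len(flagged), sum(t.is_nat_member for t in flagged))
    return out


_STAGES = [
    ("predict-nats", predict_nats_stage),
    ("map-srna", map_srna_stage),
    ("enrich", enrich_stage),
    ("targets", targets_stage),
    ("hairpins", hairpins_stage),
    ("mirna-nat", mirna_nat_stage),
]


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage in order; any failure aborts with the stage name."""
    config.validate()
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    for name, stage in _STAGES:
        try:
            result = stage(config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        if result is not None:
            outputs[name] = result
    return outputs


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

OVERLAP_BINS = [("31-99", 31, 100), ("100-200", 100, 201), (">200", 201, None)]


def make_report(outdir: Path) -> dict[str, Path]:
    """Summary tables over the stage outputs (deterministic TSVs)."""
    outdir = Path(outdir)
    pairs = io.read_nat_table(outdir / "nats.tsv")
    written: dict[str, Path] = {}

    def table(name: str, header: list[str], rows: list) -> None:
        path = outdir / f"report_{name}.tsv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(header)
            w.writerows(rows)
        written[name] = path

    # antisense-degree histogram
    degrees = nd.antisense_degree(pairs)
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d.n_antisense_partners] = hist.get(d.n_antisense_partners, 0) + 1
    table("antisense_degree", ["n_partners", "n_transcripts"],
          [[k, hist[k]] for k in sorted(hist)])

    # overlap-length bins
    rows = []
    for label, lo, hi in OVERLAP_BINS:
        n = sum(1 for p in pairs
                if p.overlap_length >= lo and (hi is None or p.overlap_length < hi))
        rows.append([label, n])
    table("overlap_bins", ["bin", "n_pairs"], rows)

    # orientation / class tallies
    tallies: dict[tuple[str, str], int] = {}
    for p in pairs:
        key = (p.locus_class, p.orientation)
        tallies[key] = tallies.get(key, 0) + 1
    table("pair_classes", ["class", "orientation", "n_pairs"],
          [[c, o, n] for (c, o), n in sorted(tallies.items())])

    # size distribution
    hits_path = outdir / "hits.tsv"
    if hits_path.exists():
        hits = read_hits_table(hits_path)
        dist = sp.size_distribution(hits)
        table("size_distribution", ["length", "unique", "total"],
              [[k, v["unique"], v["total"]] for k, v in dist.items()])

    # strand-bias fractions
    bias_path = outdir / "strand_bias.tsv"
    if bias_path.exists():
        counts: dict[tuple[str, str], int] = {}
        with open(bias_path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader)
            for row in reader:
                key = (row[1], row[5])
                counts[key] = counts.get(key, 0) + 1
        table("strand_bias_summary", ["weighting", "category", "n_pairs"],
              [[w, c, n] for (w, c), n in sorted(counts.items())])

    # origin-code tallies
    targets_path = outdir / "targets.tsv"
    if targets_path.exists():
        calls = io.read_target_table(targets_path)
        origin_counts: dict[str, int] = {}
        for c in calls:
            origin_counts[c.origin] = origin_counts.get(c.origin, 0) + 1
        table("origin_codes", ["origin", "n_calls"],
              [[o, n] for o, n in sorted(origin_counts.items())])
    return written
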