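# natpipe

Prediction and small-RNA profiling of natural antisense transcripts (NATs).

Given a set of transcript sequences and their gene coordinates, `natpipe`

1. **calls NAT pairs** by antisense complementarity (ungapped seed-and-extend
   alignment against the reverse complement, gapless Karlin–Altschul
   E-values, default cutoff `1e-9`, minimum overlap 31 nt),
2. **classifies each pair** as *cis* (overlapping gene spans on opposite
   strands of one locus) or *trans*, and types cis pairs as convergent /
   divergent / enclosed,
3. **maps small RNA libraries** onto NAT transcripts (exact, full-length,
   sense-orientation matches after screening against optional exclusion
   sets), reports per-pair strand bias (One / Equal / Bias with the
   `0.5 ≤ ratio ≤ 2` band) and overlap-region enrichment
   (density ratio Do/Dt with a 1-df χ² test and a paired t-test across
   pairs),
4. **calls nat-siRNA targets** from degradome 5′-tags: tags are mapped
   exactly, a ±20 nt "long degradome" window is extracted around each tag,
   small RNAs are aligned antisense with ≤3 substitutions and no indels,
   and sites are kept only when mismatch positions satisfy the
   position-specific rule (≤1 in positions 1–9, none at 10–11, ≤2 after 11);
   accepted calls carry an origin code (`a`/`s`/`o`, `multiple` when the
   small RNA matches >5 transcripts),
5. **screens for pre-miRNA-like hairpins** around small RNA loci (±200 nt
   precursor, built-in base-pair-maximization folding with a pluggable
   engine seam, configurable stem-loop criteria), and intersects external
   miRNA target lists with NAT membership.

A fully seeded synthetic-data generator (`natpipe.synthetic_data`) plants
NAT pairs of every orientation, overlap-concentrated small RNA clouds with
controlled strand bias, rule-compliant and rule-violating target sites, and
inverted-repeat precursors, together with a ground-truth manifest — so the
whole pipeline is testable without any external downloads.

## CLI

```bash
# generate a synthetic dataset with ground truth
natpipe simulate --seed 7 --outdir sim/

# run every stage end-to-end and write summary report tables
natpipe run-all \
    --fasta sim/transcripts.fa --genes sim/genes.tsv \
    --reads sim/srna.fa --degradome sim/degradome.fa \
    --exclude sim/exclude.fa --outdir out/

# individual stages
natpipe predict-nats --fasta T.fa --genes T.tsv --evalue 1e-9 \
    --min-overlap 31 --out nats.tsv
natpipe report --outdir out/
```

Outputs are plain TSV (1-based inclusive coordinates in all emitted tables;
0-based half-open internally): `nats.tsv`, `hits.tsv`, `enrichment.tsv`,
`strand_bias.tsv`, `targets.tsv`, `hairpins.tsv` (+ Vienna-style structure
records), `nat_mirna.tsv`, and `report_*.tsv` summaries.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes independent brute-force oracles (all-offsets
complementarity scan, substring scans, truth-table enumeration of the
mismatch-position rule, exhaustive secondary-structure enumeration),
property tests, and `tests/test_acceptance.py` with end-to-end
planted-truth recovery, statistical calibration of the enrichment test,
and byte-level determinism checks.

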