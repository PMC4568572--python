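# ipactools

Genome-wide discovery, classification and characterization of **intergenic
poly(A) site clusters (IPACs)** from poly(A)-tag data.

Given a GFF3 annotation, mapped cleavage sites (BED6, score = tag count) and
a genome FASTA, the pipeline:

1. applies a 50-nt 3'-UTR extension and derives strand-specific intergenic
   intervals (`genome_model`);
2. single-linkage clusters cleavage sites at 24 nt into PACs, drops clusters
   with fewer than 3 tags, and filters internal-priming artifacts (>50 % A or
   >60 % A+G in the downstream 20 nt) (`pat_processing`);
3. assigns each PAC a single genomic category (3'-UTR / CDS / intron /
   5'-UTR / exon / pseudogenic exon / ambiguous / intergenic) and keeps the
   intergenic subset (`pac_annotation`);
4. measures the four distances from each IPAC to its 5'/3' sense and
   antisense neighbors plus normalized intergenic positions (`neighborhood`);
5. samples random intergenic background positions and builds a binned
   empirical FDR over distance (20-nt steps to 2000 nt) to select the
   sense-extension cutoff (`null_model`);
6. labels every IPAC by an ordered rule cascade — sense extension (SE),
   antisense (A, priming-filtered), antisense-proximal, sense-promoter,
   sense-orphan (SO) (`classification`);
7. profiles per-position base composition around sites and classifies
   poly(A) signals (AATAAA / 18 one-nt variants / none) (`signal_analysis`);
8. recruits SE-IPACs as additional 3'-UTR PACs and compares 3'-UTR length
   distributions before/after (rank-sum test, rank-wise medians, mean
   extension) (`utr_extension`);
9. clusters far-from-gene SO-IPACs at the within-gene inter-PAC distance,
   associates sites/clusters with external evidence BEDs, computes
   expression correlations and cross-sample IPAC sharing
   (`downstream_inference`).

A `synthetic_data` module generates annotated toy genomes with poly(A) tags
planted in known classes (with labeled truth tables), so the whole pipeline
is testable without any external data.

## CLI

```sh
# synthesize a genome + tags with planted classes
ipac simulate --seed 3 --out sim/

# full pipeline
ipac run --gff3 sim/genome.gff3 --tags sim/tags.bed --fasta sim/genome.fa \
         --out run/ --seed 3

# individual stages
ipac annotate --gff3 sim/genome.gff3 --out-bed intergenic.bed
ipac cluster --tags sim/tags.bed --out pacs.tsv
ipac classify --gff3 sim/genome.gff3 --tags sim/tags.bed \
              --fasta sim/genome.fa --out classes.tsv
ipac signals --sites classes.tsv --fasta sim/genome.fa --out profile.tsv
ipac utr --gff3 sim/genome.gff3 --tags sim/tags.bed \
         --fasta sim/genome.fa --out utr_lengths.tsv
ipac cluster-so --gff3 sim/genome.gff3 --tags sim/tags.bed \
                --fasta sim/genome.fa --out so_clusters.tsv
ipac compare-samples --a run1/pacs.tsv --b run2/pacs.tsv --window 50
ipac verify --items run/ipac_classes.tsv --evidence ests.bed \
            --name est --window 500 --anchor-mode point
ipac defaults     # print every default parameter
```

`ipac run` writes flat TSV/BED intermediates plus `manifest.json` (config,
seed, content hashes); reruns with the same config are byte-identical.
Configuration can also be supplied as YAML (`ipac run --config cfg.yaml`);
the single `--seed` fans out to per-stage seeds by stable hashing, so adding
a stage never perturbs earlier stages' randomness.

## Layout

```
src/ipactools/        one module per pipeline stage (see list above)
  cli.py              click-based `ipac` entry point
  pipeline.py         PipelineConfig + run_pipeline orchestration
tests/                pytest suite; test_acceptance.py holds the
                      acceptance criteria (oracle equivalence, null
                      calibration, planted-class recovery, signal suite)
scripts/acceptance.py acceptance report generator
```

## Conventions

Internally all coordinates are 0-based half-open; cleavage positions are
junction (between-base) coordinates, so a site exactly on a boundary is at
distance 0 and the two flanking-gene distances of an intergenic interval sum
to its length. GFF3 and BED I/O follow each format's own convention (BED
site rows are `[pos, pos+1)` with start = junction).
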