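# homeokit

Homeolog-aware analysis toolkit for polyploid loci: paralog-discriminating
probe design, exact-match allele counting in sequencing reads, binomial
allele-dosage inference with chi-square goodness-of-fit tests,
frameshift-consequence prediction, FPKM-based expression filtering and
set-partition logic, and a two-stage logistic growth-curve analysis.
A fully seeded synthetic-data module generates every input the pipeline
consumes, so the whole workflow is testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `homeokit.seqcore` | Sequence primitives: reverse complement, canonical (leftmost-normalized) deletions, standard-code translation, frameshift reports, identity-based paralog assignment |
| `homeokit.probe_design` | Paralog-unique ref/alt probe pairs around a deletion site, verified by exact substring scan on both strands |
| `homeokit.probe_count` | Streaming FASTQ/FASTA (optionally gzipped) exact-match probe counting with per-read accounting |
| `homeokit.dosage` | ML integer dosage (d of m alleles, binomial model), Pearson chi-square GOF (df=1, no continuity correction), configuration ranking |
| `homeokit.quant` | FPKM, "expressed in all replicates of ≥1 treatment" filter, BH-FDR, fold-change estimation, unique/common/opposite DE partition |
| `homeokit.growth` | Stage 1: per-replicate logistic fits (A, r, t_half, Δt(½→¾)=ln3/r, R²); stage 2: per-parameter one-way (or Welch) ANOVA |
| `homeokit.synthetic_data` | Seeded generators: homeologous paralogs, deletion genotypes, short reads, clone sets, NB count matrices, growth trajectories |
| `homeokit.cli` | `homeokit` command-line interface |

## CLI

```sh
# synthetic locus bundle (refs.fasta, pool.fasta, reads.fastq, truth.json)
homeokit simulate --seed 7 --outdir run/

# design a probe pair around a 1-bp deletion (default window: 39-nt ref probe)
homeokit design --refs run/refs.fasta --target paralog03 --del-pos 1000 \
    --out probes.tsv

# classify reads by exact probe match on either strand
homeokit count --probes probes.tsv --reads run/reads.fastq \
    --sample-id demo --out counts.csv

# dosage inference (d of m); hypotheses default to the full 0..m grid
homeokit dosage --counts counts.csv --m 6 --out dosage.csv
homeokit dosage --n-alt 5 --n-ref 21 --m 6 --hyp 1/6 --hyp 4/6 --out dosage.csv

# expression pipeline: FPKM, expressed filter, stand-in DE test, partition
homeokit quant --counts counts_matrix.csv --lengths lengths.csv \
    --meta meta.csv --out-prefix quant

# two-stage growth analysis
homeokit growth --trajectories heights.csv --out-prefix growth

# end-to-end synthetic workflow driven by a YAML config
homeokit report --config run.yaml --out report.json
```

Each command writes a `*.provenance.json` record (tool version, subcommand,
full configuration) next to its primary output. Exit codes: 0 success,
2 usage error, 3 data error.

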