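# alubis

Discovery of evolutionarily recent Alu insertions from Alu-anchored
bisulfite PCR sequence reads, rebuilt as a tested, reusable pipeline that
runs end-to-end on synthetic genomes with known truth.

Reads from this library design carry a 5' genomic flank followed by the 5'
end of an Alu element, from bisulfite-converted DNA. The pipeline:

1. **simulate** (`alubis.simulate`) — toy reference seeded with annotated
   Alu copies; de-novo TPRT insertions (TT/AAAA-like nick, target-site
   duplication of 4–17 nt, optionally 5'-truncated AluY-subfamily body,
   poly-A tail of 11–45 nt, hemizygous or homozygous); per-CpG methylome;
   bisulfite amplicon reads with configurable conversion and error rates,
   plus complete truth tables.
2. **prepare** (`alubis.reference`) — builds the in-silico converted
   reference (C→T and G→A spaces), masks the Alu portion of each read by
   conversion-aware local alignment against consensus 5' ends, and keeps
   flanks of ≥ 40 bp.
3. **map** (`alubis.mapper`) — multi-cycle seed-and-extend mapping with
   decreasing word sizes (100, 80, 60, 40), 95% identity cutoffs, a final
   best-perfect-match ≥ 40 bp cycle, and a score-margin ambiguity rule.
4. **call** (`alubis.calling`) — junctions within 10 bp of an annotated
   Alu 5' boundary are the known class; the rest are clustered
   (single-linkage, 10 bp), cross-referenced against known
   polymorphic-insertion BEDs, annotated with genic context, and
   summarized per library (insertion regions per 100 mapped regions).
5. **features** (`alubis.features`) — TSD detection, TT/AAAA cleavage-site
   scoring, poly-A run measurement, subfamily classification by
   best-scoring consensus.
6. **methylation** (`alubis.methylation`) — per-read per-CpG calls against
   the unconverted local reference (retained C = methylated), region
   summaries (whole element, A box 5–16, B box 75–84, arms), lollipop
   matrices, incomplete-conversion QC, and hemizygous allele comparison.

`alubis.datasets` bundles the published eight-library counts and the
nineteen verified insertion loci as worked-example inputs for the
reporting code.

## CLI

```sh
# generate a synthetic dataset with truth tables
alubis simulate --seed 1 --genome-length 100000 --n-novel-insertions 5 --outdir sim_out

# run the whole pipeline from a config file
alubis run --config config.yaml

# or stage by stage (byte-identical to `run`)
alubis prepare --reads sim_out/reads.fastq --read-libraries sim_out/read_libraries.tsv --outdir out
alubis map --reference sim_out/reference.fasta --outdir out
alubis call --repeats sim_out/repeats.bed --known sim_out/known.bed \
            --genes sim_out/genes.bed --library-metadata sim_out/library_metadata.tsv --outdir out
alubis features --alleles-fasta sim_out/alleles.fasta --alleles-meta sim_out/alleles.tsv --outdir out
alubis methylation --reads sim_out/reads.fastq --alleles-fasta sim_out/alleles.fasta \
            --alleles-meta sim_out/alleles.tsv --outdir out
```

A config file holds every parameter (all keys of
`alubis.cli.PipelineConfig`; flags override). Outputs are plain-text TSV /
BED / JSON, plus a `manifest.json` recording version, seed, parameters,
and input checksums. Exit codes: 0 ok, 2 configuration error, 3 stage
failure.

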