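# deepintron

Ensemble consensus variant calling and deep-intronic variant
prioritization for targeted gene panels, as a tested, reusable pipeline:

* **variant model** — normalized `(chrom, pos, ref, alt)` variant keys
  (left-align + trim, multiallelic split) so calls from different callers
  and annotation tables join deterministically; readers/writers for
  VCF 4.2 (pysam), BED, BED12/GFF3 gene models, score TSVs and PED-style
  pedigrees.
* **consensus calling** — k-of-n merge over per-caller callsets
  (default: at least 2 of 4 callers), read-depth filter (default DP >= 20,
  minimum over supporting callers), on-target restriction, and truth-set
  benchmarking (TP/FP/FN, sensitivity = TP/(TP+FN), precision = TP/(TP+FP)).
* **annotation** — left-join of precomputed scores (CADD PHRED, GWAVA
  region score, Genomiser variant score, SPIDEX dPSI, 1000G EUR / gnomAD
  MAFs, clinical class), splice-distance region classification
  (canonical <= 2 nt, proximal 3–99, deep intronic >= 100 nt) and TF-peak
  overlap.
* **prioritization** — per-tool thresholds (CADD > 15, GWAVA >= 0.5,
  Genomiser > 0.6, |dPSI| > 5; all configurable), tool-set partition
  (Venn groups) and tiers (tier 1 = CADD ∧ GWAVA ∧ Genomiser).
* **cohort analysis** — cohort allele frequencies (with X-linked
  hemizygosity), fold enrichment vs reference MAFs, compound-heterozygote
  detection (exonic pathogenic × tier-1 intronic), pedigree segregation
  summaries with monogenic/digenic consistency flags.
* **synthetic data** — seeded generators for every input: toy genomes and
  gene models, truth sets, per-caller callsets with independent error
  rates and indel representation jitter, score tables separated around
  the thresholds, cohort matrices at planted allele frequencies, and
  families under digenic/monogenic penetrance rules.
* **packaged fixtures** — the published 26-row intronic score table, the
  classified exonic variant table, two family pedigrees and a
  frequency-consistent 16-proband genotype matrix, so everything runs
  offline.

## Command line

One executable, `deepintron`, with subcommands:

```sh
deepintron consensus  --vcf c1=a.vcf --vcf c2=b.vcf -k 2 --min-depth 20 \
                      --targets targets.bed --reference ref.fa --out consensus.vcf
deepintron benchmark  --vcf c1=a.vcf --vcf c2=b.vcf --truth truth.vcf --out bench.tsv
deepintron annotate   --scores scores.tsv --gene-models genes.bed12 \
                      --tf-peaks peaks.bed --out annotated.tsv
deepintron prioritize --scores scores.tsv --out prioritized.tsv --venn-out venn.tsv
deepintron cohort     --genotypes cohort.tsv --scores scores.tsv --out enrichment.tsv
deepintron segregate  --ped family.tsv --out segregation.tsv
deepintron simulate   --seed 1 --out simdir/
deepintron run        --config pipeline.yaml --out outdir/
deepintron fixtures   --out fixturedir/          # copy packaged fixtures
```

Exit statuses: 0 success, 2 usage error, 3 data error, 1 unexpected failure.
Thresholds can come from a flat YAML (`--config`) or per-flag overrides
(`--cadd-min`, `--gwava-min`, `--genomiser-min`, `--spidex-abs-min`).

### Pipeline config (`deepintron run`)

```yaml
callers: {caller_1: caller_1.vcf, caller_2: caller_2.vcf}  # optional
reference: reference.fa        # optional, enables indel left-alignment
truth_vcf: truth.vcf           # optional, writes benchmark.tsv
targets_bed: targets.bed       # optional
gene_models: genes.bed12       # optional (.bed12/.gff3)
score_table: scores.tsv        # variant source when no callers given
exonic_table: exonic.tsv       # optional, enables compound-het detection
tf_peaks: peaks.bed            # optional
cohort: cohort.tsv             # optional, enables enrichment
pedigrees: [{path: family.tsv, variants: [rs1, rs2]}]
thresholds: {cadd_min: 15, gwava_min: 0.5, genomiser_min: 0.6, spidex_abs_min: 5}
k: 2
min_depth: 20
fold_threshold: 3.0
reference_population: 1000g
```

Outputs: `consensus.vcf`, `benchmark.tsv`, `prioritized.tsv`,
`venn_counts.tsv`, `enrichment.tsv`, `compound_het.tsv`,
`segregation_<family>.tsv` and a `manifest.json` recording input digests
and per-stage in/out counts (the filtering funnel is asserted monotone).
Reruns on identical inputs produce byte-identical TSV/VCF outputs.

## File formats

* Score tables: TSV with header columns
  `var_id gene hgvs cadd_phred gwava_region genomiser spidex_dpsi
  maf_1000g maf_gnomad clinical_class proband_freq` (plus optional
  `chrom pos ref alt` for tuple joins). `NA`/`.`/empty load as null;
  a literal `0` is numeric zero.
* Cohort matrices: `sample<TAB>sex<TAB><variant label>...` with cells
  `hom_ref/het/hom_alt/hemi/missing`.
* Pedigrees: `family individual father mother sex phenotype <label>...`
  with carrier cells `het/hom/ref/untyped`.
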