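# svfuse

Fuse structural-variant (SV) callsets from multiple callers into a single
filtered, breakpoint-smoothed callset using a trained group-expectation
model.

## How it works

**Training.** Per-sample VCF callsets from *n* callers are compared against a
truth set inside partitions defined by SV type (DEL/DUP/INV) and size bin.
For each partition, a pooled weighted pairwise distance matrix (base-pair
Jaccard by default) is computed over all training samples, and every
nonempty subset *G* of callers receives an expectation

```
E(G) = prod over i in G of  [1 - D(c_i, c_t)] * max over j in G\{i} of D(c_j, c_i)
```

which rewards accuracy against truth and dissimilarity among members — a
pair of redundant callers collapses to 0, a complementary pair retains its
value. Calls are projected onto maximal disjoint coordinate segments labeled
by their supporting caller set; an expectation cutoff α per partition is
fitted by exhaustive search to minimise the pooled distance between the
surviving (fused) segments and the truth. Per-caller breakpoint spreads
(sample SD of offsets versus matched truth breakpoints) are estimated for
later smoothing.

**Discovery.** A new sample is partitioned the same way; segments are scored
by subset lookup, those below α are discarded, survivors are joined
(length-weighted mean expectation), per-type partitions are merged smallest
bin first (overlap resolved by discarding the lower-expectation call), and
breakpoints are smoothed by inverse-spread-weighted combination of the
contributing callers' breakpoints. A permutation Mantel test between the
sample's caller-distance matrix and each candidate model's diagnoses model
fit and drives model selection.

A fully deterministic simulator (truth sets with controlled type/size
distributions; per-caller sensitivity by partition, Gaussian breakpoint
jitter, false-positive rates and shared FP pools for caller correlation)
makes the whole pipeline testable offline.

## CLI

```sh
# write a synthetic cohort (per-caller VCFs + truth VCFs + genome table)
svfuse simulate --out cohort/ --seed 1 --samples 6 --truth-count 400 --callers 4

# train a fusion model on samples with truth
svfuse train --cohort cohort/ --out model.json --report etable.tsv \
       --samples sample_0 --samples sample_1 --samples sample_2

# apply it (several --model flags trigger Mantel-based model selection)
svfuse apply --model model.json --cohort cohort/ --sample sample_3 \
       --out fused.vcf --diagnostics diag.json

# score any callset against a truth VCF, overall and per partition
svfuse evaluate --calls fused.vcf --truth cohort/samples/sample_3/truth.vcf \
       --genome cohort/genome.tsv
```

Cohort layout: `genome.tsv` (contig lengths), `callers.yaml` (caller name →
integer id), `samples/<sample_id>/<caller>.vcf` and optional
`samples/<sample_id>/truth.vcf`. Options such as bin edges, metric, BED
exclusion mask and mask overlap threshold go in a YAML config passed with
`--config`. Exit codes: 0 success, 2 usage/config error, 3 data error.

Output VCFs carry `SVTYPE`, `END`, `SVLEN`, plus `SVEX` (fused expectation)
and `SVMETHOD` (supporting caller ids); genotypes are emitted as a `./1`
placeholder.

## Package layout

| module | contents |
|---|---|
| `svfuse.genome` | flattened-coordinate genome table |
| `svfuse.core` | Call/Callset/Observation, bin scheme, filter/mask/partition |
| `svfuse.intervals` | inclusive-interval merge/intersect primitives |
| `svfuse.vcf_io` | VCF read/write (cyvcf2/pysam), BED mask |
| `svfuse.similarity` | the four metrics, distances, pooled matrices |
| `svfuse.train` | group expectations, projection, cutoff fit, spreads, model I/O |
| `svfuse.discovery` | filter/fuse, priority merge, smoothing, Mantel, selection |
| `svfuse.simulate` | deterministic cohort simulator |
| `svfuse.cli` | `svfuse` command group |
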