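# Methods

## Detection model

`lgtscan` calls bacterial–human lateral gene transfer (LGT) from
paired-end RNA-seq using discordant pair geometry alone. The underlying
model: an expressed integration produces fragments that straddle the
host–bacteria junction; when the junction falls in the unsequenced
insert, one mate is purely host sequence and the other purely bacterial.
The pipeline therefore never attempts within-read (split-read)
breakpoint resolution — the junction is localized only to the interval
between the two mate alignments, and an event's coordinates are the
mates' alignment intervals, not the breakpoint itself. Consequences:

- Two independent biological integrations at nearby but distinct
  positions are distinct events only if their read placements differ;
  byte-identical library duplicates always collapse.
- Resolution is bounded by the insert size (~300 bp at defaults).

The pair must be *exclusively* chimeric: the host-mapped mate is
realigned to the bacterial references and the pair is discarded if it
maps there too. This guards against host–bacteria homologous sequence
(e.g. conserved rRNA-like stretches) masquerading as integration.

## Aligner

The built-in aligner is a deterministic seed-and-extend local aligner
behind a pluggable contract (an external SAM-producing aligner can be
substituted via `iter_half_mapped_sam`, which applies the same
flag-4/8/2048 semantics used for extraction).

- Exact k-mer seeding (k = 15) at every read offset, both strands;
  seeded diagonals are clustered per reference (band 12) and each
  cluster is extended by affine-gap Smith–Waterman in a padded window.
  A full-length exact match short-circuits the DP, which keeps
  error-free data fast; the DP kernel is numba-compiled.
- Scores are bwa-mem-like: match +1, mismatch −4, gap open −6, gap
  extend −1 (a gap of length g costs 6 + g), mapped iff score ≥ 30. A
  read shorter than k is unmapped by definition.
- Exactly one primary hit is reported; ties break deterministically:
  highest score, then smallest reference id, then smallest start, then
  forward strand. Determinism here is what makes whole-pipeline reruns
  byte-identical.
- `N` never matches anything (including another `N`), so ambiguous
  bases count as mismatches.

Because references are indexed independently, an alignment can never
span a reference boundary. Property tests verify score equality with a
full Smith–Waterman oracle whenever an exact seed survives inside the
optimal alignment; reads whose optimum contains no 15-mer seed (dense
mutation clusters) can be missed, which is the standard seeding
trade-off.

## Filtering cascade

Applied to candidates in order, each stage counted in a `FilterReport`:

| Filter | Rule | Default | Rationale |
| --- | --- | --- | --- |
| coverage | aligned read bases / read length ≥ threshold on **both** mates | 0.90 | partial alignments are unreliable evidence; "reads" is taken to mean each mate |
| low complexity | homopolymer run ≥ 20 bp or one base > 80% of a mate | on | poly-A/T/G/C artifacts; thresholds are config-exposed since no canonical value exists |
| repeat overlap | host interval overlaps a repeat interval by ≥ 1 bp (half-open) | exclude | sites in repeats are ambiguous; a `--keep-repeats` switch retains them flagged, since annotating rather than excluding is equally defensible |
| deduplication | one event per (host chrom, host start, accession, bacterial start) | — | identical junctions are treated as PCR/optical duplicates; per-sample, not cohort-wide, because the artifact is library-level |

The junction key uses exact alignment starts with no positional binning:
"same position" is read literally, and binning would make dedup depend
on an arbitrary width.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not real genomes:

- **Host**: one uniform-composition chromosome (default 100 kb)
  carrying non-overlapping gene models (default 30; 2–5 exons; 80%
  coding with non-empty UTRs, 20% non-coding), plus a repeat BED
  (~1 interval / 20 kb, 200–1000 bp) standing in for a RepeatMasker
  track.
- **Bacteria**: independent random references (default 20 × 5 kb), each
  with an accession and a genus label drawn from genera recurrently
  reported in host–microbe integration surveys.
- **Reads**: five truth classes per sample — host, bacterial
  (microbiome), lgt, low-complexity artifact, duplicate — drawn
  multinomially at configured rates (defaults: lgt 10⁻³, microbiome
  5·10⁻³, duplicates and artifacts 10⁻⁴ each, substitution error
  10⁻³). Fragments emulate unspliced transcript copies: every mate is
  contiguous on its reference and host fragments fall in gene spans.
  Insert sizes are truncated-normal (300 ± 30 bp), resampled until
  ≥ 2× read length so a planted junction always lies strictly between
  the mates. Duplicates are byte-copies of post-error lgt pairs.
  Qualities are constant `I` because the pipeline ignores them.
- **Cohorts**: two groups (default 20 + 20 samples at 10⁵ pairs);
  group 2 multiplies the lgt rate (default fold 2). Clinical tables use
  exponential event times (OS hazard 0.012/month ≈ 58-month median,
  PFS hazard 0.025/month), uniform censoring on [0, 96] months, a
  configurable group hazard ratio (default 1: no survival effect), and
  marker prevalences typical of CLL cohorts (IGHV-mutated 0.55,
  del11q 0.18, del17q 0.08, tri12 0.15, del13q 0.55, CD38-high 0.30),
  equal in both groups by default so that marker associations are null.

What the simulator does **not** model — splicing across mates, indels,
quality-dependent errors, strand-specific protocols, realistic base
composition, shared homology between host and bacteria (except when a
test plants it explicitly), genus-specific abundance profiles. Passing
tests therefore demonstrate the pipeline's internal correctness and its
behaviour under the stated generative model, not performance on real
RNA-seq, where repetitive sequence, contamination and index hopping
dominate the error budget.

A fast burden-level path (`simulate_cohort_burdens`) draws each sample's
planted-junction count from the same binomial law the read-level
simulator uses, skipping read synthesis. Replicate-based studies (power,
null calibration) run at this level — 100 read-level replicates of 40
samples × 10⁵ pairs would synthesize ~4·10⁸ reads for no extra
information, since junction placement is independent of the count.
Read-level behaviour is exercised end-to-end at the 10⁵-pair scale in a
single-sample recovery study and a 6+6-sample mini-cohort.

## Cohort statistics

- Burden: `pct_lgt = 100 · unique events / total pairs`. Deduplicated
  events are the counting unit (a config-level choice; raw supporting
  read pairs would systematically weight duplicated junctions).
- Enrichment: classic pooled-variance unpaired two-tailed t-test
  (Welch behind a flag). Fold change is reported both mean- and
  median-based.
- Genus matrix: unique events per (sample, genus); heat-map export
  restricted to the top 20 genera by total count, ties alphabetical.
- Stratification: classical (Torgerson) MDS — eigendecomposition of the
  doubly centered squared-distance matrix — on Euclidean distances of
  log2(count+1) profiles. The log damps a single hyper-abundant genus
  that would otherwise dominate the geometry. Axis signs are fixed
  (largest-magnitude coordinate positive) and the 2-means split is
  initialized at the two most distant samples, so the grouping is a
  pure function of the input. The higher-mean-burden cluster is labeled
  group 2, making the reported fold difference ≥ 1 by convention.

## Clinical association

- Kaplan–Meier product-limit curves and the two-group log-rank test
  (χ²(1), two-sided) compare survival between groups.
- The "burden cutpoint" is a maximally selected log-rank scan: every
  midpoint between consecutive unique burden values is a candidate,
  splits leaving < 10% of subjects on either side are inadmissible, and
  the cutoff maximizing the statistic wins (ties → smaller cutoff).
  This is the standard survminer-style operationalization; the selected
  statistic is maximal by construction and its naive p-value is
  anti-conservative, so it is reported for ranking, not inference.
- Binary markers use the two-sided Fisher exact test, computed by exact
  integer hypergeometric enumeration (tables with probability ≤ the
  observed table's, margins fixed) — integer comparison makes tie
  handling exact. RAI stage uses Pearson's χ² without continuity
  correction, after dropping all-zero rows/columns. Missing values are
  dropped per marker with the dropped counts logged. Raw p-values are
  reported (matching how such cohorts are typically described), with a
  Benjamini–Hochberg column alongside.

A calibration caveat worth stating explicitly: exact conditional tests
on discrete 2×2 tables are conservative — their null p-values are
stochastically larger than uniform, markedly so at ~20 subjects per
group. The package's null-calibration tests therefore assert uniformity
for the (continuous) t-test and log-rank p-values, and validity
(rejection rate ≤ α) for Fisher; a strict uniformity requirement on
exact Fisher p-values is not achievable by any faithful implementation.

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open; 1-based conventions
  exist only at serialization boundaries (e.g. SAM import).
- Annotation classifies the host-interval midpoint (single-class
  output), with ANNOVAR-like defaults: 1 kb up/downstream windows, 2 bp
  splice proximity, precedence exonic > splicing > UTR5 > UTR3 >
  intronic > ncRNA_exonic > ncRNA_intronic > upstream > downstream >
  intergenic, then alphabetical gene name.
- Empty event sets yield empty distributions/matrices, not errors;
  zero-total-pair samples, single-group survival comparisons, all-zero
  contingency tables and inadmissible cutpoint scans raise `ValueError`.
- `mds_group` requires ≥ 4 samples; an empty cluster during 2-means is
  repaired by moving the point farthest from its center.
- Seeds: every stage derives its generator from the single config seed
  plus a fixed stream tag, so outputs are byte-identical across reruns
  and independent of call order.

## Known limitations

- No split-read breakpoint resolution, viral/fungal references, or
  integration assembly; genus is taken from reference metadata, not
  re-estimated.
- The aligner reports no mapping-quality model and exactly one hit;
  multi-mapping ambiguity is invisible downstream.
- Sensitivity claims are conditional on the generative model above;
  junctions whose host or bacterial flank is shorter than the seed
  length are undetectable by construction.
- The MDS grouping is descriptive; no inferential guarantee attaches to
  the 2-means split.
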