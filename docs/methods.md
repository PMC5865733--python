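# Methods

## Quantification model

Each transcript model is a cDNA partitioned into 5'UTR, CDS and 3'UTR in
transcript coordinates (0-based half-open internally; GFF3 is converted at
the boundary). Reads are aligned full-length with zero mismatches against
the transcript set through a k-mer-anchored substring index (seed length
k = 20 by default, below the shortest retained read). A read with 1..25
exact occurrences contributes one hit per occurrence; more than 25 (the
multi-mapping cap) suppresses the read entirely; the cap and the
zero-mismatch policy are exposed in `PipelineConfig`. Counting credits
every retained occurrence of a multi-mapped read — the alternative of
crediting a single occurrence is deterministic only under an arbitrary
tie-break, so all-occurrence counting is the default and a
lexicographic first-match mode is available behind a flag. Models
annotated as rDNA are removed, together with their hits, before any
library total is computed, so the mapped totals used everywhere downstream
refer to the retained (nuclear, non-rDNA) set.

RPKM is count × 10⁹ / (length_nt × total_mapped). Replicates are averaged
on the RPKM scale (not counts), then floored at 0.1 (configurable,
default on). The floor serves two purposes: the TE ratio is defined for
every transcript, and the degenerate case of no signal in either library
reports TE = 1.00 exactly rather than 0/0. All reported values are rounded
half-away-from-zero to two decimals at the reporting layer only; internal
computation is full precision and the tables carry both columns.

Region coverage assigns a hit to the region holding the majority of its
bases, with exact ties going to the 5'-most region (no convention is
canonical here; a 5'-end-position rule is available behind a flag). The
region ratio table reports (FP_region/CT_region)/(FP_CDS/CT_CDS), so the
CDS is pinned at 1.00; an FP region count of 0 reports 0.00 outright, a CT
region count of 0 with nonzero FP is flagged undefined, and a zero CDS
count in either library makes the row non-computable.

## The count test

Evidence that the footprint/control ratio departs from the library-wide
expectation comes from a negative-binomial exact test in the classic
count-based differential-expression formulation, re-implemented here:

- **Size factors** are median-of-ratios: factor_j = median over
  all-positive transcripts of count_tj / geometric-mean_j(count_t·),
  with the median taken in linear space.
- **Zero conversion**: counts of 0 are lifted to 1 before testing (only in
  the test's inputs; RPKMs use the 0.1 floor instead), so no transcript is
  lost to an all-zero condition.
- **Dispersion** is estimated per transcript by method of moments, pooling
  the within-condition variances of size-factor-normalized counts across
  both conditions and subtracting the shot-noise term. With two replicates
  per condition these raw estimates have ~2 degrees of freedom and are
  useless individually, and averaging their logarithms is biased low
  (Jensen), which makes the test anti-conservative. The working dispersion
  is therefore the classic parametric mean-dispersion trend
  disp(q) = a₀ + a₁/q fitted to the raw estimates by least squares in
  linear space (keeping negative excursions, which carry information about
  the shot-noise level); transcripts share the fitted value. Below 100
  transcripts no trend is fitted and raw estimates floored at 10⁻⁸ are
  used. On a seeded 2000-transcript null simulation (common NB mean,
  dispersion 0.1, 2+2 replicates) the empirical type-I error at α = 0.05
  is 0.04–0.06 across seeds (asserted in the test suite at [0.03, 0.07]).
- **P-value**: conditioned on the total count of a transcript, the
  two-sided tail probability of CT/FP splits at least as improbable as the
  one observed, under NB marginals with the common mean and the
  variance implied by the shared dispersion. The sum is exact (no
  sampling); p is clamped into (0, 1].

No multiple-testing correction enters the filters (they act on raw
p < 0.05, matching the filtering design this pipeline reproduces); a
Benjamini–Hochberg column is emitted for information.

## Filters and summaries

High-TE: p < 0.05 (strict), TE > 1 (strict), FP_RPKM ≥ 1 (inclusive).
Low-TE: p < 0.05, TE ≤ 0.1 (inclusive), CT_RPKM ≥ 10 (inclusive). Filters
run per stage; transcript ids are collapsed to unique genes by stripping
the terminal `.N` splice-variant index, and the cross-stage union is
reported. The expressed denominator is transcripts (and unique genes) with
replicate-averaged CT_RPKM ≥ 1, and high-TE percentages are reported
against the expressed unique-gene count. An optional user-supplied
exclusion list (e.g. a top-N-by-RPKM list) can be applied upstream of the
filters; no automatic outlier rule is imposed because none is well
defined.

## Clustering

TE trajectories over the ordered stages are clustered by Lloyd-style
k-means under Pearson-correlation distance d = 1 − r. Rows are
z-standardized; centroids are means of member z-profiles, re-standardized
so the mean remains a valid representative under 1 − r (for z-scored
vectors, ‖x − y‖² = 2m(1 − r), so this is spherical k-means up to the
re-standardization). Ties in nearest-centroid assignment break toward the
lowest cluster id; an emptied cluster is re-seeded from the point farthest
from its centroid; the iteration cap defaults to 5 × 10⁶ and convergence
is reached within a handful of iterations at these problem sizes.
Zero-variance profiles have undefined correlation and must be dropped
first (`drop_zero_variance`). k is a required user choice; a silhouette
scan over k ∈ 2..10 is provided as guidance but never auto-applied.
Replicate-reproducibility QC emits the Pearson r of every replicate pair
of RPKM vectors.

## Organelle homology and chloroplast profiling

A gene model is flagged against an organelle genome when its best local
alignment on either strand reaches identity ≥ 0.90 over coverage ≥ 0.75 of
its CDS length (both inclusive). The alignment is an exact local DP
(match +1, mismatch −2, gap −2.5); identity counts matching columns over
all alignment columns including gaps, and coverage is aligned CDS bases
over CDS length taken from the single best-scoring alignment (summed
multi-segment coverage is a possible alternative; the single-alignment
reading is recorded here as the implemented choice). Passing both genomes
independently yields the verdict "both".

Chloroplast profiling aligns reads to the extracted chloroplast CDS
sequences with the same exact-match engine and computes RPKM with the
*nuclear* mapped totals as denominators, so chloroplast expression shares
the per-library scale of the gene models; TE then follows the same floor
and rounding conventions.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

- **Transcripts**: `n_genes` (default 120) random-sequence models with
  UTR5/CDS/UTR3 lengths drawn from configurable ranges (defaults 60–200 /
  300–1500 / 60–250 nt); 4 rDNA-tagged models; one nuclear near-copy of an
  organelle CDS per entry of `organelle_copy_identities` (default 1.0 and
  0.85, substitutions only); one identical-sequence paralog pair to
  exercise multi-mapping. Organelle genomes are random sequences of 12 kb
  (chloroplast) and 18 kb (mitochondrion) — scaled-down stand-ins for the
  real 152 kb / 450 kb genomes — with 6 and 3 embedded CDS features.
- **Classes and trajectories**: 10% of genes each are planted as
  high-TE-early (TE 6–25 at the first stage, ~1 later), low-TE
  (TE 0.02–0.08, abundance ≥ 10 RPKM so they are filterable), and
  storage-like (abundance peaking mid-stage with TE rising 0.4 → 0.7 →
  1.3, the seed-storage-protein pattern); the remainder are ordinary
  (TE lognormal around 1). Nuclear organelle homologs and organelle CDS
  sources carry very low TE (0.02–0.08).
- **Abundances** are log10-normal (mean 0.9, sd 0.7 in log10 RPKM), so the
  realized RPKM range spans roughly 0.1–3000 and both sides of the 1 and
  10 RPKM filter bounds are exercised.
- **Reads**: per library, `reads_per_library` (default 100,000; the real
  libraries run to ~10⁸, which desk-scale testing does not need) exact
  substrings with lengths drawn per library type — CT roughly uniform with
  mode in 26–28 nt, FP peaked at 31–33 nt, both confined to the 26–34 nt
  size selection. CT starts are uniform over the transcript; FP starts are
  uniform over CDS positions except a `utr_leakage` fraction (default
  0.05) uniform over the whole transcript. A binomial `rrna_fraction`
  share (default 0.3, configurable 0–0.8) is drawn from the rDNA models.
  The 3' linker sequence is appended by default so the trimming stage
  operates on realistic input. A sequencing-error rate is exposed but
  defaults to 0, matching the zero-mismatch alignment policy (errors would
  only discard reads).
- **Truth scaling**: after drawing, control abundances are rescaled per
  stage so that the expected control RPKM of each transcript equals its
  stored `ct_abundance` exactly, and TE values are rescaled per stage so
  the footprint and control expected library weights match
  (Σ te·a·L = Σ a·L). Without the second rescale the FP/CT RPKM ratio
  estimates te only up to a global compositional constant; with it,
  `te_true` is the exact estimand and recovery tests need no fudge factor.
  Per-library draws are seeded by (seed, stage, type, replicate), so any
  single library is reproducible in isolation.

What the generator does **not** emulate: 3-nt codon periodicity and
start/stop ramps (the analysis uses only region-level coverage, never
sub-codon structure), realistic base composition or quality scores,
indels/fragmentation biases, rRNA sequence similarity (contamination is
modeled at the sampling level under rDNA-tagged ids), and genome-level
splicing (quantification is against cDNA models throughout). Passing
recovery tests therefore demonstrate correctness of the estimators under
the model's sampling assumptions, not robustness to alignment artifacts or
library-preparation biases in real data.

## Numerical and design notes

- Rounding is half-away-from-zero at two decimals, reporting layer only.
- The TE floor, thresholds' strict/inclusive senses, the multi-mapping
  cap, seed length, adapter sequence, and k are all `PipelineConfig`
  fields with the defaults above; overrides are recorded in the run
  manifest and config round-trips through YAML.
- Adapter trimming is exact-match only: full internal occurrence, else a
  terminal adapter prefix of ≥ 6 nt at the read's 3' end; trimmed reads
  shorter than 20 nt are dropped and counted. Error-tolerant trimming is
  out of scope for the same reason error simulation is off by default.
- Determinism: fixture bytes, alignment, testing and clustering are all
  deterministic given the configured seeds; the pipeline re-run with the
  same config produces byte-identical tables.
- Known limitations: the NB test's agreement with any particular
  historical differential-expression implementation is not claimed
  (calibration and monotonicity are the contract); organelle flagging uses
  one best local alignment rather than summed segment coverage; gene-level
  aggregation across isoforms is intentionally absent (quantification is
  per transcript model).
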