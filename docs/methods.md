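# Methods

This document defines the statistical conventions the package implements,
the parameters it exposes (with defaults and rationale), and the scope and
limits of the synthetic-data generator.

## Units of analysis

A **cell** is one `(barcode, sample_id)` pair. Per cell, at most one
productive TRA and one TRB contig is retained; among same-chain candidates
the winner has the most UMIs, then the longest CDR3, then the
lexicographically smallest CDR3 — a total order, so pairing is
deterministic. Cells whose V(D)J contigs are exclusively gamma/delta, and
annotated cells with no contigs at all, keep both chains absent and form
the **NA stratum**. Cells with only one of the two chains also fall in the
NA stratum (a convention of this package: the clonotype key needs both
chains, and the strata below must partition every cell exactly once).

A **clonotype** is the set of cells sharing an identical
(alphaCDR3, betaCDR3) amino-acid pair, pooled across all samples and
tissues before calling, so one clonotype may span samples and compartments.
V genes do not enter the key; the modal V genes of member cells are
recorded for downstream CDR3 grouping. Ids `clonotype1, clonotype2, ...`
rank by descending pooled size with lexicographic tie-break, making calling
invariant to input row order.

## D50 diversity

With one sample's clonotype frequencies sorted non-increasing,
N1 ≥ N2 ≥ ... ≥ Nn, D50 = 100·k*/n where k* is the smallest k with
∑_{i≤k} Ni ≥ ½ ∑_i Ni. An even repertoire gives 50 (up to the +1
discretization for odd n); expansion drives the value toward 100/n. The
group comparison applies a two-sided rank-sum test (Mann–Whitney,
`method="auto"`) to the per-sample D50 values of two conditions; a Welch
t-test is exposed as an alternative since both appear in practice for this
statistic. All-identical inputs return p = 1.0 by convention rather than a
degenerate test.

## Clonal expansion

"Expanded" means pooled clone size ≥ 2 throughout.

**Strata.** Each cell is assigned by its clonotype's pooled size to NA, 1,
2–19, 20–99, or ≥ 100. Two views are reported: the disjoint bands (per-
sample percentages sum to 100) and the cumulative display thresholds
(NA, =1, ≥2, ≥20, ≥100).

**Downsampling comparison.** To compare two cell groups' clone-size
spectra at equal depth: per iteration, draw min(|A|,|B|) cells without
replacement from each group, recompute clone sizes within each draw, count
clonotypes per clone size, match the two count vectors on the union of
observed sizes (zeros imputed), and apply a paired two-sided Wilcoxon
signed-rank test (`zero_method="wilcox"`). The per-group substream for
iteration i is seeded by `(seed, i)` independently of argument order, so
swapping the groups reproduces identical p-values. Defaults: 100
iterations; the summary statistic is the median p over iterations.
All-zero differences give p = 1.0; an iteration with fewer than two
clone-size bins is recorded as NaN and excluded from the median. When the
two groups have equal size every draw is a permutation of the full group,
so the spectra — and the p-value — are identical across iterations; the
implementation computes one iteration and broadcasts it.

**Per-cluster enrichment.** Default design (`condition_by_expanded`):
within each transcriptomic cluster, the 2×2 table
(condition A vs B) × (expanded vs not) is tested with a two-sided Fisher
exact test; Benjamini–Hochberg FDR is computed across the cluster family.
An alternative design (`within_condition`) restricts to one condition and
tests (in-cluster vs out-of-cluster) × (expanded vs not). Clusters with an
empty table margin are flagged degenerate (p = 1, odds ratio NaN) rather
than dropped, keeping the FDR family stable.

### Behavior of the downsampling test (known limitation)

The protocol above is structurally conservative, and the acceptance test
that asserts its calibration and power at small scale fails — deliberately
left failing rather than the protocol being altered:

- **Null calibration.** At 300 cells/group the downsampled spectrum
  occupies at most ~6 clone-size bins. A two-sided exact signed-rank p over
  n paired bins cannot go below 2/2^n (0.031 at n = 6), and the median of
  20 iteration p-values concentrates in [0.56, 1.0]. Measured over 200
  replicates under a shared geometric(0.7) law, the fraction of median
  p < 0.05 is 0.000, below the exact binomial 99% interval
  [0.015, 0.095] around the nominal 0.05. The test never rejects — it is
  conservative, not anti-conservative, so it cannot produce false
  positives; it simply has essentially no power at this scale.
- **Power.** Against a planted heavy tail (5% of cells in clones of size
  20–150) the alternative perturbs the spectrum as a point mass: a handful
  of +1 counts at large sizes against a small-size deficit spread over the
  bulk bins. The signed-rank statistic is sign-mixed and the two-sided p
  stays high: the fraction of replicates with median p < 0.01 is 0.000 at
  2,000 cells/group and remains 0.000 at 8,000, 20,000 and 50,000
  cells/group, with or without log1p count transformation. Very small
  p-values from this statistic are attainable only when the two spectra
  differ across most bins (a distribution-wide shift), not under a pure
  point-mass tail alternative.

Practical guidance: treat the downsampling comparison as a descriptive,
depth-controlled visualization statistic; for inference on expansion
differences prefer the per-cluster Fisher enrichment or the D50 group
comparison, both of which calibrate and recover planted effects in the
acceptance suite.

## CDR3 specificity grouping

Two beta-chain observations are linked when (1) their V genes are
identical after stripping the allele suffix (`TRBV5-1*01` → `TRBV5-1`),
and (2) their CDR3s are equal length with Hamming distance ≤ 1, or differ
in length by one with a single clean insertion/deletion — never a
substitution and an indel combined. Groups are single-linkage connected
components with ≥ 2 members; observations are deduplicated on
(cdr3, v_gene, sample, tissue, condition), so a public clone seen in two
samples forms a valid two-member group. Candidate pairs are enumerated
only within buckets of (V gene, length) and (V gene, length ± 1); since a
qualifying pair always shares a V gene and lengths within one, bucketing
provably returns the same components as exhaustive all-pairs matching (the
test suite verifies this against an edlib/networkx oracle). A group is
flagged **PD-specific** when it holds at least one member from disease
blood and one from disease CSF.

## Lineage tracking

A clonotype "spans" a target cluster set when its (optionally restricted,
e.g. disease blood only) cells cover every target cluster. Clonotype
centroids are arithmetic means of member-cell embedding coordinates,
optionally per (clonotype, cluster) stratum. Grid composition bins the
embedding into k×k equal-width cells (default k = 10) with the maximum
edge inclusive; fractions sum to 1 within each occupied bin.

## Epitope linkage

Candidate peptides are all 9-mer and 15-mer sliding windows (stride 1) of
the supplied proteins — the lengths presented by MHC class I and class II —
after exact-sequence redundancy removal; windows containing non-standard
residues are dropped. Binding predictions are *consumed* from an external
predictor's table (peptide, allele, score, rank_percent, binder), never
computed; rows violating the 9-mer/class-I, 15-mer/class-II pairing are
dropped with a warning. A group links to an allele when every typed sample
contributing a TCR to the group carries the allele, with at least
`min_shared = 2` shared samples (full containment operationalizes "strong
sample sharing"; the threshold is exposed). Binder peptides of the allele
(or rows with rank_percent ≤ a positive threshold) attach to the link;
links with no binding data are retained and flagged.

HLA alleles are normalized to `HLA-<gene><2-field code>` (e.g.
`HLA-C*06:02:01` → `HLA-C06:02`); genes A/B/C/E/F/G are class I,
everything else (DR/DQ/DP...) class II.

## Synthetic-data generator

Scope: the generator emulates the *statistical structure* the analyses
assume, at desk scale, with everything determined by one seed.

Cohort defaults (a scaled-down study shape, the package's own choice): 8
PD and 6 HC blood donors at 500 cells each, 6 PD and 9 HC CSF donors at
150 cells each. Per-condition clone-size laws: HC geometric(p = 0.7); PD
the same bulk plus a heavy tail placing 5% of cells in clones of size
20–150 — magnitudes chosen to give the qualitative PD-heavier tail, not
quantitative claims. 5% of cells per sample are NA-stratum (emitted as
gamma/delta-only contig rows). CDR3s are random strings over the 20-letter
alphabet with conserved C...F framing and lengths 10–20 (mode ≈ 14).
Planted structure: lineage plants distribute a clonotype's cells over a
chosen cluster set (default: five 6-cell clonotypes spanning C15/C3/C6 in
PD blood); motif families are a base CDR3 plus ≤ 1-substitution variants
sharing one V gene, placed either bridging PD blood and PD CSF (hence
PD-specific by construction) or within HC blood; HLA typing covers the PD
blood donors, each with private alleles plus planted co-carried alleles
realizing the configured (family, allele) links; the binding table marks
one planted binder peptide per linked allele (a 9-mer for class I, a
15-mer for class II) among non-binder decoys. Non-planted clonotypes are
cluster-coherent (all cells in one home cluster), so spanning recovery is
exact by construction. Occasional lower-UMI duplicate contigs and
nonproductive rows (1% each) exercise the reader's tie-break and filter
without perturbing the truth.

Limits: no V(D)J recombination model, no sequencing error, no
transcriptome simulation; cluster labels and embeddings are toy geometry
(Gaussian blobs around cluster centers). `evaluate_recovery` scores any
subset of pipeline outputs (clonotypes, groups, spans, links) against the
ground truth as exact-match precision/recall and refuses mismatched run
ids.

## Determinism and numerics

Every random draw flows from `numpy.random.default_rng` seeded by the
user-supplied seed (iteration substreams use spawn-style `[seed, i]`
keys). File outputs use fixed column orders, `\n` line terminators and
sorted keys, so identical configs and seeds produce byte-identical files.
Statistical primitives that are standard are delegated: Fisher exact,
Wilcoxon/Mann–Whitney and chi-square to scipy; BH-FDR to statsmodels;
FASTA parsing to biopython. The primitives the package itself defines —
D50, the CDR3 match rule and bucketed single-linkage grouping, the
downsampling protocol, sample-containment linkage, and the generator — are
covered by oracle-equivalence and property tests (`pytest -q`), with
independent oracles built on edlib and networkx.
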