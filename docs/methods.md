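# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `combosnp`.

## Data model and conventions

Genotypes are coded by minor-allele count: 0 = normal homozygote, 1 =
heterozygote, 2 = variant (minor-allele) homozygote; the internal missing
sentinel is −1 (`NA` in the TSV dialect, `./.` in VCF). For VCF input the
raw code is the alternate-allele count; by default columns whose alternate
allele is the major allele are flipped so that code 2 always denotes the
cohort minor-allele homozygote (`orient_minor=False` preserves the
REF/ALT orientation). Positions are 1-based (VCF convention); matrix and
panel indices 0-based. Phenotype labels are binary case/control, with
common aliases (`patient`, `affected`, `1`, …) normalised at load time.

An individual with a missing call at any SNP of a combination is **not** a
carrier of that combination. This is the conservative reading — a
combination's carrier set never includes individuals whose genotype at a
member SNP is unknown — and it makes carrier sets monotone under
combination extension, which several invariants rely on.

## Quality control

Per-SNP filters, applied jointly (a SNP may be removed for several
reasons, all of which are recorded):

| filter | default | notes |
|---|---|---|
| call rate | ≥ 0.90 | fraction of non-missing calls |
| HWE exact p | ≥ 0.001 | computed in controls by default |
| MAF | ≥ 0.05 | inclusive threshold; from all individuals |

HWE is tested in controls because the case sample may legitimately deviate
under association; the subset is configurable (`controls`/`cases`/`all`).
A fourth, pass-through reason code accommodates exclusion lists produced
by upstream genotyping review (e.g. cluster-plot inspection), which has no
data analogue here. Filtering is idempotent: a filtered matrix passes
unchanged through a second filter at the same thresholds.

The HWE exact test conditions on the observed allele counts: the
probability of each admissible heterozygote count (same parity, same
allele totals) follows the standard conditional law, and the p-value sums
the probabilities of all counts no more probable than the observed one.
Weights are built by an exact rational recurrence
(w(h+2)/w(h) = 4·n_AA·n_BB / ((h+2)(h+1))) so that tail membership is
decided by exact comparison rather than floating-point log differences —
ties between equally probable configurations are then unambiguous. A
monomorphic SNP returns p = 1 and is left to the MAF filter. A 1-df χ²
variant is available for comparison.

## Single-SNP association

Each SNP contributes a 2×3 case/control × genotype table (complete-case
per SNP). Columns empty in both groups are dropped; if one column remains
the test is degenerate with p = 1. When every expected count is ≥ 5 the
test is Pearson's χ² with df = columns − 1; otherwise the Freeman–Halton
exact test, i.e. the two-sided Fisher test on the full 2×3 table: the sum
of conditional (multivariate hypergeometric) probabilities of all tables
with the observed margins whose probability does not exceed the observed
table's. Probabilities are handled as exact integer multinomial weights,
again making tie handling exact. The expected-count rule for "when the
asymptotic test is appropriate" is the conventional Cochran criterion. The
alternative of collapsing to a 2×2 table was considered and rejected: it
discards the genotype-level pattern the rest of the pipeline is built on.
Bonferroni correction multiplies nominal p by the panel size, capped at 1.

## Combination engine

Carrier sets are fixed-width packed uint64 bitsets (one bit per
individual); intersection is AND, cardinality is popcount. The enumeration
space for k of S SNPs is C(S,k)·3^k; enumeration order is lexicographic
over SNP index tuples with genotype codes in base-3 order, so outputs are
deterministic and diffable. Streaming enumeration prunes SNP pairs with
empty carrier intersections before extending to triples; the
patient-specific collector additionally prunes pairs with fewer case
carriers than the patient threshold and abandons a triple at the first
word carrying a control bit. The hot k = 3 paths are numba kernels with a
SWAR popcount; the pure-Python generator remains the reference path and
the two are held equal by randomized oracle tests against brute-force
triple loops.

Tallies satisfy, by construction and by a `validate()` re-check:
observed = common + control-only + patient-only, and the patient-count
histogram of patient-only combinations sums to the patient-only total.
Combinations may freely include SNPs from the same gene or in LD; no
LD-aware collapsing is applied at this stage.

Exhaustive triple enumeration is quadratic-to-cubic in panel size; the
engine is designed to be correct and streaming rather than cluster-scale
fast, and operations warn above a 300-SNP guard (overridable). Memory for
patient-specific collection is bounded by the size of the filtered result
set, never the combination space.

## Clusters and nested subgroups

A **cluster** is a defining (SNP, genotype) pair such that (a) at least
`min_combos` patient-specific combinations contain it and (b) the union of
patients over those combinations equals the complete set of cases carrying
the defining genotype. Condition (b) is the defining property and is
asserted exactly (bitset equality). "Relatively many" combinations is not
an intrinsically defined quantity, so `min_combos` is an explicit
configuration parameter (default 30); the patient-count threshold
`min_patients` likewise (default 1, i.e. off — in permutation studies it
is typically pinned to the smallest observed cluster). A genotype defines
at most one cluster; a combination can belong to up to three clusters
(one per member genotype). Results are sorted by patient count descending
with (rsid, code) tie-breaks for determinism.

Within a cluster, each member combination offers its two non-defining
genotypes as candidate *second* genotypes (the remaining one being the
*third*). A **pair subgroup** is emitted for a second genotype whose
distinct third-SNP count reaches `min_third_snps` (default 4); a switch
(`count_mode="combos"`) counts raw member combinations instead, for
analyses phrased in terms of combination counts. A **same-gene subgroup**
groups a pair subgroup's combinations by the gene of the third SNP (≥ 2
combinations; unannotated third SNPs are excluded).

The patient-count filter (≥ 9 patients per combination) is applied
*before* cluster detection, mirroring the narrative order of the analysis
stages; clusters are therefore built only from combinations that
individually recur in nine or more patients.

## Permutation testing

Carrier bitsets depend only on genotypes, so a permutation study builds
the carrier index once and swaps in a random case mask per replicate:
`n_cases` individuals drawn uniformly without replacement are
pseudo-patients, the rest pseudo-controls. Equality of this shortcut with
full recomputation from a relabeled matrix is enforced by oracle tests.
Per permutation the identical code path recomputes four statistics: the
number of patient-specific combinations at the patient threshold, the
number of clusters, the number of pair subgroups, and the number of
combinations in same-gene subgroups.

Thresholds are fixed from the observed analysis (never re-tuned per
permutation), and exceedance is one-sided: a permutation counts against a
feature when its statistic is ≥ the observed value. The empirical p-value
is the plug-in count/B — chosen to reproduce the conventional reporting
arithmetic (113/1000 → "0.11", 0/1000 → "p<0.001") — with the
conservative (count+1)/(B+1) estimator available behind a flag. Because
the statistics are small integers, plug-in p-values are discrete and the
test is conservative at small nominal levels; the calibration suite
accounts for this by checking coverage against the exact binomial
interval, whose lower end accommodates conservatism. Determinism: one
integer seed drives a single `numpy` Generator through all B permutations;
identical seed and configuration give bit-identical results. A projected-
runtime guard (off by default) aborts studies that would exceed a
configured budget unless forced.

## Synthetic cohorts

`generate_null_cohort` draws, per SNP, a MAF uniform on
[`maf_min`, 0.5] (default floor 0.05, matching the QC threshold) and
genotypes as Binomial(2, MAF) — exactly HWE — independently of labels;
missingness is uniform at rate 0.004 (a 99.6% call rate); SNPs are
annotated to genes in blocks of ~15, the granularity of a several-hundred
SNP, several-dozen gene candidate panel. Default dimensions are 607 cases,
1355 controls and 803 SNPs; tests and the acceptance script use smaller
panels (50–100 SNPs, 300–360 individuals) so that full enumeration and
permutation studies run in seconds on one CPU. The optional LD model is
copy-with-flip blocks: within a block each SNP copies the block seed's
genotype with probability `copy_prob`, else draws from its own HWE law. It
produces tunable within-block correlation but is not a coalescent and does
not reproduce human LD maps, population stratification or batch effects —
conclusions from passing tests concern the *algorithmic* behaviour of the
pipeline, not its yield on real genotype data.

Planting is deterministic carrier assignment rather than a relative-risk
model, because the pipeline's target quantity is exact carrier sets:
probabilistic planting would only blur recovery checks. A plant (a) writes
the defining genotype onto the selected cases and rewrites it away from
every other individual, (b) writes each partner genotype onto its subset
of the selected cases (default all). Every 3-combination containing the
defining genotype is then automatically patient-specific, and with p
partners all C(p,2) defining-genotype combinations share the full carrier
set, guaranteeing the cluster coverage condition. Plant positions chosen
by `design_plants` use the lowest-MAF SNPs' variant homozygote as defining
genotype (so exclusivity rewrites barely perturb control genotype
distributions and survive HWE QC) and heterozygotes of high-MAF SNPs as
partners (their abundant background carriers prevent partner-only
combinations from becoming case-exclusive, so partners cannot seed
clusters of their own).

Null cohorts can still produce genuine chance clusters at permissive
thresholds — the cluster definition is satisfiable by random data at a low
rate (roughly 1–2% of 60-SNP cohorts at a 10-combination threshold). This
is a property of the statistic, not a generator artifact, and is precisely
what the permutation study quantifies.

## Numerical and design choices

* Exact tests (HWE, Freeman–Halton) use exact integer/rational arithmetic
  internally; p-values are exact up to final float conversion, and the
  test suite holds them to 1e-12 against independent full-enumeration
  oracles.
* Bitsets are little-endian packed uint64 words; popcount via
  `np.bitwise_count` in Python and a SWAR implementation inside kernels.
* Combination, cluster and subgroup orderings all have deterministic
  tie-breaks ((rsid, genotype code) lexicographic).
* The theoretical count C(S,k)·3^k is computed in arbitrary-precision
  integers; no overflow at any panel size.
* Degenerate inputs: empty combination streams, zero clusters, and
  single-column association tables are all valid results, not errors;
  removing every SNP in QC is an error.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` run: oracle equivalence on 200
random matrices (≤ 8 SNPs, ≤ 30 individuals, 10% missing); planted-cluster
recovery on 50 cohorts of 60 SNPs and 120 + 240 individuals with a
12-patient plant (detection at min_combos = 10, patient threshold 9);
permutation calibration on 100 null cohorts of 50 SNPs and 100 + 200
individuals with B = 200 (cluster thresholds 5 patients/combination and
3 combinations, chosen so the null cluster statistic is non-degenerate at
this reduced panel size); and a full 3-combination tally on a 60-SNP null
cohort. These sizes were chosen so each study completes in seconds to a
couple of minutes on a single workstation core while keeping every
combinatorial code path exercised at full depth.

## Known limitations

* k is capped at 3; the combination space beyond triples grows too fast
  for exhaustive desk-scale enumeration.
* No imputation, phasing, covariate adjustment, stratified permutation or
  population-structure correction; permutations exchange labels only, so
  confounding by ancestry is out of scope.
* The Freeman–Halton choice for sparse tables (rather than a collapsed
  2×2 Fisher test) and the controls-only HWE subset are documented
  defaults with switches, not universal conventions.
* Cluster "importance" is assessed only by permutation frequency; no
  model-based effect-size or LD-aware deduplication is attempted.
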