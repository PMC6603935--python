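# Methods

## Model and assumptions

The package computes a group-level susceptibility indicator, not an
epidemiological risk: for each biallelic SNP in a curated
xenobiotic-metabolism panel, an ethnic group's relative risk (RR) is the
ratio of its unfavorable-homozygote genotype frequency to the worldwide
frequency of the same genotype. The implicit assumptions are that

* the unfavorable condition at each SNP is a property of the panel
  (`risk_direction`), known a priori — usually the variant homozygote, with
  a wild-type-homozygote exception set (rs2234922, rs6413432, rs3813867,
  rs2333227) where the variant allele is thought to be advantageous in at
  least one pathway step;
* genotype frequency is an adequate proxy for genotype at group level (no
  within-group stratification, admixture or selection is modeled);
* SNPs contribute independently and equally — no effect sizes, no LD, no
  gene–gene interaction.

Heterozygous RRs are computed and exported for completeness but do not enter
the area indices: each group profile is one curve of
unfavorable-homozygote RRs per ethnicity.

## Panel

The built-in panel has 24 entries: 6 oxidative-stress, 11 detoxification and
7 DNA-repair rows. The DNA-repair block intentionally lists rs13181 twice
(under XRCC1 and under XPD/ERCC2): the default `table1_verbatim` variant
preserves this published layout so that profile curves have the published
number of points, and `validate_panel` surfaces the duplication as a
warning. The `table1_dedup` variant keeps rs13181 once, under XPD/ERCC2
(its canonical gene; the variant is ERCC2 Lys751Gln), giving 6 distinct
DNA-repair SNPs. Exact duplicate (rsid, gene, group) entries are rejected
outright.

Group sizes are reported both as SNP rows and as distinct gene symbols
(detoxification: 11 SNPs across 8 genes; DNA repair: 7 rows across 4 gene
symbols) via `GenePanel.group_summary()`, since "genes per group" is
ambiguous for multi-SNP genes; all computation is at SNP level.

Panel order is data, not an implementation detail: it defines the x-axis of
the profile curves and therefore the trapezoid areas. It is preserved by the
TSV/JSON serializers and versioned with the panel. Risk direction is
likewise panel data and can be overridden per SNP in user files (flagged by
validation when a non-exception SNP is marked wildtype-risk).

## Frequency inputs

The primary carrier is a genotype-frequency TSV
(`rsid population n f_hom_ref f_het f_hom_alt`), which preserves any
departure from Hardy–Weinberg present in the source counts. VCFs with
1000 Genomes-style per-population allele-frequency INFO keys are an
alternate carrier; their genotype frequencies are HWE expansions
p → ((1−p)², 2p(1−p), p²), and the table's provenance string records this.
Records are matched to the panel by rsID only — no positions, no liftover,
no strand flipping; multiallelic records are skipped with a warning.

Validation enforces each frequency in [0, 1] and triple sums within 1e-6 of
one; inputs are never silently renormalized. The worldwide reference is an
explicit `ALL` population when present (never overwritten), otherwise built
per rsID as a weighted mean of the population triples — sample-size weights
by default, explicit weights optionally. Convexity guarantees the aggregate
satisfies the same invariants.

## Relative-risk grid

`build_rr_matrix` keeps the ethnicity-by-SNP grid rectangular: a SNP missing
for any requested population, or with a zero worldwide unfavorable-genotype
frequency, is dropped for *all* ethnicities and listed with its reason.
Nothing is imputed by default; an optional `pseudo_freq` epsilon (added to
both numerator and denominator) exists for sensitivity analysis only.
Exact contracts: if an ethnicity's frequencies equal the worldwide ones the
RR is exactly 1 (IEEE x/x), and using `ALL` itself as an ethnicity yields an
exact row of ones.

## Area indices

The "area subtended" by a risk profile is computed by the trapezoid rule on
the polyline through the RR values at unit SNP spacing — the natural reading
of an area under a plotted curve. A `sum` rule (plain rectangle sum) is
available as a switch; for constant profiles both rules give identical
min-normalized indices, and the rule used is recorded in the run manifest.
Indices are areas divided by the group minimum, so the reference
(minimum-risk) ethnicity scores exactly 1 by construction; ties for the
minimum resolve to the first ethnicity in configured order with a logged
notice. The cumulative index is the unweighted arithmetic mean of the three
group indices. The per-group "odds ratio with respect to the reference
ethnicity" is this same area ratio — no 2×2-table odds computation is
involved anywhere.

Display rounding (one decimal, trailing `.0` dropped) applies only at
report-rendering time; all stored artifacts keep full precision
(12 significant digits in CSV).

Because the areas depend on SNP ordering for non-constant profiles, and the
published figures' ordering is not recoverable, reproducing published index
values from fresh database exports is not guaranteed even with identical
frequencies; the package therefore treats the panel ordering as explicit,
serialized input.

## PCA

Per group, the ethnicity-by-SNP RR grid is column-mean-centered and the
covariance matrix (ddof = 1) is eigendecomposed (`numpy.linalg.eigh`; dense,
deterministic). Components are sorted by descending eigenvalue with tiny
negative eigenvalues clipped to zero, and a fixed sign convention (each
component's largest-magnitude loading nonnegative) makes outputs
reproducible. Covariance — not correlation — PCA is the default, so SNPs
with larger RR spread dominate; `scale=True` switches to correlation PCA for
sensitivity. With four ethnicities at most three eigenvalues are nonzero;
two components are retained by default (the PC plane). Biplot loadings are
eigenvectors scaled by the square root of their eigenvalue
(correlation-style biplot), recorded in the variance sidecar. A grid with
numerically zero total variance (≤ 1e-12) is flagged degenerate: scores sit
at the origin and pairwise distances are zero with a warning, rather than
being undefined.

`CovariancePCA` keeps the full eigenvalue spectrum in
`explained_variance_` (so explained ratios always sum to one) while
`components_` holds only the retained components; it is otherwise a
standard sklearn transformer and composes with sklearn pipelines.

## Synthetic-data generator

The generator emulates a multi-population frequency export: per SNP an
ancestral alternate-allele frequency is drawn uniformly from (0.05, 0.95) by
default — wide enough to produce both common and rarer variants while
keeping Beta shape parameters well-defined — and each population's frequency
follows the Balding–Nichols distribution Beta(p(1−F)/F, (1−p)(1−F)/F),
mean p and variance F·p(1−p). Defaults: 4 populations (AFR/EAS/EUR/SAS),
FST = 0.1 (continental-scale human differentiation), 500 diploid samples per
population, exact-HWE output; `genotype_counts` mode adds multinomial
sampling noise at the configured sample size. The `ALL` row is a
sample-size-weighted aggregate (equal n by default). A seed is mandatory and
output is bit-identical for identical configurations.

What the generator does *not* emulate: HWE departures (other than sampling
noise), linkage between SNPs, admixed or continuously structured
populations, and any systematic relation between risk direction and
frequency. Passing tests on synthetic tables therefore demonstrate the
arithmetic contracts of the pipeline, not the field validity of the
susceptibility model on real cohorts.

`make_null_table` is the degenerate case used for exactness checks: one HWE
triple (p = 0.3) shared by every population and ALL, which forces every RR
and index to exactly 1 and every PCA to degeneracy.

### FST estimator

With p_k the per-population alternate-allele frequencies of one SNP
(k populations, ALL excluded), p̄ their unweighted mean and s² their sample
variance (ddof = 1), the per-SNP estimate is

    F̂ = s² / (p̄(1 − p̄) + s²/k)

averaged over polymorphic SNPs. The s²/k term corrects the small-sample
bias of the naive ratio Var(p)/(p̄(1 − p̄)), which with only k = 4
populations underestimates F by a factor near (k − 1)/k — far outside any
useful recovery tolerance at F = 0.2. The corrected form is unbiased to
first order under Balding–Nichols and still returns exactly 1 for a
population pair fixed at p = 0 and p = 1, and exactly 0 for identical
populations. It remains a moment estimator on frequencies (no finite-sample
allele-count correction à la Weir–Cockerham), sufficient for verifying the
generator.

## Numerical choices

* Sum-to-one tolerance 1e-6 on input triples; no silent renormalization.
* Degenerate-variance threshold 1e-12 for PCA.
* Exact (not approximate) equality for the reference-index-equals-one
  contract, guaranteed by x/x = 1 in IEEE arithmetic for finite nonzero x.
* CSV artifacts at 12 significant digits; PCA score exports at 17 (full
  round-trip); display rounding only in rendered reports.
* Ties (minimum area) break to the first ethnicity in configured order,
  logged.

## Problem sizes in tests and the acceptance script

Verification runs use the built-in 24-entry panel with 4 populations + ALL:
200 simulated tables for the normalization contract, 100 random tables for
the RR oracle, 25 random 4×G grids (G ≤ 12) for the PCA oracle, and
1000-SNP tables for FST recovery at targets 0.02/0.1/0.2 — sizes at which
the stochastic checks are stable across seeds while the whole suite runs in
well under a minute.

## Known limitations

* The RR statistic is a frequency ratio; it carries no uncertainty (no
  confidence intervals — a deliberate non-goal) and no outcome calibration.
* Index values depend on the panel's SNP ordering (trapezoid areas) and on
  the frequency snapshot used; cross-study comparisons require pinning both
  (the manifest records panel version and data provenance for this reason).
* VCF input assumes HWE within populations; genotype-count TSVs are
  preferred when available.
* The worldwide aggregate is only as representative as its weights; Ensembl-
  style ALL columns include super-populations (e.g. AMR) that are not among
  the four analyzed ethnicities.
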