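# Methods

This note documents the statistical model, the synthetic-data generator,
and the numerical and design choices behind `ferroglc`.

## Factorial model and equation simplification

Protein abundances are analyzed on the log2 scale but replicates are always
averaged on the linear scale (values are de-logged before the mean, then
re-logged for reporting); normalization equalizes each sample's mean (or
median) detected abundance to the grand mean of per-sample centers, which
makes the operation idempotent.

The per-protein model is OLS on the ±1-coded design

    log2(y) = α + β·(Fe, Glc, strain, Fe:Glc, strain:Glc, strain:Fe, strain:Fe:Glc)

restricted to WT and *hxk1-2* (the second mutant, *hxk1-1*, carries extra
polymorphisms and is excluded from classification while remaining in the
enrichment statistics). With ±1 coding the intercept is the grand mean and
a condition difference equals 2β; on a balanced 2×2×2 design every
coefficient is the corresponding signed-contrast mean and the design matrix
is orthogonal. Cells lost to non-detection make per-protein designs mildly
unbalanced; the fit simply drops missing samples and requires >8
observations. Two-sided p-values use the t distribution with n−8 df. With
exactly zero residual variance (noiseless fixtures, fully imputed
conditions) p is set to 0 for |β| > 1e−9 and 1 otherwise — a documented
degenerate rule that keeps noiseless unit tests well-defined.

Simplification applies, in order: (1) Benjamini–Hochberg at 5% FDR over a
*pooled* family of all proteins × 7 terms — the most conservative
single-family reading; a per-term family is available via
`PipelineConfig(bh_family="per_term")`; (2) an effect floor: if every
surviving |β| < 0.25 log2 the protein gets no terms (the floor does not
remove individual small terms — that is the dominance rule's job); (3)
dominance truncation: survivors sorted by |β| (canonical term order breaks
exact ties) are cut immediately after the first position whose coefficient
is ≥4× the next one. The rule is idempotent, and every retained consecutive
pair satisfies |β_k| < 4·|β_{k+1}| by construction.

Subgroups are signed term patterns; their profile is the per-condition mean
of per-protein condition-centered log2 condition means over all 12
conditions. Merging is greedy: the highest-correlated pair above r = 0.9
merges first, profiles are recomputed as member-weighted means, and the
merged subgroup takes the larger member's name (ties break to the
lexicographically smaller label — an explicit convention where the original
analysis allowed ad hoc naming exceptions).

Cross-validation refits a reduced `Fe + Glc + Fe:Glc` model on WT samples
only (same FDR/floor/dominance steps) and evaluates residuals on WT (train)
and *hxk1-2* (test). Training residuals shrink by √(1−h) and test residuals
inflate by √(1+h) for hat leverage h = p/n, so a gap of several percentage
points in the |r| < 0.5 bin between train and test is expected even for
perfectly strain-independent proteins; the |r| < 1.0 bin is nearly
insensitive to this.

## Missing data

Missing abundances are empty/NA cells, never zeros (log2 must be defined;
zeros are rejected on read). A condition with no detected replicate is
imputed at half the protein's least abundant *detected condition mean*
(log2(min) − 1), filling every replicate slot identically — so imputed
conditions have zero within-condition variance. The minimum over raw
replicate values instead of condition means is available as a sensitivity
switch. Normalization precedes imputation so imputed values inherit the
normalized scale. Partially detected conditions are left as-is.

## Extreme-condition enrichment

For target set T (WT−Fe+Glc alone, or together with WT+Fe+Glc for the TAG
variant) and direction *lowest* (symmetric for *highest*):

1. **Rank filter** — max over T of the log2 condition means must be
   strictly below the min over non-target conditions. Exact ties fail:
   imputed conditions of one protein share a value, and a tie must not
   create a spurious extreme.
2. **Gap** — distance from the nearest target mean to the nearest
   non-target mean (for |T| = 1 this is simply target to next-nearest).
3. **Max-p** — Welch two-tailed t-tests of the pooled target replicates
   against each other condition's replicates; the statistic is the largest
   of the 11 (or 10) p-values, forcing separation from *every* condition.
   Welch was chosen to match the default two-tailed behavior of the
   original analysis environment; a zero-variance group degrades the
   statistic gracefully to the other group's variance (df = n−1), and when
   neither group has ≥2 finite values the comparison contributes p = 1 (no
   evidence). BH adjustment runs across rank-passing proteins per
   (direction, analysis) family — only they have a defined statistic; an
   all-proteins family is available.
4. **Tiers** — stringent: FDR pass and gap > 0.5; expanded: additionally
   FDR-pass-only proteins and, for heterotrophy, proteins whose simplified
   equation puts the (−Fe, +Glc) corner at the strict extremum for both
   strain levels (evaluated over all 8 corners; strain-only equations tie
   and never qualify). A provenance column records which rule admitted each
   protein.

## Overlap statistics

Cross-species tests operate in ortholog-group units: query genes map
through the species' gene→group table (deduplicated, unmapped counted),
and overlap with the comparison species' group set is tested one-sided
("greater") by Fisher's exact test. The default universe is groups with ≥1
member in *each* species; this choice is the largest reproducibility caveat
of any published overlap p-value and is recorded in every output manifest
(an "either species" universe is available). GO enrichment is the classic
independent-term Fisher test with BH across terms — no GO-graph
decorrelation. Conservation tallies count groups qualifying in ≥k
comparison species.

## Phenotype formulas

Volumetric biomass sums per-cell sphere volumes 4π/3·(d/2)³ scaled by
dilution over counted volume; it is additive over partitions of the cell
list. Specific growth rate is (log10 b_end − log10 b_0)/hours. Fv/Fm uses
the noise-floor rule: F_o is the mean of the baseline trace, its noise is
4 standard deviations (~95% of the noise range), and Fv = Fm − F_o at or
below the noise (including negative Fv) is scored not-detected and assigned
0. The Wilcoxon rank-sum statistic W is fixed to the Mann–Whitney U of the
first group; the null is enumerated exactly for tie-free pooled n ≤ 12 and
otherwise uses the normal approximation with tie and continuity corrections
(the real ETC comparison, n = 64 vs 97, always takes the approximation).
ETC fold changes are log2 ratios of linear condition means (−Fe over +Fe)
per (strain, Glc) stratum, and complex summaries are plain means over
member subunits supplied as annotation tables, never hard-coded.

## Synthetic-data generator

The generator is the package's test surface and emulates the study's
shape: 12 conditions (3 strains × 2 Fe × 2 Glc) × 4 replicates, per-protein
log2 surfaces α + Σβ·x with Gaussian replicate noise (default sd 0.25
log2), intercepts α ~ N(10, 1.5) log2 units, and Poisson(5)+1 unique
peptide counts so the ≥2-peptide filter has realistic bite. Generic
non-null proteins draw 1–3 terms of fixed magnitude (default 1 log2) with
random signs; planted extreme-condition classes use three-term sign
patterns (strain/Fe/Glc for heterotrophy, strain/Glc/strain:Glc for TAG)
whose target corner sits 2–4 effect units beyond the rest of the landscape.
Ground-truth classes are assigned from the analytic extremum of the
noiseless model over the 8 design corners, so a generic protein whose
random terms happen to single out the WT−Fe+Glc corner is also counted as a
planted extreme — recovery is defined against the model, not the label used
to draw it.

Non-detection is intensity-dependent by default: each cell is missing
independently with probability logistic((m − log2 y)·s), midpoint m = 6 and
slope s = 1, putting ~2–5% of cells below the floor at the default
intercept scale. The real experiment's missingness mechanism is not
characterized; the logistic form is this package's assumption, and a
missing-completely-at-random mode plus a detection-off mode are provided.

What passing tests do and do not show: recovery and type-I benchmarks
(≥90% exact term-set recovery, ≤5% null flagging, ≥90% planted-extreme
sensitivity) are measured with detection off — they certify the inference
machinery on observed data. With dropout on, planted "lowest" proteins sit
near the detection limit in exactly their target condition, lose
replicates, and the Welch max-p statistic loses degrees of freedom;
sensitivity then degrades into the 70–90% range depending on the intercept
scale. That degradation is a property of extreme-condition discovery on
censored data — real datasets share it — not of the estimator. The
generator also does not simulate reporter-ion ratio compression or isotope
impurity; noise is a single Gaussian per cell on the log2 scale.

## Problem sizes and runtime choices

Desk-scale benchmarks use 1000-protein proteomes for recovery/sensitivity
and 20 × 300-protein replicates for null-rate estimates; these sizes give
binomial standard errors comfortably below the margins being tested while
keeping the full suite and the acceptance script each under a minute. The
real 7000-protein table runs through the same code paths in a few minutes.

## Known limitations

- Peptide-level normalization and roll-up are out of scope; the pipeline
  ingests protein-level tables (the original analysis normalized peptides
  before summation).
- Whether imputation preceded or followed normalization in the original
  analysis is not stated; this package normalizes first.
- The exact BH family of the original notebook (pooled vs per-term) is
  unverified; pooled is the default here, per-term is a switch.
- The universe behind any published overlap p-value is not recoverable from
  text; overlap results depend on it and the manifest records the choice.
- No moderated-variance (limma-style) estimation: plain OLS matches the
  original analysis but is less powerful at 3–4 replicates.
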