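# Methods

This note documents the models and procedures implemented in `irtax`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Data model

PIR (percent intron retention) values live in [0, 100] with missing cells
kept as NaN; all summary statistics skip missing values pairwise and record
the effective n. Genomic coordinates are 0-based half-open everywhere in
memory; conversions happen only at file boundaries. Cross-link events are
single-nucleotide: each BED interval collapses to its start coordinate,
because the statistics count *events*, not peak widths; duplicated
(chromosome, position, strand) triples collapse to one event.

## Synthetic study design

The generator emulates a fractionated differentiation time course: six
time points (DIV 0, 3, 7, 14, 21, 35) × {nucleus, cytoplasm} × seven clones
(four control clones from four donors, three mutant clones from two
donors), 84 samples in total. Intron PIR profiles follow nine archetypes —
anchored per DIV and interpretable as: stable nuclear (N1), declining
nuclear (N2), transient nuclear peak (N3), declining in both compartments
(C1), rising in both (C2), terminal cytoplasmic rise (C3), constitutively
high (C4), early transient peak at DIV 7 (C5), late transient peak at
DIV 21 (C6). Values are archetype mean + optional mutant shift + Gaussian
noise (default sd 5 PIR points), clipped to [0, 100] (clipping rather than
resampling; the bias is negligible away from the bounds).

The mutant perturbation is unidirectional (only PIR increases) and applied
in the cytoplasm at DIV 14: +15 PIR points on C5 and +5 on C1 and C3. The
compartment/time placement and the ordering (C5 ≫ C1, C3) reproduce the
perturbation structure the analysis is designed to detect; the magnitudes
in PIR points are calibration choices — no published effect sizes exist on
that scale.

Companion generators produce: one contig per gene with three introns
(≥ 30 nt flanking exons, ≥ 91 nt introns, i.i.d. bases at a target GC);
per-RBP cross-link tracks where each (RBP, intron, region) is hit with
probability p₀ = 0.2 (planted enrichments use min(1, fold·p₀), one event
placed uniformly in a hit region, so planted folds are defined on the
fraction-with-≥ 1-event scale the enrichment statistic measures); bimodal
log2 expression (off ≈ N(1, 1), on ≈ N(9, 1), 75 % of genes expressed, four
replicates per condition) with a planted miRNA target set shifted −0.5
log2FC in the control DIV 7→14 contrast and +0.5 in the mutant-vs-control
contrast at DIV 14, plus an unshifted negative-control set. One master seed
drives every generator through fixed named substreams, so regeneration is
byte-identical.

**What the benchmark does not emulate:** PIR estimation noise is Gaussian
and homoscedastic (real junction-count-based PIR has beta-binomial-like,
coverage-dependent error); archetype membership is exact rather than graded;
cross-link events are independent across RBPs and regions (no co-binding);
expression is normal on the log scale with equal variances and no
mean–variance trend; there is no mapping bias, batch structure, or clone
effect in PIR (patient effects are simulated only in the mixed-model
benchmarks). Passing recovery tests therefore demonstrates correctness of
the machinery under the assumed statistical structure, not performance on
real sequencing data.

## Expression gate

Per sample, a two-component unequal-variance Gaussian mixture is fitted to
log2(count + 1) by EM: deterministic initialisation at the 25th/75th
percentiles with equal weights and the pooled sd, convergence when the
relative log-likelihood change is < 1e-8 (cap 500 iterations), component
sds floored at 1e-3 to guard collapse. Components are relabelled so
mean_on > mean_off. A gene is reliably expressed in a condition iff its
posterior probability of the off component is below α = 0.01 in **every**
sample of the condition; the union over conditions defines the analysis
gene universe. Unequal variances were chosen (the alternative equal-variance
model is a special case; expression modes are visibly heteroscedastic);
fits are per sample, not pooled, to match the per-sample probability rule.

## IR classification

All thresholds are strict inequalities. Prevalence: PIR > 10 in ≥ 3 samples
of one compartment; missing never passes. NIRT/CIRT: with S = per-condition
mean PIR (conditions = fraction × DIV × genotype), CIRT iff
max S_nucleus > 20 and max S_cytoplasm > 15, NIRT iff max S_nucleus > 20
and max S_cytoplasm < 5, otherwise neither (the 5–15 gap zone is a
deliberate buffer). The per-condition mean is the default summary; an
any-sample mode is kept behind a flag for sensitivity analysis. ΔPIR
events: |mean PIR(b) − mean PIR(a)| ≥ 15 between two conditions, restricted
to introns whose host gene passes the expression gate in both conditions;
a replicate-aware Bayesian event caller is out of scope — the mean-ΔPIR
rule is the implemented criterion.

## SVD taxonomy

Each compartment's intron × sample PIR matrix is row-mean imputed (count
logged), row-centred by default, and decomposed by thin SVD. Row-centring
makes components capture retention *dynamics* rather than baseline level;
a no-centring mode is retained. A consequence to be aware of: archetypes
with flat profiles (N1, C4) have ≈ 0 centred signal, are never extreme on
any component, and remain unassigned — recovery metrics are therefore
computed over assigned introns. Signs are fixed (each right vector's
largest-magnitude entry positive) so runs are deterministic.

Per component k, each intron gets a Pearson correlation and a projection of
its (centred) profile onto v⃗ₖ; zero-variance profiles get a missing
correlation and are excluded. Extremes are selected by k-means on the
standardised (correlation, projection) plane — input points are sorted
canonically first so the result is independent of intron order — keeping
the clusters with the largest and smallest centroid coordinate sum. The
assembly uses k = 5 clusters per component (the standalone selector
defaults to 3): with only three clusters, a component with a one-sided
signal wing splits the large near-zero central mass across the remaining
two clusters and leaks null introns into an "extreme" cluster; five
clusters give the central mass its own clusters. Selections are assembled
into groups: introns selected on any cytoplasmic component become C groups,
introns selected only on nuclear components become N groups, one group per
(component, polarity) cell. An intron selected in several cells goes to the
cell with the largest projection **standardised within its component** —
raw projections scale with the singular values, so comparing them raw lets
the dominant component absorb groups that are better explained by a later
one. The cell → group-label map is configurable; the default enumerates
cells, so recovered labels are positional, not archetype names.

Defaults: 3 components per compartment (six cytoplasmic cells match the six
C archetypes; an auto mode picks the smallest k explaining ≥ 60 % variance,
capped at 5), seed-controlled k-means with 20 restarts. On the default
simulation the assigned-intron adjusted Rand index vs planted labels is
0.97 at noise sd 5 and exactly 1.0 at zero noise, with ~1400/1800 introns
assigned (the two flat archetypes are unassignable by construction under
row-centring).

## Cross-link enrichment

Regions are strand-aware: on the minus strand the upstream exon is the one
with larger genomic coordinates. R3 is 30 nt centred on
floor((start + end)/2). Introns shorter than 91 nt would have overlapping
R2/R3/R4 and are flagged invalid for regional (not whole-intron) analyses;
flanking exons shorter than 30 nt invalidate R1/R5. Whole-intron hits count
events anywhere in [start, end). Group enrichment = (group hit fraction) /
(background hit fraction), where the background is the complete intron set
(it includes the group, matching the fraction-of-complete-set convention);
significance is a one-sided (greater) Fisher exact test on
{group, non-group} × {hit, miss}, reported without multiple-testing
correction by default (Benjamini–Hochberg available behind a flag).
Group enrichment profiles are clustered with the Ward update on Manhattan
distances (scipy's linkage applies the Lance–Williams Ward step to whatever
dissimilarity is supplied); groups are pre-sorted by label so ties break
deterministically.

## Feature ANOVA and PTC scan

The feature model predicts each intron's maximum PIR (over one
compartment's samples) from five standardised features: log10 length (the
bounded logit(length/max) variant is available behind a flag, but the log
is the default since a logit of an unbounded count is ill-defined), GC
content, median conservation, per-intron cross-link enrichment, and introns
per gene. Each feature is tested by comparing the full OLS model with the
reduced model dropping it: F = ((RSS_red − RSS_full)/Δdf)/(RSS_full/df_den).
Collinearity (design condition number > 1e8) is an error naming the most
correlated pair. The PTC scan translates the intron-retaining transcript
from the CDS start, terminates at the first stop codon, and calls it a PTC
iff it lies more than 50 nt upstream of the last exon–exon junction of the
retaining transcript; the retained intron's own boundaries are not
junctions, so a retained final intron is never an NMD target. Only the
annotated reading frame is scanned.

## miRNA activity statistics

Target-shift tests are two-sided Welch t-tests (unequal variances,
Welch–Satterthwaite df) of target vs non-target log2FC within a declared
gene universe (the universe is an explicit argument everywhere). Concordance
tests mark a gene concordant iff its log2FC signs in two contrasts match the
given strict-sign predicates (zero is never concordant) and apply a
one-sided (greater) Fisher test to {target, non-target} × {concordant,
not}. Overlap tests are one-sided hypergeometric. Target sets may be
flagged as negative controls (housekeeping-style); reports expect them
non-significant.

The group PIR-shift test models long-form observations (intron × sample) as
PIR ~ genotype with a random intercept per patient, fitted by REML
(statsmodels MixedLM, default optimiser — L-BFGS produced unstable standard
errors on small balanced designs). The genotype Wald statistic is referred
to a t distribution with n_patients − 2 degrees of freedom: the genotype
contrast carries only between-patient information, and in the balanced case
this choice makes the test exact (it coincides with the pooled t-test on
patient means), whereas a normal reference is badly anticalibrated with six
patients. If the mixed fit is degenerate (non-finite coefficient or se) the
implementation falls back to a Welch t-test on per-patient mean PIR and
says so in the result.

## Benchmark problem sizes

Chosen so each check runs in seconds while keeping its statistical meaning:
taxonomy recovery at 200 introns/group (1800 × 42 per compartment); null
calibration with 1000 replicates per test — Fisher enrichment with a group
of 800 in a background of 4000 at p₀ = 0.2 (large enough that the exact
test's discreteness is negligible and its size approaches the nominal
0.05), shift/concordance with 200 targets in 2000 genes, mixed model with
3+3 patients × 2 samples × 40 introns and patient sd 5; power runs with 200
replicates — target shift −0.5 log2FC on 200 of 5000 genes, and a +10 PIR
genotype effect with noise sd 3 and patient sd 1 on 100 introns (the power
condition probes measurement noise around a real effect; with patient sd
comparable to the effect itself, no test at 3+3 patients has meaningful
power, which is a property of the design, not of the estimator).

## Known limitations

- Group labels produced by the taxonomy are positional (component/polarity
  cells); mapping them to named dynamics requires either the configurable
  group map or post-hoc inspection of the group mean profiles.
- Flat-dynamics intron classes are invisible to the row-centred taxonomy by
  construction; use `centering="none"` to trade dynamics resolution for
  baseline sensitivity.
- The mean-ΔPIR event rule ignores replicate dispersion.
- The PTC scan checks the annotated frame only and assumes the CDS start is
  known in transcript coordinates.
- Per-intron enrichment is undefined for genes without non-retained introns
  and for zero background rates; such introns drop out of the feature ANOVA.
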