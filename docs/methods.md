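# Methods

## Scope and data model

`htlmap` maps overdominant heterosis in a diallel of homozygous founder
lines.  Founders carry one allele per SSR marker, so each hybrid's
genotype is the unordered pair of its parents' alleles ("projection").
Per marker, hybrids partition into hetero-genotypic groups (one per
distinct allele pair) and a single pooled homozygous reference group; the
pooling reflects the assumption that homo-allelic combinations produce no
synergistic intra-locus interaction, and is switchable (`split_homo`) to
per-allele homozygous groups.  Any group with fewer than `min_group`
crosses (default 3) is excluded — the generalization of the rare-allele
rule that an allele carried by fewer than three founders cannot support a
testable group.  Groups that do reach three crosses are kept even when one
allele is rare, since group size, not allele frequency per se, limits the
contrast.

Years are analyzed separately throughout: parental means, ODH values, and
scan statistics are all within-year quantities.

## ODH, MPH, BPH

ODH is computed per hybrid replicate against the same-year parental means
(P1 low, P2 high), then averaged over replicates; it is zero inside the
parental range, positive only beyond the high parent and negative only
below the low parent, and invariant to positive rescaling of the trait.
Traits must be positive; crosses with a non-positive or missing parental
mean are flagged and excluded rather than silently dropped.  Seed number
is derived as SN = (DPW/SDW) × 50 from dry panicle weight and the
50-grain seed dry weight.

Reciprocal crosses of the same unordered pair are pooled before ODH
computation.  A Welch two-sample t-test per (pair, year) screens for
reciprocal (maternal/imprinting) differences; pairs significant at
P ≤ 0.01 are reported and excluded from the scan for that year — the
conservative generalization of treating imprinting as negligible when no
reciprocal pair differs.  Welch's test is a documented choice; any
two-sample location test can be substituted.  Directions with fewer than
three replicates are untestable.

## Two-step scan

Step 1 is the one-way fixed-effects GLM Y = µ + α(group) + e on
cross-level mean ODH.  The analysis unit is the cross mean, not the plant
replicate, so the residual is between-cross variation within a genotypic
group.  Genome-wide significance uses the permutation min-p law: the ODH
vector is shuffled against the fixed genotype structure `n_perm` times
(default 1000), the minimum nominal p across testable markers recorded per
permutation, and the threshold set at the empirical α-quantile (the
⌊α·n_perm⌋-th smallest).  A single top-level seed drives one generator for
the whole permutation matrix, so marker order cannot change results and
reruns are bit-identical.  Degenerate cases: markers with fewer than two
eligible groups are skipped with a reason; zero residual variance with
unequal means yields F = ∞, p = 0; zero total variance yields F = 0,
p = 1.

Step 2 contrasts each hetero group against the homozygous pool with the
two-sample Kolmogorov–Smirnov statistic.  One-sided by default:
D⁺ = sup[F̂_homo − F̂_hetero] (an advantaged hetero group lies to the
right, its ECDF below), with the asymptotic one-sided p = exp(−2D²nn′/(n+n′));
two-sided uses the Kolmogorov limit law.  The critical-value form
c(α)·√((n+n′)/nn′) is provided for reference but the p-value is
authoritative.  ECDFs are right-continuous; ties are kept, never jittered.
The advantage flag requires significance at `ks_alpha` (default 0.05,
uncorrected across hetero groups within a locus to match standard
reporting; a per-locus Bonferroni switch exists) *and* the hetero group
being the stochastically larger sample.  An HTL is called when the same
allele pair is advantaged in all years (strict intersection; a lenient
any-year mode exists), and calls are named h\<TRAIT\>\<chromosome\>.\<ordinal\>
with ordinals by map position.

With a founder cluster assignment, step 1 tests the genotype term
sequentially after a cluster-pair cofactor (Y = µ + α + β(cluster pair) + e;
aliasing of genotype with the cofactor is flagged as untestable), and
step 2 uses ODH values adjusted by each cluster combination's deviation
from the grand mean — the adjustment conserves the weighted grand mean and
removes all between-combination variance.

The permutation threshold calibrates the *exchangeable* no-association
null.  Real diallels are not exchangeable: crosses within a genotypic
group share parents, so GCA differences move group means even without any
overdominant locus.  In simulations with founder GCA at its default the
per-year chance that some marker passes step 1 is ≈0.10 rather than 0.05;
this is genuine family-structure association, and it is exactly what the
cluster-cofactor variant is for.  Type-I calibration tests therefore zero
the parental-structure effects.

## Epistasis models

Detected HTLs are binarized per cross: P if the cross carries an
advantaged pair, N otherwise.  The two-way model is
Y = µ + A + B + A:B + year + e and the three-way model adds C but only the
A:B interaction.  Year enters as a blocking term absorbed first; fixed
effects are tested against the residual mean square.  Sums of squares are
sequential (Type I) — exact decomposition in balanced data, documented
convention in unbalanced — with main-effect entry order defaulting to
descending single-factor R² and overridable.  The accumulated-R² sequence
(non-decreasing, ending at the model R²) tracks the genetic factors.  An
empty A×B cell drops the interaction; mains are still reported.

## F2 validation

An F1 heterozygous at the focal marker is selfed; the F2 segregates 1:2:1.
The locus–trait linkage is tested by one-way ANOVA; Hsu's MCB compares
each genotype with the best of the others using the pooled residual mean
square, one-sided at level α.  The MCB critical constant is the
(1−α)-quantile of max over the other groups of a studentized mean
difference; it is computed by seeded Monte Carlo from the fitted null
(20 000 draws) so the implementation is table-free, and collapses to the
exact one-sided t quantile for two groups.  With zero residual variance
the exact sample ordering is reported.  The overdominance effect is
100·(mean_het − baseline)/baseline with the baseline the unweighted
average of the two homozygote means (symmetric convention; the
better-homozygote baseline is exposed as an option).

## Synthetic data generator

The generator emulates the mapping study's structure: 19 founders at 85
multi-allelic markers spread over 10 chromosomes; per-locus allele
frequencies drawn from a skewed Dirichlet (concentration 1.5) so loci
carry a few common and several rare alleles, re-drawn (and finally
repaired deterministically) until at least two alleles have ≥3 carriers;
four founder clusters with weakly differentiated allele frequencies; a
near-complete half diallel (8% of pair-years missing, ~10% of pairs grown
reciprocally) over two years with 7/4 hybrid and 14/10 parent replicates
(2010/2011 pattern); strictly positive traits on a 100 g DPW scale.

Phenotypes: founder replicate = baseline + 2·GCA + year + noise
(GCA sd 2 g, year sd 3 g, residual sd 8 g); hybrid replicate =
(baseline + GCA_x + GCA_y + cluster-pair effect + year + noise) ×
(1 + 0.25 + SCA) × Π(1+d) over carried planted pairs.  The 25% general
hybrid advantage and the cross-specific SCA term (sd 0.12, genetic, hence
identical across years) reproduce the broad, predominantly positive ODH
distribution characteristic of reproductive traits; without them ODH
collapses to a point mass at zero plus isolated outliers, which corrupts
the permutation min-p null.  Planted overdominance is multiplicative on
the trait, giving a mean-ODH displacement of roughly d (default d = 0.85,
comfortably above the 0.5 working definition of a strong effect and ≈7
residual SDs of the cross-level ODH spread); an additive formulation can
be obtained by passing explicit planted effects.

Planted loci are chosen by an identifiability search rather than at
random.  Because all markers segregate over the same 19 founders, a
hetero group at another marker can draw most of its members from a
planted carrier set and echo the signal in both years — the
shared-segregation confounding that equally besets real diallel scans and
cannot be removed by any analysis setting.  The picker therefore searches
candidate triples (allele pairs with ≥3 carrier founders each and 10–16
carrier crosses) for disjoint carrier sets on distinct chromosomes,
maximizing the worst-case look-alike group's approximate KS p (capped,
beyond a comfortable level, so that markers with fewer genotypic groups —
whose single-locus F test is sharpest — are preferred).  This emulates
three genuinely distinct, non-interacting causal loci.  Under these
conditions the full two-step scan recovers exactly the planted set in
~93% of seeds (56/60 at 200 permutations; 27/30 at 1000).

What the generator does *not* emulate: linkage between markers (loci are
unlinked; LD can be mimicked by duplicating columns), trait–trait
correlation networks, spatial field effects, and genotype-by-year
interaction beyond the shared SCA.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated inheritance
model, not robustness to every feature of field data.

`simulate_epistasis_dataset` plants binary P/N factors with chosen
variance fractions (defaults 0.12/0.07/0.04 over ~280 cross-years) for
parameter-recovery tests of the ANOVA models; `simulate_f2` draws 1:2:1
genotypes with a multiplicative heterozygote shift (default 21%).

## Problem sizes and reporting

The acceptance script (`scripts/acceptance.py`) estimates the headline
quantity — the percentage of scanned loci declared HTLs when three loci
are planted among 85 — as the mean over 10 replicate studies, each scanned
with 1000 permutations; replicate seeds derive deterministically from the
single `--seed`.  The test suite uses 200 null datasets at 200
permutations for type-I calibration and 50 seeds for epistasis recovery;
these sizes give Monte-Carlo standard errors comfortably inside the
asserted tolerances.
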