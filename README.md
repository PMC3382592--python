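# htlmap — heterotic trait locus mapping in diallel crosses

`htlmap` maps **heterotic trait loci (HTLs)**: marker loci at which a
specific heterozygous allele combination confers *overdominant* hybrid
vigor — the heterozygote outperforming both homozygotes.  It is written for
quantitative geneticists and breeders working with diallel designs built
from homozygous inbred founder lines (the motivating system is a sorghum
half diallel of 19 founders genotyped at 85 multi-allelic SSR markers),
where every hybrid's genotype can be projected from its two parents.

## The statistics

**Overdominant heterosis (ODH).**  For a cross with parental trait means
P1 ≤ P2 and hybrid replicate value F1ᵣ,

    ODHᵣ = (F1ᵣ − P2)/P2   if F1ᵣ ≥ P2
         = (F1ᵣ − P1)/P1   if F1ᵣ ≤ P1
         = 0               otherwise,

averaged over the R replicates of the cross.  ODH isolates the part of
hybrid performance that lies *outside* the parental range, unlike
mid-parent heterosis MPH = (F̄1 − MP)/MP or best-parent heterosis
BPH = (F̄1 − P2)/P2, which are also computed.

**Two-step genome scan.**  At each marker the hybrids fall into
hetero-genotypic groups (one per unordered allele pair) and one pooled
homozygous group.  Step 1 fits Y<sub>ij</sub> = µ + α<sub>i</sub> +
e<sub>ij</sub> (one-way GLM of cross-level mean ODH on genotypic group) and
compares each marker's nominal p with an experiment-wise threshold: the
empirical α-quantile of the genome-wide minimum p over 1000 permutations of
the ODH values against the fixed genotype structure (Churchill–Doerge).
Step 2, at passing markers only, contrasts each hetero group against the
homozygous pool with a one-sided two-sample Kolmogorov–Smirnov test,
D = sup<sub>x</sub>[F̂<sub>homo</sub>(x) − F̂<sub>hetero</sub>(x)].  A
marker is called an HTL when the *same* allele pair is significantly
advantaged in every trial year; calls are named h\<TRAIT\>\<chrom\>.\<ordinal\>
(e.g. `hDPW4.1`).  A founder cluster assignment (e.g. from a structure
analysis) can be supplied, adding a cluster-pair cofactor to step 1 and
adjusting ODH values for step 2.

**Downstream.**  Detected HTLs are recoded per cross as P (carries the
advantaged pair) or N, and two-/three-way ANOVA with year as a blocking
term quantifies main, interaction, and accumulated R² contributions.  An
F2 segregating at a focal marker is analyzed by one-way ANOVA, Hsu's
multiple-comparisons-with-the-best, and a percent overdominance effect of
the heterozygote over the homozygote average.

Because no field data are bundled, `htlmap.simdata` generates a synthetic
study with the same structure (founders, multi-allelic markers, clusters,
near-complete two-year diallel with reciprocals, planted overdominant
loci) so the whole pipeline is testable end to end against known truth.

## Worked example

```sh
htlmap simulate --seed 0 --out study/
htlmap scan --geno study/founders.tsv --pheno study/pheno.tsv \
    --map study/markers.tsv --design study/design.tsv \
    --trait DPW --nperm 1000 --seed 1 --out scanout/
```

prints

```
HTL calls: hDPW1.1, hDPW3.1, hDPW6.1
```

Those are the three loci whose planted overdominant allele pairs (recorded
in `study/truth.json`) were advantaged in both simulated years; the
per-marker F statistics, permutation thresholds, and per-pair KS contrasts
are written to `scanout/scan.tsv`, and `scanout/htl_calls.json` holds the
named calls with per-year statistics.  The same computation is available as
a library call:

```python
from htlmap import SimConfig, ScanConfig, simulate_study, scan
study = simulate_study(SimConfig(seed=0))
result = scan(study.geno, study.pheno, study.design,
              ScanConfig(n_perm=1000, seed=1), "DPW")
[c.name for c in result.calls]   # ['hDPW1.1', 'hDPW3.1', 'hDPW6.1']
```

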