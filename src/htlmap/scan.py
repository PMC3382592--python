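"""Two-step genome scan for heterotic trait loci (HTLs).

Step 1 tests, marker by marker, whether the genotypic grouping of the
hybrids explains variation in cross-level mean ODH with a one-way
fixed-effects GLM (Y_ij = mu + alpha_i + e_ij); genome-wide significance is
set by an experiment-wise permutation threshold (Churchill–Doerge style):
cross-level ODH values are shuffled against the fixed genotype structure,
the minimum nominal p across markers is recorded per permutation, and the
threshold is the empirical alpha-quantile of that min-p distribution.

Step 2, run only at markers passing step 1, contrasts the ODH distribution
of each hetero-genotypic group against the pooled homozygous group with a
two-sample Kolmogorov–Smirnov test, one-sided toward hetero advantage by
default.  A locus is called an HTL when the same allele pair is
significantly advantaged in all required years.

With a founder structure assignment, step 1 adds the unordered pair of
parental cluster labels as a cofactor (Y_ij = mu + alpha_i + beta_k + e_ij,
sequential, cofactor first) and step 2 uses ODH values adjusted by each
cluster-combination's deviation from the weighted grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .diallel_core import (
    CrossKey,
    DiallelDesign,
    FounderGenotypeMatrix,
    GenotypeGroups,
    cross_key,
    format_cross,
    partition_by_locus,
    project_hybrid_genotypes,
)
from .heterosis import compute_odh_table, reciprocal_screen

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ScanConfig:
    """Tuning knobs of the two-step scan.

    alpha            experiment-wise step-1 error level
    n_perm           number of permutations for the genome-wide threshold
    seed             RNG seed (single source of randomness)
    min_group        minimal crosses per genotypic group
    ks_alpha         per-contrast level of the step-2 KS test
    ks_sided         "greater" (hetero advantage) or "two-sided"
    require_both_years   call HTLs only when advantaged in every year
    split_homo       keep per-allele homozygous groups instead of pooling
    bonferroni_within_locus   correct step-2 p across hetero groups of a locus
    exclude_reciprocal_different   drop pairs whose reciprocals differ (P<=0.01)
    """

    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    min_group: int = 3
    ks_alpha: float = 0.05
    ks_sided: str = "greater"
    require_both_years: bool = True
    split_homo: bool = False
    bonferroni_within_locus: bool = False
    exclude_reciprocal_different: bool = True
    reciprocal_alpha: float = 0.01

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.ks_sided not in ("greater", "two-sided"):
            raise ValueError("ks_sided must be 'greater' or 'two-sided'")


# ---------------------------------------------------------------------------
# vectorized fixed-effects ANOVA machinery


def _orthonormal(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank by SVD tolerance)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0:
        return u[:, :0]
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps))
    return u[:, :rank]


@dataclass
class _MarkerDesign:
    """Precomputed per-marker design for fast (permuted) F computation."""

    marker: str
    idx: np.ndarray                 # positions of eligible crosses in the y vector
    labels: np.ndarray              # group label per eligible cross
    group_names: list               # allele pair tuples, "homo" last if present
    homo_gid: Optional[int]
    q_reduced: np.ndarray           # orthonormal basis of the null model
    q_full: np.ndarray              # orthonormal basis incl. genotype groups
    df1: int
    df2: int
    skip_reason: Optional[str] = None


def _build_marker_design(
    marker: str,
    groups: GenotypeGroups,
    pos_of: Mapping[CrossKey, int],
    cofactor: Optional[np.ndarray] = None,
) -> _MarkerDesign:
    member_lists: list[tuple[object, list[CrossKey]]] = [
        (pair, members) for pair, members in groups.hetero.items()
    ]
    homo_gid = None
    if groups.homo:
        homo_gid = len(member_lists)
        member_lists.append(("homo", groups.homo))
    idx, labels = [], []
    for gid, (_, members) in enumerate(member_lists):
        for k in members:
            if k in pos_of:
                idx.append(pos_of[k])
                labels.append(gid)
    idx = np.asarray(idx, dtype=np.intp)
    labels = np.asarray(labels, dtype=np.intp)
    names = [name for name, _ in member_lists]
    keep = np.bincount(labels, minlength=len(names)) if labels.size else np.zeros(0)
    n_groups = int(np.sum(keep > 0)) if labels.size else 0
    base = _MarkerDesign(
        marker=marker, idx=idx, labels=labels, group_names=names,
        homo_gid=homo_gid, q_reduced=np.empty(0), q_full=np.empty(0),
        df1=0, df2=0,
    )
    if n_groups < 2:
        base.skip_reason = "fewer than 2 eligible genotypic groups"
        return base
    m = idx.size
    G = np.zeros((m, len(names)))
    G[np.arange(m), labels] = 1.0
    G = G[:, keep > 0]
    if cofactor is None:
        q_r = np.full((m, 1), 1.0 / np.sqrt(m))
        # disjoint indicator columns are orthogonal already
        q_f = G / np.sqrt(G.sum(axis=0))
    else:
        cof = cofactor[idx]
        levels = np.unique(cof)
        C = (cof[:, None] == levels[None, :]).astype(float)
        q_r = _orthonormal(np.hstack([np.ones((m, 1)), C]))
        q_f = _orthonormal(np.hstack([np.ones((m, 1)), C, G]))
    df1 = q_f.shape[1] - q_r.shape[1]
    df2 = m - q_f.shape[1]
    if df1 < 1:
        base.skip_reason = "genotype groups aliased with cofactor"
        return base
    if df2 < 1:
        base.skip_reason = "no residual degrees of freedom"
        return base
    base.q_reduced, base.q_full, base.df1, base.df2 = q_r, q_f, df1, df2
    return base


def _f_pvalues(V: np.ndarray, d: _MarkerDesign) -> tuple[np.ndarray, np.ndarray]:
    """F and p of the genotype term for each row of V (rows are y vectors)."""
    Vm = V[:, d.idx]
    ssq = np.einsum("ij,ij->i", Vm, Vm)
    pr = Vm @ d.q_reduced
    pf = Vm @ d.q_full
    ss_r = np.einsum("ij,ij->i", pr, pr)
    ss_f = np.einsum("ij,ij->i", pf, pf)
    num = np.maximum(ss_f - ss_r, 0.0) / d.df1
    den = np.maximum(ssq - ss_f, 0.0) / d.df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / den
    F = np.where((num <= 1e-300) & (den <= 1e-300), 0.0, F)
    F = np.where(np.isnan(F), 0.0, F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), d.df1, d.df2))
    p = np.where(F == 0.0, 1.0, p)
    return F, p


def glm_marker_test(
    odh: Mapping[CrossKey, float] | pd.Series,
    groups: GenotypeGroups,
    cofactor: Optional[Mapping[CrossKey, str]] = None,
) -> tuple[float, float]:
    """One-way GLM of cross-level mean ODH on genotypic group: (F, p).

    With ``cofactor`` (cross -> cluster-pair label) the genotype effect is
    tested after the cofactor (sequential fit, cofactor first).
    Raises ValueError when fewer than 2 eligible groups remain.
    """
    odh = _as_cross_series(odh)
    keys = [k for k in odh.index]
    pos_of = {k: i for i, k in enumerate(keys)}
    cof = None
    if cofactor is not None:
        cof = np.asarray([cofactor[k] for k in keys], dtype=object)
    d = _build_marker_design(groups.marker.name, groups, pos_of, cof)
    if d.skip_reason:
        raise ValueError(f"marker {groups.marker.name}: {d.skip_reason}")
    y = odh.to_numpy(dtype=float)[None, :]
    F, p = _f_pvalues(y, d)
    return float(F[0]), float(p[0])


def _as_cross_series(odh) -> pd.Series:
    if isinstance(odh, pd.Series):
        idx = [k if isinstance(k, tuple) else cross_key(*str(k).split("/")) for k in odh.index]
        return pd.Series(odh.to_numpy(dtype=float), index=idx)
    return pd.Series({k: float(v) for k, v in odh.items()})


# ---------------------------------------------------------------------------
# permutation threshold


def _min_p_distribution(
    y: np.ndarray, designs: Sequence[_MarkerDesign], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    V = np.tile(y, (n_perm, 1))
    V = rng.permuted(V, axis=1)
    min_p = np.full(n_perm, np.inf)
    for d in designs:
        if d.skip_reason:
            continue
        _, p = _f_pvalues(V, d)
        np.minimum(min_p, p, out=min_p)
    return min_p


def _threshold_from_min_p(min_p: np.ndarray, alpha: float) -> float:
    k = max(1, int(np.floor(alpha * min_p.size)))
    return float(np.sort(min_p)[k - 1])


def permutation_threshold(
    odh: Mapping[CrossKey, float] | pd.Series,
    groups_by_marker: Mapping[str, GenotypeGroups],
    config: ScanConfig,
    cofactor: Optional[Mapping[CrossKey, str]] = None,
) -> float:
    """Experiment-wise nominal-p threshold from the permutation min-p law.

    The ODH vector is shuffled against the (fixed) genotype structure
    ``n_perm`` times; the threshold is the empirical alpha-quantile of the
    per-permutation genome-wide minimum p.  Deterministic given the seed.
    """
    odh = _as_cross_series(odh)
    keys = list(odh.index)
    pos_of = {k: i for i, k in enumerate(keys)}
    cof = None
    if cofactor is not None:
        cof = np.asarray([cofactor[k] for k in keys], dtype=object)
    designs = [
        _build_marker_design(m, g, pos_of, cof) for m, g in groups_by_marker.items()
    ]
    testable = [d for d in designs if not d.skip_reason]
    if len(testable) < 1:
        raise ValueError("no testable markers")
    rng = np.random.default_rng(config.seed)
    min_p = _min_p_distribution(odh.to_numpy(dtype=float), testable, config.n_perm, rng)
    return _threshold_from_min_p(min_p, config.alpha)


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov contrast


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    advantage: bool
    n_hetero: int
    n_homo: int


def _ecdf_sup_diff(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x [ ECDF_a(x) - ECDF_b(x) ] over the pooled sample points."""
    xs = np.concatenate([a, b])
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    Fa = np.searchsorted(a_sorted, xs, side="right") / a.size
    Fb = np.searchsorted(b_sorted, xs, side="right") / b.size
    return float(np.max(Fa - Fb))


def ks_critical_D(alpha: float, n: int, n_prime: int, sided: str = "greater") -> float:
    """Critical D: c(alpha) * sqrt((n + n') / (n n')), asymptotic coefficient."""
    c = np.sqrt(-np.log(alpha if sided == "greater" else alpha / 2.0) / 2.0)
    return float(c * np.sqrt((n + n_prime) / (n * n_prime)))


def ks_hetero_vs_homo(
    hetero: Sequence[float],
    homo: Sequence[float],
    ks_alpha: float = 0.05,
    sided: str = "greater",
) -> KSResult:
    """KS contrast of a hetero-genotypic group against the homozygous pool.

    ``sided="greater"`` tests hetero stochastic advantage: the statistic is
    D+ = sup_x [ECDF_homo(x) − ECDF_hetero(x)] (an advantaged hetero group
    has its ECDF shifted right, i.e. below the homozygous ECDF), with the
    one-sided asymptotic p = exp(−2 D² nn′/(n+n′)).  ``sided="two-sided"``
    uses D = sup|difference| and the Kolmogorov law; the advantage flag then
    additionally requires the dominant deviation to favor the hetero group.
    Ties are handled by right-continuous ECDFs; no jittering.
    """
    het = np.asarray(hetero, dtype=float)
    hom = np.asarray(homo, dtype=float)
    if het.size == 0 or hom.size == 0:
        raise ValueError("empty sample in KS contrast")
    n, n_prime = het.size, hom.size
    en = n * n_prime / (n + n_prime)
    d_plus = _ecdf_sup_diff(hom, het)   # hetero stochastically larger
    d_minus = _ecdf_sup_diff(het, hom)  # hetero stochastically smaller
    if sided == "greater":
        D = max(d_plus, 0.0)
        p = float(min(1.0, np.exp(-2.0 * en * D * D)))
        advantage = p <= ks_alpha and D > 0
    elif sided == "two-sided":
        D = max(d_plus, d_minus)
        p = float(min(1.0, stats.kstwobign.sf(np.sqrt(en) * D))) if D > 0 else 1.0
        advantage = p <= ks_alpha and d_plus >= d_minus and D > 0
    else:
        raise ValueError("sided must be 'greater' or 'two-sided'")
    return KSResult(D=float(D), p=p, advantage=bool(advantage),
                    n_hetero=n, n_homo=n_prime)


# ---------------------------------------------------------------------------
# founder-structure adjustment


def hybrid_cofactor(
    assign: Mapping[str, str], keys: Sequence[CrossKey]
) -> dict[CrossKey, str]:
    """Cluster-pair cofactor label per cross (unordered pair of parent clusters)."""
    out = {}
    for a, b in keys:
        for p in (a, b):
            if p not in assign:
                raise KeyError(f"founder {p!r} has no cluster assignment")
        ca, cb = sorted((str(assign[a]), str(assign[b])))
        out[(a, b)] = f"{ca}|{cb}"
    return out


def adjust_for_structure(
    odh: pd.Series, combos: Mapping[CrossKey, str] | pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Remove the cluster-combination effect from cross-level ODH values.

    The effect of a combination is its mean ODH minus the grand mean (the
    average of combination means weighted by combination size); subtracting
    it centers every combination on the grand mean, which is conserved.
    Returns (adjusted ODH, per-combination effects).
    """
    odh = _as_cross_series(odh)
    if isinstance(combos, pd.Series):
        combo_of = pd.Series(
            combos.to_numpy(dtype=object),
            index=[k if isinstance(k, tuple) else cross_key(*str(k).split("/")) for k in combos.index],
        )
    else:
        combo_of = pd.Series({k: combos[k] for k in odh.index})
    labels = combo_of.reindex(odh.index)
    if labels.isna().any():
        missing = [format_cross(k) for k in odh.index[labels.isna()]]
        raise KeyError(f"crosses without cluster combination: {missing[:5]}")
    grand = float(odh.mean())
    means = odh.groupby(labels.to_numpy()).mean()
    effects = means - grand
    adjusted = odh - labels.map(effects).to_numpy(dtype=float)
    return adjusted, effects


def glm_with_cofactor(
    odh: Mapping[CrossKey, float] | pd.Series,
    groups: GenotypeGroups,
    assign: Mapping[str, str],
) -> tuple[float, float]:
    """Genotype-effect F and p after the cluster-pair cofactor (sequential)."""
    odh = _as_cross_series(odh)
    cof = hybrid_cofactor(assign, list(odh.index))
    return glm_marker_test(odh, groups, cofactor=cof)


# ---------------------------------------------------------------------------
# scan orchestration


@dataclass
class MarkerScanResult:
    """Step-1 statistic and (when passed) step-2 KS contrasts for one marker."""

    marker: str
    year: object
    F: Optional[float]
    p: Optional[float]
    threshold: float
    passed: bool
    skip_reason: Optional[str] = None
    step2: dict = field(default_factory=dict)  # allele pair -> KSResult
    group_sizes: dict = field(default_factory=dict)


@dataclass
class HTLCall:
    """A marker where one allele pair is advantaged in all required years."""

    marker: str
    trait: str
    pairs: list
    name: str = ""
    chromosome: Optional[str] = None
    position: Optional[float] = None
    per_year: dict = field(default_factory=dict)


@dataclass
class ScanResult:
    trait: str
    years: dict          # year -> list[MarkerScanResult]
    thresholds: dict     # year -> float
    calls: list          # list[HTLCall]
    odh: pd.DataFrame
    excluded_crosses: dict = field(default_factory=dict)


def _scan_one_year(
    y: np.ndarray,
    keys: list[CrossKey],
    proj,
    marker_names: Sequence[str],
    geno: FounderGenotypeMatrix,
    config: ScanConfig,
    year,
    assign: Optional[Mapping[str, str]],
) -> tuple[list[MarkerScanResult], float]:
    pos_of = {k: i for i, k in enumerate(keys)}
    cof_map = hybrid_cofactor(assign, keys) if assign is not None else None
    cof = (
        np.asarray([cof_map[k] for k in keys], dtype=object)
        if cof_map is not None
        else None
    )
    designs, groups_by_marker = [], {}
    for m in marker_names:
        g = partition_by_locus(
            proj, geno.marker(m), min_group=config.min_group,
            split_homo=config.split_homo, crosses=keys,
        )
        groups_by_marker[m] = g
        designs.append(_build_marker_design(m, g, pos_of, cof))
    testable = [d for d in designs if not d.skip_reason]
    if not testable:
        raise ValueError(f"year {year}: no testable markers")
    rng = np.random.default_rng(config.seed)
    min_p = _min_p_distribution(y, testable, config.n_perm, rng)
    threshold = _threshold_from_min_p(min_p, config.alpha)

    if assign is not None:
        y_step2, _ = adjust_for_structure(
            pd.Series(y, index=keys), cof_map
        )
        y_step2 = y_step2.to_numpy(dtype=float)
    else:
        y_step2 = y

    results = []
    yrow = y[None, :]
    for d, mname in zip(designs, marker_names):
        g = groups_by_marker[mname]
        sizes = {pair: len(members) for pair, members in g.hetero.items()}
        if g.homo:
            sizes["homo"] = len(g.homo)
        if d.skip_reason:
            results.append(
                MarkerScanResult(
                    marker=mname, year=year, F=None, p=None, threshold=threshold,
                    passed=False, skip_reason=d.skip_reason, group_sizes=sizes,
                )
            )
            continue
        F, p = _f_pvalues(yrow, d)
        F, p = float(F[0]), float(p[0])
        res = MarkerScanResult(
            marker=mname, year=year, F=F, p=p, threshold=threshold,
            passed=bool(p <= threshold), group_sizes=sizes,
        )
        if res.passed and g.homo:
            homo_vals = y_step2[[pos_of[k] for k in g.homo if k in pos_of]]
            n_contrasts = max(1, len(g.hetero))
            for pair, members in g.hetero.items():
                het_vals = y_step2[[pos_of[k] for k in members if k in pos_of]]
                ks = ks_hetero_vs_homo(
                    het_vals, homo_vals, ks_alpha=config.ks_alpha,
                    sided=config.ks_sided,
                )
                if config.bonferroni_within_locus:
                    p_adj = min(1.0, ks.p * n_contrasts)
                    ks = KSResult(
                        D=ks.D, p=p_adj,
                        advantage=bool(ks.advantage and p_adj <= config.ks_alpha),
                        n_hetero=ks.n_hetero, n_homo=ks.n_homo,
                    )
                res.step2[pair] = ks
        results.append(res)
    return results, threshold


def call_htls(
    years: Mapping[object, Sequence[MarkerScanResult]],
    geno: FounderGenotypeMatrix,
    trait: str,
    require_both_years: bool = True,
) -> list[HTLCall]:
    """Intersect per-year advantaged (marker, allele pair) sets and name calls.

    Names follow the h<TRAIT><chromosome>.<ordinal> convention, ordinals by
    map position within a chromosome (e.g. hDPW4.1).
    """
    year_list = list(years)
    adv: dict[str, dict[object, set]] = {}
    for yr in year_list:
        for res in years[yr]:
            pairs = {p for p, ks in res.step2.items() if ks.advantage}
            if pairs:
                adv.setdefault(res.marker, {})[yr] = pairs
    calls = []
    for marker, per_year in adv.items():
        if require_both_years:
            if set(per_year) != set(year_list):
                continue
            common = set.intersection(*(per_year[yr] for yr in year_list))
        else:
            common = set.union(*per_year.values())
        if not common:
            continue
        mdef = geno.marker(marker)
        calls.append(
            HTLCall(
                marker=marker, trait=trait,
                pairs=sorted(common),
                chromosome=mdef.chromosome, position=mdef.position,
                per_year={
                    yr: {
                        p: ks
                        for p, ks in _find(years[yr], marker).step2.items()
                    }
                    for yr in year_list
                    if _find(years[yr], marker) is not None
                },
            )
        )
    # naming: ordinal by position within chromosome
    def sort_key(c: HTLCall):
        chrom = c.chromosome if c.chromosome is not None else ""
        pos = c.position if c.position is not None else np.inf
        return (str(chrom), pos, c.marker)

    calls.sort(key=sort_key)
    counter: dict[str, int] = {}
    for c in calls:
        chrom = c.chromosome if c.chromosome is not None else "0"
        counter[chrom] = counter.get(chrom, 0) + 1
        c.name = f"h{trait}{chrom}.{counter[chrom]}"
    return calls


def _find(results: Sequence[MarkerScanResult], marker: str):
    for r in results:
        if r.marker == marker:
            return r
    return None


def scan(
    geno: FounderGenotypeMatrix,
    pheno: pd.DataFrame,
    design: DiallelDesign,
    config: ScanConfig,
    trait: str,
    assign: Optional[Mapping[str, str]] = None,
    odh: Optional[pd.DataFrame] = None,
) -> ScanResult:
    """Run the full two-step HTL scan for one trait, per year, and call HTLs.

    ``odh`` may be a precomputed table from
    :func:`htlmap.heterosis.compute_odh_table`; otherwise it is computed
    from the plant-level phenotypes.  Years are analyzed separately; HTLs
    are called by intersecting advantaged allele pairs across years (strict
    same-pair intersection when ``require_both_years``).
    """
    if odh is None:
        if pheno is None:
            raise ValueError("either pheno or odh must be given")
        odh = compute_odh_table(pheno, design, [trait])
    sub = odh[(odh["trait"] == trait) & (odh["flag"] == "")].copy()
    if sub.empty:
        raise ValueError(f"no ODH rows for trait {trait}")

    excluded: dict = {}
    if config.exclude_reciprocal_different and pheno is not None:
        screen = reciprocal_screen(
            pheno, design, trait, alpha=config.reciprocal_alpha
        )
        if not screen.empty:
            bad = screen[screen["verdict"] == "different"]
            for _, row in bad.iterrows():
                excluded.setdefault(row["year"], set()).add(row["cross"])

    proj = project_hybrid_genotypes(geno, design)
    marker_names = geno.marker_names
    years_out: dict = {}
    thresholds: dict = {}
    for year in sorted(sub["year"].unique()):
        ysub = sub[sub["year"] == year]
        drop = excluded.get(year, set())
        ysub = ysub[~ysub["cross"].isin(drop)]
        keys = [cross_key(*c.split("/")) for c in ysub["cross"]]
        known = set()
        for mvals in proj.values():
            known.update(mvals)
            break
        common = [k for k in keys if k in known]
        if not common:
            raise ValueError(
                f"year {year}: no crosses shared between genotype projection and ODH table"
            )
        mask = [k in known for k in keys]
        y = ysub["ODH"].to_numpy(dtype=float)[mask]
        keys = [k for k, m in zip(keys, mask) if m]
        results, thr = _scan_one_year(
            y, keys, proj, marker_names, geno, config, year, assign
        )
        years_out[year] = results
        thresholds[year] = thr
    calls = call_htls(
        years_out, geno, trait, require_both_years=config.require_both_years
    )
    return ScanResult(
        trait=trait, years=years_out, thresholds=thresholds, calls=calls,
        odh=odh, excluded_crosses={k: sorted(v) for k, v in excluded.items()},
    )
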