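"""Single-locus overdominance validation in an F2 population.

An F1 heterozygous at the focal marker is selfed; the F2 segregates
1 : 2 : 1 into the two parental homozygotes and the heterozygote.  The
locus-trait linkage is tested by one-way ANOVA, the best genotype is
identified with Hsu's multiple-comparisons-with-the-best (MCB), and the
overdominance effect is reported as the percent advantage of the
heterozygote over the homozygote baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class F2GroupStats:
    """Per-genotype summaries plus the overall one-way ANOVA."""

    table: pd.DataFrame     # index genotype, columns n, mean, se
    F: float
    p: float
    ms_error: float
    df_error: int


def f2_group_stats(records: pd.DataFrame, trait: str, genotype_col: str = "genotype") -> F2GroupStats:
    """Group n/mean/SE per genotype and the one-way ANOVA F and p."""
    sub = records[[genotype_col, trait]].dropna()
    groups = {g: v[trait].to_numpy(dtype=float) for g, v in sub.groupby(genotype_col)}
    if sum(1 for v in groups.values() if v.size > 0) < 2:
        raise ValueError("need >= 2 non-empty genotype groups")
    names = sorted(groups)
    arrays = [groups[g] for g in names]
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_error = int(ns.sum() - len(names))
    ss_error = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    ms_error = ss_error / df_error if df_error > 0 else 0.0
    se = np.sqrt(ms_error / ns) if ms_error > 0 else np.array(
        [a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0 for a in arrays]
    )
    grand = float(np.concatenate(arrays).mean())
    ss_between = float((ns * (means - grand) ** 2).sum())
    df_between = len(names) - 1
    if ms_error > 0:
        F = (ss_between / df_between) / ms_error
        p = float(stats.f.sf(F, df_between, df_error))
    elif ss_between > 0:
        F, p = np.inf, 0.0
    else:
        F, p = 0.0, 1.0
    table = pd.DataFrame({"n": ns, "mean": means, "se": se}, index=pd.Index(names, name="genotype"))
    return F2GroupStats(table=table, F=float(F), p=p, ms_error=ms_error, df_error=df_error)


@dataclass
class MCBResult:
    """Hsu's MCB output: per-group comparison with the best of the others."""

    table: pd.DataFrame     # index genotype: mean, diff_from_best, upper, p, in_best_set, letter
    best: str               # group with the maximal sample mean
    critical: dict          # per-group critical constant d_i


def _mcb_critical(ns: np.ndarray, df_error: int, alpha: float,
                  i: int, rng: np.random.Generator, n_mc: int) -> float:
    """Monte-Carlo (1-alpha) quantile of max_{j!=i} (Z_j - Z_i)/(s sqrt(1/n_i+1/n_j)).

    Exact one-sided t quantile for two groups; seeded Monte Carlo otherwise
    (the constant is the one-sided Dunnett-type quantile for comparing group
    i with the best of the others under the fitted null).
    """
    k = ns.size
    if k == 2:
        return float(stats.t.ppf(1 - alpha, df_error))
    z = rng.standard_normal((n_mc, k)) / np.sqrt(ns)
    s = np.sqrt(rng.chisquare(df_error, size=n_mc) / df_error)
    others = [j for j in range(k) if j != i]
    scale = np.sqrt(1.0 / ns[i] + 1.0 / ns[others])
    T = ((z[:, others] - z[:, [i]]) / scale) / s[:, None]
    return float(np.quantile(T.max(axis=1), 1 - alpha))


def hsu_mcb(
    stats_in: F2GroupStats,
    alpha: float = 0.05,
    seed: int = 0,
    n_mc: int = 20000,
) -> MCBResult:
    """Hsu's multiple comparisons with the best, one-sided at level alpha.

    For each group i the comparison is mean_i - max_{j!=i} mean_j with the
    pooled-residual standard error; a group is *not in the best set* when
    the upper confidence bound of that difference is negative.  The best
    set shares letter "a"; significantly worse groups get "b".  With zero
    residual variance the exact sample ordering is reported.
    """
    tbl = stats_in.table
    names = list(tbl.index)
    ns = tbl["n"].to_numpy(dtype=float)
    means = tbl["mean"].to_numpy(dtype=float)
    k = len(names)
    if k < 2:
        raise ValueError("need >= 2 groups")
    best_idx = int(np.argmax(means))
    rng = np.random.default_rng(seed)
    rows, critical = [], {}
    if stats_in.ms_error <= 0 or stats_in.df_error < 1:
        # degenerate: no residual variance -> exact ordering
        for i, g in enumerate(names):
            diff = means[i] - max(means[j] for j in range(k) if j != i)
            in_best = diff >= 0
            rows.append({"mean": means[i], "diff_from_best": diff, "upper": diff,
                         "p": 0.0 if diff < 0 else 1.0, "in_best_set": in_best})
            critical[g] = 0.0
    else:
        s2 = stats_in.ms_error
        for i, g in enumerate(names):
            others = [j for j in range(k) if j != i]
            j_star = others[int(np.argmax(means[others]))]
            diff = means[i] - means[j_star]
            se = float(np.sqrt(s2 * (1.0 / ns[i] + 1.0 / ns[j_star])))
            d = _mcb_critical(ns, stats_in.df_error, alpha, i, rng, n_mc)
            critical[g] = d
            upper = diff + d * se
            # one-sided p for "group i worse than the best": MC tail of the
            # max-T statistic at the observed standardized difference
            t_obs = -diff / se if se > 0 else np.inf * np.sign(-diff)
            if k == 2:
                p = float(stats.t.sf(t_obs, stats_in.df_error))
            else:
                z = rng.standard_normal((n_mc, k)) / np.sqrt(ns)
                s = np.sqrt(rng.chisquare(stats_in.df_error, size=n_mc) / stats_in.df_error)
                scale = np.sqrt(1.0 / ns[i] + 1.0 / ns[others])
                T = ((z[:, others] - z[:, [i]]) / scale) / s[:, None]
                p = float(np.mean(T.max(axis=1) >= t_obs))
            rows.append({"mean": means[i], "diff_from_best": diff, "upper": upper,
                         "p": p, "in_best_set": bool(upper >= 0)})
    table = pd.DataFrame(rows, index=pd.Index(names, name="genotype"))
    table["letter"] = np.where(table["in_best_set"], "a", "b")
    return MCBResult(table=table, best=names[best_idx], critical=critical)


def overdominance_effect(
    stats_in: F2GroupStats,
    het: str,
    hom1: str,
    hom2: str,
    baseline: str = "mean_homo",
) -> float:
    """Percent heterozygote effect over the homozygote baseline.

    ``baseline="mean_homo"`` (default) uses the unweighted average of the
    two homozygote group means; ``"best_homo"`` uses the larger one.
    """
    tbl = stats_in.table
    for g in (het, hom1, hom2):
        if g not in tbl.index:
            raise KeyError(f"genotype group {g!r} absent")
    m1, m2 = float(tbl.loc[hom1, "mean"]), float(tbl.loc[hom2, "mean"])
    base = (m1 + m2) / 2.0 if baseline == "mean_homo" else max(m1, m2)
    if base <= 0:
        raise ValueError("non-positive homozygote baseline")
    return 100.0 * (float(tbl.loc[het, "mean"]) - base) / base


def segregation_chi2(records: pd.DataFrame, genotype_col: str = "genotype",
                     het: Optional[str] = None) -> tuple[float, float]:
    """Chi-square goodness of fit of genotype counts to 1:2:1 segregation."""
    counts = records[genotype_col].value_counts()
    if len(counts) != 3:
        raise ValueError("expected exactly 3 genotype classes")
    if het is None:
        het = max(counts.index, key=lambda g: len(set(str(g).split("/"))))
    n = counts.sum()
    expected = {g: (n / 2 if g == het else n / 4) for g in counts.index}
    chi2 = sum((counts[g] - expected[g]) ** 2 / expected[g] for g in counts.index)
    return float(chi2), float(stats.chi2.sf(chi2, df=2))
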