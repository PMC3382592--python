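"""Epistasis among detected HTLs: P/N recoding and multi-way ANOVA.

Each HTL is binarized per cross into **P** (the cross carries one of the
locus's advantaged allele pairs — a positive intra-locus interaction) or
**N** (any other allelic combination).  Two- and three-way fixed-effects
models on cross-level ODH then quantify main, interaction, and cumulative
contributions of the HTLs to heterotic variation:

    two-way:    Y = mu + A + B + A:B + year + e
    three-way:  Y = mu + A + B + C + A:B + year + e

Year enters as a random blocking term whose sum of squares is absorbed
before the fixed terms; fixed effects are tested against the residual mean
square.  Sums of squares are sequential (Type I), with entry order
defaulting to descending single-factor R² so the largest main effect is
credited first; the accumulated-R² sequence reports the cumulative variance
explained as terms enter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .diallel_core import CrossKey, cross_key
from .scan import HTLCall


@dataclass
class AnovaResult:
    """Sequential-ANOVA summary: per-term df/SS/F/p, model R², accumulated R²."""

    terms: pd.DataFrame            # index term, columns df, sum_sq, F, PR(>F)
    r_squared: float
    accumulated: list              # [(term, cumulative R²), ...]
    order: list = field(default_factory=list)

    def __post_init__(self):
        cum = [r2 for _, r2 in self.accumulated]
        if any(b < a - 1e-9 for a, b in zip(cum, cum[1:])):
            raise ValueError("accumulated R² must be non-decreasing")


def pn_recode(
    proj: Mapping[str, Mapping[CrossKey, Optional[tuple[int, int]]]],
    htl: HTLCall,
) -> pd.Series:
    """P/N state per cross for one HTL.

    P iff the cross's unordered allele pair at the HTL marker is among the
    advantaged pairs; crosses with a missing genotype are dropped.
    """
    if not htl.pairs:
        raise ValueError(f"HTL {htl.marker} has no advantaged pairs")
    locus = proj[htl.marker]
    adv = {tuple(sorted(p)) for p in htl.pairs}
    states = {}
    for k, pair in locus.items():
        if pair is None:
            continue
        states[k] = "P" if tuple(sorted(pair)) in adv else "N"
    return pd.Series(states, name=htl.name or htl.marker)


def _single_factor_r2(df: pd.DataFrame, response: str, factor: str) -> float:
    fit = smf.ols(f"{response} ~ C(f_{factor})", data=df).fit()
    return float(fit.rsquared)


def _fit_sequential(
    df: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    interactions: Sequence[tuple[str, str]],
    year_col: Optional[str],
    order: Optional[Sequence[str]],
) -> AnovaResult:
    if order is None:
        r2 = {f: _single_factor_r2(df, response, f) for f in factors}
        order = sorted(factors, key=lambda f: -r2[f])
    else:
        order = list(order)
        if set(order) != set(factors):
            raise ValueError("order must be a permutation of the factors")
    rhs = []
    if year_col is not None and df[year_col].nunique() > 1:
        rhs.append(f"C({year_col})")
        year_term = f"C({year_col})"
    else:
        year_term = None
    rhs += [f"C(f_{f})" for f in order]
    inter_terms = []
    for a, b in interactions:
        t = f"C(f_{a}):C(f_{b})"
        rhs.append(t)
        inter_terms.append(t)
    formula = f"{response} ~ " + " + ".join(rhs)
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=1)
    ss_total = float(table["sum_sq"].sum())
    seq_terms = []
    if year_term is not None:
        seq_terms.append((year_term, "year"))
    seq_terms += [(f"C(f_{f})", f) for f in order]
    for (a, b), t in zip(interactions, inter_terms):
        seq_terms.append((t, f"{a}:{b}"))
    rename = dict(seq_terms)
    terms = table.rename(index=rename)
    accumulated, cum = [], 0.0
    for raw, label in seq_terms:
        cum += float(table.loc[raw, "sum_sq"]) / ss_total
        if label == "year":
            continue  # accumulated R² tracks the genetic factors
        accumulated.append((label, cum))
    return AnovaResult(
        terms=terms,
        r_squared=float(fit.rsquared),
        accumulated=accumulated,
        order=list(order),
    )


def _assemble(odh: pd.DataFrame, factors: Mapping[str, pd.Series], trait: Optional[str]) -> pd.DataFrame:
    sub = odh
    if trait is not None and "trait" in odh.columns:
        sub = odh[odh["trait"] == trait]
    if "flag" in sub.columns:
        sub = sub[sub["flag"] == ""]
    keys = [cross_key(*c.split("/")) for c in sub["cross"]]
    data = {"odh": sub["ODH"].to_numpy(dtype=float), "year": sub["year"].to_numpy()}
    df = pd.DataFrame(data, index=pd.Index(keys, tupleize_cols=False))
    for name, f in factors.items():
        lut = dict(f.items())
        df[f"f_{name}"] = [lut.get(k, np.nan) for k in df.index]
    return df.dropna().reset_index(drop=True)


def two_way_anova(
    odh: pd.DataFrame,
    A: pd.Series,
    B: pd.Series,
    trait: Optional[str] = None,
    order: Optional[Sequence[str]] = None,
) -> AnovaResult:
    """Two-way P/N model Y = mu + A + B + A:B + year + e on cross-level ODH.

    A and B are P/N factors indexed by cross key (see :func:`pn_recode`).
    When any of the four A x B cells is empty the interaction is dropped and
    only main effects are reported.
    """
    df = _assemble(odh, {"A": A, "B": B}, trait)
    cells = df.groupby(["f_A", "f_B"]).size()
    full_cells = len(cells) == df["f_A"].nunique() * df["f_B"].nunique()
    interactions = [("A", "B")] if full_cells else []
    return _fit_sequential(df, "odh", ["A", "B"], interactions, "year", order)


def three_way_model(
    odh: pd.DataFrame,
    A: pd.Series,
    B: pd.Series,
    C: pd.Series,
    trait: Optional[str] = None,
    order: Optional[Sequence[str]] = None,
) -> AnovaResult:
    """Three-way P/N model Y = mu + A + B + C + A:B + year + e.

    Only the A x B interaction is included; entry order of the mains
    defaults to descending single-factor R².
    """
    df = _assemble(odh, {"A": A, "B": B, "C": C}, trait)
    cells = df.groupby(["f_A", "f_B"]).size()
    full_cells = len(cells) == df["f_A"].nunique() * df["f_B"].nunique()
    interactions = [("A", "B")] if full_cells else []
    return _fit_sequential(df, "odh", ["A", "B", "C"], interactions, "year", order)


def variance_explained(result: AnovaResult) -> pd.DataFrame:
    """Accumulated-R² table: one row per factor added, cumulative R²."""
    return pd.DataFrame(result.accumulated, columns=["factor", "cumulative_r2"])
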