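"""Heterosis estimators for diallel phenotypes.

Three per-cross statistics are computed from replicated phenotypes, always
within one year (years are analyzed separately):

* **MPH** (mid-parent heterosis): (F1bar − MP)/MP with MP = (P1+P2)/2.
* **BPH** (best-parent heterosis): (F1bar − P2)/P2.
* **ODH** (overdominant heterosis): a per-replicate piecewise statistic —
  the relative deviation of the hybrid replicate *beyond* the parental
  range.  With P1 ≤ P2 the parental means,

      ODH_r = (F1_r − P2)/P2   if F1_r ≥ P2
            = (F1_r − P1)/P1   if F1_r ≤ P1
            = 0                otherwise,

  averaged over the R replicates of the cross.  ODH isolates over- and
  underdominant modes of inheritance: it is positive only when replicates
  exceed the high parent and negative only when they fall below the low
  parent.

All three are invariant to rescaling the trait by a positive constant and
require strictly positive parental means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diallel_core import CrossKey, DiallelDesign, cross_key, format_cross

REQUIRED_PHENO_COLUMNS = ("entry", "year", "replicate")


@dataclass(frozen=True)
class ParentBounds:
    """Low (P1) and high (P2) parental means for one cross/trait/year."""

    cross: CrossKey
    trait: str
    P1: float
    P2: float


def validate_phenotypes(pheno: pd.DataFrame, traits: Sequence[str]) -> None:
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    absent = [t for t in traits if t not in pheno.columns]
    if absent:
        raise ValueError(f"trait columns absent: {absent}")
    dup = pheno.duplicated(subset=["entry", "year", "replicate"])
    if dup.any():
        raise ValueError(
            f"duplicate (entry, year, replicate) rows at index {list(pheno.index[dup])[:5]}"
        )


def parent_means(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Mean trait value per (entry, year) — used for parental lines."""
    return (
        pheno.groupby(["entry", "year"], sort=False)[trait]
        .mean()
        .rename("mean")
        .reset_index()
    )


def parent_bounds(
    pheno: pd.DataFrame, cross: CrossKey, trait: str, year
) -> ParentBounds:
    """P1/P2: low/high of the two parental means in the given year."""
    means = []
    for parent in cross:
        sub = pheno.loc[(pheno["entry"] == parent) & (pheno["year"] == year), trait]
        sub = sub.dropna()
        if sub.empty:
            raise ValueError(
                f"parent {parent} has no {trait} replicates in year {year}"
            )
        means.append(float(sub.mean()))
    lo, hi = sorted(means)
    return ParentBounds(cross=cross, trait=trait, P1=lo, P2=hi)


def odh_replicate(F1, P1: float, P2: float):
    """Piecewise single-replicate ODH; accepts scalar or array F1."""
    if not (P1 > 0 and P2 > 0):
        raise ValueError(f"non-positive parental mean (P1={P1}, P2={P2})")
    if P1 > P2:
        raise ValueError("P1 must not exceed P2")
    f = np.asarray(F1, dtype=float)
    out = np.where(f >= P2, (f - P2) / P2, np.where(f <= P1, (f - P1) / P1, 0.0))
    return float(out) if np.isscalar(F1) else out


def odh_cross(replicates: Iterable[float], P1: float, P2: float) -> tuple[float, int]:
    """Mean ODH over the hybrid replicates; returns (mean ODH, R)."""
    reps = np.asarray(list(replicates), dtype=float)
    if reps.size == 0:
        raise ValueError("no hybrid replicates")
    return float(np.mean(odh_replicate(reps, P1, P2))), int(reps.size)


def mph_bph(f1_mean: float, P1: float, P2: float) -> tuple[float, float]:
    """Mid-parent and best-parent heterosis from the hybrid mean."""
    mp = (P1 + P2) / 2.0
    if mp <= 0 or P2 <= 0:
        raise ValueError("non-positive parental baseline")
    return (f1_mean - mp) / mp, (f1_mean - P2) / P2


def derive_seed_number(dpw, sdw):
    """Seed number from dry panicle weight and 50-grain seed dry weight:
    SN = (DPW/SDW) x 50."""
    dpw = np.asarray(dpw, dtype=float)
    sdw = np.asarray(sdw, dtype=float)
    if np.any(sdw <= 0):
        raise ValueError("SDW must be positive")
    out = dpw / sdw * 50.0
    return float(out) if out.ndim == 0 else out


def reciprocal_test(
    reps_ab: Sequence[float], reps_ba: Sequence[float], alpha: float = 0.01
) -> tuple[Optional[float], str]:
    """Welch two-sample t-test between reciprocal replicate sets.

    Returns (p, verdict) with verdict in {"different", "not different",
    "untestable"}; each direction needs >= 3 replicates to be testable.
    """
    a = np.asarray(reps_ab, dtype=float)
    b = np.asarray(reps_ba, dtype=float)
    if a.size < 3 or b.size < 3:
        return None, "untestable"
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0, "not different"
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if np.isnan(p):
        return 1.0, "not different"
    return p, ("different" if p <= alpha else "not different")


def reciprocal_screen(
    pheno: pd.DataFrame,
    design: DiallelDesign,
    trait: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Reciprocal-difference check for every pair grown in both directions.

    One row per (pair, year) with the Welch p-value and verdict; pairs
    flagged "different" carry a maternal/imprinting effect and are excluded
    from mapping by default.
    """
    rows = []
    directed = design.crosses.drop_duplicates(["female", "male"])
    by_key = directed.groupby("key")
    for key_label, grp in by_key:
        if grp.shape[0] < 2:
            continue
        cids = grp["cross_id"].tolist()
        for year in sorted(pheno["year"].unique()):
            sets = [
                pheno.loc[
                    (pheno["entry"] == cid) & (pheno["year"] == year), trait
                ].dropna().to_numpy()
                for cid in cids
            ]
            if all(s.size == 0 for s in sets):
                continue
            p, verdict = reciprocal_test(sets[0], sets[1], alpha=alpha)
            rows.append(
                {
                    "cross": key_label,
                    "year": year,
                    "trait": trait,
                    "n_fwd": sets[0].size,
                    "n_rev": sets[1].size,
                    "p": p,
                    "verdict": verdict,
                }
            )
    return pd.DataFrame(
        rows, columns=["cross", "year", "trait", "n_fwd", "n_rev", "p", "verdict"]
    )


def compute_odh_table(
    pheno: pd.DataFrame,
    design: DiallelDesign,
    traits: Sequence[str],
    pool_reciprocals: bool = True,
) -> pd.DataFrame:
    """Per-(cross, trait, year) mean ODH, replicate count R, MPH and BPH.

    Hybrid replicates are identified by the design's cross ids; reciprocal
    crosses of the same unordered pair are pooled by default.  Crosses
    lacking a parental mean, or with a non-positive parental mean, are
    flagged and dropped (column ``flag`` in the returned frame holds the
    reason for flagged rows, which carry NaN statistics).
    """
    validate_phenotypes(pheno, traits)
    cid_to_key = dict(zip(design.crosses["cross_id"], design.crosses["key"]))
    hyb = pheno[pheno["entry"].isin(cid_to_key)].copy()
    hyb["key"] = hyb["entry"].map(cid_to_key)
    group_col = "key" if pool_reciprocals else "entry"
    rows = []
    for trait in traits:
        pm = parent_means(pheno, trait).set_index(["entry", "year"])["mean"]
        for (key_label, year), grp in hyb.groupby([group_col, "year"], sort=True):
            key = (
                cross_key(*key_label.split("/"))
                if group_col == "key"
                else design.parents_of(key_label)
            )
            reps = grp[trait].dropna().to_numpy(dtype=float)
            base = {
                "cross": format_cross(key),
                "female": key[0],
                "male": key[1],
                "trait": trait,
                "year": year,
                "R": int(reps.size),
            }
            if reps.size == 0:
                continue
            try:
                p_lo = pm[(key[0], year)]
                p_hi = pm[(key[1], year)]
            except KeyError as e:
                rows.append(
                    {**base, "ODH": np.nan, "MPH": np.nan, "BPH": np.nan,
                     "flag": f"parent {e.args[0][0]} unphenotyped"}
                )
                continue
            P1, P2 = sorted((float(p_lo), float(p_hi)))
            if P1 <= 0:
                rows.append(
                    {**base, "ODH": np.nan, "MPH": np.nan, "BPH": np.nan,
                     "flag": "non-positive parental mean"}
                )
                continue
            odh, _ = odh_cross(reps, P1, P2)
            mph, bph = mph_bph(float(reps.mean()), P1, P2)
            rows.append({**base, "ODH": odh, "MPH": mph, "BPH": bph, "flag": ""})
    cols = ["cross", "female", "male", "trait", "year", "R", "ODH", "MPH", "BPH", "flag"]
    return pd.DataFrame(rows, columns=cols)
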