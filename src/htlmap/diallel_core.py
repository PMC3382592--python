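"""Domain model of the diallel: founders, markers, crosses, genotype projection.

A diallel mating design crosses a panel of homozygous founder lines in
(nearly) all pairwise combinations.  Because every founder is homozygous,
its single allele at each marker can be projected onto all hybrids derived
from it, so the hybrids' genotypes are known without genotyping them.  At
each locus the hybrids then fall into *hetero-genotypic groups* (one per
unordered allele pair) and a pooled *homo-genotypic* reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = None

#: canonical unordered cross key
CrossKey = tuple[str, str]


def cross_key(a: str, b: str) -> CrossKey:
    """Order-free key for the cross between founders ``a`` and ``b``."""
    return (a, b) if a <= b else (b, a)


def format_cross(key: CrossKey) -> str:
    return f"{key[0]}/{key[1]}"


def parse_cross(label: str) -> CrossKey:
    a, b = label.split("/")
    return cross_key(a, b)


@dataclass(frozen=True)
class FounderLine:
    """A homozygous inbred parent of the diallel."""

    id: str
    cluster: Optional[str] = None


@dataclass(frozen=True)
class MarkerDef:
    """A genetic marker (SSR locus) with optional map location."""

    name: str
    chromosome: Optional[str] = None
    position: Optional[float] = None

    def __post_init__(self):
        if self.position is not None and self.position < 0:
            raise ValueError(f"marker {self.name}: negative position")


@dataclass(frozen=True)
class CrossID:
    """A directed cross (female x male) between two distinct founders."""

    female: str
    male: str

    def __post_init__(self):
        if self.female == self.male:
            raise ValueError(f"self cross not allowed in diallel: {self.female}")

    @property
    def key(self) -> CrossKey:
        return cross_key(self.female, self.male)


class FounderGenotypeMatrix:
    """Founder x marker table of single allele calls (integer fragment sizes).

    Founders are homozygous so exactly one allele is recorded per
    (founder, marker); missing calls are NaN.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        markers: Optional[Sequence[MarkerDef]] = None,
        clusters: Optional[Mapping[str, str]] = None,
    ):
        if calls.index.has_duplicates:
            dups = calls.index[calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate founder ids: {dups}")
        if calls.columns.has_duplicates:
            raise ValueError("duplicate marker names")
        self.calls = calls.astype(float)
        if markers is None:
            markers = [MarkerDef(str(m)) for m in calls.columns]
        by_name = {m.name: m for m in markers}
        unknown = [c for c in calls.columns if c not in by_name]
        if unknown:
            raise ValueError(f"markers absent from marker definitions: {unknown}")
        self.markers = [by_name[c] for c in calls.columns]
        self.clusters = dict(clusters) if clusters else {}

    @property
    def founder_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def founders(self) -> list[FounderLine]:
        return [FounderLine(f, self.clusters.get(f)) for f in self.founder_ids]

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def call(self, founder: str, marker: str) -> Optional[int]:
        v = self.calls.at[founder, marker]
        return None if pd.isna(v) else int(v)


@dataclass
class DiallelDesign:
    """The realized crossing design: directed crosses with ids, per year."""

    crosses: pd.DataFrame  # columns: cross_id, female, male [, year]

    def __post_init__(self):
        req = {"cross_id", "female", "male"}
        missing = req - set(self.crosses.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if (self.crosses["female"] == self.crosses["male"]).any():
            bad = self.crosses.loc[
                self.crosses["female"] == self.crosses["male"], "cross_id"
            ].tolist()
            raise ValueError(f"self crosses not allowed: {bad}")
        keys = [
            cross_key(f, m)
            for f, m in zip(self.crosses["female"], self.crosses["male"])
        ]
        self.crosses = self.crosses.assign(key=[format_cross(k) for k in keys])
        # at most two directed crosses (the two reciprocals) per unordered pair
        per_pair = self.crosses.groupby("key")[["female", "male"]].apply(
            lambda g: g.drop_duplicates().shape[0]
        )
        if (per_pair > 2).any():
            bad = per_pair[per_pair > 2].index.tolist()
            raise ValueError(f"more than two directed crosses for pairs: {bad}")

    @staticmethod
    def n_possible(n_founders: int) -> int:
        """Number of unordered crosses in a complete half diallel: n(n-1)/2."""
        return n_founders * (n_founders - 1) // 2

    @classmethod
    def half_diallel(cls, founder_ids: Sequence[str]) -> "DiallelDesign":
        """Complete half diallel (all unordered pairs, no reciprocals)."""
        rows = []
        ids = list(founder_ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append(
                    {
                        "cross_id": f"{ids[i]}x{ids[j]}",
                        "female": ids[i],
                        "male": ids[j],
                    }
                )
        return cls(pd.DataFrame(rows))

    @property
    def pair_keys(self) -> list[CrossKey]:
        """Unique unordered cross keys, in first-appearance order."""
        seen: dict[CrossKey, None] = {}
        for f, m in zip(self.crosses["female"], self.crosses["male"]):
            seen.setdefault(cross_key(f, m), None)
        return list(seen)

    def parents_of(self, cid: str) -> CrossKey:
        row = self.crosses.loc[self.crosses["cross_id"] == cid]
        if row.empty:
            raise KeyError(f"unknown cross id {cid}")
        return cross_key(row.iloc[0]["female"], row.iloc[0]["male"])

    def reciprocal_pairs(self) -> list[CrossKey]:
        """Unordered pairs realized in both directions."""
        g = self.crosses.drop_duplicates(["female", "male"]).groupby("key").size()
        return [parse_cross(k) for k in g[g > 1].index]


@dataclass
class GenotypeGroups:
    """Per-marker partition of crosses into genotypic groups.

    ``hetero`` maps each unordered allele pair to its crosses; ``homo`` pools
    all homozygous crosses (regardless of which allele they carry); crosses
    that cannot be grouped (missing parental call, group below the minimum
    size) are listed in ``excluded`` with a reason.
    """

    marker: MarkerDef
    hetero: dict[tuple[int, int], list[CrossKey]] = field(default_factory=dict)
    homo: list[CrossKey] = field(default_factory=list)
    homo_by_allele: dict[int, list[CrossKey]] = field(default_factory=dict)
    excluded: list[tuple[CrossKey, str]] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        """Number of eligible groups (hetero groups + pooled homo if kept)."""
        return len(self.hetero) + (1 if self.homo else 0)

    def group_of(self, key: CrossKey):
        for pair, keys in self.hetero.items():
            if key in keys:
                return pair
        if key in self.homo:
            return "homo"
        return None


def project_hybrid_genotypes(
    geno: FounderGenotypeMatrix, design: DiallelDesign
) -> dict[str, dict[CrossKey, Optional[tuple[int, int]]]]:
    """Project founder alleles onto hybrids.

    Returns ``{marker: {cross key: (a_low, a_high) or None}}`` — the unordered
    pair of parental alleles at each marker, or None when either parental
    call is missing.  Unknown parents raise ``KeyError`` naming the cross.
    """
    founders = set(geno.founder_ids)
    pairs = design.pair_keys
    for a, b in pairs:
        for p in (a, b):
            if p not in founders:
                raise KeyError(
                    f"parent {p!r} of cross {format_cross((a, b))} not genotyped"
                )
    calls = geno.calls
    out: dict[str, dict[CrossKey, Optional[tuple[int, int]]]] = {}
    for marker in geno.marker_names:
        col = calls[marker]
        proj: dict[CrossKey, Optional[tuple[int, int]]] = {}
        for a, b in pairs:
            ca, cb = col[a], col[b]
            if pd.isna(ca) or pd.isna(cb):
                proj[(a, b)] = None
            else:
                ia, ib = int(ca), int(cb)
                proj[(a, b)] = (ia, ib) if ia <= ib else (ib, ia)
        out[marker] = proj
    return out


def partition_by_locus(
    proj: Mapping[str, Mapping[CrossKey, Optional[tuple[int, int]]]],
    marker: MarkerDef | str,
    min_group: int = 3,
    split_homo: bool = False,
    crosses: Optional[Iterable[CrossKey]] = None,
) -> GenotypeGroups:
    """Partition crosses at one marker into hetero / pooled-homo / excluded.

    ``min_group`` is the minimal number of crosses per genotypic group;
    smaller groups are excluded (generalizing the rare-allele rule that an
    allele carried by fewer than three founders cannot support a testable
    group).  With ``split_homo`` the homozygous crosses are kept per allele
    instead of pooled.
    """
    if min_group < 2:
        raise ValueError("min_group must be >= 2")
    mdef = marker if isinstance(marker, MarkerDef) else MarkerDef(marker)
    if mdef.name not in proj:
        raise KeyError(f"marker {mdef.name} absent from projection")
    locus = proj[mdef.name]
    keys = list(crosses) if crosses is not None else list(locus)
    groups = GenotypeGroups(marker=mdef)
    hetero: dict[tuple[int, int], list[CrossKey]] = {}
    homo_by_allele: dict[int, list[CrossKey]] = {}
    for k in keys:
        pair = locus.get(k)
        if pair is None:
            groups.excluded.append((k, "missing parental call"))
        elif pair[0] == pair[1]:
            homo_by_allele.setdefault(pair[0], []).append(k)
        else:
            hetero.setdefault(pair, []).append(k)
    for pair in sorted(hetero):
        members = hetero[pair]
        if len(members) < min_group:
            groups.excluded.extend(
                (k, "below minimum group size") for k in members
            )
        else:
            groups.hetero[pair] = members
    groups.homo_by_allele = {a: homo_by_allele[a] for a in sorted(homo_by_allele)}
    if split_homo:
        kept: list[CrossKey] = []
        for a in sorted(homo_by_allele):
            members = homo_by_allele[a]
            if len(members) < min_group:
                groups.excluded.extend(
                    (k, "below minimum group size") for k in members
                )
            else:
                kept.extend(members)
        groups.homo = kept
    else:
        pooled = [k for a in sorted(homo_by_allele) for k in homo_by_allele[a]]
        if pooled and len(pooled) < min_group:
            groups.excluded.extend((k, "below minimum group size") for k in pooled)
        else:
            groups.homo = pooled
    return groups


def allele_summary(geno: FounderGenotypeMatrix, rare_below: int = 3) -> pd.DataFrame:
    """Per-marker allele carrier counts with rare flag.

    An allele is *rare* when carried by fewer than ``rare_below`` founders
    (default 3); rare alleles cannot form testable genotypic groups.
    """
    rows = []
    for marker in geno.marker_names:
        col = geno.calls[marker].dropna()
        counts = col.astype(int).value_counts().sort_index()
        for allele, n in counts.items():
            rows.append(
                {
                    "marker": marker,
                    "allele": int(allele),
                    "n_founders": int(n),
                    "rare": bool(n < rare_below),
                }
            )
    return pd.DataFrame(rows, columns=["marker", "allele", "n_founders", "rare"])
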