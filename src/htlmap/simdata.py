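"""Synthetic diallel generator emulating the mapping study's structure.

The generator reproduces the population facts of the field experiment it
stands in for: ~19 homozygous founder lines genotyped at ~85 multi-allelic
SSR loci (5-8 alleles each, with at least two alleles shared by >= 3
founders so testable genotypic groups exist), four founder clusters with
cluster-correlated allele frequencies, a near-complete half diallel with a
few reciprocals and missing crosses, two years with 7/4 hybrid and 14/10
parent replicates, and strictly positive trait values.  Overdominance is
planted at chosen loci as a multiplicative trait shift for hybrids carrying
the planted allele pair, which translates into a mean-ODH shift of about
``d`` for that hetero-genotypic group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diallel_core import (
    CrossKey,
    DiallelDesign,
    FounderGenotypeMatrix,
    MarkerDef,
    cross_key,
)


@dataclass(frozen=True)
class PlantedHTL:
    """Ground truth for one planted overdominant locus."""

    marker: str
    pair: tuple[int, int]
    d: float


@dataclass
class TruthTable:
    """What was planted — the reference for recovery tests."""

    planted: list = field(default_factory=list)
    variance_fractions: Optional[dict] = None


@dataclass
class SimConfig:
    """Study conditions of the emulated diallel experiment."""

    n_founders: int = 19
    n_markers: int = 85
    alleles_per_locus: tuple[int, int] = (5, 8)
    n_clusters: int = 4
    planted_htls: Optional[Sequence[PlantedHTL]] = None
    n_planted: int = 3
    planted_d: float = 0.85
    baseline: float = 100.0          # trait baseline (g DPW scale)
    gca_sd: float = 2.0              # founder general-combining-ability SD
    cluster_effect_sd: float = 2.0   # cluster-pair effect SD
    year_effect_sd: float = 3.0
    residual_sd: float = 8.0
    hybrid_advantage: float = 0.25   # pervasive hybrid vigor (relative)
    sca_sd: float = 0.12             # cross-specific heterosis SD (genetic)
    allele_skew: float = 1.5         # Dirichlet concentration of locus allele freqs
    cluster_freq_concentration: float = 100.0  # cluster vs base allele-freq similarity
    reps_hybrid: tuple[int, ...] = (7, 4)    # per year
    reps_parent: tuple[int, ...] = (14, 10)  # per year
    missing_cross_rate: float = 0.08
    reciprocal_rate: float = 0.1
    years: tuple = (2010, 2011)
    trait: str = "DPW"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_cross_rate <= 1:
            raise ValueError("missing_cross_rate must be in [0, 1]")
        if self.alleles_per_locus[0] < 2:
            raise ValueError("need >= 2 alleles per locus")


def _founder_ids(n: int) -> list[str]:
    return [f"SB{i:03d}" for i in range(1, n + 1)]


def simulate_founders(cfg: SimConfig) -> tuple[FounderGenotypeMatrix, dict]:
    """Founder genotypes plus cluster assignment.

    Per locus the allele frequencies are drawn per cluster from a shared
    Dirichlet base (so clusters are genetically correlated but distinct);
    draws are retried, then deterministically repaired, until at least two
    alleles have >= 3 carrier founders.  Deterministic given the seed.
    """
    if cfg.n_founders < 4:
        raise ValueError("need >= 4 founders")
    if cfg.n_founders < 6:
        raise ValueError(
            "cannot guarantee two alleles with >= 3 carriers with < 6 founders"
        )
    rng = np.random.default_rng(cfg.seed)
    ids = _founder_ids(cfg.n_founders)
    cluster_names = [chr(ord("A") + i) for i in range(cfg.n_clusters)]
    assign = {f: cluster_names[i % cfg.n_clusters] for i, f in enumerate(ids)}
    lo, hi = cfg.alleles_per_locus
    calls = np.zeros((cfg.n_founders, cfg.n_markers), dtype=float)
    markers = []
    for j in range(cfg.n_markers):
        n_alleles = int(rng.integers(lo, hi + 1))
        alleles = 150 + 2 * np.arange(n_alleles)
        # skewed frequencies: SSR loci carry a few common and several rare
        # alleles, so only a handful of hetero groups are testable per locus
        base = rng.dirichlet(np.full(n_alleles, cfg.allele_skew))
        freq_by_cluster = {
            c: rng.dirichlet(base * cfg.cluster_freq_concentration + 0.1)
            for c in cluster_names
        }
        ok = False
        for _ in range(100):
            draw = np.array(
                [rng.choice(n_alleles, p=freq_by_cluster[assign[f]]) for f in ids]
            )
            counts = np.bincount(draw, minlength=n_alleles)
            if np.sum(counts >= 3) >= 2:
                ok = True
                break
        if not ok:
            # deterministic repair: force the two most common alleles to 3 carriers
            order = np.argsort(-counts)
            for a in order[:2]:
                need = 3 - counts[a]
                if need > 0:
                    donors = np.where(np.isin(draw, order[2:]))[0][:need]
                    if donors.size < need:
                        donors = np.where(draw != a)[0][:need]
                    draw[donors] = a
                    counts = np.bincount(draw, minlength=n_alleles)
        calls[:, j] = alleles[draw]
        markers.append(
            MarkerDef(
                name=f"M{j + 1:03d}",
                chromosome=str(j % 10 + 1),
                position=float((j // 10 + 1) * 1_000_000),
            )
        )
    frame = pd.DataFrame(calls, index=ids, columns=[m.name for m in markers])
    geno = FounderGenotypeMatrix(frame, markers=markers, clusters=assign)
    return geno, assign


def choose_planted_htls(
    geno: FounderGenotypeMatrix,
    n: int = 3,
    d: float = 0.85,
    min_crosses: int = 10,
    max_crosses: int = 16,
    confound_trigger: float = 0.3,
    safety_cap: float = 0.03,
    search_pool: int = 60,
    seed: int = 0,
) -> list[PlantedHTL]:
    """Pick loci/allele pairs whose planted effects are identifiable.

    A pair of alleles carried by c1 and c2 founders yields c1*c2 hetero
    crosses in a complete half diallel.  Candidates need both carrier
    counts >= 3 (non-rare alleles) and min_crosses <= c1*c2 <= max_crosses:
    a bounded group keeps the planted loci from saturating the diallel,
    mirroring a locus defined by two alleles each shared by a handful of
    founders.

    Because the markers are unlinked but share the same 19 founders, a
    hetero group at another marker can echo a planted signal whenever its
    members are drawn largely from planted carrier crosses — the shared-
    segregation confounding that also besets real diallel scans.  The
    picker therefore searches triples of candidates (disjoint carrier
    sets, distinct markers and chromosomes) and scores each triple by

    * safety — the worst-case approximate one-sided KS p of any look-alike
      group (fraction f > ``confound_trigger`` of its members inside the
      combined carrier union; reference size 30), capped at ``safety_cap``
      so that, once look-alikes are comfortably sub-detectable, the score
      is decided by
    * sharpness — fewer genotypic groups at the planted markers (a smaller
      numerator df concentrates the single-locus F test).

    Deterministic given the seed.
    """
    import itertools

    from .diallel_core import partition_by_locus, project_hybrid_genotypes

    rng = np.random.default_rng(seed)
    design = DiallelDesign.half_diallel(geno.founder_ids)
    proj = project_hybrid_genotypes(geno, design)
    all_groups = []  # (marker, members frozenset) for every hetero group
    candidates = []
    eligible = []  # non-rare pairs regardless of group size
    for m in geno.markers:
        col = geno.calls[m.name].dropna().astype(int)
        counts = col.value_counts()
        groups = partition_by_locus(proj, m, crosses=design.pair_keys)
        for (a, b), members in groups.hetero.items():
            fs = frozenset(members)
            all_groups.append((m.name, fs))
            if counts.get(a, 0) >= 3 and counts.get(b, 0) >= 3:
                cand = (m.name, m.chromosome, (int(a), int(b)), fs, groups.n_groups)
                eligible.append(cand)
                if min_crosses <= len(fs) <= max_crosses:
                    candidates.append(cand)
    if len(candidates) < n:
        # small panels may lack groups in the preferred size band
        candidates = [c for c in eligible if len(c[3]) >= 3]
    if len(candidates) < n:
        raise ValueError("not enough mappable allele pairs to plant")
    rng.shuffle(candidates)

    n_groups_total = len(all_groups)
    sizes = np.array([len(fs) for _, fs in all_groups], dtype=float)
    group_marker = np.array([m for m, _ in all_groups])
    en = sizes * 30.0 / (sizes + 30.0)
    overlap = np.zeros((len(candidates), n_groups_total))
    for i, (name, _, _, fs, _) in enumerate(candidates):
        for j, (om, ofs) in enumerate(all_groups):
            if om != name:
                overlap[i, j] = len(fs & ofs)

    def safety_of(v: np.ndarray, own_markers) -> float:
        mask = ~np.isin(group_marker, own_markers)
        f = np.where(mask, v / sizes, 0.0)
        danger = np.where(
            f > confound_trigger, np.exp(-2.0 * en * f * f), 1.0
        )
        return float(danger.min())

    own_safety = np.array(
        [safety_of(overlap[i], [candidates[i][0]]) for i in range(len(candidates))]
    )
    pre = np.argsort(
        [
            -(min(own_safety[i], safety_cap) * 100.0) + candidates[i][4] * 0.01
            for i in range(len(candidates))
        ]
    )[:search_pool]

    if n != 3:
        # n other than the study's three: greedy by the same score components
        order = sorted(
            range(len(candidates)),
            key=lambda i: (-min(own_safety[i], safety_cap), candidates[i][4]),
        )
        picked: list = []
        union: frozenset = frozenset()
        for i in order:
            if len(picked) == n:
                break
            cand = candidates[i]
            if cand[0] in {p[0] for p in picked} or (cand[3] & union):
                continue
            picked.append(cand)
            union = union | cand[3]
        if len(picked) < n:
            raise ValueError("not enough identifiable allele pairs to plant")
        return [PlantedHTL(marker=c[0], pair=c[2], d=d) for c in picked]

    best = None
    for i, j, k in itertools.combinations(pre, 3):
        ci, cj, ck = candidates[i], candidates[j], candidates[k]
        if len({ci[0], cj[0], ck[0]}) < 3 or len({ci[1], cj[1], ck[1]}) < 3:
            continue
        if (ci[3] & cj[3]) or (ci[3] & ck[3]) or (cj[3] & ck[3]):
            continue
        worst = safety_of(
            overlap[i] + overlap[j] + overlap[k], [ci[0], cj[0], ck[0]]
        )
        score = (min(worst, safety_cap), -(ci[4] + cj[4] + ck[4]))
        if best is None or score > best[0]:
            best = (score, (ci, cj, ck))
    if best is None:
        raise ValueError("not enough identifiable allele pairs to plant")
    return [PlantedHTL(marker=c[0], pair=c[2], d=d) for c in best[1]]


def _positive_normal(rng, loc, scale, size=None):
    """Normal draw resampled (then clipped) to stay strictly positive."""
    v = rng.normal(loc, scale, size)
    for _ in range(10):
        bad = v <= 0
        if not np.any(bad):
            break
        v = np.where(bad, rng.normal(loc, scale, np.shape(v)), v)
    return np.maximum(v, 1e-6)


def simulate_diallel_phenotypes(
    geno: FounderGenotypeMatrix,
    assign: dict,
    cfg: SimConfig,
    planted: Optional[Sequence[PlantedHTL]] = None,
) -> tuple[pd.DataFrame, DiallelDesign, TruthTable]:
    """Replicated founder and hybrid phenotypes for a near-complete diallel.

    Founder replicate value: baseline + 2*GCA_f + year + noise.
    Hybrid replicate value: (baseline + GCA_x + GCA_y + cluster-pair effect
    + year + noise) * (1 + hybrid advantage + SCA_xy) * prod(1 + d) over
    planted loci whose allele pair the hybrid carries.  The general hybrid
    advantage and the cross-specific (SCA) term emulate the pervasive,
    broadly distributed positive ODH seen for reproductive traits; SCA is
    genetic and therefore constant across years.  A fraction of
    (pair, year) combinations is dropped to emulate missing crosses; a
    fraction of pairs is grown reciprocally.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ids = geno.founder_ids
    if planted is None:
        planted = list(cfg.planted_htls) if cfg.planted_htls is not None else (
            choose_planted_htls(
                geno, n=cfg.n_planted, d=cfg.planted_d, seed=cfg.seed
            )
            if cfg.n_planted > 0
            else []
        )
    marker_set = set(geno.marker_names)
    for p in planted:
        if p.marker not in marker_set:
            raise ValueError(f"planted marker {p.marker} not in genotype matrix")

    gca = {f: rng.normal(0.0, cfg.gca_sd) for f in ids}
    year_eff = {y: rng.normal(0.0, cfg.year_effect_sd) for y in cfg.years}
    cluster_names = sorted(set(assign.values()))
    cluster_pair_eff = {}
    for i, a in enumerate(cluster_names):
        for b in cluster_names[i:]:
            cluster_pair_eff[(a, b)] = rng.normal(0.0, cfg.cluster_effect_sd)

    base_design = DiallelDesign.half_diallel(ids)
    pairs = base_design.pair_keys
    recip = {
        k: bool(rng.random() < cfg.reciprocal_rate) for k in pairs
    }
    rows = []
    for k in pairs:
        f, m = k
        rows.append({"cross_id": f"{f}x{m}", "female": f, "male": m})
        if recip[k]:
            rows.append({"cross_id": f"{m}x{f}", "female": m, "male": f})
    design = DiallelDesign(pd.DataFrame(rows))

    # cross-specific heterosis factor, shared across years (genetic)
    vigor = {
        k: max(1.0 + cfg.hybrid_advantage + rng.normal(0.0, cfg.sca_sd), 0.05)
        for k in pairs
    }

    # planted-pair carrier lookup per cross
    carrier_mult = {k: 1.0 for k in pairs}
    for p in planted:
        col = geno.calls[p.marker]
        want = tuple(sorted(p.pair))
        for k in pairs:
            ca, cb = col[k[0]], col[k[1]]
            if pd.isna(ca) or pd.isna(cb):
                continue
            got = tuple(sorted((int(ca), int(cb))))
            if got == want:
                carrier_mult[k] *= 1.0 + p.d

    pheno_rows = []
    for yi, year in enumerate(cfg.years):
        n_rep_h = cfg.reps_hybrid[yi % len(cfg.reps_hybrid)]
        n_rep_p = cfg.reps_parent[yi % len(cfg.reps_parent)]
        for f in ids:
            loc = cfg.baseline + 2.0 * gca[f] + year_eff[year]
            vals = _positive_normal(rng, loc, cfg.residual_sd, n_rep_p)
            for r, v in enumerate(vals, 1):
                pheno_rows.append(
                    {"entry": f, "year": year, "replicate": r, cfg.trait: v}
                )
        for k in pairs:
            if rng.random() < cfg.missing_cross_rate:
                continue
            f, m = k
            cp = tuple(sorted((assign[f], assign[m])))
            loc = (
                cfg.baseline + gca[f] + gca[m]
                + cluster_pair_eff[cp] + year_eff[year]
            )
            directed = [f"{f}x{m}"] + ([f"{m}x{f}"] if recip[k] else [])
            for cid in directed:
                vals = _positive_normal(rng, loc, cfg.residual_sd, n_rep_h)
                vals = vals * vigor[k] * carrier_mult[k]
                for r, v in enumerate(vals, 1):
                    pheno_rows.append(
                        {"entry": cid, "year": year, "replicate": r, cfg.trait: v}
                    )
    pheno = pd.DataFrame(pheno_rows, columns=["entry", "year", "replicate", cfg.trait])
    return pheno, design, TruthTable(planted=list(planted))


@dataclass
class SimStudy:
    geno: FounderGenotypeMatrix
    assign: dict
    pheno: pd.DataFrame
    design: DiallelDesign
    truth: TruthTable


def simulate_study(cfg: SimConfig) -> SimStudy:
    """One-call generator for the whole synthetic mapping study."""
    geno, assign = simulate_founders(cfg)
    pheno, design, truth = simulate_diallel_phenotypes(geno, assign, cfg)
    return SimStudy(geno=geno, assign=assign, pheno=pheno, design=design, truth=truth)


def simulate_f2(
    alleles: tuple[int, int] = (154, 162),
    shift: float = 0.21,
    n_plants: int = 100,
    baseline: float = 100.0,
    residual_sd: float = 15.0,
    trait: str = "DPW",
    seed: int = 0,
) -> pd.DataFrame:
    """F2 records at a single focal marker: 1:2:1 genotypes, het trait shift.

    The heterozygote carries a multiplicative ``shift`` on the trait
    baseline (0.21 emulates a 21% overdominant effect).  Parents must
    differ at the marker.
    """
    a, b = alleles
    if a == b:
        raise ValueError("parents are monomorphic at the focal marker")
    a, b = sorted((a, b))
    rng = np.random.default_rng(seed)
    g = rng.choice(3, size=n_plants, p=[0.25, 0.5, 0.25])
    labels = {0: f"{a}/{a}", 1: f"{a}/{b}", 2: f"{b}/{b}"}
    mult = np.where(g == 1, 1.0 + shift, 1.0)
    vals = _positive_normal(rng, baseline, residual_sd, n_plants) * mult
    return pd.DataFrame(
        {
            "plant": [f"F2-{i + 1:03d}" for i in range(n_plants)],
            "genotype": [labels[int(x)] for x in g],
            trait: vals,
        }
    )


def simulate_epistasis_dataset(
    fractions: Sequence[float] = (0.12, 0.07, 0.04),
    interaction_fraction: float = 0.0,
    n_crosses: int = 140,
    years: tuple = (2010, 2011),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict, TruthTable]:
    """Cross-level ODH data with planted P/N variance fractions.

    Three binary P/N factors (P frequency 0.5) receive main effects sized so
    each contributes the requested fraction of the total variance; an
    optional A x B interaction fraction can be planted.  Returns the ODH
    table (one row per cross-year), the factor series keyed "A"/"B"/"C",
    and the truth.
    """
    fracs = list(fractions)
    if len(fracs) != 3:
        raise ValueError("exactly three main-effect fractions required")
    tot = sum(fracs) + interaction_fraction
    if tot >= 1:
        raise ValueError("variance fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    keys = [cross_key(f"SB{i:03d}", f"SB{i + 500:03d}") for i in range(n_crosses)]
    states = {name: rng.random(n_crosses) < 0.5 for name in "ABC"}
    effects = [np.sqrt(f / 0.25) for f in fracs]
    inter_eff = np.sqrt(interaction_fraction / 0.25) if interaction_fraction else 0.0
    resid_sd = np.sqrt(1.0 - tot)
    rows, factors = [], {}
    for name in "ABC":
        factors[name] = pd.Series(
            ["P" if s else "N" for s in states[name]], index=keys, name=name
        )
    for year in years:
        mu = (
            effects[0] * (states["A"] - 0.5)
            + effects[1] * (states["B"] - 0.5)
            + effects[2] * (states["C"] - 0.5)
        )
        if inter_eff:
            ab = (states["A"] ^ states["B"]).astype(float) - 0.5
            mu = mu + inter_eff * ab
        y = mu + rng.normal(0.0, resid_sd, n_crosses)
        for k, v in zip(keys, y):
            rows.append(
                {
                    "cross": f"{k[0]}/{k[1]}", "female": k[0], "male": k[1],
                    "trait": "DPW", "year": year, "R": 1, "ODH": float(v),
                    "MPH": np.nan, "BPH": np.nan, "flag": "",
                }
            )
    odh = pd.DataFrame(rows)
    truth = TruthTable(
        planted=[],
        variance_fractions={
            "A": fracs[0], "B": fracs[1], "C": fracs[2],
            "A:B": interaction_fraction,
        },
    )
    return odh, factors, truth
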