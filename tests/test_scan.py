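import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from htlmap import (
    GenotypeGroups,
    MarkerDef,
    ScanConfig,
    adjust_for_structure,
    glm_marker_test,
    glm_with_cofactor,
    hybrid_cofactor,
    ks_critical_D,
    ks_hetero_vs_homo,
    permutation_threshold,
    scan,
)
from htlmap.scan import _threshold_from_min_p, call_htls, HTLCall, KSResult, MarkerScanResult


def make_groups(hetero, homo=(), marker="m"):
    """GenotypeGroups from {pair: [cross keys]} and a homo list."""
    g = GenotypeGroups(marker=MarkerDef(marker))
    g.hetero = {p: list(v) for p, v in hetero.items()}
    g.homo = list(homo)
    return g


def series(values):
    """ODH series indexed by synthetic cross keys k0, k1, ..."""
    keys = [(f"a{i}", f"b{i}") for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=keys), keys


class TestGlmMarkerTest:
    def test_two_group_closed_form(self):
        # one-way ANOVA of [.1,.2,.3] vs [.4,.5,.6]: F = 13.5, p ~ 0.0213
        odh, keys = series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        g = make_groups({(1, 2): keys[:3]}, homo=keys[3:])
        F, p = glm_marker_test(odh, g)
        assert F == pytest.approx(13.5)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-6)
        assert p == pytest.approx(0.0213, abs=2e-3)

    def test_null_identity_all_equal(self):
        odh, keys = series([0.2] * 6)
        g = make_groups({(1, 2): keys[:3]}, homo=keys[3:])
        F, p = glm_marker_test(odh, g)
        assert F == 0.0
        assert p == 1.0

    def test_single_group_skipped(self):
        odh, keys = series([0.1, 0.2, 0.3])
        g = make_groups({(1, 2): keys})
        with pytest.raises(ValueError, match="fewer than 2"):
            glm_marker_test(odh, g)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(100):
            sizes = rng.integers(3, 10, size=rng.integers(2, 5))
            values = [rng.normal(rng.normal(0, 0.5), 1.0, s) for s in sizes]
            odh, keys = series(np.concatenate(values))
            het, start = {}, 0
            for i, s in enumerate(sizes[:-1]):
                het[(150 + 2 * i, 152 + 2 * i)] = keys[start:start + s]
                start += s
            g = make_groups(het, homo=keys[start:])
            F, p = glm_marker_test(odh, g)
            F_ref, p_ref = stats.f_oneway(*values)
            assert F == pytest.approx(F_ref, rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-9)


class TestKolmogorovSmirnov:
    def test_disjoint_supports(self):
        res = ks_hetero_vs_homo([4, 5, 6], [1, 2, 3])
        assert res.D == 1.0
        assert res.advantage

    def test_identical_samples(self):
        res = ks_hetero_vs_homo([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.D == 0.0
        assert res.p == 1.0
        assert not res.advantage

    def test_enumerated_one_sided_example(self):
        # ECDF difference sup over pooled points: D(greater) = 1/3
        res = ks_hetero_vs_homo([0.5, 0.6], [0.0, 0.55, 0.7])
        assert res.D == pytest.approx(1.0 / 3.0)

    def test_underdominant_direction_not_advantaged(self):
        res = ks_hetero_vs_homo([1, 2, 3], [4, 5, 6], sided="greater")
        assert res.D == 0.0
        assert not res.advantage
        res2 = ks_hetero_vs_homo([1, 2, 3], [7, 8, 9], sided="two-sided")
        assert not res2.advantage  # significant only in the wrong direction

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_hetero_vs_homo([], [1.0])

    def test_exhaustive_ecdf_oracle(self, rng):
        """D matches brute-force ECDF enumeration for all n, n' <= 8."""
        def brute(a, b):
            pts = np.concatenate([a, b])
            dplus = max(
                np.mean(b <= x) - np.mean(a <= x) for x in pts
            )
            dabs = max(
                abs(np.mean(a <= x) - np.mean(b <= x)) for x in pts
            )
            return dplus, dabs

        for n, m in itertools.product(range(1, 9), range(1, 9)):
            het = rng.normal(0.3, 1.0, n)
            hom = np.round(rng.normal(0.0, 1.0, m), 1)  # rounded -> ties
            d_plus, d_abs = brute(het, hom)
            assert ks_hetero_vs_homo(het, hom, sided="greater").D == pytest.approx(
                max(d_plus, 0.0), abs=1e-12
            )
            assert ks_hetero_vs_homo(het, hom, sided="two-sided").D == pytest.approx(
                d_abs, abs=1e-12
            )

    def test_two_sided_matches_scipy_asymptotic(self, rng):
        het = rng.normal(0.5, 1.0, 30)
        hom = rng.normal(0.0, 1.0, 40)
        res = ks_hetero_vs_homo(het, hom, sided="two-sided")
        ref = stats.ks_2samp(het, hom, method="asymp")
        assert res.D == pytest.approx(ref.statistic, abs=1e-12)
        # scipy's "asymp" uses a finite-n refinement of the Kolmogorov law;
        # the classical limit used here agrees to leading order
        assert res.p == pytest.approx(ref.pvalue, rel=0.6)

    def test_critical_value_formula(self):
        # c(alpha) * sqrt((n + n')/(n n')) with the asymptotic coefficient
        expected = np.sqrt(-np.log(0.05) / 2) * np.sqrt((12 + 30) / (12 * 30))
        assert ks_critical_D(0.05, 12, 30) == pytest.approx(expected)


class TestPermutationThreshold:
    def test_quantile_rule_is_kth_smallest(self, rng):
        min_p = rng.uniform(size=100)
        assert _threshold_from_min_p(min_p, 0.05) == np.sort(min_p)[4]

    def test_deterministic_given_seed(self, rng):
        odh, keys = series(rng.normal(0.3, 0.1, 30))
        g = make_groups(
            {(1, 2): keys[:6], (3, 4): keys[6:12]}, homo=keys[12:20]
        )
        g2 = make_groups({(1, 2): keys[3:9]}, homo=keys[9:18], marker="m2")
        cfg = ScanConfig(n_perm=150, seed=7)
        t1 = permutation_threshold(odh, {"m": g, "m2": g2}, cfg)
        t2 = permutation_threshold(odh, {"m": g, "m2": g2}, cfg)
        assert t1 == t2
        t3 = permutation_threshold(
            odh, {"m": g, "m2": g2}, ScanConfig(n_perm=150, seed=8)
        )
        assert t3 != t1

    def test_single_marker_threshold_near_alpha(self, rng):
        """comparison-wise = experiment-wise for one marker."""
        odh, keys = series(rng.normal(0.0, 1.0, 60))
        g = make_groups(
            {(1, 2): keys[:15], (3, 4): keys[15:30]}, homo=keys[30:]
        )
        cfg = ScanConfig(n_perm=2000, seed=3)
        thr = permutation_threshold(odh, {"m": g}, cfg)
        assert 0.02 < thr < 0.09


class TestStructureAdjustment:
    def test_two_group_centering(self):
        odh, keys = series([0.2] * 10 + [0.4] * 10)
        combos = {k: ("X" if i < 10 else "Y") for i, k in enumerate(keys)}
        adj, effects = adjust_for_structure(odh, combos)
        assert effects["X"] == pytest.approx(-0.1)
        assert effects["Y"] == pytest.approx(0.1)
        assert adj.mean() == pytest.approx(odh.mean())
        assert adj.groupby(pd.Series(combos)).mean().std() == pytest.approx(0.0)

    def test_single_combination_identity(self):
        odh, keys = series([0.1, 0.5, 0.3])
        adj, effects = adjust_for_structure(odh, {k: "X" for k in keys})
        assert np.allclose(adj, odh)
        assert effects["X"] == pytest.approx(0.0)

    def test_weighted_average_example(self):
        # combination means 0.1 (n=1) and 0.4 (n=3): weighted mean 0.325
        odh, keys = series([0.1, 0.4, 0.4, 0.4])
        combos = {keys[0]: "A", **{k: "B" for k in keys[1:]}}
        adj, effects = adjust_for_structure(odh, combos)
        assert effects["A"] == pytest.approx(-0.225)
        assert effects["B"] == pytest.approx(0.075)

    def test_unlabeled_founder_errors(self, small_study):
        with pytest.raises(KeyError):
            hybrid_cofactor({"SB001": "A"}, [("SB001", "SB002")])

    def test_removes_between_combination_variance(self, rng):
        odh, keys = series(rng.normal(0.3, 0.2, 40))
        combos = {k: f"C{i % 3}" for i, k in enumerate(keys)}
        adj, _ = adjust_for_structure(odh, combos)
        by = adj.groupby(pd.Series(combos)).mean()
        assert by.std() < 1e-12


class TestCofactorGlm:
    def test_single_cofactor_level_reduces_to_plain_glm(self, rng):
        odh, keys = series(rng.normal(0.3, 0.1, 24))
        g = make_groups({(1, 2): keys[:8]}, homo=keys[8:16])
        assign = {f: "A" for pair in keys for f in pair}
        F0, p0 = glm_marker_test(odh, g)
        F1, p1 = glm_with_cofactor(odh, g, assign)
        assert F1 == pytest.approx(F0, rel=1e-9)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_cofactor_absorbs_cluster_signal(self, rng):
        # genotype effect absent, all signal from the cluster pair: the
        # genotype p should be null-distributed, not significant
        n = 60
        keys = [(f"a{i}", f"b{i}") for i in range(n)]
        assign = {}
        for i, (a, b) in enumerate(keys):
            assign[a] = "A" if i < n // 2 else "B"
            assign[b] = assign[a]
        cof = hybrid_cofactor(assign, keys)
        shift = np.array([0.5 if cof[k] == "A|A" else 0.0 for k in keys])
        pvals = []
        for trial in range(40):
            r = np.random.default_rng(trial)
            odh = pd.Series(shift + r.normal(0, 0.1, n), index=keys)
            g = make_groups(
                {(1, 2): keys[: n // 2]}, homo=keys[n // 2:]
            )
            try:
                _, p = glm_with_cofactor(odh, g, assign)
            except ValueError:
                continue  # aliased
            pvals.append(p)
        if pvals:  # genotype aliased with cofactor here -> aliasing accepted
            assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_aliasing_flagged(self, rng):
        odh, keys = series(rng.normal(0.3, 0.1, 12))
        g = make_groups({(1, 2): keys[:6]}, homo=keys[6:])
        assign = {}
        for i, (a, b) in enumerate(keys):
            assign[a] = assign[b] = "A" if i < 6 else "B"
        with pytest.raises(ValueError, match="aliased"):
            glm_with_cofactor(odh, g, assign)


class TestScanPipeline:
    def test_planted_truth_recovered(self, default_study):
        cfg = ScanConfig(n_perm=200, seed=11)
        res = scan(
            default_study.geno, default_study.pheno, default_study.design,
            cfg, "DPW",
        )
        truth = {
            (p.marker, tuple(sorted(p.pair)))
            for p in default_study.truth.planted
        }
        called = {
            (c.marker, tuple(sorted(p))) for c in res.calls for p in c.pairs
        }
        assert called == truth

    def test_step2_gated_on_step1(self, default_study):
        cfg = ScanConfig(n_perm=150, seed=5)
        res = scan(
            default_study.geno, default_study.pheno, default_study.design,
            cfg, "DPW",
        )
        for results in res.years.values():
            for r in results:
                if not r.passed:
                    assert not r.step2

    def test_deterministic_given_seed(self, small_study):
        cfg = ScanConfig(n_perm=120, seed=9)
        r1 = scan(small_study.geno, small_study.pheno, small_study.design, cfg, "DPW")
        r2 = scan(small_study.geno, small_study.pheno, small_study.design, cfg, "DPW")
        assert r1.thresholds == r2.thresholds
        assert [c.marker for c in r1.calls] == [c.marker for c in r2.calls]

    def test_structure_aware_scan_runs(self, small_study):
        cfg = ScanConfig(n_perm=120, seed=9)
        res = scan(
            small_study.geno, small_study.pheno, small_study.design, cfg,
            "DPW", assign=small_study.assign,
        )
        assert set(res.years) == {2010, 2011}

    def test_single_year_reduction(self, small_study):
        pheno_1y = small_study.pheno[small_study.pheno["year"] == 2010]
        cfg = ScanConfig(n_perm=120, seed=9, require_both_years=False)
        res = scan(
            small_study.geno, pheno_1y, small_study.design, cfg, "DPW"
        )
        advantaged = {
            (r.marker, p)
            for r in res.years[2010]
            for p, ks in r.step2.items()
            if ks.advantage
        }
        called = {(c.marker, p) for c in res.calls for p in c.pairs}
        assert called == advantaged


class TestHtlNaming:
    def _result(self, marker, pairs, year):
        r = MarkerScanResult(
            marker=marker, year=year, F=10.0, p=1e-6, threshold=1e-3,
            passed=True,
        )
        for p in pairs:
            r.step2[p] = KSResult(D=0.9, p=1e-4, advantage=True,
                                  n_hetero=10, n_homo=20)
        return r

    def test_both_year_intersection_and_position_naming(self, toy_geno):
        years = {
            2010: [self._result("mA", [(154, 162)], 2010),
                   self._result("mB", [(150, 152)], 2010)],
            2011: [self._result("mA", [(154, 162)], 2011)],
        }
        calls = call_htls(years, toy_geno, "DPW")
        assert [c.marker for c in calls] == ["mA"]
        assert calls[0].name == "hDPW1.1"

    def test_different_pairs_across_years_not_called(self, toy_geno):
        years = {
            2010: [self._result("mA", [(154, 162)], 2010)],
            2011: [self._result("mA", [(154, 158)], 2011)],
        }
        assert call_htls(years, toy_geno, "DPW") == []

    def test_ordinals_by_position_within_chromosome(self):
        import pandas as pd
        from htlmap import FounderGenotypeMatrix
        calls_df = pd.DataFrame(
            {"m1": [150.0, 152], "m2": [150.0, 152]}, index=["F1", "F2"]
        )
        geno = FounderGenotypeMatrix(
            calls_df,
            markers=[MarkerDef("m1", "1", 5e6), MarkerDef("m2", "1", 1e6)],
        )
        years = {
            2010: [self._result("m1", [(150, 152)], 2010),
                   self._result("m2", [(150, 152)], 2010)],
        }
        calls = call_htls(years, geno, "DPW", require_both_years=False)
        # m2 sits earlier on chromosome 1 -> gets ordinal .1
        names = {c.marker: c.name for c in calls}
        assert names == {"m2": "hDPW1.1", "m1": "hDPW1.2"}
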