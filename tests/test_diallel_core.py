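import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from htlmap import (
    CrossID,
    DiallelDesign,
    FounderGenotypeMatrix,
    MarkerDef,
    allele_summary,
    cross_key,
    partition_by_locus,
    project_hybrid_genotypes,
)


class TestDesign:
    @pytest.mark.parametrize("n,expected", [(17, 136), (19, 171), (2, 1), (4, 6)])
    def test_possible_cross_count(self, n, expected):
        assert DiallelDesign.n_possible(n) == expected
        design = DiallelDesign.half_diallel([f"F{i}" for i in range(n)])
        assert len(design.pair_keys) == expected

    def test_self_cross_rejected(self):
        with pytest.raises(ValueError, match="self cross"):
            DiallelDesign(
                pd.DataFrame(
                    [{"cross_id": "x", "female": "A", "male": "A"}]
                )
            )
        with pytest.raises(ValueError):
            CrossID("A", "A")

    def test_cross_key_order_free(self):
        assert cross_key("B", "A") == cross_key("A", "B") == ("A", "B")
        assert CrossID("B", "A").key == CrossID("A", "B").key

    def test_reciprocal_pairs_detected(self):
        design = DiallelDesign(
            pd.DataFrame(
                [
                    {"cross_id": "AxB", "female": "A", "male": "B"},
                    {"cross_id": "BxA", "female": "B", "male": "A"},
                    {"cross_id": "AxC", "female": "A", "male": "C"},
                ]
            )
        )
        assert design.reciprocal_pairs() == [("A", "B")]


class TestProjection:
    def test_heterozygous_pair(self, toy_geno, toy_design):
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        assert proj["mA"][("F1", "F4")] == (154, 162)

    def test_homozygous_pair(self, toy_geno, toy_design):
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        assert proj["mA"][("F1", "F2")] == (154, 154)

    def test_missing_call_propagates(self, toy_geno, toy_design):
        toy_geno.calls.loc["F1", "mA"] = np.nan
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        assert proj["mA"][("F1", "F4")] is None
        groups = partition_by_locus(proj, "mA", min_group=2)
        assert (("F1", "F4"), "missing parental call") in groups.excluded

    def test_unknown_parent_is_hard_error(self, toy_geno):
        design = DiallelDesign(
            pd.DataFrame([{"cross_id": "x", "female": "F1", "male": "NOPE"}])
        )
        with pytest.raises(KeyError, match="NOPE"):
            project_hybrid_genotypes(toy_geno, design)

    def test_symmetry_under_parent_swap(self, toy_geno, toy_design):
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        swapped = DiallelDesign(
            toy_design.crosses.rename(
                columns={"female": "male", "male": "female"}
            )[["cross_id", "female", "male"]]
        )
        assert project_hybrid_genotypes(toy_geno, swapped) == proj


class TestPartition:
    def test_balanced_biallelic_locus(self, toy_geno, toy_design):
        # 3+3 founders at a biallelic locus, complete half diallel of 15:
        # 3*3 = 9 hetero crosses, C(3,2)*2 = 6 homozygous
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        groups = partition_by_locus(proj, toy_geno.marker("mA"), min_group=3)
        assert len(groups.hetero[(154, 162)]) == 9
        assert len(groups.homo) == 6
        assert not groups.excluded

    def test_monomorphic_locus_all_homo(self, toy_geno, toy_design):
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        groups = partition_by_locus(proj, "mB", min_group=3)
        assert not groups.hetero
        assert len(groups.homo) == 15

    def test_rare_pair_excluded_below_min_group(self):
        calls = pd.DataFrame(
            {"m": [154.0, 154, 154, 154, 162, 170]},
            index=[f"F{i}" for i in range(6)],
        )
        geno = FounderGenotypeMatrix(calls)
        design = DiallelDesign.half_diallel(geno.founder_ids)
        proj = project_hybrid_genotypes(geno, design)
        groups = partition_by_locus(proj, "m", min_group=3)
        # the 162/170 pair has a single cross -> excluded
        assert (("F4", "F5"), "below minimum group size") in groups.excluded
        assert (162, 170) not in groups.hetero

    def test_min_group_lower_bound(self, toy_geno, toy_design):
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        with pytest.raises(ValueError):
            partition_by_locus(proj, "mA", min_group=1)

    def test_absent_marker_errors(self, toy_geno, toy_design):
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        with pytest.raises(KeyError):
            partition_by_locus(proj, "nope")

    def test_split_homo_keeps_per_allele_groups(self, toy_geno, toy_design):
        proj = project_hybrid_genotypes(toy_geno, toy_design)
        groups = partition_by_locus(proj, "mA", min_group=3, split_homo=True)
        assert set(groups.homo_by_allele) == {154, 162}
        assert all(len(v) == 3 for v in groups.homo_by_allele.values())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        alleles=st.lists(
            st.sampled_from([150, 152, 154, 156]), min_size=4, max_size=10
        ),
        min_group=st.integers(2, 4),
    )
    def test_partition_property(self, alleles, min_group):
        """hetero + homo + excluded always partitions the projected crosses."""
        ids = [f"F{i}" for i in range(len(alleles))]
        geno = FounderGenotypeMatrix(
            pd.DataFrame({"m": [float(a) for a in alleles]}, index=ids)
        )
        design = DiallelDesign.half_diallel(ids)
        proj = project_hybrid_genotypes(geno, design)
        groups = partition_by_locus(proj, "m", min_group=min_group)
        members = [k for v in groups.hetero.values() for k in v]
        members += groups.homo + [k for k, _ in groups.excluded]
        assert sorted(members) == sorted(proj["m"])
        assert len(set(members)) == len(members)
        for pair in groups.hetero:
            assert pair[0] != pair[1]
            assert len(groups.hetero[pair]) >= min_group


class TestAlleleSummary:
    def test_counts_and_rare_flag(self):
        calls = pd.DataFrame(
            {"m": [154.0, 154, 154, 162, 162, 162, 170]},
            index=[f"F{i}" for i in range(7)],
        )
        out = allele_summary(FounderGenotypeMatrix(calls))
        by_allele = out.set_index("allele")
        assert by_allele.loc[154, "n_founders"] == 3
        assert not by_allele.loc[154, "rare"]
        assert not by_allele.loc[162, "rare"]
        assert by_allele.loc[170, "rare"]
        assert out["n_founders"].sum() == 7

    def test_all_missing_gives_empty_table(self):
        calls = pd.DataFrame(
            {"m": [np.nan, np.nan]}, index=["F0", "F1"], dtype=float
        )
        assert allele_summary(FounderGenotypeMatrix(calls)).empty

    def test_small_counts_all_rare(self):
        calls = pd.DataFrame(
            {"m": [150.0, 150, 152]}, index=["F0", "F1", "F2"]
        )
        out = allele_summary(FounderGenotypeMatrix(calls))
        assert out["rare"].all()

    def test_duplicate_founwhile_rejected(self):
        calls = pd.DataFrame({"m": [150.0, 152]}, index=["F0", "F0"])
        with pytest.raises(ValueError, match="duplicate"):
            FounderGenotypeMatrix(calls)
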