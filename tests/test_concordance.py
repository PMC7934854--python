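"""Directional discordance, hypergeometric ORA, and UpSet intersections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import retmosaic as rm
from retmosaic.errors import ValidationError


def toy_table(genes, log2fc, padj, comparison="X"):
    return pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "padj": padj, "comparison": comparison}
    )


from oracles import exact_hypergeom_upper_tail as exact_upper_tail


class TestSignificantSet:
    def test_empty_table(self):
        assert rm.significant_set(pd.DataFrame(columns=["gene", "log2fc", "padj"])) == frozenset()

    def test_toy_directional_filter(self):
        t = toy_table(
            [f"gene{i}" for i in range(1, 7)],
            [+1, +1, -2, +0.5, -1, -3],
            [0.01, 0.2, 0.01, 0.04, 0.5, 0.001],
        )
        assert rm.significant_set(t, 0.05, "up") == {"gene1", "gene4"}
        assert rm.significant_set(t, 0.05, "down") == {"gene3", "gene6"}
        assert rm.significant_set(t, 0.05, "any") == rm.significant_set(
            t, 0.05, "up"
        ) | rm.significant_set(t, 0.05, "down")

    def test_duplicate_gene_rows_rejected(self):
        t = toy_table(["g1", "g1"], [1, 2], [0.01, 0.02])
        with pytest.raises(ValidationError):
            rm.significant_set(t)


class TestDiscordance:
    def test_recovers_planted_genes_exactly(self, de_bundle):
        spec, a, b, _, planted = de_bundle
        res = rm.discordant_genes(a, b, alpha=spec.alpha)
        assert res.discordant_up_in_a == frozenset(planted["discordant_up_in_a"])
        assert res.discordant_down_in_a == frozenset(planted["discordant_down_in_a"])
        assert res.concordant == frozenset(planted["concordant"])

    def test_self_comparison_is_all_concordant(self, de_bundle):
        spec, a, _, _, _ = de_bundle
        res = rm.discordant_genes(a, a, alpha=spec.alpha)
        assert not res.discordant
        assert res.concordant == rm.significant_set(a, spec.alpha, "any")

    def test_disjoint_significance_gives_empty_results(self):
        a = toy_table(["g1", "g2"], [1.0, -1.0], [0.01, 0.9])
        b = toy_table(["g1", "g2"], [1.0, -1.0], [0.9, 0.01])
        res = rm.discordant_genes(a, b)
        assert not res.discordant and not res.concordant

    def test_zero_log2fc_reported_separately(self):
        a = toy_table(["g1"], [0.0], [0.01])
        b = toy_table(["g1"], [1.0], [0.01])
        res = rm.discordant_genes(a, b)
        assert res.zero_sign == {"g1"}
        assert not res.discordant and not res.concordant

    def test_antisymmetric_under_table_swap(self, de_bundle):
        spec, a, b, _, _ = de_bundle
        ab = rm.discordant_genes(a, b, spec.alpha)
        ba = rm.discordant_genes(b, a, spec.alpha)
        assert ab.discordant_up_in_a == ba.discordant_down_in_a
        assert ab.discordant_down_in_a == ba.discordant_up_in_a
        assert ab.concordant == ba.concordant


class TestHypergeomORA:
    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = rm.hypergeom_ora(universe[:5], {"T": universe[10:15]}, universe)
        assert res[0].k == 0 and res[0].p_hypergeometric == 1.0

    def test_small_instance_matches_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        study = universe[:4] + [universe[10]]  # k = 4 of K = 5, n = 5
        res = rm.hypergeom_ora(study, {"T": term}, universe)[0]
        assert res.p_hypergeometric == pytest.approx(exact_upper_tail(20, 5, 5, 4), abs=1e-12)

    def test_saturated_study(self):
        universe = [f"g{i}" for i in range(12)]
        res = rm.hypergeom_ora(universe, {"T": universe[:4]}, universe)[0]
        assert res.k == res.K and res.p_hypergeometric == pytest.approx(1.0)

    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            rm.hypergeom_ora({"zz"}, {"T": ["g1"]}, {"g1", "g2"})

    def test_bh_correction_bounds(self, de_bundle):
        spec, a, b, term_map, _ = de_bundle
        res = rm.discordant_genes(a, b, spec.alpha)
        enr = rm.hypergeom_ora(res.discordant, term_map, set(a["gene"]))
        qs = [e.q_bh for e in enr]
        assert all(0.0 <= q <= 1.0 for q in qs)
        assert min(e.p_hypergeometric for e in enr) <= min(qs)


class TestSharedTerms:
    def test_common_term_across_four_lists(self):
        lists = {name: ["T"] + [f"{name}_{i}" for i in range(3)] for name in "ABCD"}
        res = rm.shared_terms(lists)
        assert res.full_intersection == {"T"}
        assert res.regions[("A", "B", "C", "D")] == {"T"}

    def test_identical_lists(self):
        lists = {"A": ["x", "y"], "B": ["x", "y"]}
        res = rm.shared_terms(lists)
        assert res.full_intersection == {"x", "y"}
        assert res.regions[("A",)] == frozenset()
        assert res.regions[("B",)] == frozenset()

    def test_needs_two_lists(self):
        with pytest.raises(ValidationError):
            rm.shared_terms({"A": ["x"]})

    @given(st.integers(0, 2**31 - 1))
    def test_exclusive_regions_partition_the_union(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 5))
        pool = [f"item{i}" for i in range(20)]
        lists = {
            f"L{j}": list(rng.choice(pool, size=int(rng.integers(0, 15)), replace=False))
            for j in range(m)
        }
        res = rm.shared_terms(lists)
        union = set().union(*(set(v) for v in lists.values()))
        combined: list = []
        for items in res.regions.values():
            combined.extend(items)
        assert len(combined) == len(set(combined))  # disjoint
        assert set(combined) == union  # covers
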