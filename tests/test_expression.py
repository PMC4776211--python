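"""Normalizations, Rank Product, GSEA, uncentered-Pearson clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from esomics import synthetic as syn
from esomics.expression import (
    CountMatrix,
    community_summary,
    enrichment_score,
    filter_complete,
    gsea,
    hcluster,
    normalize_community,
    normalize_organism,
    rank_product,
    uncentered_pearson_distance,
    unique_mapped,
)


def make_matrix(values, conditions, organisms=None, **kw):
    values = pd.DataFrame(values)
    return CountMatrix(
        values=values,
        conditions=pd.Series(conditions),
        organisms=None if organisms is None else pd.Series(organisms),
        **kw,
    )


class TestNormalizeCommunity:
    def test_single_feature_sample_becomes_one_million(self):
        m = make_matrix({"s1": [123.0]}, {"s1": "A"})
        out = normalize_community(m)
        assert out.values.iloc[0, 0] == 1_000_000.0

    def test_column_sums_exactly_one_million(self):
        rng = np.random.default_rng(3)
        m = make_matrix(
            {f"s{i}": rng.integers(1, 500, 100) for i in range(5)},
            {f"s{i}": "A" for i in range(5)},
        )
        out = normalize_community(m)
        np.testing.assert_allclose(out.values.sum(axis=0), 1_000_000.0, atol=1e-6)
        # brute-force per-column scaling
        expected = m.values / m.values.sum(axis=0) * 1e6
        np.testing.assert_allclose(out.values.to_numpy(), expected.to_numpy())

    def test_idempotent_on_normalized_input(self):
        m = make_matrix({"s1": [3.0, 7.0], "s2": [1.0, 4.0]}, {"s1": "A", "s2": "B"})
        once = normalize_community(m)
        twice = normalize_community(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_zero_total_sample_named_in_error(self):
        m = make_matrix({"good": [1.0], "bad": [0.0]}, {"good": "A", "bad": "A"})
        with pytest.raises(ValueError, match="bad"):
            normalize_community(m)


class TestNormalizeOrganism:
    def _matrix(self):
        values = {"s1": [60.0, 40.0, 10.0], "s2": [120.0, 80.0, 10.0]}
        return make_matrix(
            values,
            {"s1": "A", "s2": "B"},
            organisms={0: "fungus", 1: "fungus", 2: "other"},
        )

    def test_totals_equalized_to_mean(self):
        out = normalize_organism(self._matrix(), "fungus")
        sub = out.values.loc[[0, 1]]
        # totals (100, 200) -> both rescaled to 150
        np.testing.assert_allclose(sub.sum(axis=0), [150.0, 150.0])

    def test_other_organisms_untouched(self):
        out = normalize_organism(self._matrix(), "fungus")
        np.testing.assert_allclose(out.values.loc[2], [10.0, 10.0])

    def test_already_equal_totals_unchanged(self):
        m = make_matrix(
            {"s1": [5.0, 5.0], "s2": [6.0, 4.0]},
            {"s1": "A", "s2": "B"},
            organisms={0: "f", 1: "f"},
        )
        out = normalize_organism(m, "f")
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_absent_organism_in_sample_is_error(self):
        m = make_matrix(
            {"s1": [5.0], "s2": [0.0]}, {"s1": "A", "s2": "B"}, organisms={0: "f"}
        )
        with pytest.raises(ValueError, match="s2"):
            normalize_organism(m, "f")


class TestFilterComplete:
    def test_feature_with_any_zero_dropped(self):
        m = make_matrix({"s1": [1.0, 0.0], "s2": [2.0, 5.0]}, {"s1": "A", "s2": "B"})
        out = filter_complete(m)
        assert list(out.values.index) == [0]

    def test_all_positive_matrix_unchanged(self):
        m = make_matrix({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, {"s1": "A", "s2": "B"})
        assert filter_complete(m).values.equals(m.values)

    def test_empty_result_warns(self):
        m = make_matrix({"s1": [0.0], "s2": [1.0]}, {"s1": "A", "s2": "B"})
        with pytest.warns(UserWarning):
            filter_complete(m)


def test_unique_filter_never_increases_counts():
    rng = np.random.default_rng(6)
    total = pd.DataFrame(rng.integers(0, 50, (30, 4)).astype(float))
    unique = (total * rng.random((30, 4))).round()
    out = unique_mapped(total, unique)
    assert ((out <= total).all()).all()
    with pytest.raises(ValueError):
        unique_mapped(total, total + 1)


class TestRankProduct:
    def _matrix(self, values):
        cols = list(values)
        cond = {c: ("A" if c.startswith("a") else "B") for c in cols}
        return make_matrix(values, cond)

    def test_top_ranked_feature_has_rp_one_and_minimal_p(self):
        m = self._matrix({"a1": [100.0, 10.0, 5.0, 1.0], "b1": [1.0, 10.0, 5.0, 100.0]})
        res = rank_product(m, "A", "B")
        top = res.set_index("feature_id").loc[0]
        assert top["rp_up"] == 1.0
        assert top["p_up"] == res["p_up"].min() == pytest.approx(1 / 4)

    def test_exhaustive_equals_brute_force_enumeration(self):
        """G = 4, K = 1: p-values equal enumeration over all 4! rank
        assignments computed independently."""
        m = self._matrix({"a1": [9.0, 7.0, 2.0, 1.0], "b1": [3.0, 7.0, 1.0, 8.0]})
        res = rank_product(m, "A", "B").set_index("feature_id")
        ratio = m.values["a1"] / m.values["b1"]
        from scipy.stats import rankdata

        obs_up = rankdata(-ratio)
        G = 4
        for f in range(G):
            counts = [
                sum(r <= obs_up[f] for r in perm)
                for perm in itertools.permutations(range(1, G + 1))
            ]
            expected_p = np.mean(counts) / G
            assert res.loc[f, "p_up"] == pytest.approx(expected_p)

    def test_montecarlo_matches_exhaustive_within_001(self):
        """K = 1, G = 6: Monte-Carlo p with 1e5 permutations within 0.01
        of the exhaustive enumeration (tie-free continuous values, where
        the two null constructions target the same distribution)."""
        rng = np.random.default_rng(17)
        m = self._matrix({"a1": rng.uniform(1, 100, 6), "b1": rng.uniform(1, 100, 6)})
        exact = rank_product(m, "A", "B").set_index("feature_id")
        mc = rank_product(
            m, "A", "B", n_perm=100_000, seed=2, exhaustive_limit=0
        ).set_index("feature_id")
        assert np.abs(exact["p_up"] - mc["p_up"]).max() <= 0.01
        assert np.abs(exact["p_down"] - mc["p_down"]).max() <= 0.01

    def test_invariant_to_monotone_rescaling_of_one_sample(self):
        rng = np.random.default_rng(8)
        values = {
            "a1": rng.uniform(1, 100, 40), "a2": rng.uniform(1, 100, 40),
            "b1": rng.uniform(1, 100, 40), "b2": rng.uniform(1, 100, 40),
        }
        m1 = self._matrix(values)
        scaled = dict(values)
        scaled["a2"] = values["a2"] * 37.5  # uniform rescale of one sample
        m2 = self._matrix(scaled)
        r1 = rank_product(m1, "A", "B", n_perm=50, seed=4)
        r2 = rank_product(m2, "A", "B", n_perm=50, seed=4)
        np.testing.assert_allclose(r1["rp_up"], r2["rp_up"])
        np.testing.assert_allclose(r1["p_up"], r2["p_up"])

    def test_joint_significance_rule(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(10, 100, 50)
        values = {
            "a1": base.copy(), "a2": base * rng.uniform(0.9, 1.1, 50),
            "b1": base * rng.uniform(0.9, 1.1, 50), "b2": base.copy(),
        }
        values["a1"][:3] *= 10  # strong planted up-features
        values["a2"][:3] *= 10
        m = self._matrix(values)
        res = rank_product(m, "A", "B", n_perm=200, seed=1)
        sig = res[res["significant"]]
        assert ((sig["ratio"] > 2) | (sig["ratio"] < 0.5)).all()
        assert (np.minimum(sig["p_up"], sig["p_down"]) <= 0.01).all()

    def test_zero_values_rejected(self):
        m = self._matrix({"a1": [0.0, 1.0], "b1": [1.0, 1.0]})
        with pytest.raises(ValueError, match="complete-case"):
            rank_product(m, "A", "B")

    def test_needs_two_features(self):
        m = self._matrix({"a1": [1.0], "b1": [1.0]})
        with pytest.raises(ValueError):
            rank_product(m, "A", "B")


def brute_force_es(ranked, members):
    """Running-sum oracle evaluated at every list position."""
    S = sum(1 for g in ranked if g in members)
    N = len(ranked)
    running, best = 0.0, 0.0
    path = []
    for g in ranked:
        running += 1.0 / S if g in members else -1.0 / (N - S)
        path.append(running)
    for v in path:
        if abs(v) > abs(best):
            best = v
    return best


class TestGsea:
    def _matrix(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        values = {
            "a1": rng.uniform(1, 100, n), "a2": rng.uniform(1, 100, n),
            "b1": rng.uniform(1, 100, n), "b2": rng.uniform(1, 100, n),
        }
        m = pd.DataFrame(values, index=[f"g{i}" for i in range(n)])
        return CountMatrix(
            values=m,
            conditions=pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
        )

    def test_singleton_set_at_top_reaches_es_one(self):
        ranked = [f"g{i}" for i in range(10)]
        assert enrichment_score(ranked, {"g0"}) == pytest.approx(1.0)

    def test_es_matches_brute_force_running_sum(self):
        m = self._matrix()
        res = gsea(m, {"set1": ["g1", "g4", "g7"]}, "A", "B", n_perm=50, seed=1)
        mean_a = m.values[["a1", "a2"]].mean(axis=1)
        mean_b = m.values[["b1", "b2"]].mean(axis=1)
        ranked = list(np.log2(mean_a / mean_b).sort_values(ascending=False).index)
        expected = brute_force_es(ranked, {"g1", "g4", "g7"})
        assert res.iloc[0]["es"] == pytest.approx(expected)

    def test_complement_set_has_opposite_sign(self):
        ranked = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(2)
        members = set(rng.choice(ranked, 4, replace=False))
        complement = set(ranked) - members
        es_a = enrichment_score(ranked, members)
        es_b = enrichment_score(ranked, complement)
        assert np.sign(es_a) == -np.sign(es_b)

    def test_whole_universe_set_skipped_with_warning(self):
        m = self._matrix()
        with pytest.warns(UserWarning, match="skipped"):
            res = gsea(m, {"all": [f"g{i}" for i in range(10)]}, "A", "B", n_perm=20, seed=0)
        assert res.empty

    def test_fdr_q_monotone_nonincreasing_in_abs_nes(self):
        m = self._matrix(n=60, seed=5)
        sets = {
            f"set{k}": [f"g{i}" for i in np.random.default_rng(k).choice(60, 8, replace=False)]
            for k in range(8)
        }
        res = gsea(m, sets, "A", "B", n_perm=100, seed=3)
        ordered = res.reindex(res["nes"].abs().sort_values(ascending=False).index)
        assert (np.diff(ordered["fdr_q"]) >= -1e-12).all()

    def test_planted_up_set_detected_against_gseapy_oracle(self):
        """Cross-check the classic (unweighted) ES against gseapy prerank
        on an identical ranking."""
        import gseapy

        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        metric = pd.Series(np.sort(rng.normal(0, 1, 40))[::-1], index=genes)
        members = ["g0", "g2", "g5", "g9", "g30"]
        ours = enrichment_score(list(metric.index), members)
        pre = gseapy.prerank(
            rnk=metric.reset_index().rename(columns={"index": "gene", 0: "score"}),
            gene_sets={"s": members},
            permutation_num=10,
            weight=0,
            outdir=None,
            min_size=2,
            seed=1,
            threads=1,
        )
        theirs = float(pre.res2d.loc[pre.res2d["Term"] == "s", "ES"].iloc[0])
        assert ours == pytest.approx(theirs, abs=1e-6)


def naive_upgma_cophenetic(D, labels):
    """Brute-force average-linkage agglomeration; returns cophenetic map."""
    active = [frozenset([l]) for l in labels]

    def d(c1, c2):
        vals = [D.loc[x, y] for x in c1 for y in c2]
        return float(np.mean(vals))

    coph = {}
    while len(active) > 1:
        best = None
        for c1, c2 in itertools.combinations(sorted(active, key=sorted), 2):
            cur = d(c1, c2)
            if best is None or cur < best[0] - 1e-15:
                best = (cur, c1, c2)
        h, c1, c2 = best
        for x in c1:
            for y in c2:
                coph[frozenset([x, y])] = h
        active.remove(c1)
        active.remove(c2)
        active.append(c1 | c2)
    return coph


class TestHcluster:
    def _two_group_matrix(self, seed=4):
        rng = np.random.default_rng(seed)
        profile1 = rng.uniform(10, 100, 40)
        profile2 = rng.uniform(10, 100, 40)
        cols = {}
        for i in range(3):
            cols[f"g1_{i}"] = profile1 * rng.uniform(0.9, 1.1, 40)
            cols[f"g2_{i}"] = profile2 * rng.uniform(0.9, 1.1, 40)
        return CountMatrix(
            values=pd.DataFrame(cols),
            conditions=pd.Series({c: "x" for c in cols}),
        )

    def test_duplicate_samples_merge_first_at_distance_zero(self):
        values = pd.DataFrame(
            {"s1": [1.0, 5.0, 2.0], "s2": [1.0, 5.0, 2.0], "s3": [9.0, 1.0, 7.0]}
        )
        m = CountMatrix(values=values, conditions=pd.Series({c: "x" for c in values}))
        res = hcluster(m)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.distance.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profiles_have_distance_one(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        D = uncentered_pearson_distance(X)
        assert D[0, 1] == pytest.approx(1.0)

    def test_distance_is_bounded_and_zero_on_diagonal(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 10, (20, 6))
        D = uncentered_pearson_distance(X)
        assert (D >= 0).all() and (D <= 2).all()
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)

    def test_recovers_planted_bipartition_and_matches_naive_oracle(self):
        import scipy.cluster.hierarchy as sch

        m = self._two_group_matrix()
        res = hcluster(m)
        two = sch.fcluster(res.linkage, 2, criterion="maxclust")
        cols = sorted(m.values.columns)
        groups = {}
        for c, k in zip(cols, two):
            groups.setdefault(k, set()).add(c.split("_")[0])
        assert sorted(map(sorted, groups.values())) == [["g1"], ["g2"]]

        coph_oracle = naive_upgma_cophenetic(res.distance, cols)
        coph_impl = sch.cophenet(res.linkage)
        idx = {c: i for i, c in enumerate(cols)}
        from scipy.spatial.distance import squareform

        impl_matrix = squareform(coph_impl)
        for pair, h in coph_oracle.items():
            a, b = sorted(pair)
            assert impl_matrix[idx[a], idx[b]] == pytest.approx(h)

    def test_newick_is_parseable_and_covers_all_samples(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        m = self._two_group_matrix()
        res = hcluster(m)
        tree = Phylo.read(StringIO(res.newick), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == sorted(m.values.columns)


class TestCommunitySummary:
    def test_single_group_gets_everything(self):
        m = make_matrix({"s1": [3.0, 7.0]}, {"s1": "A"})
        frac = community_summary(m, {0: "g", 1: "g"})
        assert frac.loc["g", "s1"] == pytest.approx(1.0)

    def test_two_group_hand_example(self):
        m = make_matrix({"s1": [30.0, 20.0, 50.0]}, {"s1": "A"})
        frac = community_summary(m, {0: "fungi", 1: "fungi", 2: "bacteria"})
        assert frac.loc["fungi", "s1"] == pytest.approx(0.5)
        assert frac.loc["bacteria", "s1"] == pytest.approx(0.5)
        assert frac["s1"].sum() == pytest.approx(1.0)

    def test_unmapped_feature_is_error(self):
        m = make_matrix({"s1": [1.0, 1.0]}, {"s1": "A"})
        with pytest.raises(ValueError, match="unmapped"):
            community_summary(m, {0: "g"})
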