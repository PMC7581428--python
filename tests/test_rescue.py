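import itertools

import numpy as np
import pandas as pd
import pytest

from cagdyn.expression import (
    FilterConfig,
    de_test,
    filter_genes,
    normalize_log_cpm,
)
from cagdyn.rescue import (
    ConcordanceResult,
    DirectionalOverlap,
    RescueResult,
    cross_study_concordance,
    directional_overlap,
    geneset_enrichment,
    overlap_fisher,
    read_gmt,
    relative_impact_permutation,
    rescue_classify,
)
from cagdyn.synthetic import CountSimParams, simulate_count_matrix


def deg_table(genes, lfc, p):
    p = np.asarray(p, dtype=float)
    return pd.DataFrame(
        {
            "log2fc": np.asarray(lfc, dtype=float),
            "p": p,
            "fdr": np.minimum(p * len(p), 1.0),
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestDirectionalOverlap:
    def test_disjoint_significant_sets(self):
        a = deg_table(["g1", "g2"], [1, 1], [0.001, 0.9])
        b = deg_table(["g1", "g2"], [1, 1], [0.9, 0.001])
        ov = directional_overlap(a, b)
        assert ov.n_total_overlap == 0
        assert all(c == 0 for c in ov.counts.values())

    def test_hand_tally_12_genes(self):
        genes = [f"g{i}" for i in range(12)]
        # 3 up/up, 2 up/down, 4 down/up, 1 down/down, 2 not significant
        lfc_a = [1, 1, 1, 1, 1, -1, -1, -1, -1, -1, 1, -1]
        lfc_b = [1, 1, 1, -1, -1, 1, 1, 1, 1, -1, 1, -1]
        p_a = [0.01] * 10 + [0.5, 0.5]
        p_b = [0.01] * 10 + [0.01, 0.01]
        ov = directional_overlap(
            deg_table(genes, lfc_a, p_a), deg_table(genes, lfc_b, p_b)
        )
        assert ov.counts == {
            "up_up": 3,
            "up_down": 2,
            "down_up": 4,
            "down_down": 1,
        }
        assert ov.n_total_overlap == 10

    def test_cells_always_sum_to_total(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(300)]
        a = deg_table(genes, rng.normal(size=300), rng.uniform(size=300))
        b = deg_table(genes, rng.normal(size=300), rng.uniform(size=300))
        ov = directional_overlap(a, b)
        assert sum(ov.counts.values()) == ov.n_total_overlap

    def test_zero_lfc_excluded_and_reported(self):
        a = deg_table(["g1"], [0.0], [0.01])
        b = deg_table(["g1"], [1.0], [0.01])
        ov = directional_overlap(a, b)
        assert ov.n_total_overlap == 0
        assert ov.zero_lfc_genes == ("g1",)

    def test_bad_alpha(self):
        a = deg_table(["g1"], [1.0], [0.01])
        with pytest.raises(ValueError):
            directional_overlap(a, a, alpha=1.5)


class TestOverlapFisher:
    def test_zero_overlap_p_one(self):
        a = deg_table(["g1", "g2"], [1, 1], [0.001, 0.9])
        b = deg_table(["g1", "g2"], [1, 1], [0.9, 0.001])
        assert overlap_fisher(a, b).p_one_sided == pytest.approx(1.0)

    def test_matches_hypergeometric_toy(self):
        # N=10 universe, K=3 sig in a, n=3 sig in b, k=2 joint
        genes = [f"g{i}" for i in range(10)]
        p_a = [0.01, 0.01, 0.01] + [0.9] * 7
        p_b = [0.01, 0.01, 0.9, 0.01] + [0.9] * 6
        res = overlap_fisher(
            deg_table(genes, [1] * 10, p_a), deg_table(genes, [1] * 10, p_b)
        )
        assert (res.overlap_k, res.query_size_K, res.draw_size_n) == (2, 3, 3)
        assert res.p_one_sided == pytest.approx(22 / 120)

    def test_identical_tables_saturated(self):
        genes = [f"g{i}" for i in range(8)]
        p = [0.01] * 3 + [0.9] * 5
        a = deg_table(genes, [1] * 8, p)
        res = overlap_fisher(a, a)
        assert res.overlap_k == res.query_size_K == res.draw_size_n == 3

    def test_empty_universe(self):
        a = deg_table(["g1"], [1], [0.5])
        b = deg_table(["x1"], [1], [0.5])
        with pytest.raises(ValueError, match="universe"):
            overlap_fisher(a, b)


class TestRescueClassify:
    @pytest.fixture()
    def sim(self):
        params = CountSimParams(
            n_genes=800,
            dispersion=0.05,
            lfc_magnitude=2.0,
            fractions={"rescued": 0.05, "exacerbated": 0.05},
            seed=21,
        )
        cm, meta, truth = simulate_count_matrix(params)
        kept = filter_genes(cm, meta, FilterConfig())
        deg3 = de_test(kept, meta, 3)
        deg2 = de_test(kept, meta, 2)
        ov = directional_overlap(deg3, deg2, 0.05)
        expr = normalize_log_cpm(kept)
        return meta, truth, ov, expr

    def test_partitions_overlap_exactly(self, sim):
        meta, truth, ov, expr = sim
        res = rescue_classify(expr, meta, ov)
        classified = (
            list(res.rescued_opposite_up)
            + list(res.rescued_opposite_down)
            + list(res.not_normalized)
        )
        all_overlap = [g for cell in ov.genes.values() for g in cell] + list(
            ov.zero_lfc_genes
        )
        assert sorted(classified) == sorted(all_overlap)
        assert len(classified) == len(set(classified))

    def test_planted_rescued_recovered(self, sim):
        meta, truth, ov, expr = sim
        res = rescue_classify(expr, meta, ov)
        reported = set(res.rescued_opposite_up) | set(res.rescued_opposite_down)
        planted = set(truth.genes_of_class("rescued_up")) | set(
            truth.genes_of_class("rescued_down")
        )
        assert len(reported & planted) / len(planted) > 0.5

    def test_persistent_difference_not_rescued(self, sim):
        # exacerbated genes differ at the endpoints by 2x lfc -> never rescued
        meta, truth, ov, expr = sim
        res = rescue_classify(expr, meta, ov)
        reported = set(res.rescued_opposite_up) | set(res.rescued_opposite_down)
        assert not reported & set(truth.genes_of_class("exacerbated"))

    def test_same_direction_gene_never_rescued(self, toy_meta):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(5, 0.1, size=(1, 12)),
            index=["g1"],
            columns=list(toy_meta.table.index),
        )
        ov = DirectionalOverlap(
            alpha=0.05,
            counts={"up_up": 1, "up_down": 0, "down_up": 0, "down_down": 0},
            genes={
                "up_up": ("g1",),
                "up_down": (),
                "down_up": (),
                "down_down": (),
            },
        )
        res = rescue_classify(expr, toy_meta, ov)
        assert res.n_rescued == 0
        assert res.not_normalized == ("g1",)
        assert res.endpoint_p["g1"] > 0.05  # equal endpoints, yet not rescued

    def test_opposite_gene_with_equal_endpoints_rescued(self, toy_meta):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(5, 0.1, size=(1, 12)),
            index=["g1"],
            columns=list(toy_meta.table.index),
        )
        ov = DirectionalOverlap(
            alpha=0.05,
            counts={"up_up": 0, "up_down": 1, "down_up": 0, "down_down": 0},
            genes={
                "up_up": (),
                "up_down": ("g1",),
                "down_up": (),
                "down_down": (),
            },
        )
        res = rescue_classify(expr, toy_meta, ov)
        assert res.rescued_opposite_up == ("g1",)

    def test_missing_group_errors(self, toy_meta):
        expr = pd.DataFrame(
            np.ones((1, 3)),
            index=["g1"],
            columns=[f"WT_WT_s{j:02d}" for j in (1, 2, 3)],
        )
        ov = DirectionalOverlap(
            alpha=0.05,
            counts={c: 0 for c in ("up_up", "up_down", "down_up", "down_down")},
            genes={c: () for c in ("up_up", "up_down", "down_up", "down_down")},
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            rescue_classify(expr, toy_meta, ov)


def permutation_oracle(reduced, set_idx, k):
    """Exact tail probability over all k-subsets of the universe."""
    observed = sum(reduced[i] for i in set_idx)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(len(reduced)), k):
        stat = sum(reduced[i] for i in combo)
        hits += stat >= observed
        total += 1
    return hits / total


class TestRelativeImpactPermutation:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        wt = {g: float(rng.normal()) for g in genes}
        ko = {g: float(rng.normal()) for g in genes}
        gene_set = ["g0", "g3", "g7"]
        universe = sorted(genes)
        reduced = [abs(ko[g]) < abs(wt[g]) for g in universe]
        set_idx = [universe.index(g) for g in gene_set]
        exact = permutation_oracle(reduced, set_idx, 3)
        res = relative_impact_permutation(wt, ko, gene_set, n_perm=40_000, seed=1)
        assert res.p_empirical == pytest.approx(exact, abs=0.02)

    def test_all_reduced_extreme_case(self):
        wt = {f"g{i}": 1.0 for i in range(200)}
        ko = dict(wt)
        gene_set = [f"g{i}" for i in range(5)]
        for g in gene_set:
            ko[g] = 0.5
        res = relative_impact_permutation(wt, ko, gene_set, n_perm=1000, seed=2)
        assert res.observed_stat == 5
        assert res.p_empirical == pytest.approx(1 / 1001)

    def test_ties_count_as_no_reduction(self):
        wt = {f"g{i}": 1.0 for i in range(10)}
        ko = dict(wt)  # all ties
        res = relative_impact_permutation(
            wt, ko, ["g0", "g1"], n_perm=100, seed=3
        )
        assert res.observed_stat == 0
        assert res.p_empirical == pytest.approx(1.0)

    def test_bit_identical_under_seed(self):
        rng = np.random.default_rng(4)
        wt = {f"g{i}": float(rng.normal()) for i in range(50)}
        ko = {g: float(rng.normal()) for g in wt}
        a = relative_impact_permutation(wt, ko, ["g1", "g2"], 500, seed=9)
        b = relative_impact_permutation(wt, ko, ["g1", "g2"], 500, seed=9)
        assert a == b

    def test_set_outside_universe(self):
        wt = {"g1": 1.0, "g2": 1.0, "g3": 1.0}
        ko = {"g1": 0.5, "g2": 0.5, "g3": 0.5}
        with pytest.raises(ValueError, match="universe"):
            relative_impact_permutation(wt, ko, ["gX"], 10, seed=0)

    def test_p_in_valid_range(self):
        rng = np.random.default_rng(5)
        wt = {f"g{i}": float(rng.normal()) for i in range(30)}
        ko = {g: float(rng.normal()) for g in wt}
        res = relative_impact_permutation(wt, ko, ["g0", "g5"], 200, seed=0)
        assert 1 / 201 <= res.p_empirical <= 1.0


class TestConcordance:
    def test_identical_tables(self):
        genes = [f"g{i}" for i in range(6)]
        a = deg_table(genes, [1, -1, 1, -1, 1, -1], [0.001] * 4 + [0.9] * 2)
        res = cross_study_concordance(a, a, threshold_mode="nominal_p")
        assert res.n_opposite == 0
        assert res.n_common == 4

    def test_hand_tally(self):
        genes = [f"g{i}" for i in range(7)]
        lfc_a = [1, 1, -1, -1, -1, 1, 1]
        lfc_b = [1, 1, -1, -1, -1, -1, 1]
        p = [0.001] * 6 + [0.9]
        res = cross_study_concordance(
            deg_table(genes, lfc_a, p),
            deg_table(genes, lfc_b, p),
            threshold_mode="nominal_p",
        )
        assert (res.n_both_up, res.n_both_down, res.n_opposite) == (2, 3, 1)
        assert res.n_common == 6

    def test_additivity_invariant(self):
        res = ConcordanceResult("fdr", n_both_up=11, n_both_down=18, n_opposite=0)
        assert res.n_common == 29


class TestGenesetEnrichment:
    def test_disjoint_set_p_one(self):
        table = geneset_enrichment(
            ["g1"], [f"g{i}" for i in range(1, 11)], {"s": ["g5", "g6"]}
        )
        assert table.loc["s", "p"] == pytest.approx(1.0)

    def test_enumeration_toy(self):
        background = [f"g{i}" for i in range(20)]
        query = background[:10]
        sets = {"half": background[:10]}
        table = geneset_enrichment(query, background, sets)
        from cagdyn.stats_core import fisher_one_sided

        assert table.loc["half", "p"] == pytest.approx(
            fisher_one_sided(10, 10, 10, 20).p_one_sided
        )

    def test_query_outside_background_errors(self):
        with pytest.raises(ValueError, match="absent"):
            geneset_enrichment(["gX"], ["g1"], {})

    def test_empty_set_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            table = geneset_enrichment(
                ["g1"], ["g1", "g2"], {"empty": ["zz"], "ok": ["g1"]}
            )
        assert list(table.index) == ["ok"]

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(6)
        background = [f"g{i}" for i in range(50)]
        query = list(rng.choice(background, size=10, replace=False))
        sets = {
            f"s{j}": list(rng.choice(background, size=8, replace=False))
            for j in range(5)
        }
        table = geneset_enrichment(query, background, sets)
        assert (table["fdr"] >= table["p"] - 1e-12).all()

    def test_read_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        sets = read_gmt(path)
        assert sets == {"setA": ("g1", "g2"), "setB": ("g3",)}


class TestRescueResultContract:
    def test_partition_counts(self):
        res = RescueResult(
            rescued_opposite_up=tuple(f"u{i}" for i in range(55)),
            rescued_opposite_down=tuple(f"d{i}" for i in range(97)),
            not_normalized=tuple(f"n{i}" for i in range(368)),
        )
        assert res.n_rescued == 152
        assert res.n_total == 520
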