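"""Enrichment engine vs brute-force oracles; permutation-null calibration."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hdacsig.gsea import (
    EnrichmentResult,
    RankedList,
    enrichment_score,
    leading_edge,
    nominal_p,
    normalize_and_fdr,
    permutation_null,
    run_gsea,
)
from hdacsig.types import GeneSet, GeneSetCollection


def brute_force_es(metric, hit_mask, p_weight):
    """Independent running-sum evaluator: explicit Python loop."""
    n = len(metric)
    n_hits = int(sum(hit_mask))
    denom = sum(abs(metric[i]) ** p_weight for i in range(n) if hit_mask[i])
    running, best, best_i = 0.0, 0.0, 0
    values = []
    for i in range(n):
        if hit_mask[i]:
            running += (abs(metric[i]) ** p_weight) / denom if denom else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        values.append(running)
        if abs(running) > abs(best):
            best, best_i = running, i
    return best, values, best_i


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.standard_normal(n))[::-1]
    return RankedList([f"g{i}" for i in range(n)], metric)


class TestEnrichmentScore:
    def test_whole_list_set_gives_es_one(self):
        ranked = _ranked(10)
        es, running, peak = enrichment_score(ranked, set(ranked.gene_ids))
        assert es == pytest.approx(1.0)
        assert peak == 9

    def test_hand_computed_singleton_case(self):
        # metrics (3,2,1,0.5), set {g4}: running sum (-1/3, -2/3, -1, 0), ES=-1
        ranked = RankedList(["g1", "g2", "g3", "g4"], np.array([3.0, 2.0, 1.0, 0.5]))
        es, running, peak = enrichment_score(ranked, {"g4"}, p_weight=1.0)
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12)
        assert es == pytest.approx(-1.0, abs=1e-12)
        assert peak == 2
        assert leading_edge(ranked, {"g4"}, running, peak) == ["g4"]

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(_ranked(5), {"absent"})

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = rng.integers(5, 50)
            ranked = _ranked(n, seed=rng.integers(1e6))
            size = rng.integers(1, n)
            hit_idx = rng.choice(n, size=size, replace=False)
            gene_set = {ranked.gene_ids[i] for i in hit_idx}
            p_weight = float(rng.choice([0.0, 1.0, 1.5]))
            es, running, peak = enrichment_score(ranked, gene_set, p_weight)
            mask = [g in gene_set for g in ranked.gene_ids]
            es_o, running_o, peak_o = brute_force_es(ranked.metric, mask, p_weight)
            assert es == pytest.approx(es_o, abs=1e-12)
            assert peak == peak_o
            np.testing.assert_allclose(running, running_o, atol=1e-12)

    def test_p_weight_zero_equals_ks_statistic(self):
        """Unweighted ES reduces to the classical two-sample KS statistic
        between hit and miss rank distributions."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            ranked = _ranked(n, seed=int(rng.integers(1e6)))
            size = int(rng.integers(2, n - 2))
            hit_idx = np.sort(rng.choice(n, size=size, replace=False))
            gene_set = {ranked.gene_ids[i] for i in hit_idx}
            es, _, _ = enrichment_score(ranked, gene_set, p_weight=0.0)
            miss_idx = np.setdiff1d(np.arange(n), hit_idx)
            ks = stats.ks_2samp(hit_idx, miss_idx).statistic
            assert abs(es) == pytest.approx(ks, abs=1e-12)

    def test_reversal_antisymmetry_unweighted(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(8, 40))
            ranked = _ranked(n, seed=int(rng.integers(1e6)))
            size = int(rng.integers(1, n))
            gene_set = set(rng.choice(ranked.gene_ids, size=size, replace=False))
            es_fwd, running, _ = enrichment_score(ranked, gene_set, p_weight=0.0)
            rev = RankedList(ranked.gene_ids[::-1], -ranked.metric[::-1])
            es_rev, _, _ = enrichment_score(rev, gene_set, p_weight=0.0)
            assert abs(es_fwd) == pytest.approx(abs(es_rev), abs=1e-12)
            # the sign flips exactly unless the extreme positive and negative
            # deviations tie in magnitude (then the first-peak rule wins)
            if abs(running.max() + running.min()) > 1e-12:
                assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    @given(
        n=st.integers(6, 40),
        size=st.integers(1, 5),
        seed=st.integers(0, 10_000),
        p_weight=st.sampled_from([0.0, 0.5, 1.0, 2.0]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_es_bounded_and_leading_edge_contained(self, n, size, seed, p_weight):
        ranked = _ranked(n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        gene_set = set(rng.choice(ranked.gene_ids, size=min(size, n - 1), replace=False))
        es, running, peak = enrichment_score(ranked, gene_set, p_weight)
        assert abs(es) <= 1.0 + 1e-12
        le = leading_edge(ranked, gene_set, running, peak)
        assert set(le) <= gene_set


class TestPermutationNull:
    def test_p_floor_from_add_one_estimator(self):
        ranked = _ranked(30, seed=0)
        es = 0.99
        null = np.full(99, 0.1)
        assert nominal_p(es, null) == pytest.approx(1 / 100)

    def test_full_universe_set_null_all_ones(self):
        ranked = _ranked(12)
        null = permutation_null(ranked, set(ranked.gene_ids), n_perm=20, seed=0)
        np.testing.assert_allclose(null, 1.0)

    def test_nperm_zero_errors(self):
        ranked = _ranked(10)
        with pytest.raises(ValueError):
            permutation_null(ranked, {"g1"}, n_perm=0)

    def test_deterministic_under_seed(self):
        ranked = _ranked(40, seed=3)
        gs = {"g1", "g5", "g9"}
        a = permutation_null(ranked, gs, n_perm=50, seed=11)
        b = permutation_null(ranked, gs, n_perm=50, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_null_p_values_uniform(self):
        """Random sets on a null ranking: nominal p ~ U(0,1)."""
        ranked = _ranked(400, seed=21)
        rng = np.random.default_rng(22)
        ps = []
        for i in range(500):
            gs = set(rng.choice(ranked.gene_ids, size=15, replace=False))
            es, _, _ = enrichment_score(ranked, gs)
            null = permutation_null(ranked, gs, n_perm=99, seed=i)
            ps.append(nominal_p(es, null))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_phenotype_mode_reranks(self, small_panel):
        expr, resp, _, pathways, _ = small_panel
        from hdacsig.selection import dichotomize_response
        from hdacsig import sam as _sam

        labels = dichotomize_response(resp, resp.drug_ids[0])
        two = labels[labels != "intermediate"]
        sub = type(expr)(expr.data[two.index])
        res = _sam.compute_sam(sub, two.to_numpy())
        ranked = RankedList.from_series(_sam.rank_genes(res))
        gs = set(pathways[pathways.names[0]].genes)
        null = permutation_null(
            ranked, gs, n_perm=5, mode="phenotype", seed=0,
            expr=sub, labels=two.to_numpy(),
        )
        assert len(null) == 5 and np.all(np.abs(null) <= 1)


class TestNormalizeAndFdr:
    def test_nes_is_es_over_same_sign_null_mean(self):
        res = EnrichmentResult(set_name="S", es=0.5)
        nulls = {"S": np.array([0.25, 0.25, 0.25, -0.4])}
        out = normalize_and_fdr([res], nulls)[0]
        assert out.nes == pytest.approx(0.5 / 0.25)

    def test_single_set_q_equals_exceedance_fraction(self):
        res = EnrichmentResult(set_name="S", es=0.5)
        null = np.array([0.6, 0.4, 0.2, 0.25, 0.5])
        out = normalize_and_fdr([res], {"S": null})[0]
        nes = 0.5 / null.mean()
        null_nes = null / null.mean()
        expected = min(1.0, (null_nes >= nes).mean() / 1.0)
        assert out.q_fdr == pytest.approx(expected)

    def test_no_same_sign_null_flagged(self):
        res = EnrichmentResult(set_name="S", es=0.5)
        out = normalize_and_fdr([res], {"S": np.array([-0.3, -0.2])})[0]
        assert out.nes is None and out.q_fdr == 1.0

    def test_planted_set_attains_top_nes(self):
        """A set planted at the top of the ranking beats 30 random sets."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            metric = np.sort(rng.standard_normal(n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            planted = GeneSet("PLANTED", "", tuple(f"g{i}" for i in rng.choice(40, 12, replace=False)))
            randoms = [
                GeneSet(f"R{j}", "", tuple(f"g{i}" for i in rng.choice(n, 12, replace=False)))
                for j in range(30)
            ]
            ranked = RankedList(genes, metric)
            results = run_gsea(ranked, GeneSetCollection([planted] + randoms),
                               n_perm=100, seed=seed)
            best = max(results, key=lambda r: abs(r.nes or 0))
            wins += best.set_name == "PLANTED"
        assert wins >= 9

    def test_null_joint_call_rate_low(self):
        """Null ranking, many random sets: p<0.01 & q<0.05 jointly rare."""
        rng = np.random.default_rng(33)
        n = 400
        ranked = _ranked(n, seed=34)
        sets = [
            GeneSet(f"R{j}", "", tuple(f"g{i}" for i in rng.choice(n, 15, replace=False)))
            for j in range(100)
        ]
        results = run_gsea(ranked, GeneSetCollection(sets), n_perm=100, seed=35)
        joint = [r for r in results if r.p_nominal < 0.01 and r.q_fdr < 0.05]
        assert len(joint) / len(results) <= 0.02


class TestLeadingEdge:
    def test_whole_set_when_es_one(self):
        ranked = _ranked(8)
        gs = set(ranked.gene_ids)
        es, running, peak = enrichment_score(ranked, gs)
        assert leading_edge(ranked, gs, running, peak) == ranked.gene_ids

    def test_order_preserved_from_ranking(self):
        ranked = _ranked(20, seed=2)
        gs = {"g2", "g5", "g11"}
        es, running, peak = enrichment_score(ranked, gs)
        le = leading_edge(ranked, gs, running, peak)
        positions = [ranked.gene_ids.index(g) for g in le]
        assert positions == sorted(positions)
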