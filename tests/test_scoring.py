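"""Signature derivation, the weighted-average score, Welch associations."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hdacsig.gsea import EnrichmentResult
from hdacsig.scoring import (
    associate_scores,
    association_panel,
    combine_signatures,
    derive_signature,
    gene_direction_t,
    score_samples,
    validate_cohort,
)
from hdacsig.types import ExpressionMatrix, ScoreVector, Signature


def _expr(values, genes=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestDeriveSignature:
    def _enr(self, name, genes):
        return EnrichmentResult(set_name=name, es=0.5, leading_edge=list(genes))

    def test_direction_rule(self):
        t = pd.Series({"A": 2.0, "B": -1.0})
        sig = derive_signature([self._enr("P", ["A", "B"])], t)
        assert sig.up_genes == ("A",) and sig.down_genes == ("B",)

    def test_gene_in_two_pathways_appears_once(self):
        t = pd.Series({"A": 2.0, "B": 1.0})
        sig = derive_signature(
            [self._enr("P1", ["A", "B"]), self._enr("P2", ["A"])], t
        )
        assert sorted(sig.up_genes) == ["A", "B"]

    def test_t_zero_excluded(self):
        t = pd.Series({"A": 2.0, "B": 0.0})
        sig = derive_signature([self._enr("P", ["A", "B"])], t)
        assert "B" not in sig.up_genes + sig.down_genes

    def test_disjoint_combination_sums_sizes(self):
        a = Signature("BCAA", ("A", "B"), ("C",))
        b = Signature("FA", ("D",), ("E", "F"))
        combined = combine_signatures(a, b, "BCAA_FA")
        assert len(combined) == len(a) + len(b)

    def test_direction_conflict_drops_gene(self):
        a = Signature("X", ("A", "B"), ())
        b = Signature("Y", (), ("A",))
        combined = combine_signatures(a, b, "XY")
        assert "A" not in combined.up_genes + combined.down_genes
        assert combined.up_genes == ("B",)

    def test_empty_union_errors(self):
        t = pd.Series({"A": 1.0})
        with pytest.raises(ValueError):
            derive_signature([self._enr("P", [])], t)


class TestScoreSamples:
    def test_literal_formula_example(self):
        # up={A,B}, down={C}, e=(4,6,2): (4+6-2)/3 = 8/3
        expr = _expr([[4.0], [6.0], [2.0]], genes=["A", "B", "C"])
        sig = Signature("S", ("A", "B"), ("C",))
        sv = score_samples(expr, sig, mode="raw")
        assert sv.scores.iloc[0] == pytest.approx(8 / 3, abs=1e-12)

    def test_swap_up_down_negates(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.standard_normal((6, 5)))
        sig = Signature("S", ("g0", "g1"), ("g2", "g3"))
        flipped = Signature("S2", ("g2", "g3"), ("g0", "g1"))
        s1 = score_samples(expr, sig, mode="raw").scores
        s2 = score_samples(expr, flipped, mode="raw").scores
        np.testing.assert_allclose(s1.to_numpy(), -s2.to_numpy(), atol=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_genes = int(rng.integers(4, 15))
            n_samples = int(rng.integers(2, 8))
            expr = _expr(rng.standard_normal((n_genes, n_samples)))
            genes = list(expr.gene_ids)
            rng.shuffle(genes)
            n_up = int(rng.integers(1, n_genes))
            sig = Signature("S", tuple(genes[:n_up]), tuple(genes[n_up:]))
            sv = score_samples(expr, sig, mode="raw")
            for j, s in enumerate(expr.sample_ids):
                brute = (
                    sum(expr.data.loc[g, s] for g in sig.up_genes)
                    - sum(expr.data.loc[g, s] for g in sig.down_genes)
                ) / (len(sig.up_genes) + len(sig.down_genes))
                assert sv.scores[s] == pytest.approx(brute, abs=1e-12)

    def test_unmatched_genes_dropped_from_denominator(self):
        expr = _expr([[4.0], [6.0]], genes=["A", "B"])
        sig = Signature("S", ("A", "B", "MISSING"), ())
        sv = score_samples(expr, sig, mode="raw")
        assert sv.scores.iloc[0] == pytest.approx((4 + 6) / 2)

    def test_no_matched_genes_errors(self):
        expr = _expr([[1.0]], genes=["A"])
        sig = Signature("S", ("X",), ("Y",))
        with pytest.raises(ValueError):
            score_samples(expr, sig)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_raw_score_linearity(self, seed):
        """Scoring a sum of matrices equals the sum of scores (raw mode)."""
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((5, 3))
        b = rng.standard_normal((5, 3))
        sig = Signature("S", ("g0", "g2"), ("g4",))
        s_a = score_samples(_expr(a), sig, mode="raw").scores.to_numpy()
        s_b = score_samples(_expr(b), sig, mode="raw").scores.to_numpy()
        s_ab = score_samples(_expr(a + b), sig, mode="raw").scores.to_numpy()
        np.testing.assert_allclose(s_ab, s_a + s_b, atol=1e-10)


class TestAssociateScores:
    def _sv(self, values, samples=None):
        samples = samples or [f"s{i}" for i in range(len(values))]
        return ScoreVector(pd.Series(values, index=samples, dtype=float), "S", "raw")

    def test_welch_hand_example(self):
        # {1,2,3} vs {2,3,4}: t = -1/sqrt(2/3) = -1.224745, df = 4
        sv = self._sv([1, 2, 3, 2, 3, 4])
        labels = pd.Series(
            ["sensitive"] * 3 + ["resistant"] * 3, index=sv.scores.index
        )
        rec = associate_scores(sv, labels)
        assert rec["t"] == pytest.approx(-1.2247448713915892, abs=1e-12)
        assert rec["df"] == pytest.approx(4.0, abs=1e-12)
        assert rec["direction"] == "resistance-linked"

    def test_identical_groups_t_zero_p_one(self):
        sv = self._sv([1, 2, 1, 2])
        labels = pd.Series(["sensitive"] * 2 + ["resistant"] * 2, index=sv.scores.index)
        rec = associate_scores(sv, labels)
        assert rec["t"] == pytest.approx(0.0) and rec["p"] == pytest.approx(1.0)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(1000):
            sv = self._sv(rng.standard_normal(24))
            labels = pd.Series(["sensitive"] * 12 + ["resistant"] * 12,
                               index=sv.scores.index)
            ps.append(associate_scores(sv, labels)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_member_class_errors(self):
        sv = self._sv([1, 2, 3])
        labels = pd.Series(["sensitive", "resistant", "resistant"], index=sv.scores.index)
        with pytest.raises(ValueError):
            associate_scores(sv, labels)


class TestAssociationPanel:
    def test_missing_drug_isolated(self):
        rng = np.random.default_rng(10)
        sv = ScoreVector(pd.Series(rng.standard_normal(12),
                                   index=[f"s{i}" for i in range(12)]), "S", "raw")
        good = pd.Series(["sensitive"] * 6 + ["resistant"] * 6, index=sv.scores.index)
        bad = pd.Series(["intermediate"] * 12, index=sv.scores.index)
        table = association_panel([sv], {"ok": good, "broken": bad})
        assert table.loc[("S", "broken"), "direction"] == "missing"
        assert np.isfinite(table.loc[("S", "ok"), "p"])

    def test_null_significant_count_near_alpha_expectation(self):
        """effect 0: ~0.4 of 8 drugs expected significant at a=0.05."""
        rng = np.random.default_rng(11)
        counts = []
        for _ in range(100):
            sv = ScoreVector(pd.Series(rng.standard_normal(60),
                                       index=[f"s{i}" for i in range(60)]), "S", "raw")
            drug_labels = {}
            for d in range(8):
                perm = rng.permutation(60)
                lab = np.array(["intermediate"] * 60, dtype=object)
                lab[perm[:20]] = "sensitive"
                lab[perm[20:40]] = "resistant"
                drug_labels[f"d{d}"] = pd.Series(lab, index=sv.scores.index)
            table = association_panel([sv], drug_labels)
            counts.append(int((table["p"] < 0.05).sum()))
        assert abs(np.mean(counts) - 0.4) < 0.3


class TestValidateCohort:
    def test_identical_expression_errors(self):
        expr = _expr(np.ones((4, 8)))
        sig = Signature("S", ("g0", "g1"), ("g2",))
        labels = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=expr.sample_ids)
        with pytest.raises(ValueError):
            validate_cohort(expr, labels, sig)

    def test_low_coverage_flagged(self, caplog):
        rng = np.random.default_rng(12)
        expr = _expr(rng.standard_normal((2, 8)), genes=["g0", "g1"])
        sig = Signature("S", ("g0", "g1", "x1", "x2", "x3"), ())
        labels = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=expr.sample_ids)
        with caplog.at_level("WARNING"):
            out = validate_cohort(expr, labels, sig)
        assert out["low_coverage"] and out["coverage"] == pytest.approx(0.4)

    def test_permuted_labels_p_uniform(self):
        from hdacsig.simulate import SimulationSpec, simulate_cohort, simulate_panel

        spec = SimulationSpec(n_genes=200, n_samples=60, n_pathways=3,
                              genes_per_pathway=10, n_causal_pathways=2,
                              effect_size=1.5, n_drugs=2, seed=0, cohort_size=16)
        _, _, _, _, truth = simulate_panel(spec)
        sig = truth.true_signature()
        rng = np.random.default_rng(13)
        ps = []
        for s in range(500):
            spec_s = SimulationSpec(**{**spec.__dict__, "seed": s})
            cexpr, labels = simulate_cohort(spec_s, sig, n_background=30)
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            if perm.sum() < 2 or (1 - perm).sum() < 2:
                continue
            ps.append(validate_cohort(cexpr, perm, sig)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
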