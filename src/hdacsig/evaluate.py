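"""Recovery and calibration benchmarks on panels with planted ground truth.

These helpers run whole pipeline stages on simulated data and score them
against the generator's ground truth: does the elastic net retain exactly
the causal pathways, does the derived signature point the planted way, how
many drugs show the sensitivity-linked association, does the small-cohort
validation reach significance, and are all the null-statistics calibrated.
They back both the test suite and the reproduction script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import gsea, sam, scoring, selection
from .simulate import SimulationSpec, simulate_cohort, simulate_panel
from .types import ExpressionMatrix

__all__ = ["recovery_run", "gsea_null_calibration", "sam_null_fdr", "welch_null_ps"]


def recovery_run(spec: SimulationSpec, n_perm: int = 100) -> dict:
    """One planted-panel pipeline pass scored against ground truth.

    Returns causal-retention flags, false-positive count, signature
    direction agreement, the number of drugs with a significant
    sensitivity-linked association, and the cohort-validation p.
    """
    expr, resp, _, pathways, truth = simulate_panel(spec)

    scores = selection.pathway_scores(expr, pathways)
    sel = selection.elastic_net_select(scores, resp, seed=spec.seed)
    causal = set(truth.causal_pathway_names)
    got = set(sel.retained_pathways)

    drug_labels = {d: selection.dichotomize_response(resp, d) for d in resp.drug_ids}
    anchor = drug_labels[resp.drug_ids[0]]
    two_group = anchor[anchor != "intermediate"]
    sub = ExpressionMatrix(expr.data[two_group.index])
    sam_res = sam.compute_sam(sub, two_group.to_numpy())
    ranked = gsea.RankedList.from_series(sam.rank_genes(sam_res))

    source = sorted(got) if got else sorted(causal)
    enr = gsea.run_gsea(ranked, pathways.subset(source), n_perm=n_perm, seed=spec.seed)
    direction_t = scoring.gene_direction_t(sub, two_group)
    signature = scoring.derive_signature(enr, direction_t, name="GES")

    dirs = truth.gene_sensitivity_directions
    votes = [
        (1 if g in signature.up_genes else -1) == dirs[g]
        for g in signature.up_genes + signature.down_genes
        if g in dirs
    ]
    agreement = float(np.mean(votes)) if votes else np.nan

    sv = scoring.score_samples(expr, signature)
    panel = scoring.association_panel([sv], drug_labels)
    n_sig = int(panel["significant_sensitivity_linked"].sum())

    cohort_expr, responders = simulate_cohort(spec, truth.true_signature())
    validation = scoring.validate_cohort(cohort_expr, responders, signature)

    return {
        "causal_retained": causal <= got,
        "n_false_retained": len(got - causal),
        "direction_agreement": agreement,
        "n_significant_drugs": n_sig,
        "n_drugs": len(drug_labels),
        "cohort_p": validation["p"],
    }


def gsea_null_calibration(
    n_sets: int = 500, n_genes: int = 400, set_size: int = 15,
    n_perm: int = 99, seed: int = 0,
) -> pd.DataFrame:
    """Nominal p and FDR q for random sets against a null ranking."""
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.standard_normal(n_genes))[::-1]
    genes = [f"g{i}" for i in range(n_genes)]
    ranked = gsea.RankedList(genes, metric)
    from .types import GeneSet, GeneSetCollection

    sets = [
        GeneSet(f"R{j}", "", tuple(f"g{i}" for i in rng.choice(n_genes, set_size, replace=False)))
        for j in range(n_sets)
    ]
    results = gsea.run_gsea(ranked, GeneSetCollection(sets), n_perm=n_perm, seed=seed + 1)
    return pd.DataFrame(
        {"p": [r.p_nominal for r in results], "q": [r.q_fdr for r in results]}
    )


def sam_null_fdr(
    n_reps: int = 20, n_genes: int = 200, n_per_group: int = 6,
    n_perm: int = 50, seed: int = 0, target_calls: int = 10,
) -> list[float]:
    """Estimated FDR at a ~5%-call delta on label-independent expression."""
    out = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        values = rng.standard_normal((n_genes, 2 * n_per_group))
        expr = ExpressionMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{j}" for j in range(2 * n_per_group)])
        )
        labels = ["A"] * n_per_group + ["B"] * n_per_group
        res = sam.compute_sam(expr, labels)
        curve = sam.fdr_curve(res, expr, labels,
                              deltas=np.linspace(0.02, 0.5, 12),
                              n_perm=n_perm, seed=seed + rep)
        curve = curve[curve["n_called"] > 0]
        if not len(curve):
            continue
        row = curve.iloc[(curve["n_called"] - target_calls).abs().argmin()]
        out.append(float(row["fdr"]))
    return out


def welch_null_ps(n_reps: int = 500, seed: int = 0, cohort: bool = False) -> list[float]:
    """Welch p under the null: effect-free panels or permuted cohort labels."""
    ps: list[float] = []
    if cohort:
        base = SimulationSpec(
            n_genes=200, n_samples=60, n_pathways=3, genes_per_pathway=10,
            n_causal_pathways=2, effect_size=0.0, n_drugs=2, cohort_size=16, seed=seed,
        )
        _, _, _, _, truth = simulate_panel(base)
        sig = truth.true_signature()
        for rep in range(n_reps):
            spec = SimulationSpec(**{**base.__dict__, "seed": seed + rep})
            cexpr, labels = simulate_cohort(spec, sig, n_background=30)
            ps.append(scoring.validate_cohort(cexpr, labels, sig)["p"])
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_reps):
            sv = scoring.ScoreVector(
                pd.Series(rng.standard_normal(60), index=[f"s{i}" for i in range(60)]),
                "S", "raw",
            )
            lab = np.array(["intermediate"] * 60, dtype=object)
            perm = rng.permutation(60)
            lab[perm[:20]] = "sensitive"
            lab[perm[20:40]] = "resistant"
            labels = pd.Series(lab, index=sv.scores.index)
            ps.append(scoring.associate_scores(sv, labels)["p"])
    return ps
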