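"""Gene-expression signature derivation, scoring and validation.

A signature is a pair of up- and down-regulated gene lists, built here from
the leading-edge genes of retained pathways with each gene's direction set
by the sign of its Welch t statistic (sensitive minus resistant) on the
training panel.  The per-sample score is the weighted average

    score(s) = ( sum_{g in up} e_{g,s} - sum_{g in down} e_{g,s} )
               / (|up| + |down|)

where e is per-gene z-scored expression by default (``mode="zscore"``) or
raw log2 values (``mode="raw"``).  Associations with drug sensitivity use
Welch's unequal-variance t-test, and cohort validation scores an
independent sample set with the signature frozen from training.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gsea import EnrichmentResult
from .types import ExpressionMatrix, ScoreVector, Signature

logger = logging.getLogger(__name__)

__all__ = [
    "gene_direction_t",
    "derive_signature",
    "score_samples",
    "associate_scores",
    "association_panel",
    "validate_cohort",
]


def gene_direction_t(
    expr: ExpressionMatrix, labels: pd.Series, genes: list[str] | None = None
) -> pd.Series:
    """Welch t per gene, sensitive minus resistant, on the training panel."""
    sens = labels.index[labels == "sensitive"]
    res = labels.index[labels == "resistant"]
    if len(sens) < 2 or len(res) < 2:
        raise ValueError("need >= 2 sensitive and >= 2 resistant samples")
    data = expr.data if genes is None else expr.data.loc[[g for g in genes if g in expr.data.index]]
    t, _ = stats.ttest_ind(
        data[sens].to_numpy(), data[res].to_numpy(), axis=1, equal_var=False
    )
    return pd.Series(t, index=data.index, name="t")


def derive_signature(
    enrichments: list[EnrichmentResult],
    direction_t: pd.Series,
    name: str = "GES",
) -> Signature:
    """Union of leading-edge genes, split into up/down by t sign.

    Genes with t = 0 (or no t value) are excluded with a log message; a gene
    appearing in several source pathways with conflicting derived directions
    cannot occur (direction is a function of the gene), but duplicates are
    collapsed.
    """
    pool: list[str] = []
    sources: dict[str, list[str]] = {}
    for res in enrichments:
        if not res.leading_edge:
            continue
        for g in res.leading_edge:
            if g not in sources:
                sources[g] = []
                pool.append(g)
            sources[g].append(res.set_name)
    if not pool:
        raise ValueError("no leading-edge genes to build a signature from")
    up, down = [], []
    for g in pool:
        t = direction_t.get(g, np.nan)
        if not np.isfinite(t) or t == 0:
            logger.info("gene %s: t = 0 or unavailable; excluded from signature", g)
            continue
        (up if t > 0 else down).append(g)
    if not up and not down:
        raise ValueError("all candidate genes had t = 0; empty signature")
    return Signature(
        name=name,
        up_genes=tuple(up),
        down_genes=tuple(down),
        provenance={"source_pathways": sorted({p for ps in sources.values() for p in ps})},
    )


def combine_signatures(a: Signature, b: Signature, name: str) -> Signature:
    """Set union of two signatures; direction conflicts drop the gene."""
    up = dict.fromkeys(list(a.up_genes) + list(b.up_genes))
    down = dict.fromkeys(list(a.down_genes) + list(b.down_genes))
    conflicts = set(up) & set(down)
    if conflicts:
        logger.warning(
            "combined signature %s: %d gene(s) with conflicting direction dropped",
            name, len(conflicts),
        )
    return Signature(
        name=name,
        up_genes=tuple(g for g in up if g not in conflicts),
        down_genes=tuple(g for g in down if g not in conflicts),
        provenance={"combined_from": [a.name, b.name]},
    )


def score_samples(
    expr: ExpressionMatrix, signature: Signature, mode: str = "zscore"
) -> ScoreVector:
    """The weighted-average signature score per sample.

    Unmatched signature genes are dropped from both the sums and the
    denominator count, with coverage logged.
    """
    if mode not in ("zscore", "raw"):
        raise ValueError(f"unknown score mode {mode!r}")
    data = expr.zscored().data if mode == "zscore" else expr.data
    up = [g for g in signature.up_genes if g in data.index]
    down = [g for g in signature.down_genes if g in data.index]
    matched = len(up) + len(down)
    if matched == 0:
        raise ValueError(f"signature {signature.name}: no genes matched in expression")
    if matched < len(signature):
        logger.warning(
            "signature %s: %d/%d genes matched", signature.name, matched, len(signature)
        )
    up_sum = data.loc[up].sum(axis=0) if up else 0.0
    down_sum = data.loc[down].sum(axis=0) if down else 0.0
    scores = (up_sum - down_sum) / matched
    return ScoreVector(
        scores=pd.Series(scores, index=data.columns, name=signature.name),
        signature_name=signature.name,
        mode=mode,
    )


def signature_coverage(expr: ExpressionMatrix, signature: Signature) -> float:
    matched = sum(g in expr.data.index for g in signature.up_genes + signature.down_genes)
    return matched / len(signature)


def associate_scores(scores: ScoreVector, labels: pd.Series) -> dict:
    """Welch t-test of scores between sensitive and resistant samples.

    ``direction`` is ``sensitivity-linked`` when the mean score is higher in
    the sensitive class.
    """
    common = scores.scores.index.intersection(labels.index)
    lab = labels.loc[common]
    sens = scores.scores.loc[common[lab == "sensitive"]]
    res = scores.scores.loc[common[lab == "resistant"]]
    if len(sens) < 2 or len(res) < 2:
        raise ValueError("each class needs >= 2 samples")
    if sens.std(ddof=1) == 0 and res.std(ddof=1) == 0:
        if sens.mean() == res.mean():
            return {"t": 0.0, "df": float(len(sens) + len(res) - 2), "p": 1.0,
                    "direction": "none", "n_sensitive": len(sens), "n_resistant": len(res)}
        raise ValueError("zero within-group variance; Welch t undefined")
    t, p = stats.ttest_ind(sens.to_numpy(), res.to_numpy(), equal_var=False)
    v1, v2 = sens.var(ddof=1) / len(sens), res.var(ddof=1) / len(res)
    df = (v1 + v2) ** 2 / (v1**2 / (len(sens) - 1) + v2**2 / (len(res) - 1))
    direction = "sensitivity-linked" if sens.mean() > res.mean() else "resistance-linked"
    return {
        "t": float(t), "df": float(df), "p": float(p), "direction": direction,
        "n_sensitive": int(len(sens)), "n_resistant": int(len(res)),
    }


def association_panel(
    score_vectors: list[ScoreVector],
    drug_labels: dict[str, pd.Series],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch record per (signature, drug) plus BH q per signature row.

    Rows where a drug has too few labelled samples are recorded as missing
    and excluded from the per-signature BH correction.
    """
    rows = []
    for sv in score_vectors:
        for drug, labels in drug_labels.items():
            try:
                rec = associate_scores(sv, labels)
            except ValueError as exc:
                logger.warning("signature %s, drug %s: %s", sv.signature_name, drug, exc)
                rec = {"t": np.nan, "df": np.nan, "p": np.nan, "direction": "missing"}
            rows.append({"signature": sv.signature_name, "drug": drug, **rec})
    table = pd.DataFrame(rows)
    table["q_bh"] = np.nan
    for sig_name, idx in table.groupby("signature").groups.items():
        p = table.loc[idx, "p"]
        ok = p.notna()
        if ok.any():
            table.loc[p.index[ok], "q_bh"] = multipletests(p[ok], method="fdr_bh")[1]
    table["significant_sensitivity_linked"] = (
        (table["p"] < alpha) & (table["direction"] == "sensitivity-linked")
    )
    return table.set_index(["signature", "drug"])


def validate_cohort(
    cohort_expr: ExpressionMatrix,
    responder_labels: pd.Series,
    signature: Signature,
    mode: str = "zscore",
    coverage_floor: float = 0.5,
) -> dict:
    """Score an independent cohort with a frozen signature; Welch test.

    Responders (label 1/True) are compared against non-responders; the
    result carries per-sample scores for a boxplot-style export and a
    low-coverage flag when fewer than ``coverage_floor`` signature genes
    are present in the cohort expression.
    """
    coverage = signature_coverage(cohort_expr, signature)
    low_coverage = coverage < coverage_floor
    if low_coverage:
        logger.warning(
            "signature %s: cohort coverage %.0f%% below floor %.0f%%",
            signature.name, 100 * coverage, 100 * coverage_floor,
        )
    sv = score_samples(cohort_expr, signature, mode=mode)
    labels = responder_labels.loc[sv.scores.index].astype(bool)
    resp = sv.scores[labels]
    non = sv.scores[~labels]
    if len(resp) < 2 or len(non) < 2:
        raise ValueError("both responder classes need >= 2 samples")
    if resp.std(ddof=1) == 0 and non.std(ddof=1) == 0:
        raise ValueError("zero-variance score groups; Welch t undefined")
    t, p = stats.ttest_ind(resp.to_numpy(), non.to_numpy(), equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "n_responders": int(len(resp)),
        "n_nonresponders": int(len(non)),
        "coverage": coverage,
        "low_coverage": low_coverage,
        "scores": sv.scores,
        "mean_responder": float(resp.mean()),
        "mean_nonresponder": float(non.mean()),
    }
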