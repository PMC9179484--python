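"""Elastic-net selection of sensitivity-linked pathways.

Per-sample pathway scores (mean member-gene z-score) are regressed on the
continuous drug response with an elastic-net penalty, one model per drug,
the penalty chosen by seeded K-fold cross-validation with the 1-SE rule.
A pathway counts as selected for a drug when its coefficient is non-zero at
the chosen penalty; pathways selected for at least half the drugs are
retained.  Retained pathways can then be annotated against curated
acetyl-CoA groups (BCAA degradation, fatty-acid metabolism).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .types import ExpressionMatrix, GeneSetCollection, ResponseTable

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayScoreMatrix",
    "SelectionResult",
    "pathway_scores",
    "dichotomize_response",
    "elastic_net_select",
    "annotate_retained",
]


@dataclass
class PathwayScoreMatrix:
    scores: pd.DataFrame  # pathways x samples
    mode: str = "mean_zscore"

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class SelectionResult:
    coefficients: pd.DataFrame       # pathways x drugs
    chosen_alpha: pd.Series          # per drug penalty strength
    retained_pathways: list[str]
    retention_threshold: int
    l1_ratio: float
    selection_counts: pd.Series = field(default_factory=pd.Series)


def pathway_scores(
    expr: ExpressionMatrix,
    pathways: GeneSetCollection,
    min_genes: int = 2,
) -> PathwayScoreMatrix:
    """Per-pathway mean of per-gene z-scored expression over matched genes."""
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    z = expr.zscored().data
    rows = {}
    for gs in pathways:
        matched = [g for g in gs.genes if g in z.index]
        if len(matched) < min_genes:
            logger.warning(
                "pathway %s: %d matched genes < min_genes=%d; dropped",
                gs.name, len(matched), min_genes,
            )
            continue
        rows[gs.name] = z.loc[matched].mean(axis=0)
    if not rows:
        raise ValueError("no pathway matched enough genes")
    return PathwayScoreMatrix(pd.DataFrame(rows).T)


def dichotomize_response(
    response: ResponseTable, drug: str, rule: str = "tertile"
) -> pd.Series:
    """Ternary sensitive / intermediate / resistant labels for one drug.

    Tertile rule: the most-sensitive third (highest % cell death, or lowest
    lnIC50) is ``sensitive``, the least-sensitive third ``resistant``, the
    middle ``intermediate``.  Ties straddling a boundary are assigned by
    stable sample-id order.
    """
    if rule != "tertile":
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    values = response.data[drug].dropna()
    if len(values) < 10:
        raise ValueError(f"need >= 10 samples with response for {drug}, got {len(values)}")
    ascending = response.unit == "lnIC50"  # low lnIC50 = sensitive
    # sort on positional arrays so a named index can't collide with columns
    order = np.lexsort((values.index.to_numpy(), values.to_numpy()))
    if not ascending:
        order = np.lexsort((values.index.to_numpy(), -values.to_numpy()))
    frame = values.iloc[order]
    n = len(frame)
    third = n // 3
    labels = pd.Series("intermediate", index=frame.index, name=drug)
    labels.iloc[:third] = "sensitive"
    labels.iloc[n - third:] = "resistant"
    if frame.duplicated().any():
        logger.info("%s: ties present; boundary ties assigned by sample-id order", drug)
    return labels.reindex(values.index)


def _one_se_alpha(
    X: np.ndarray, y: np.ndarray, l1_ratio: float, cv_folds: int, seed: int,
    n_alphas: int = 50,
) -> float:
    """Penalty by K-fold CV with the 1-SE rule (largest alpha within 1 SE)."""
    # enet_path fits no intercept, so center X and y explicitly per fold
    alphas, _, _ = enet_path(
        X - X.mean(axis=0), y - y.mean(), l1_ratio=l1_ratio, alphas=n_alphas
    )
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = np.empty((len(alphas), cv_folds))
    for f, (train, test) in enumerate(kf.split(X)):
        xm, ym = X[train].mean(axis=0), y[train].mean()
        _, coefs, _ = enet_path(
            X[train] - xm, y[train] - ym, l1_ratio=l1_ratio, alphas=alphas
        )
        pred = (X[test] - xm) @ coefs + ym  # n_test x n_alphas
        mse[:, f] = ((pred - y[test][:, None]) ** 2).mean(axis=0)
    mean_mse = mse.mean(axis=1)
    se_mse = mse.std(axis=1, ddof=1) / math.sqrt(cv_folds)
    best = int(np.argmin(mean_mse))
    threshold = mean_mse[best] + se_mse[best]
    # alphas from enet_path are descending; pick the largest within threshold
    within = np.where(mean_mse <= threshold)[0]
    return float(alphas[within.min()])


def elastic_net_select(
    scores: PathwayScoreMatrix,
    response: ResponseTable,
    drugs: list[str] | None = None,
    l1_ratio: float = 0.95,
    cv_folds: int = 5,
    seed: int = 0,
    retention_threshold: int | None = None,
) -> SelectionResult:
    """Per-drug elastic net on standardized pathway scores; majority retention.

    The regression target is the continuous response (lnIC50 or % death).
    ``retention_threshold`` defaults to ceil(n_drugs / 2).
    """
    if not 0 < l1_ratio <= 1:
        raise ValueError("l1_ratio must be in (0, 1] for selection (0 = ridge never zeroes)")
    drugs = list(drugs) if drugs is not None else list(response.drug_ids)
    if retention_threshold is None:
        retention_threshold = math.ceil(len(drugs) / 2)

    coef_cols = {}
    chosen = {}
    for drug in drugs:
        y_all = response.data[drug].dropna()
        # sample-id-sorted before splitting -> reproducible folds
        sample_order = sorted(set(y_all.index) & set(scores.scores.columns))
        if len(sample_order) < 2 * cv_folds:
            raise ValueError(f"drug {drug}: need >= {2 * cv_folds} samples")
        y = y_all.loc[sample_order].to_numpy(dtype=float)
        if np.std(y) == 0:
            raise ValueError(f"drug {drug}: constant response")
        X = scores.scores[sample_order].T.to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

        alpha = _one_se_alpha(X, y, l1_ratio, cv_folds, seed)
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000)
        model.fit(X, y)
        if model.n_iter_ is not None and model.n_iter_ >= 50_000:
            raise RuntimeError(f"elastic net failed to converge for drug {drug}")
        coef_cols[drug] = model.coef_
        chosen[drug] = alpha

    coefficients = pd.DataFrame(coef_cols, index=scores.pathway_ids)
    selected = coefficients != 0.0
    counts = selected.sum(axis=1)
    retained = sorted(counts.index[counts >= retention_threshold].tolist())
    return SelectionResult(
        coefficients=coefficients,
        chosen_alpha=pd.Series(chosen),
        retained_pathways=retained,
        retention_threshold=retention_threshold,
        l1_ratio=l1_ratio,
        selection_counts=counts,
    )


def annotate_retained(
    retained: list[str], curated_groups: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Partition retained pathways by curated group membership; rest = other.

    ``curated_groups`` maps group name (e.g. ``BCAA``, ``FA``) to pathway
    ids.  A retained pathway falls in the first group that lists it.
    """
    out: dict[str, list[str]] = {name: [] for name in curated_groups}
    out["other"] = []
    for pw in retained:
        for group, members in curated_groups.items():
            if pw in members:
                out[group].append(pw)
                break
        else:
            out["other"].append(pw)
    return out
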