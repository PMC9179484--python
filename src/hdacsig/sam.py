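"""Significance Analysis of Microarrays: moderated d statistic + permutation FDR.

The relative difference statistic for gene g between groups 1 and 2 is

    d_g = (mean1_g - mean2_g) / (s_g + s0)

with the pooled standard error

    s_g = sqrt( (1/n1 + 1/n2) * (SS1_g + SS2_g) / (n1 + n2 - 2) )

and an exchangeability constant s0 that damps small-variance genes.  s0 is
set to a fixed percentile of the s_g distribution (default 5th); with
s0 = 0, d_g is exactly the pooled-variance two-sample t statistic.

FDR follows the permutation recipe: order the observed d, average the
ordered d across label permutations to get the expected order statistics
d_bar, call genes whose deviation |d_(i) - d_bar_(i)| exceeds delta, and
estimate FDR as (median permutation false-call count) / (observed calls).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

__all__ = ["SamResult", "compute_sam", "sam_fdr", "rank_genes", "fdr_curve"]

FULL_ENUMERATION_LIMIT = 10_000


@dataclass
class SamResult:
    gene_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    s0: float
    n1: int
    n2: int
    q: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"d": self.d, "s": self.s}, index=pd.Index(self.gene_ids, name="gene"))
        if self.q is not None:
            out["q"] = self.q
        return out


def _group_masks(group_labels, sample_ids, group_order=None) -> tuple[np.ndarray, np.ndarray, list]:
    labels = pd.Series(list(group_labels), index=sample_ids)
    uniq = sorted(pd.unique(labels)) if group_order is None else list(group_order)
    if len(uniq) != 2 or set(uniq) != set(pd.unique(labels)):
        raise ValueError(f"exactly two groups required, got {sorted(pd.unique(labels))}")
    mask1 = (labels == uniq[0]).to_numpy()
    mask2 = ~mask1
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    return mask1, mask2, uniq


def _d_stat(values: np.ndarray, mask1: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    mask2 = ~mask1
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    x1, x2 = values[:, mask1], values[:, mask2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    denom = s + s0
    if np.any(denom == 0):
        raise ValueError("gene with zero variance in both groups and s0 = 0: d undefined")
    return (m1 - m2) / denom, s


def compute_sam(
    expr: ExpressionMatrix,
    group_labels,
    s0: float | None = None,
    s0_percentile: float = 5.0,
    group_order: tuple | None = None,
) -> SamResult:
    """Compute the SAM d statistic for group1 minus group2.

    Groups are ordered lexicographically by label (so relabelling the groups
    negates d exactly) unless ``group_order`` fixes the orientation.  If
    ``s0`` is None it is set to the ``s0_percentile``-th percentile of the
    per-gene pooled standard errors; pass ``s0=0`` for the plain t statistic.
    """
    values = expr.data.to_numpy()
    mask1, _, _ = _group_masks(group_labels, expr.sample_ids, group_order)
    if s0 is None:
        _, s_raw = _d_stat(values, mask1, s0=1.0)  # s independent of s0
        s0 = float(np.percentile(s_raw, s0_percentile))
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    d, s = _d_stat(values, mask1, s0)
    return SamResult(
        gene_ids=expr.gene_ids, d=d, s=s, s0=float(s0),
        n1=int(mask1.sum()), n2=int((~mask1).sum()),
    )


def _permutation_masks(n: int, n1: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean matrix of group-1 masks, one row per permutation.

    All distinct assignments are enumerated when there are at most
    ``FULL_ENUMERATION_LIMIT``; otherwise ``n_perm`` uniform random draws.
    """
    total = comb(n, n1)
    if total <= FULL_ENUMERATION_LIMIT:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n1, replace=False)] = True
    return masks


def sam_fdr(
    sam: SamResult,
    expr: ExpressionMatrix,
    group_labels,
    n_perm: int = 200,
    delta: float = 1.0,
    seed: int = 0,
) -> dict:
    """Tusher permutation FDR at one delta; also fills per-gene q in ``sam``.

    Returns a dict with the called gene ids, the estimated FDR (capped at 1;
    0 by convention when nothing is called), and the expected order
    statistics ``d_bar``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = expr.data.to_numpy()
    mask1, _, _ = _group_masks(group_labels, expr.sample_ids)
    n = values.shape[1]
    rng = np.random.default_rng(seed)
    masks = _permutation_masks(n, int(mask1.sum()), n_perm, rng)

    order = np.argsort(sam.d, kind="stable")
    d_sorted = sam.d[order]

    perm_sorted = np.empty((masks.shape[0], len(sam.d)))
    for i, m in enumerate(masks):
        d_perm, _ = _d_stat(values, m, sam.s0)
        perm_sorted[i] = np.sort(d_perm)
    d_bar = perm_sorted.mean(axis=0)

    deviation = d_sorted - d_bar
    called_sorted = np.abs(deviation) > delta

    def _false_counts(cut_up: float, cut_low: float) -> np.ndarray:
        return ((perm_sorted >= cut_up) | (perm_sorted <= cut_low)).sum(axis=1)

    if not called_sorted.any():
        fdr = 0.0
        called_genes: list[str] = []
    else:
        up = called_sorted & (deviation > 0)
        low = called_sorted & (deviation < 0)
        cut_up = d_sorted[up].min() if up.any() else np.inf
        cut_low = d_sorted[low].max() if low.any() else -np.inf
        median_false = float(np.median(_false_counts(cut_up, cut_low)))
        fdr = min(1.0, median_false / int(called_sorted.sum()))
        gene_arr = np.asarray(sam.gene_ids)[order]
        called_genes = sorted(gene_arr[called_sorted].tolist())

    # per-gene q: FDR at the delta that just calls this gene, monotonized so
    # q never decreases as the call set grows
    n_genes = len(sam.d)
    abs_dev = np.abs(deviation)
    dev_order = np.argsort(-abs_dev, kind="stable")
    cut_up_arr = np.empty(n_genes)
    cut_low_arr = np.empty(n_genes)
    cut_up, cut_low = np.inf, -np.inf
    for rank_i, gi in enumerate(dev_order):
        if deviation[gi] > 0:
            cut_up = min(cut_up, d_sorted[gi])
        elif deviation[gi] < 0:
            cut_low = max(cut_low, d_sorted[gi])
        cut_up_arr[rank_i] = cut_up
        cut_low_arr[rank_i] = cut_low
    # rows of perm_sorted are ascending, so threshold counts vectorize
    false_counts = np.empty((perm_sorted.shape[0], n_genes))
    for p in range(perm_sorted.shape[0]):
        row = perm_sorted[p]
        ge = n_genes - np.searchsorted(row, cut_up_arr, side="left")
        le = np.searchsorted(row, cut_low_arr, side="right")
        false_counts[p] = ge + le
    median_false_arr = np.median(false_counts, axis=0)
    q_sorted_by_dev = np.minimum(1.0, median_false_arr / np.arange(1, n_genes + 1))
    q_sorted_by_dev = np.maximum.accumulate(q_sorted_by_dev)
    q = np.empty(n_genes)
    q[dev_order] = q_sorted_by_dev
    q_genes = np.empty(n_genes)
    q_genes[order] = q
    sam.q = q_genes

    return {
        "called": called_genes,
        "fdr": fdr,
        "d_bar": d_bar,
        "d_sorted": d_sorted,
        "delta": delta,
    }


def fdr_curve(sam: SamResult, expr: ExpressionMatrix, group_labels,
              deltas, n_perm: int = 200, seed: int = 0) -> pd.DataFrame:
    """Scan a delta grid and report (delta, n_called, FDR) rows."""
    rows = []
    for delta in deltas:
        res = sam_fdr(sam, expr, group_labels, n_perm=n_perm, delta=float(delta), seed=seed)
        rows.append({"delta": float(delta), "n_called": len(res["called"]), "fdr": res["fdr"]})
    return pd.DataFrame(rows)


def rank_genes(sam: SamResult) -> pd.Series:
    """Genes ordered by d descending; ties broken by gene id (deterministic)."""
    frame = pd.DataFrame({"gene": sam.gene_ids, "d": sam.d})
    frame = frame.sort_values(["d", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(frame["d"].to_numpy(), index=frame["gene"].to_numpy(), name="d")
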