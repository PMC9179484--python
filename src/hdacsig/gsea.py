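"""Gene set enrichment analysis on a ranked gene list, from first principles.

Given genes ranked by a differential metric, a gene set's enrichment score
(ES) is the maximal deviation of a weighted Kolmogorov–Smirnov running sum:
walking down the ranking, hitting a set member increments the sum by
|metric|^p / sum_hits |metric|^p and missing decrements by 1/(N - N_hits).
Significance comes from a permutation null (random same-size gene sets, or
phenotype relabelling when expression + labels are available); NES divides
ES by the mean same-sign null ES, and FDR q uses the sign-stratified pooled
null with monotonization — the standard published scheme.  The leading edge
is the set members at or before (positive ES) / at or after (negative ES)
the running-sum peak.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSet, GeneSetCollection
from . import sam as _sam

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "enrichment_score",
    "permutation_null",
    "normalize_and_fdr",
    "leading_edge",
    "run_gsea",
]


@dataclass
class RankedList:
    """Genes in rank order with a non-increasing real metric."""

    gene_ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.gene_ids) != len(self.metric):
            raise ValueError("gene list and metric length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be non-increasing")

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        frame = pd.DataFrame({"gene": s.index.astype(str), "metric": s.to_numpy(dtype=float)})
        frame = frame.sort_values(["metric", "gene"], ascending=[False, True], kind="stable")
        return cls(frame["gene"].tolist(), frame["metric"].to_numpy())

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float | None = None
    p_nominal: float | None = None
    q_fdr: float | None = None
    leading_edge: list[str] = field(default_factory=list)
    n_hits: int = 0
    peak_index: int = -1
    running_sum: np.ndarray | None = None


def _hit_positions(ranked: RankedList, gene_set: GeneSet | set) -> np.ndarray:
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else gene_set
    members = set(genes)
    return np.fromiter(
        (i for i, g in enumerate(ranked.gene_ids) if g in members), dtype=int
    )


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet | set, p_weight: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted running-sum ES for one gene set.

    Returns ``(ES, running_sum, peak_index)``; the peak is the first index
    attaining the maximal absolute deviation.  Raises when the set shares no
    gene with the ranked list.
    """
    hits = _hit_positions(ranked, gene_set)
    if hits.size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    return _es_from_hits(ranked.metric, hits, len(ranked), p_weight)


def _es_from_hits(
    metric: np.ndarray, hits: np.ndarray, n: int, p_weight: float
) -> tuple[float, np.ndarray, int]:
    n_hits = hits.size
    steps = np.full(n, -1.0 / (n - n_hits) if n > n_hits else 0.0)
    weights = np.abs(metric[hits]) ** p_weight
    total = weights.sum()
    if total == 0:  # all hit metrics zero: fall back to unweighted hits
        weights = np.ones(n_hits)
        total = float(n_hits)
    steps[hits] = weights / total
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


def leading_edge(
    ranked: RankedList,
    gene_set: GeneSet | set,
    running_sum: np.ndarray,
    peak_index: int,
) -> list[str]:
    """Set members at ranks <= peak (ES > 0) or >= peak (ES < 0), rank order."""
    es = running_sum[peak_index]
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else gene_set
    members = set(genes)
    if es > 0:
        span = range(0, peak_index + 1)
    elif es < 0:
        span = range(peak_index, len(ranked.gene_ids))
    else:
        logger.warning("ES is exactly 0; empty leading edge")
        return []
    return [ranked.gene_ids[i] for i in span if ranked.gene_ids[i] in members]


def permutation_null(
    ranked: RankedList,
    gene_set: GeneSet | set,
    n_perm: int,
    mode: str = "gene_set",
    seed: int = 0,
    p_weight: float = 1.0,
    expr: ExpressionMatrix | None = None,
    labels=None,
    s0: float | None = None,
) -> np.ndarray:
    """Null ES sample for one gene set.

    ``gene_set`` mode draws random same-size sets from the ranked universe;
    ``phenotype`` mode permutes the sample labels and re-ranks by the SAM d
    statistic each time (requires ``expr`` and ``labels``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
    size = len(set(genes) & set(ranked.gene_ids))
    if size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    null = np.empty(n_perm)
    if mode == "gene_set":
        for b in range(n_perm):
            hits = np.sort(rng.choice(n, size=size, replace=False))
            null[b], _, _ = _es_from_hits(ranked.metric, hits, n, p_weight)
    elif mode == "phenotype":
        if expr is None or labels is None:
            raise ValueError("phenotype mode requires expr and labels")
        labels = np.asarray(list(labels))
        members = set(genes)
        for b in range(n_perm):
            perm_labels = rng.permutation(labels)
            res = _sam.compute_sam(expr, perm_labels, s0=s0)
            rl = RankedList.from_series(_sam.rank_genes(res))
            hits = _hit_positions(rl, members)
            null[b], _, _ = _es_from_hits(rl.metric, hits, len(rl), p_weight)
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    return null


def nominal_p(es: float, null: np.ndarray) -> float:
    """Sign-stratified add-one estimator: p >= 1/(n_perm + 1), never 0."""
    null = np.asarray(null)
    if es >= 0:
        same = null[null >= 0]
        b = int((same >= es).sum())
    else:
        same = null[null < 0]
        b = int((same <= es).sum())
    denom = max(len(same), 1)
    return (b + 1) / (denom + 1)


def normalize_and_fdr(
    observed: list[EnrichmentResult], nulls: dict[str, np.ndarray]
) -> list[EnrichmentResult]:
    """Fill NES and FDR q on draft results, given per-set null ES samples.

    NES = ES / mean(|null ES| of matching sign).  q compares each observed
    NES against the pooled sign-matched null NES:
    q = (fraction of pooled null NES at least as extreme) /
        (fraction of observed NES at least as extreme), capped at 1 and
    monotonized to be non-increasing in |NES|.  Sets with no same-sign null
    get NES = None, q = 1 and a warning.
    """
    null_nes_pool: list[np.ndarray] = []
    for res in observed:
        null = np.asarray(nulls[res.set_name])
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = np.abs(pos).mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        same_mean = mean_pos if res.es >= 0 else mean_neg
        if not np.isfinite(same_mean) or same_mean == 0:
            logger.warning("set %s: no same-sign null ES; NES undefined", res.set_name)
            res.nes = None
            res.q_fdr = 1.0
        else:
            res.nes = res.es / same_mean
        res.p_nominal = nominal_p(res.es, null)
        # pool this set's normalized nulls (both signs, each by its own mean)
        parts = []
        if pos.size and np.isfinite(mean_pos) and mean_pos > 0:
            parts.append(pos / mean_pos)
        if neg.size and np.isfinite(mean_neg) and mean_neg > 0:
            parts.append(neg / mean_neg)
        if parts:
            null_nes_pool.append(np.concatenate(parts))

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs_nes = np.array([r.nes if r.nes is not None else np.nan for r in observed])

    for res in observed:
        if res.nes is None:
            continue
        nes = res.nes
        if nes >= 0:
            n_null_extreme = (pool >= nes).sum()
            n_null_sign = (pool >= 0).sum()
            n_obs_extreme = np.nansum(obs_nes >= nes)
            n_obs_sign = np.nansum(obs_nes >= 0)
        else:
            n_null_extreme = (pool <= nes).sum()
            n_null_sign = (pool < 0).sum()
            n_obs_extreme = np.nansum(obs_nes <= nes)
            n_obs_sign = np.nansum(obs_nes < 0)
        if n_null_sign == 0 or n_obs_extreme == 0:
            res.q_fdr = 1.0
            continue
        null_frac = n_null_extreme / n_null_sign
        obs_frac = n_obs_extreme / max(n_obs_sign, 1)
        res.q_fdr = min(1.0, float(null_frac / obs_frac)) if obs_frac > 0 else 1.0

    # monotonize so q is non-increasing in |NES| within each sign stratum:
    # each set's q becomes the min of the raw q over all less-extreme sets
    # and itself (the Benjamini-Hochberg-style tail minimum)
    for sign in (1, -1):
        stratum = [r for r in observed if r.nes is not None
                   and (r.nes >= 0 if sign > 0 else r.nes < 0)]
        running = 1.0
        for r in sorted(stratum, key=lambda r: abs(r.nes)):
            running = min(running, r.q_fdr)
            r.q_fdr = running
    return observed


def run_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    p_weight: float = 1.0,
    mode: str = "gene_set",
    seed: int = 0,
    expr: ExpressionMatrix | None = None,
    labels=None,
) -> list[EnrichmentResult]:
    """ES/NES/p/q/leading edge for every set with ranked-list overlap."""
    universe = set(ranked.gene_ids)
    results: list[EnrichmentResult] = []
    nulls: dict[str, np.ndarray] = {}
    for i, gs in enumerate(collection):
        matched = [g for g in gs.genes if g in universe]
        if not matched:
            logger.warning("set %s: no genes in ranked list; skipped", gs.name)
            continue
        if len(matched) < len(gs.genes):
            logger.info(
                "set %s: %d/%d genes matched", gs.name, len(matched), len(gs.genes)
            )
        es, running, peak = enrichment_score(ranked, set(matched), p_weight)
        res = EnrichmentResult(
            set_name=gs.name, es=es, n_hits=len(matched), peak_index=peak,
            leading_edge=leading_edge(ranked, set(matched), running, peak),
        )
        nulls[gs.name] = permutation_null(
            ranked, set(matched), n_perm=n_perm, mode=mode,
            seed=seed + i, p_weight=p_weight, expr=expr, labels=labels,
        )
        results.append(res)
    if not results:
        raise ValueError("no gene set overlaps the ranked list")
    return normalize_and_fdr(results, nulls)


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten results for TSV export (leading edge semicolon-joined)."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "size": [r.n_hits for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes if r.nes is not None else np.nan for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "q_fdr": [r.q_fdr for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        }
    ).set_index("set")
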