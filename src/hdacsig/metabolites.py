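"""Metabolomics stage: per-metabolite Welch tests + hypergeometric enrichment.

Treated-versus-control abundances (replicated arms) are compared per
metabolite with Welch's t-test on log2 values; fold change is the ratio of
arm medians.  Pathways are then scored for over-representation of the
significantly modified metabolites with a one-sided hypergeometric test
P(X >= k), and the top pathways reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetaboliteTable",
    "metabolite_tests",
    "hypergeometric_enrichment",
    "top_pathways",
]


@dataclass
class MetaboliteTable:
    """Abundances (metabolites x replicates) with arm labels and annotation."""

    abundance: pd.DataFrame
    arms: pd.Series          # per replicate column: "treated" / "control"
    annotation: pd.Series    # per metabolite: pathway id ("unannotated" allowed)

    def __post_init__(self) -> None:
        if list(self.arms.index) != list(self.abundance.columns):
            raise ValueError("arm labels must align with abundance columns")
        for arm in ("treated", "control"):
            if (self.arms == arm).sum() < 2:
                raise ValueError(f"need >= 2 replicates in arm {arm!r}")
        self.annotation = self.annotation.reindex(self.abundance.index).fillna("unannotated")

    @classmethod
    def from_columns(cls, abundance: pd.DataFrame, annotation: pd.Series) -> "MetaboliteTable":
        """Infer arms from column-name prefixes (``treated_*`` / ``control_*``)."""
        arms = pd.Series(
            [c.split("_")[0] for c in abundance.columns], index=abundance.columns
        )
        return cls(abundance, arms, annotation)


def metabolite_tests(table: MetaboliteTable, alpha: float = 0.05,
                     adjust: str | None = None) -> pd.DataFrame:
    """Welch t on log2 abundances; fold change as treated/control median ratio.

    Zero-variance metabolites (both arms constant) get p = 1 and a flag.
    ``adjust="bh"`` adds a Benjamini–Hochberg column and bases the
    significance flag on it instead of the raw p.
    """
    treated = table.abundance.loc[:, (table.arms == "treated").to_numpy()]
    control = table.abundance.loc[:, (table.arms == "control").to_numpy()]
    log_t = np.log2(treated.to_numpy(dtype=float))
    log_c = np.log2(control.to_numpy(dtype=float))

    t_stat, p = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False)
    flat = (log_t.std(axis=1, ddof=1) == 0) & (log_c.std(axis=1, ddof=1) == 0)
    same_mean = flat & (log_t.mean(axis=1) == log_c.mean(axis=1))
    t_stat = np.where(same_mean, 0.0, t_stat)
    p = np.where(flat, 1.0, p)

    fold = np.median(treated.to_numpy(), axis=1) / np.median(control.to_numpy(), axis=1)
    out = pd.DataFrame(
        {
            "t": t_stat,
            "p": p,
            "fold_change": fold,
            "zero_variance": flat,
            "pathway": table.annotation,
        },
        index=table.abundance.index,
    )
    if adjust == "bh":
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q_bh"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def hypergeometric_enrichment(tests: pd.DataFrame) -> pd.DataFrame:
    """One-sided over-representation of significant metabolites per pathway.

    For each pathway with K annotated metabolites of N total, of which k of
    the n significant ones fall inside, p = P(X >= k) under
    Hypergeometric(N, K, n); fold enrichment is (k/n)/(K/N).
    """
    n_total = len(tests)
    sig = tests["significant"]
    n_sig = int(sig.sum())
    if n_sig == 0:
        raise ValueError("no significant metabolites; enrichment undefined")
    rows = []
    for pathway, members in tests.groupby("pathway").groups.items():
        big_k = len(members)
        if big_k == 0:
            continue
        k = int(sig.loc[members].sum())
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_sig))
        rows.append(
            {
                "pathway": pathway,
                "N": n_total,
                "K": big_k,
                "n": n_sig,
                "k": k,
                "fold_enrichment": (k / n_sig) / (big_k / n_total),
                "p_hyper": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows).set_index("pathway")


def top_pathways(enrichments: pd.DataFrame, k_top: int = 15) -> pd.DataFrame:
    """Top pathways by ascending p, ties by descending fold enrichment, then id."""
    frame = enrichments.reset_index()
    frame["_neg_fold"] = -frame["fold_enrichment"]
    frame = frame.sort_values(
        ["p_hyper", "_neg_fold", "pathway"], ascending=True, kind="stable"
    ).drop(columns="_neg_fold")
    return frame.head(k_top).set_index("pathway")
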