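"""Core in-memory containers shared by every pipeline stage.

All tabular payloads are pandas objects; the dataclasses add the domain
invariants (unique identifiers, finiteness, binary flags) that pandas does
not enforce on its own.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ResponseTable",
    "GeneSet",
    "GeneSetCollection",
    "MutationTable",
    "Signature",
    "ScoreVector",
    "RunConfig",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes as rows, samples as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        self.data = pd.DataFrame(
            values, index=self.data.index.astype(str), columns=self.data.columns.astype(str)
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def zscored(self) -> "ExpressionMatrix":
        """Per-gene z-score across samples; zero-variance genes map to 0."""
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples to z-score expression")
        values = self.data.to_numpy(dtype=float)
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(
            pd.DataFrame((values - mu) / sd, index=self.data.index, columns=self.data.columns)
        )


@dataclass
class ResponseTable:
    """Per-sample, per-drug response (samples as rows, drugs as columns).

    ``unit`` is either ``"percent_death"`` (values in [0, 100]) or
    ``"lnIC50"`` (unbounded; lower = more sensitive).  ``labels`` is an
    optional same-shaped frame of ternary strings
    (``sensitive`` / ``resistant`` / ``intermediate``).
    """

    data: pd.DataFrame
    unit: str = "percent_death"
    labels: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "drug ids")
        if self.unit not in ("percent_death", "lnIC50"):
            raise ValueError(f"unknown response unit {self.unit!r}")
        values = self.data.to_numpy(dtype=float)
        if self.unit == "percent_death":
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise ValueError("percent cell death outside [0, 100]")
        if self.labels is not None:
            if list(self.labels.index) != list(self.data.index) or list(
                self.labels.columns
            ) != list(self.data.columns):
                raise ValueError("label frame must align with response frame")
            has_label = self.labels.notna().to_numpy()
            has_value = np.isfinite(values)
            if (has_label & ~has_value).any():
                raise ValueError("label present for sample without a response value")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"genes in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set names")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        wanted = set(names)
        return GeneSetCollection([s for s in self.sets if s.name in wanted])


@dataclass
class MutationTable:
    """Binary alteration flags, samples as rows, genes/pathways as columns."""

    flags: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.flags.index, "sample ids")
        _check_unique(self.flags.columns, "mutation ids")
        values = self.flags.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mutation flags must be strictly binary")
        self.flags = self.flags.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.flags.index)


@dataclass
class Signature:
    """Up/down gene lists with provenance, consumed by the score formula."""

    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up_genes = tuple(self.up_genes)
        self.down_genes = tuple(self.down_genes)
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"genes in both up and down lists: {sorted(overlap)[:5]}")
        if not self.up_genes and not self.down_genes:
            raise ValueError("signature has no genes")
        _check_unique(self.up_genes, "up genes")
        _check_unique(self.down_genes, "down genes")

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class ScoreVector:
    scores: pd.Series
    signature_name: str
    mode: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("non-finite signature scores")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class RunConfig:
    """Run-level knobs shared by the pipeline stages."""

    seed: int = 0
    permutations: int = 1000
    nominal_p: float = 0.01
    fdr_q: float = 0.05
    n_clusters: int = 4
    linkage_method: str = "ward"
    zscore_responses: bool = True
    enet_l1_ratio: float = 0.95
    enet_cv_folds: int = 5
    score_mode: str = "zscore"
    sam_s0_percentile: float = 5.0
    gsea_weight: float = 1.0
    min_pathway_genes: int = 2

    def __post_init__(self) -> None:
        for name in ("nominal_p", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not 0 <= self.enet_l1_ratio <= 1:
            raise ValueError("enet_l1_ratio must be in [0,1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
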