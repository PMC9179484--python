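"""Synthetic expression panels with planted pathway structure.

The generator emulates a cancer cell-line panel profiled at baseline and
screened against a set of HDAC inhibitors: most genes are background noise,
a minority are organised into pathways driven by latent factors, and a small
number of *causal* pathways share a latent sensitivity axis with the drug
responses.  Sensitive samples (top response tertile) therefore carry a
standardized causal-pathway expression shift of ``effect_size`` relative to
resistant samples — the planted signal every downstream stage (SAM, GSEA,
elastic net, signature scoring) is asked to recover.

Everything is driven by a single ``numpy.random.Generator`` seeded from the
spec, so identical specs give bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    GeneSet,
    MutationTable,
    ResponseTable,
    Signature,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_panel",
    "simulate_cohort",
    "simulate_metabolite_table",
    "TERTILE_GAP",
]

# Expected gap between the top- and bottom-tertile means of a standard
# normal: 2 * phi(z_{2/3}) / (1/3) with z_{2/3} = 0.4307...
TERTILE_GAP = 2.1840


@dataclass(frozen=True)
class SimulationSpec:
    """Knobs of the synthetic panel; defaults give a mid-size cell panel."""

    n_genes: int = 5000
    n_samples: int = 200
    n_pathways: int = 20
    genes_per_pathway: int = 25
    n_causal_pathways: int = 2
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_drugs: int = 8
    drug_noise_sd: float = 0.4
    positive_gene_fraction: float = 0.8
    cohort_size: int = 13
    responder_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_pathways > self.n_pathways:
            raise ValueError("n_causal_pathways exceeds n_pathways")
        if self.genes_per_pathway * self.n_pathways > self.n_genes:
            raise ValueError("pathway genes exceed total genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0 or self.drug_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        if not 0 <= self.positive_gene_fraction <= 1:
            raise ValueError("positive_gene_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-deriving labels."""

    causal_pathway_names: list[str]
    pathway_directions: dict[str, int]          # causal pathway -> +1/-1
    gene_directions: dict[str, int]             # causal gene -> loading sign within pathway
    gene_sensitivity_directions: dict[str, int]  # causal gene -> net sign vs sensitivity
    latent_sensitivity: pd.Series                # per sample, shared across drugs
    drug_latents: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x drugs

    def true_signature(self, name: str = "PLANTED") -> Signature:
        up = tuple(sorted(g for g, d in self.gene_sensitivity_directions.items() if d > 0))
        down = tuple(sorted(g for g, d in self.gene_sensitivity_directions.items() if d < 0))
        return Signature(name=name, up_genes=up, down_genes=down,
                         provenance={"source": "synthetic ground truth"})


def _factor_loading(effect_size: float) -> float:
    """Loading of the sensitivity latent on causal pathway factors.

    Chosen so the standardized factor shift between top and bottom response
    tertiles equals ``effect_size`` (factors are kept at unit variance).
    Effects beyond the tertile gap saturate at a loading of ~1.
    """
    gamma = min(effect_size / TERTILE_GAP, 0.999)
    return gamma


def simulate_panel(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, ResponseTable, MutationTable, GeneSetCollection, GroundTruth]:
    """Generate one panel: expression, responses, mutations, pathway GMT, truth.

    Model: background genes iid N(0,1); pathway ``p`` has a unit-variance
    latent factor ``f_p``; member gene ``g`` has expression
    ``dir_g * f_p + N(0, noise_sd^2)``.  Causal pathway factors load on a
    per-sample latent sensitivity ``L`` with sign ``dir_p``; per-drug latents
    are ``L`` plus drug noise, mapped to % cell death by ``100 * logistic``
    and to lnIC50 by negation plus noise.  Mutation flags are Bernoulli with
    probability ``clip(0.2 + 0.6 * logistic(L), 0.05, 0.95)``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    drug_ids = [f"HDACi{d + 1}" for d in range(spec.n_drugs)]

    latent = rng.standard_normal(spec.n_samples)
    gamma = _factor_loading(spec.effect_size)

    expr = rng.standard_normal((spec.n_genes, spec.n_samples))

    pathway_sets: list[GeneSet] = []
    causal_names: list[str] = []
    pathway_directions: dict[str, int] = {}
    gene_directions: dict[str, int] = {}
    gene_sens_directions: dict[str, int] = {}

    gene_cursor = 0
    for p in range(spec.n_pathways):
        name = f"PW{p:02d}"
        members = gene_ids[gene_cursor : gene_cursor + spec.genes_per_pathway]
        gene_cursor += spec.genes_per_pathway
        causal = p < spec.n_causal_pathways
        dir_p = int(rng.choice([-1, 1]))
        if causal:
            factor = dir_p * gamma * latent + np.sqrt(1 - gamma**2) * rng.standard_normal(
                spec.n_samples
            )
        else:
            factor = rng.standard_normal(spec.n_samples)
        # co-expression modules are predominantly positively loaded on their
        # factor; a minority of members anti-correlate
        signs = np.where(
            rng.random(len(members)) < spec.positive_gene_fraction, 1, -1
        )
        rows = slice(gene_cursor - spec.genes_per_pathway, gene_cursor)
        expr[rows] = signs[:, None] * factor[None, :] + spec.noise_sd * rng.standard_normal(
            (len(members), spec.n_samples)
        )
        pathway_sets.append(GeneSet(name, "synthetic pathway", tuple(members)))
        if causal:
            causal_names.append(name)
            pathway_directions[name] = dir_p
            for g, s in zip(members, signs):
                gene_directions[g] = int(s)
                gene_sens_directions[g] = int(s) * dir_p

    expression = ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids))

    drug_latents = latent[:, None] + spec.drug_noise_sd * rng.standard_normal(
        (spec.n_samples, spec.n_drugs)
    )
    percent_death = 100.0 * expit(drug_latents)
    response = ResponseTable(
        pd.DataFrame(percent_death, index=sample_ids, columns=drug_ids),
        unit="percent_death",
    )

    mut_prob = np.clip(0.2 + 0.6 * expit(latent), 0.05, 0.95)
    flags = (rng.random(spec.n_samples) < mut_prob).astype(int)
    mutations = MutationTable(
        pd.DataFrame({"TKR_RAS_BRAF": flags}, index=sample_ids)
    )

    truth = GroundTruth(
        causal_pathway_names=causal_names,
        pathway_directions=pathway_directions,
        gene_directions=gene_directions,
        gene_sensitivity_directions=gene_sens_directions,
        latent_sensitivity=pd.Series(latent, index=sample_ids),
        drug_latents=pd.DataFrame(drug_latents, index=sample_ids, columns=drug_ids),
    )
    return expression, response, mutations, GeneSetCollection(pathway_sets), truth


def lnic50_response(response: ResponseTable, truth: GroundTruth, noise_sd: float = 0.3,
                    seed: int = 0) -> ResponseTable:
    """Alternative response dialect: lnIC50 = -latent + noise (lower = sensitive)."""
    rng = np.random.default_rng(seed)
    values = -truth.drug_latents.to_numpy() + noise_sd * rng.standard_normal(
        truth.drug_latents.shape
    )
    return ResponseTable(
        pd.DataFrame(values, index=truth.drug_latents.index, columns=truth.drug_latents.columns),
        unit="lnIC50",
    )


def simulate_cohort(
    spec: SimulationSpec, signature: Signature, n_background: int = 200
) -> tuple[ExpressionMatrix, pd.Series]:
    """A small patient cohort carrying the planted signature shift.

    Responders and non-responders differ by a standardized shift of
    ``effect_size`` on each signature gene's underlying factor, in the
    gene's signed direction.  Degenerate label draws (fewer than two samples
    in a class) are resampled.
    """
    if spec.cohort_size < 4:
        raise ValueError("cohort_size must be >= 4")
    if not 0 < spec.responder_fraction < 1:
        raise ValueError("responder_fraction must be in (0,1)")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = spec.cohort_size
    while True:
        labels = (rng.random(n) < spec.responder_fraction).astype(int)
        if 2 <= labels.sum() <= n - 2:
            break
    sample_ids = [f"P{i:02d}" for i in range(n)]
    group_code = 2.0 * labels - 1.0  # -1 / +1; group gap below = effect_size

    sig_genes = list(signature.up_genes) + list(signature.down_genes)
    signs = np.array([1] * len(signature.up_genes) + [-1] * len(signature.down_genes))
    expr_sig = signs[:, None] * (spec.effect_size / 2.0) * group_code[None, :]
    expr_sig = expr_sig + rng.standard_normal((len(sig_genes), n))

    bg_ids = [f"BG{i:04d}" for i in range(n_background)]
    expr_bg = rng.standard_normal((n_background, n))

    data = pd.DataFrame(
        np.vstack([expr_sig, expr_bg]), index=sig_genes + bg_ids, columns=sample_ids
    )
    return ExpressionMatrix(data), pd.Series(labels, index=sample_ids, name="responder")


def simulate_metabolite_table(
    n_metabolites: int = 620,
    n_pathways: int = 40,
    n_shifted: int = 60,
    fold: float = 4.0,
    seed: int = 0,
    n_replicates: int = 4,
    log_noise_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series]:
    """Quadruplicate treated/control metabolite abundances with planted shifts.

    Returns ``(abundance, annotation)`` where ``abundance`` is a metabolites x
    replicates frame with columns ``control_1.. treated_1..`` and
    ``annotation`` maps metabolite -> pathway id.  Shifted metabolites are
    concentrated in the first pathways (filled in order), so those pathways
    are the planted enrichment targets.
    """
    if n_shifted > n_metabolites:
        raise ValueError("n_shifted exceeds n_metabolites")
    rng = np.random.default_rng(seed)
    met_ids = [f"M{i:04d}" for i in range(n_metabolites)]
    pathways = [f"MP{p:02d}" for p in range(n_pathways)]
    annotation = pd.Series(
        [pathways[i % n_pathways] for i in range(n_metabolites)], index=met_ids, name="pathway"
    )
    # pack the shifted metabolites into the earliest pathways
    order = np.argsort([int(a[2:]) for a in annotation])  # group by pathway index
    shifted = np.zeros(n_metabolites, dtype=bool)
    shifted[order[:n_shifted]] = True

    base = rng.normal(10.0, 1.0, size=n_metabolites)  # log2 mean abundance
    cols, arms = [], []
    for arm in ("control", "treated"):
        for r in range(n_replicates):
            cols.append(f"{arm}_{r + 1}")
            arms.append(arm)
    log_values = np.empty((n_metabolites, len(cols)))
    for j, arm in enumerate(arms):
        mu = base.copy()
        if arm == "treated":
            mu = mu + shifted * np.log2(fold)
        log_values[:, j] = mu + log_noise_sd * rng.standard_normal(n_metabolites)
    abundance = pd.DataFrame(2.0 ** log_values, index=met_ids, columns=cols)
    abundance.attrs["shifted"] = [m for m, s in zip(met_ids, shifted) if s]
    return abundance, annotation
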