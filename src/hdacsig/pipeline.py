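"""End-to-end synthetic-panel pipeline: simulate -> cluster -> SAM -> GSEA
-> elastic net -> signature -> associations -> cohort validation ->
metabolite enrichment.

``run_all`` executes every stage on one simulated panel and writes each
stage's table under an output directory.  All randomness descends from the
config seed and floats are serialized at fixed precision, so two runs with
the same config produce byte-identical files.  A ``manifest.json`` records
the seed, a hash of the configuration, and a checksum per output file.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import clustering, gsea, io, metabolites, sam, scoring, selection
from .simulate import SimulationSpec, simulate_cohort, simulate_metabolite_table, simulate_panel
from .types import RunConfig

__all__ = ["run_all"]


def _config_hash(config: RunConfig, spec: SimulationSpec) -> str:
    payload = json.dumps(
        {"config": config.to_dict(), "spec": spec.__dict__}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig, spec: SimulationSpec, out_dir) -> dict:
    """Run every stage on a simulated panel; returns the in-memory results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def _save(write_fn, path: Path) -> None:
        write_fn(path)
        outputs.append(path)

    expr, response, mutations, pathways, truth = simulate_panel(spec)
    _save(lambda p: io.write_expression(expr, p), out / "expression.tsv")
    _save(lambda p: io.write_response(response, p), out / "response.tsv")
    _save(lambda p: io.write_mutations(mutations, p), out / "mutations.tsv")
    _save(lambda p: io.write_gmt(pathways, p), out / "pathways.gmt")

    # 1. response clustering + mutation association
    assignment = clustering.cluster_responses(
        response, k=config.n_clusters, zscore=config.zscore_responses,
        method=config.linkage_method,
    )
    labels_frame = pd.DataFrame(
        {"cluster": assignment.labels}, index=pd.Index(assignment.sample_ids, name="sample")
    )
    _save(lambda p: io.write_table(labels_frame, p, index_label="sample"),
          out / "clusters.tsv")
    _save(lambda p: p.write_text(clustering.linkage_to_newick(assignment) + "\n"),
          out / "dendrogram.nwk")

    mut_assoc = [
        clustering.cluster_mutation_association(assignment, mutations, c)
        for c in range(1, config.n_clusters + 1)
    ]
    _save(
        lambda p: io.write_table(pd.DataFrame(mut_assoc).set_index("cluster"), p,
                                 index_label="cluster"),
        out / "cluster_mutation_association.tsv",
    )

    # 2. sensitive/resistant labels per drug (tertile rule)
    drug_labels = {
        drug: selection.dichotomize_response(response, drug)
        for drug in response.drug_ids
    }
    anchor_drug = response.drug_ids[0]
    anchor = drug_labels[anchor_drug]
    two_group = anchor[anchor != "intermediate"]

    # 3. SAM ranking on the anchor drug's sensitive vs resistant groups
    sub_expr = type(expr)(expr.data[two_group.index])
    sam_res = sam.compute_sam(sub_expr, two_group.to_numpy(),
                              s0_percentile=config.sam_s0_percentile)
    sam.sam_fdr(sam_res, sub_expr, two_group.to_numpy(),
                n_perm=min(config.permutations, 200), delta=0.5, seed=config.seed)
    _save(lambda p: io.write_table(sam_res.as_frame(), p, index_label="gene"),
          out / "sam.tsv")
    ranking = sam.rank_genes(sam_res)
    _save(lambda p: io.write_rnk(ranking.index, ranking.to_numpy(), p), out / "ranking.rnk")

    # 4. GSEA of the pathway collection on the SAM ranking
    ranked = gsea.RankedList.from_series(ranking)
    enr = gsea.run_gsea(
        ranked, pathways, n_perm=config.permutations,
        p_weight=config.gsea_weight, seed=config.seed,
    )
    _save(lambda p: io.write_table(gsea.results_frame(enr), p, index_label="set"),
          out / "gsea.tsv")

    # 5. pathway scores + elastic-net retention across drugs
    scores = selection.pathway_scores(expr, pathways, min_genes=config.min_pathway_genes)
    sel = selection.elastic_net_select(
        scores, response, l1_ratio=config.enet_l1_ratio,
        cv_folds=config.enet_cv_folds, seed=config.seed,
    )
    _save(lambda p: io.write_table(sel.coefficients, p, index_label="pathway"),
          out / "enet_coefficients.tsv")
    _save(lambda p: p.write_text("".join(f"{pw}\n" for pw in sel.retained_pathways)),
          out / "retained_pathways.txt")

    # 6. signature from leading edges of retained pathways
    retained_enr = [r for r in enr if r.set_name in sel.retained_pathways]
    if not retained_enr:  # fall back to the top |NES| pathway so the run completes
        retained_enr = sorted(enr, key=lambda r: -abs(r.nes or 0))[:1]
    direction_t = scoring.gene_direction_t(sub_expr, two_group)
    signature = scoring.derive_signature(retained_enr, direction_t, name="ACoA_GES")
    _save(lambda p: io.write_signature(signature, p), out / "signature.gmt")

    # 7. association panel across drugs
    sig_scores = scoring.score_samples(expr, signature, mode=config.score_mode)
    panel = scoring.association_panel([sig_scores], drug_labels)
    _save(lambda p: io.write_table(panel, p, index_label="signature\tdrug"),
          out / "associations.tsv")

    # 8. independent cohort validation with the frozen signature
    cohort_expr, responder = simulate_cohort(spec, truth.true_signature())
    validation = scoring.validate_cohort(cohort_expr, responder, signature,
                                         mode=config.score_mode)
    val_frame = pd.DataFrame(
        {"score": validation["scores"], "responder": responder}
    )
    _save(lambda p: io.write_table(val_frame, p, index_label="patient"),
          out / "validation_scores.tsv")
    _save(
        lambda p: p.write_text(json.dumps(
            {k: v for k, v in validation.items() if k != "scores"}, indent=2,
            sort_keys=True) + "\n"),
        out / "validation.json",
    )

    # 9. metabolite enrichment on a simulated treated/control table
    abundance, annotation = simulate_metabolite_table(seed=spec.seed)
    met_table = metabolites.MetaboliteTable.from_columns(abundance, annotation)
    met_tests = metabolites.metabolite_tests(met_table)
    met_enr = metabolites.hypergeometric_enrichment(met_tests)
    top = metabolites.top_pathways(met_enr)
    _save(lambda p: io.write_table(met_tests, p, index_label="metabolite"),
          out / "metabolite_tests.tsv")
    _save(lambda p: io.write_table(top, p, index_label="pathway"),
          out / "metabolite_enrichment.tsv")

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config, spec),
        "checksums": {p.name: _checksum(p) for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "assignment": assignment,
        "sam": sam_res,
        "enrichments": enr,
        "selection": sel,
        "signature": signature,
        "association_panel": panel,
        "validation": validation,
        "metabolite_enrichment": met_enr,
        "truth": truth,
    }
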