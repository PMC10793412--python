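"""End-to-end pipeline runs on synthetic cohorts.

These helpers wire the stages together the way the full analysis runs
on real data: simulate -> meta-analysis -> effect-ranked GSEA ->
bipartite hub selection; ECM-activity association with Fisher
combination; ligand-receptor ranking; and co-expression network
propagation. They are the entry points used by the command line
``run-all`` stage and by the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycohub import enrich, hub, meta, pathway_assoc, propagate, sc, synth

__all__ = [
    "run_hub_pipeline",
    "run_ecm_association",
    "run_lr_ranking",
    "run_module_propagation",
]


@dataclass
class HubPipelineResult:
    selected: hub.HubSelection | None
    meta_table: pd.DataFrame
    gsea_table: pd.DataFrame
    truth: dict


def run_hub_pipeline(
    spec: synth.BulkSimSpec,
    gsea_perm: int = 250,
    fdr: float = 0.05,
    gsea_seed: int = 0,
) -> HubPipelineResult:
    """simulate -> meta -> GSEA -> bipartite graph -> hub selection.

    The meta-analysis runs over all genes; GSEA ranks genes by combined
    effect size and flags pathways at BH q < ``fdr``; DE glycogenes
    (glycogene-restricted BH, q < ``fdr``) intersect the enriched sets
    to form the bipartite graph whose maximal-degree gene is the hub.
    """
    cohorts, truth = synth.simulate_bulk(spec)
    collection = synth.simulate_pathways(spec)
    glyco = synth.glycogene_table(spec)

    full = meta.meta_differential_expression(cohorts, glycogenes=None, fdr=fdr)
    ranks = dict(zip(full["gene"], full["mu"]))
    gsea = enrich.gsea_collection(
        ranks, collection, n_perm=gsea_perm, seed=gsea_seed
    )
    enriched_names = gsea.loc[gsea["q"] < fdr, "set"].tolist()

    glyco_meta = meta.meta_differential_expression(cohorts, glycogenes=glyco, fdr=fdr)
    de_glyco = glyco_meta.loc[glyco_meta["is_deg"], "gene"].tolist()

    selected = None
    if enriched_names and de_glyco:
        graph = hub.build_bipartite(collection.subset(enriched_names), de_glyco)
        if any(d.get("bipartite") == 1 for _, d in graph.nodes(data=True)):
            selected = hub.select_hub(graph)
    return HubPipelineResult(selected, full, gsea, truth)


def run_ecm_association(
    spec: synth.BulkSimSpec,
    n_decoys: int = 30,
    n_pc: int = 1,
    n_perm: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pathway Fisher-combined association with ECM activity.

    For each cohort x region stratum the ECM outcome is the mean
    activity of the planted ECM signature; every candidate pathway
    (the planted driver plus ``n_decoys`` decoy sets) is tested by PCA
    permutation regression and the per-stratum p-values are combined by
    Fisher's method. Returns one row per pathway sorted by combined p.
    """
    if spec.ecm_driver is None:
        raise ValueError("spec must plant an ECM driver")
    cohorts, truth = synth.simulate_bulk(spec)
    collection = synth.simulate_pathways(spec)
    ecm_names, signature = pathway_assoc.ecm_pathway_signature(collection)
    candidates = [truth["driver_set"]] + [
        n for n in collection.names if n not in ecm_names and n != truth["driver_set"]
    ][:n_decoys]

    rng = np.random.default_rng(seed)
    per_path: dict[str, list[float]] = {n: [] for n in candidates}
    for expr in cohorts:
        for cohort, region in expr.strata():
            sub = expr.subset_stratum(cohort, region)
            outcome = pathway_assoc.pathway_activity(sub, signature, method="mean")
            for name in candidates:
                p = pathway_assoc.pca_regression_association(
                    sub,
                    outcome,
                    collection.members(name),
                    n_pc=n_pc,
                    n_perm=n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    exclude=signature,
                )
                per_path[name].append(p)

    rows = []
    for name, ps in per_path.items():
        x2, df, comb = pathway_assoc.fisher_combine(ps)
        rows.append({"set": name, "x2": x2, "df": df, "p_combined": comb,
                     "is_driver": name == truth["driver_set"]})
    return (
        pd.DataFrame(rows)
        .sort_values(["p_combined", "set"], kind="mergesort")
        .reset_index(drop=True)
    )


def run_lr_ranking(
    spec: synth.ScSimSpec, n_decoys: int = 50, kh: float = 0.5
) -> pd.DataFrame:
    """Score the planted ligand-receptor pair against decoy pairs.

    Decoys are background-gene pairs scored for the same sender ->
    receiver channel; the result is sorted by score descending with the
    planted pair flagged.
    """
    if spec.lr is None:
        raise ValueError("spec must plant a ligand-receptor pair")
    adata, truth = synth.simulate_single_cell(spec)
    sc.normalize(adata)
    planted = sc.LrPair(truth["lr"]["ligand"], tuple(truth["lr"]["receptors"]))
    special = {planted.ligand, *planted.receptors}
    bg = [g for g in adata.var_names if g.startswith("SGENE") and g not in special]
    decoys = [
        sc.LrPair(bg[2 * i], (bg[2 * i + 1],))
        for i in range(min(n_decoys, len(bg) // 2))
    ]
    scores = sc.ligand_receptor_score(
        adata, [planted] + decoys, truth["lr"]["sender"], truth["lr"]["receiver"],
        kh=kh,
    )
    scores["is_planted"] = scores["pair"] == planted.pair_id
    return scores.sort_values(
        ["score", "pair"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def run_module_propagation(
    spec: synth.ScSimSpec,
    beta: float = 8.0,
    percentile: float = 90.0,
    restart: float = 0.7,
    top_k: int = 30,
    n_network_genes: int = 120,
) -> tuple[list[str], dict]:
    """Cell-type network -> TOM -> RWR from module seeds -> top neighbors.

    The network is built on the module cell type over the planted
    module genes plus background genes (``n_network_genes`` total).
    Returns (top-k neighbor genes, truth record).
    """
    if spec.module is None:
        raise ValueError("spec must plant a co-expression module")
    adata, truth = synth.simulate_single_cell(spec)
    sc.normalize(adata)
    mod = truth["module"]
    cells = adata.obs["cell_type"] == mod["celltype"]
    module_genes = [*mod["seed_genes"], *mod["member_genes"]]
    bg = [g for g in adata.var_names if g.startswith("SGENE")]
    genes = module_genes + bg[: max(0, n_network_genes - len(module_genes))]
    expr = pd.DataFrame(
        np.asarray(adata.layers["lognorm"])[cells.to_numpy()][
            :, [adata.var_names.get_loc(g) for g in genes]
        ].T,
        index=genes,
    )
    adj = propagate.soft_adjacency(expr, beta=beta)
    tom = propagate.tom_matrix(adj)
    net = propagate.threshold_edges(tom, percentile=percentile)
    result = propagate.rwr(net, seeds=list(mod["seed_genes"]), r=restart)
    return propagate.top_neighbors(result, k=top_k), truth
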