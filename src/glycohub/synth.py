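"""Synthetic data with planted ground truth for every pipeline stage.

Real inputs for this kind of analysis (multi-cohort case/control brain
expression, labeled single-cell counts) sit behind controlled-access
repositories, so the generators here emulate their statistical
structure with known planted effects: Gaussian log-scale bulk
expression with standardized-mean-difference shifts, correlated gene
pairs, an ECM-driver latent factor, a pathway collection carrying a
planted hub glycogene, and negative-binomial single-cell counts with a
planted sender-ligand/receiver-receptor pair and a latent co-expression
module. Every generator takes an explicit integer seed and returns a
JSON-serializable truth record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glycohub.io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GlycogeneTable,
    SingleCellDataset,
)
import anndata as ad

__all__ = [
    "CorrelatedPair",
    "HubSpec",
    "PathwaySpec",
    "EcmDriverSpec",
    "BulkSimSpec",
    "default_bulk_spec",
    "simulate_bulk",
    "simulate_pathways",
    "glycogene_table",
    "LrPlant",
    "ModulePlant",
    "ScSimSpec",
    "default_sc_spec",
    "simulate_single_cell",
]


# ---------------------------------------------------------------------------
# Bulk


@dataclass(frozen=True)
class CorrelatedPair:
    gene_a: str
    gene_b: str
    rho: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")


@dataclass(frozen=True)
class HubSpec:
    """Plant one glycogene into exactly ``n_pathways`` gene sets."""

    gene: str
    n_pathways: int = 10


@dataclass(frozen=True)
class PathwaySpec:
    n_sets: int = 40
    min_size: int = 10
    max_size: int = 30
    overlap: float = 0.5  # fraction of background fill shared between sets
    n_seeded: int = 12  # sets seeded with planted DE genes
    seeded_fraction: float = 0.5  # DE-gene share of a seeded set

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.min_size < 1 or self.max_size < self.min_size:
            raise ValueError("invalid pathway size specification")


@dataclass(frozen=True)
class EcmDriverSpec:
    """A predictor pathway whose latent activity drives ECM activity.

    Per sample a latent factor t ~ N(0,1) loads onto the driver genes
    (unit loading) and onto the ECM signature genes with the stated
    coefficient, plus Gaussian noise of ``noise_sd`` standard
    deviations.
    """

    coefficient: float = 1.0
    noise_sd: float = 0.5
    n_driver_genes: int = 10
    n_ecm_genes: int = 10


@dataclass
class BulkSimSpec:
    """Study conditions for the bulk arm of the synthetic cohort.

    Defaults mirror a three-cohort, two-regions-per-cohort case/control
    design (six meta-analysis strata, echoing the multi-cohort,
    multi-region structure of public AD compendia) with 30 samples per
    arm, 500 genes of which 50 are glycogenes, and planted standardized
    effects of 0.8 (a conventionally large SMD).
    """

    n_cohorts: int = 3
    n_regions: int = 2
    n_genes: int = 500
    n_per_arm: int = 30
    n_glycogenes: int = 50
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true SMD
    correlated_pairs: list[CorrelatedPair] = field(default_factory=list)
    hub: HubSpec | None = None
    pathways: PathwaySpec = field(default_factory=PathwaySpec)
    ecm_driver: EcmDriverSpec | None = None
    baseline_mean_range: tuple[float, float] = (4.0, 10.0)
    baseline_sd_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "n_regions", "n_genes", "n_per_arm", "n_glycogenes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        bad = [g for g in self.de_genes if g not in set(self.gene_universe())]
        if bad:
            raise ValueError(f"planted DE genes outside universe: {bad[:5]}")

    # gene roles, deterministic from the spec
    def glycogenes(self) -> list[str]:
        return [f"GLYC{i:04d}" for i in range(self.n_glycogenes)]

    def ecm_genes(self) -> list[str]:
        if self.ecm_driver is None:
            return []
        return [f"ECMG{i:04d}" for i in range(self.ecm_driver.n_ecm_genes)]

    def driver_genes(self) -> list[str]:
        if self.ecm_driver is None:
            return []
        return [f"DRVG{i:04d}" for i in range(self.ecm_driver.n_driver_genes)]

    def gene_universe(self) -> list[str]:
        special = self.glycogenes() + self.ecm_genes() + self.driver_genes()
        n_bg = self.n_genes - len(special)
        if n_bg < 0:
            raise ValueError("n_genes smaller than the special-role gene count")
        return special + [f"GENE{i:04d}" for i in range(n_bg)]


def default_bulk_spec(seed: int = 0, delta: float = 0.8) -> BulkSimSpec:
    """The standard planted-hub study conditions.

    Ten DE glycogenes (GLYC0000 the hub, in 10 pathways; nine decoys in
    at most 3 each) plus thirty non-glyco DE genes, all at SMD
    ``delta``; a rho=0.9 correlated pair; and an ECM-driver pathway.
    """
    glyco_de = {f"GLYC{i:04d}": delta for i in range(10)}
    other_de = {f"GENE{i:04d}": delta for i in range(30)}
    return BulkSimSpec(
        de_genes={**glyco_de, **other_de},
        correlated_pairs=[CorrelatedPair("GENE0100", "GENE0101", 0.9)],
        hub=HubSpec(gene="GLYC0000", n_pathways=10),
        ecm_driver=EcmDriverSpec(),
        seed=seed,
    )


def glycogene_table(spec: BulkSimSpec) -> GlycogeneTable:
    """Synthetic glycogene annotation: 4 cyclic glycosylation pathways."""
    pathways = ["N-glycosylation", "O-glycosylation", "Glycolipid", "GPI-anchor"]
    genes = spec.glycogenes()
    return GlycogeneTable(
        pd.DataFrame(
            {
                "gene": genes,
                "pathway": [pathways[i % len(pathways)] for i in range(len(genes))],
                "step": ["core" if i % 2 else "initiation" for i in range(len(genes))],
                "pathway_specific": ["yes" if i % 3 else "no" for i in range(len(genes))],
            }
        )
    )


def _pair_correlation_cholesky(
    pairs: Sequence[CorrelatedPair],
) -> tuple[list[str], np.ndarray]:
    """Cholesky factor of the planted correlation structure.

    Raises if the requested structure is not positive semi-definite
    (e.g. inconsistent correlations through a shared gene).
    """
    genes: dict[str, int] = {}
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            genes.setdefault(g, len(genes))
    c = np.eye(len(genes))
    for p in pairs:
        i, j = genes[p.gene_a], genes[p.gene_b]
        c[i, j] = c[j, i] = p.rho
    try:
        chol = np.linalg.cholesky(c + 1e-12 * np.eye(len(genes)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("infeasible (non-PSD) correlation structure") from exc
    return list(genes), chol


def simulate_bulk(
    spec: BulkSimSpec,
) -> tuple[list[ExpressionMatrix], dict]:
    """Gaussian log-scale expression per cohort, with planted structure.

    Within each cohort x region stratum, gene g in sample s is
    mean_g + sd_g * z_gs, with case samples shifted by delta_g * sd_g
    for planted DE genes. Correlated pairs share a bivariate Gaussian
    z; driver/ECM genes load on a per-sample latent factor. Returns one
    :class:`ExpressionMatrix` per cohort (regions stacked in the
    metadata) and the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_universe()
    idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    base_mean = rng.uniform(*spec.baseline_mean_range, size=n_genes)
    base_sd = rng.uniform(*spec.baseline_sd_range, size=n_genes)
    delta = np.zeros(n_genes)
    for g, d in spec.de_genes.items():
        delta[idx[g]] = d

    corr_genes, chol = (
        _pair_correlation_cholesky(spec.correlated_pairs)
        if spec.correlated_pairs
        else ([], np.zeros((0, 0)))
    )
    corr_rows = [idx[g] for g in corr_genes]

    drv = spec.ecm_driver
    driver_rows = [idx[g] for g in spec.driver_genes()]
    ecm_rows = [idx[g] for g in spec.ecm_genes()]

    matrices: list[ExpressionMatrix] = []
    for c in range(spec.n_cohorts):
        cohort = f"cohort{c + 1}"
        blocks, meta_rows = [], []
        for rgn in range(spec.n_regions):
            region = f"region{rgn + 1}"
            n_s = 2 * spec.n_per_arm
            z = rng.standard_normal((n_genes, n_s))
            if corr_rows:
                z[corr_rows] = chol @ rng.standard_normal((len(corr_rows), n_s))
            if drv is not None:
                t = rng.standard_normal(n_s)
                z[driver_rows] = t + drv.noise_sd * rng.standard_normal(
                    (len(driver_rows), n_s)
                )
                z[ecm_rows] = drv.coefficient * t + drv.noise_sd * rng.standard_normal(
                    (len(ecm_rows), n_s)
                )
            x = base_mean[:, None] + base_sd[:, None] * z
            is_case = np.arange(n_s) < spec.n_per_arm
            x[:, is_case] += (delta * base_sd)[:, None]
            ids = [f"{cohort}_{region}_s{i:03d}" for i in range(n_s)]
            blocks.append(pd.DataFrame(x, index=genes, columns=ids))
            for i, sid in enumerate(ids):
                meta_rows.append(
                    {
                        "sample": sid,
                        "cohort": cohort,
                        "region": region,
                        "condition": "case" if is_case[i] else "control",
                    }
                )
        values = pd.concat(blocks, axis=1)
        meta = pd.DataFrame(meta_rows).set_index("sample")
        matrices.append(ExpressionMatrix(values, meta))

    truth = {
        "seed": spec.seed,
        "de_genes": dict(spec.de_genes),
        "glycogenes": spec.glycogenes(),
        "correlated_pairs": [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "rho": p.rho}
            for p in spec.correlated_pairs
        ],
        "hub": None if spec.hub is None else {
            "gene": spec.hub.gene, "n_pathways": spec.hub.n_pathways
        },
        "ecm_genes": spec.ecm_genes(),
        "driver_genes": spec.driver_genes(),
        "ecm_set": "SYN_ECM_ORGANIZATION" if drv is not None else None,
        "driver_set": "SYN_PATHWAY_DRIVER" if drv is not None else None,
    }
    return matrices, truth


def simulate_pathways(spec: BulkSimSpec) -> GeneSetCollection:
    """A gene-set collection coherent with the planted bulk structure.

    Seeded sets carry ``seeded_fraction`` planted DE genes so that
    effect-size GSEA can find them; the hub glycogene appears in
    exactly ``hub.n_pathways`` of them and decoy DE glycogenes in at
    most 3 each. When an ECM driver is planted, the collection includes
    an ECM-named set holding the ECM signature genes and a driver set
    holding the driver genes. Background fill is drawn from non-planted
    genes; with ``overlap=0`` the fill is globally without replacement,
    so backgrounds of distinct sets never intersect.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ps = spec.pathways
    genes = spec.gene_universe()
    de = [g for g in spec.de_genes]
    glyco = set(spec.glycogenes())
    de_glyco = [g for g in de if g in glyco]
    de_other = [g for g in de if g not in glyco]
    special = set(de) | glyco | set(spec.ecm_genes()) | set(spec.driver_genes())
    background = [g for g in genes if g not in special]

    n_seeded = ps.n_seeded
    if spec.hub is not None:
        if spec.hub.n_pathways > ps.n_sets:
            raise ValueError("hub membership count exceeds n_sets")
        n_seeded = max(n_seeded, spec.hub.n_pathways)
    n_seeded = min(n_seeded, ps.n_sets)

    sizes = rng.integers(ps.min_size, ps.max_size + 1, size=ps.n_sets)
    collection = GeneSetCollection()
    bg_cursor = 0

    def draw_background(k: int) -> list[str]:
        nonlocal bg_cursor
        k_shared = int(round(ps.overlap * k))
        k_own = k - k_shared
        if bg_cursor + k_own > len(background):
            raise ValueError("not enough background genes for non-overlapping sets")
        own = background[bg_cursor : bg_cursor + k_own]
        bg_cursor += k_own
        shared = (
            list(rng.choice(background, size=k_shared, replace=False))
            if k_shared
            else []
        )
        # a shared draw may collide with this set's own block; dedupe
        return list(dict.fromkeys(own + shared))

    # round-robin: each decoy DE glycogene lands in <= 3 seeded sets
    decoy_glyco = [g for g in de_glyco if spec.hub is None or g != spec.hub.gene]
    decoy_sets: dict[int, list[str]] = {i: [] for i in range(n_seeded)}
    for d_i, g in enumerate(decoy_glyco):
        for j in range(min(3, n_seeded)):
            decoy_sets[(d_i + j) % n_seeded].append(g)

    for s_i in range(ps.n_sets):
        name = f"SYN_SET_{s_i:03d}"
        size = int(sizes[s_i])
        members: list[str] = []
        if s_i < n_seeded:
            if spec.hub is not None and s_i < spec.hub.n_pathways:
                members.append(spec.hub.gene)
            members.extend(decoy_sets[s_i])
            n_de = max(0, int(np.ceil(ps.seeded_fraction * size)) - len(members))
            pool = [g for g in de_other if g not in members]
            members.extend(pool[i % len(pool)] for i in range(min(n_de, len(pool))))
            members = list(dict.fromkeys(members))
        fill = max(0, size - len(members))
        members.extend(draw_background(fill))
        collection.add(GeneSet(name, "synthetic pathway", tuple(members)))

    if spec.ecm_driver is not None:
        collection.add(
            GeneSet(
                "SYN_ECM_ORGANIZATION",
                "planted ECM signature",
                tuple(spec.ecm_genes()),
            )
        )
        collection.add(
            GeneSet(
                "SYN_PATHWAY_DRIVER",
                "planted driver of ECM activity",
                tuple(spec.driver_genes()),
            )
        )
    return collection


# ---------------------------------------------------------------------------
# Single cell


@dataclass(frozen=True)
class LrPlant:
    """Elevate a ligand in sender cells and its receptor in receivers."""

    ligand: str = "LIG0000"
    receptors: tuple[str, ...] = ("REC0000",)
    sender: str = "oligodendrocyte"
    receiver: str = "astrocyte"
    fold: float = 5.0

    def __post_init__(self) -> None:
        if self.fold < 1.0:
            raise ValueError("fold-up must be >= 1")


@dataclass(frozen=True)
class ModulePlant:
    """A latent-factor co-expression module inside one cell type."""

    celltype: str = "astrocyte"
    seed_genes: tuple[str, ...] = ("SEED0000", "SEED0001")
    member_genes: tuple[str, ...] = tuple(f"MODG{i:04d}" for i in range(28))
    loading: float = 0.8


@dataclass
class ScSimSpec:
    """Study conditions for the synthetic single-cell dataset.

    Negative-binomial counts with gene-specific dispersion; conditions
    split evenly within each cell type. Defaults emulate a small
    vascular-niche experiment: 200 cells per type across four types.
    """

    cell_types: tuple[str, ...] = (
        "astrocyte",
        "oligodendrocyte",
        "pericyte",
        "endothelial",
    )
    n_cells_per_type: int = 200
    conditions: tuple[str, ...] = ("NCI", "AD")
    n_genes: int = 300
    mean_range: tuple[float, float] = (0.5, 4.0)
    dispersion: float = 2.0
    dispersion_overrides: dict[str, float] = field(default_factory=dict)
    condition_fold: dict[str, float] = field(default_factory=dict)  # gene -> AD fold
    lr: LrPlant | None = field(default_factory=LrPlant)
    module: ModulePlant | None = field(default_factory=ModulePlant)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0 or any(
            d <= 0 for d in self.dispersion_overrides.values()
        ):
            raise ValueError("dispersion must be positive")
        if self.lr is not None:
            if self.lr.sender not in self.cell_types or (
                self.lr.receiver not in self.cell_types
            ):
                raise ValueError("sender/receiver must be declared cell types")
        if self.module is not None and self.module.celltype not in self.cell_types:
            raise ValueError("module cell type must be declared")

    def gene_universe(self) -> list[str]:
        special: dict[str, None] = {}
        if self.lr is not None:
            special.setdefault(self.lr.ligand)
            for g in self.lr.receptors:
                special.setdefault(g)
        if self.module is not None:
            for g in (*self.module.seed_genes, *self.module.member_genes):
                special.setdefault(g)
        n_bg = self.n_genes - len(special)
        if n_bg < 0:
            raise ValueError("n_genes smaller than the planted gene count")
        return list(special) + [f"SGENE{i:04d}" for i in range(n_bg)]


def default_sc_spec(seed: int = 0) -> ScSimSpec:
    return ScSimSpec(seed=seed)


def simulate_single_cell(spec: ScSimSpec) -> tuple[SingleCellDataset, dict]:
    """Negative-binomial counts with the planted communication structure.

    The ligand mean is multiplied by the fold-up in sender cells and the
    receptor mean in receiver cells; module genes share a per-cell
    latent factor f ~ N(0,1) within the module cell type through a
    log-normal mean multiplier exp(loading * f - loading^2 / 2), which
    preserves the marginal mean.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_universe()
    idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    base_mean = rng.uniform(*spec.mean_range, size=n_genes)
    theta = np.full(n_genes, spec.dispersion)
    for g, d in spec.dispersion_overrides.items():
        theta[idx[g]] = d

    cells_per_type = {ct: spec.n_cells_per_type for ct in spec.cell_types}
    obs_type: list[str] = []
    obs_cond: list[str] = []
    for ct in spec.cell_types:
        n_ct = cells_per_type[ct]
        obs_type.extend([ct] * n_ct)
        for i in range(n_ct):
            obs_cond.append(spec.conditions[i % len(spec.conditions)])
    n_cells = len(obs_type)
    type_arr = np.asarray(obs_type)
    cond_arr = np.asarray(obs_cond)

    mu = np.tile(base_mean, (n_cells, 1))
    if spec.lr is not None and spec.lr.fold > 1.0:
        mu[type_arr == spec.lr.sender, idx[spec.lr.ligand]] *= spec.lr.fold
        for g in spec.lr.receptors:
            mu[type_arr == spec.lr.receiver, idx[g]] *= spec.lr.fold
    for g, fold in spec.condition_fold.items():
        mu[cond_arr == "AD", idx[g]] *= fold
    if spec.module is not None and spec.module.loading != 0:
        mod_cells = np.where(type_arr == spec.module.celltype)[0]
        f = rng.standard_normal(mod_cells.size)
        lam = spec.module.loading
        mult = np.exp(lam * f - lam**2 / 2.0)
        mod_genes = [idx[g] for g in
                     (*spec.module.seed_genes, *spec.module.member_genes)]
        mu[np.ix_(mod_cells, mod_genes)] *= mult[:, None]

    shape = np.tile(theta, (n_cells, 1))
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.float64)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"cell_type": type_arr, "condition": cond_arr},
            index=[f"cell{i:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=pd.Index(genes)),
    )
    truth = {
        "seed": spec.seed,
        "lr": None if spec.lr is None else {
            "ligand": spec.lr.ligand,
            "receptors": list(spec.lr.receptors),
            "sender": spec.lr.sender,
            "receiver": spec.lr.receiver,
            "fold": spec.lr.fold,
        },
        "module": None if spec.module is None else {
            "celltype": spec.module.celltype,
            "seed_genes": list(spec.module.seed_genes),
            "member_genes": list(spec.module.member_genes),
            "loading": spec.module.loading,
        },
        "condition_fold": dict(spec.condition_fold),
    }
    return adata, truth
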