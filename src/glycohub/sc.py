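"""Single-cell stage: normalization, feature selection, cell-type
profiles, marker tests, ECM activity scoring and ligand-receptor
communication.

Data travel as :class:`anndata.AnnData` (cells x genes raw counts in
``X``, ``cell_type``/``condition`` in ``obs``); normalization adds a
``lognorm`` layer. The ligand-receptor score is a saturating
mass-action summary — score = LR/(Kh + LR) with L and R the mean
normalized ligand expression in the sender type and receptor expression
in the receiver type (geometric mean over subunits for multi-subunit
receptors) — a deliberately simplified stand-in for full CellChat-style
models, with the half-saturation constant Kh exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse

from glycohub.enrich import wilcoxon_rank_sum
from glycohub.meta import bh_fdr

__all__ = [
    "normalize",
    "select_hvg",
    "celltype_profile",
    "find_markers",
    "ecm_score_matrix",
    "LrPair",
    "ligand_receptor_score",
    "interaction_permutation_test",
]

SC_ECM_TOKENS = ("ECM", "Extracellular", "Matrisome", "Collagen")


def _dense(x) -> np.ndarray:
    return x.toarray() if scipy.sparse.issparse(x) else np.asarray(x)


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Library-size normalization: ln(1 + count * scale / cell total).

    Adds a ``lognorm`` layer in place (and returns the object). A cell
    with zero total counts is an error naming its barcode.
    """
    counts = _dense(adata.X)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = adata.obs_names[np.where(totals == 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero total counts")
    adata.layers["lognorm"] = np.log1p(counts * scale / totals[:, None])
    return adata


def select_hvg(adata: ad.AnnData, n: int) -> list[str]:
    """Top-n highly variable genes by VST-style standardized variance.

    A mean-variance trend (degree-2 polynomial of log10 variance on
    log10 mean, over genes with positive mean and variance) predicts a
    per-gene expected SD on raw counts; counts are standardized against
    it, clipped at sqrt(n_cells), and genes are ranked by the variance
    of the clipped values (ties broken alphabetically). Constant genes
    score zero.
    """
    if n > adata.n_vars:
        raise ValueError(f"requested {n} genes but only {adata.n_vars} present")
    counts = _dense(adata.X)
    n_cells = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)

    usable = (mean > 0) & (var > 0)
    std_var = np.zeros(adata.n_vars)
    if usable.sum() >= 3:
        coef = np.polyfit(np.log10(mean[usable]), np.log10(var[usable]), deg=2)
        sd_exp = np.sqrt(10 ** np.polyval(coef, np.log10(mean[usable])))
        z = (counts[:, usable] - mean[usable]) / sd_exp
        clip = np.sqrt(n_cells)
        z = np.clip(z, -clip, clip)
        std_var[usable] = z.var(axis=0, ddof=1)
    order = sorted(
        range(adata.n_vars), key=lambda i: (-std_var[i], adata.var_names[i])
    )
    return [adata.var_names[i] for i in order[:n]]


def celltype_profile(
    adata: ad.AnnData, gene: str, split_condition: bool = False
) -> pd.DataFrame:
    """Mean normalized expression and detection fraction per cell type."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in dataset")
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize() first")
    j = adata.var_names.get_loc(gene)
    norm = np.asarray(adata.layers["lognorm"])[:, j]
    raw = _dense(adata.X)[:, j]
    keys = ["cell_type", "condition"] if split_condition else ["cell_type"]
    df = pd.DataFrame(
        {"norm": norm, "detected": raw > 0, **{k: adata.obs[k].to_numpy() for k in keys}}
    )
    out = (
        df.groupby(keys, sort=True)
        .agg(mean_norm=("norm", "mean"), frac_detected=("detected", "mean"))
        .reset_index()
    )
    return out


def find_markers(
    adata: ad.AnnData,
    group_by: str,
    g1: str,
    g2: str,
    min_frac: float = 0.1,
    min_abs_lfc: float = 0.25,
) -> pd.DataFrame:
    """Wilcoxon marker test between two groups on normalized values.

    log2 fold change uses expm1-backtransformed means with a 1e-9
    pseudocount; genes detected in fewer than ``min_frac`` of cells in
    both groups or with |lfc| below ``min_abs_lfc`` are not tested. BH
    is applied across tested genes. Columns: gene, lfc, frac1, frac2,
    p, q.
    """
    labels = adata.obs[group_by].to_numpy()
    m1, m2 = labels == g1, labels == g2
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError(f"empty group among {g1!r}, {g2!r}")
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize() first")
    norm = np.asarray(adata.layers["lognorm"])
    raw = _dense(adata.X)
    eps = 1e-9

    x1, x2 = norm[m1], norm[m2]
    frac1 = (raw[m1] > 0).mean(axis=0)
    frac2 = (raw[m2] > 0).mean(axis=0)
    lfc = np.log2(
        (np.expm1(x1).mean(axis=0) + eps) / (np.expm1(x2).mean(axis=0) + eps)
    )
    tested = (np.maximum(frac1, frac2) >= min_frac) & (np.abs(lfc) >= min_abs_lfc)

    rows = []
    for j in np.where(tested)[0]:
        _, p = wilcoxon_rank_sum(x1[:, j], x2[:, j])
        rows.append(
            {"gene": adata.var_names[j], "lfc": float(lfc[j]),
             "frac1": float(frac1[j]), "frac2": float(frac2[j]), "p": p}
        )
    out = pd.DataFrame(rows, columns=["gene", "lfc", "frac1", "frac2", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def ecm_score_matrix(
    ora_by_celltype: Mapping[str, pd.DataFrame],
    tokens: Sequence[str] = SC_ECM_TOKENS,
) -> pd.DataFrame:
    """Cell type x ECM pathway matrix of -log10(q) enrichment signals.

    ``ora_by_celltype`` maps a cell type to its marker-gene ORA result.
    Columns are the token-matched set names (union across cell types);
    q is floored at the smallest positive float, and an untested set
    scores 0 for that type.
    """
    lowered = [t.lower() for t in tokens]
    matched: dict[str, None] = {}
    for df in ora_by_celltype.values():
        for name in df["set"]:
            if any(t in name.lower() for t in lowered):
                matched.setdefault(name)
    if not matched:
        warnings.warn("no token-matched pathway in any ORA result")
        return pd.DataFrame(index=list(ora_by_celltype))
    tiny = np.finfo(float).tiny
    mat = pd.DataFrame(0.0, index=list(ora_by_celltype), columns=list(matched))
    for ct, df in ora_by_celltype.items():
        sub = df[df["set"].isin(matched)]
        for _, row in sub.iterrows():
            mat.loc[ct, row["set"]] = -np.log10(max(row["q"], tiny))
    return mat


# ---------------------------------------------------------------------------
# Ligand-receptor communication


@dataclass(frozen=True)
class LrPair:
    """A ligand-receptor pair; multi-subunit receptors list all subunits."""

    ligand: str
    receptors: tuple[str, ...]
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not self.receptors:
            raise ValueError("receptor subunit list must be non-empty")
        if self.ligand in self.receptors:
            raise ValueError("ligand and receptor must differ")
        if not self.pair_id:
            object.__setattr__(
                self, "pair_id", f"{self.ligand}->{'+'.join(self.receptors)}"
            )


def read_lr_pairs(path) -> list[LrPair]:
    """LR pair TSV: columns ligand, receptor (``;``-separated subunits),
    optional pair_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            LrPair(
                row["ligand"],
                tuple(row["receptor"].split(";")),
                row.get("pair_id", "") or "",
            )
        )
    return pairs


def _mean_expression(norm: np.ndarray, mask: np.ndarray, j: int) -> float:
    return float(norm[mask, j].mean())


def ligand_receptor_score(
    adata: ad.AnnData,
    pairs: Sequence[LrPair],
    sender: str,
    receiver: str,
    kh: float = 0.5,
) -> pd.DataFrame:
    """Saturating communication score per pair for one (sender, receiver).

    score = L*R / (Kh + L*R), where L is the mean normalized ligand
    expression over sender cells and R the mean receptor expression over
    receiver cells (geometric mean across subunits). Pairs with genes
    missing from the dataset are skipped with a warning.
    """
    if kh <= 0:
        raise ValueError("Kh must be positive")
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize() first")
    norm = np.asarray(adata.layers["lognorm"])
    types = adata.obs["cell_type"].to_numpy()
    s_mask, r_mask = types == sender, types == receiver
    if s_mask.sum() == 0 or r_mask.sum() == 0:
        raise ValueError("sender or receiver type has no cells")

    rows = []
    for pair in pairs:
        needed = (pair.ligand, *pair.receptors)
        if any(g not in adata.var_names for g in needed):
            warnings.warn(f"pair {pair.pair_id}: gene(s) missing; skipped")
            continue
        lbar = _mean_expression(norm, s_mask, adata.var_names.get_loc(pair.ligand))
        sub_means = [
            _mean_expression(norm, r_mask, adata.var_names.get_loc(g))
            for g in pair.receptors
        ]
        rbar = float(np.prod(sub_means) ** (1.0 / len(sub_means)))
        lr = lbar * rbar
        rows.append(
            {"pair": pair.pair_id, "sender": sender, "receiver": receiver,
             "L": lbar, "R": rbar, "score": lr / (kh + lr)}
        )
    return pd.DataFrame(rows, columns=["pair", "sender", "receiver", "L", "R", "score"])


def interaction_permutation_test(
    adata: ad.AnnData,
    pair: LrPair,
    sender: str,
    receiver: str,
    n_perm: int = 100,
    seed: int = 0,
    kh: float = 0.5,
) -> tuple[float, float]:
    """Label-permutation significance of one pair's communication score.

    Cell-type labels are permuted across all cells; the p-value is
    (1 + #{score_perm >= score_obs})/(1 + n_perm). Returns
    (observed score, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = ligand_receptor_score(adata, [pair], sender, receiver, kh=kh)
    if obs.empty:
        raise ValueError("pair genes missing from dataset")
    score_obs = float(obs["score"].iloc[0])

    norm = np.asarray(adata.layers["lognorm"])
    lig = norm[:, adata.var_names.get_loc(pair.ligand)]
    recs = np.column_stack(
        [norm[:, adata.var_names.get_loc(g)] for g in pair.receptors]
    )
    types = adata.obs["cell_type"].to_numpy()
    n_s = int((types == sender).sum())
    n_r = int((types == receiver).sum())
    n = adata.n_obs

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # permuting labels == assigning the first n_s permuted cells to the
        # sender slot and the next n_r to the receiver slot
        s_idx = perm[:n_s]
        r_idx = perm[n_s : n_s + n_r]
        lbar = float(lig[s_idx].mean())
        sub = recs[r_idx].mean(axis=0)
        rbar = float(np.prod(sub) ** (1.0 / sub.size))
        lr = lbar * rbar
        if lr / (kh + lr) >= score_obs - 1e-15:
            hits += 1
    return score_obs, (1 + hits) / (1 + n_perm)
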