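"""Over-representation analysis, preranked GSEA and the dual post-hoc
glyco-pathway test.

ORA uses the hypergeometric upper tail against an all-gene background.
Preranked GSEA implements the weighted Kolmogorov-Smirnov running sum
(weight exponent 1) with a gene-label permutation null, normalized
enrichment scores and same-sign permutation p-values. The dual post-hoc
test asks, for each (glycosylation pathway, enriched pathway) pair,
whether the glyco members are over-represented in the pathway
(hypergeometric) AND carry larger absolute effect sizes than the
pathway's other members (Wilcoxon rank-sum); both families are BH
corrected and a pair passes only if both q-values clear the FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glycohub.io import GeneSetCollection, GlycogeneTable
from glycohub.meta import bh_fdr

__all__ = [
    "ora_hypergeom",
    "top_sets",
    "GseaResult",
    "gsea_preranked",
    "wilcoxon_rank_sum",
    "glyco_posthoc_dual_test",
]


# ---------------------------------------------------------------------------
# Over-representation analysis


def ora_hypergeom(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    For a set with K members in the universe of size N and a query of
    size n, p = P[X >= k] with X ~ Hypergeom(N, K, n) and k the observed
    overlap. Query genes outside the universe are dropped with a
    warning. Returns columns: set, k, K, n, N, p, q.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q_in = [g for g in dict.fromkeys(query) if g in uni]
    outside = len(set(query)) - len(q_in)
    if outside:
        warnings.warn(f"{outside} query genes outside the universe; dropped")
    qset = set(q_in)
    n, N = len(qset), len(uni)

    rows = []
    for s in collection:
        members = set(s.members) & uni
        K = len(members)
        k = len(members & qset)
        # upper tail P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": s.name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def top_sets(ora: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """Top-n enriched sets, sorted by q then p then name (deterministic)."""
    return ora.sort_values(["q", "p", "set"], kind="mergesort").head(n).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Preranked GSEA


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    leading_edge: tuple[str, ...]
    n_perm: int


def _order_ranks(ranks: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Genes sorted by score descending, ties broken by gene name."""
    genes = np.array(sorted(ranks, key=lambda g: (-ranks[g], g)))
    scores = np.array([ranks[g] for g in genes], dtype=float)
    return genes, scores


def _enrichment_score(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score and the index of its extremum.

    Hit increments are |score|^w normalized over the set; misses
    decrement 1/(N - |S|). The ES is the running-sum value of largest
    magnitude.
    """
    absw = np.abs(scores) ** weight
    hit_total = absw[hit_mask].sum()
    n_miss = hit_mask.size - int(hit_mask.sum())
    step = np.where(
        hit_mask,
        absw / hit_total if hit_total > 0 else 1.0 / max(int(hit_mask.sum()), 1),
        -1.0 / n_miss if n_miss else 0.0,
    )
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def gsea_preranked(
    ranks: Mapping[str, float],
    gene_set: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Preranked GSEA of one gene set against a gene -> score ranking.

    The null distribution is generated by gene-label permutation: random
    same-size gene sets drawn from the ranked universe. NES = ES divided
    by the mean |null ES| of the same sign; p is the same-sign
    permutation tail (1 + hits)/(1 + same-sign count).
    """
    if len(ranks) < 2:
        raise ValueError("need at least 2 ranked genes")
    vals = np.array(list(ranks.values()), dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("NaN or infinite scores in ranking")
    genes, scores = _order_ranks(ranks)
    gene_pos = {g: i for i, g in enumerate(genes)}
    hits = sorted({gene_pos[g] for g in gene_set if g in gene_pos})
    if not hits:
        raise ValueError("gene set is disjoint from the ranked genes")
    n = genes.size
    hit_mask = np.zeros(n, dtype=bool)
    hit_mask[hits] = True

    es, peak = _enrichment_score(scores, hit_mask, weight)
    if es >= 0:
        leading = tuple(genes[i] for i in hits if i <= peak)
    else:
        leading = tuple(genes[i] for i in hits if i >= peak)

    rng = np.random.default_rng(seed)
    m = len(hits)
    # vectorized gene-label permutation null: random same-size sets
    rand = rng.random((n_perm, n))
    hit_idx = np.argpartition(rand, m - 1, axis=1)[:, :m]
    masks = np.zeros((n_perm, n), dtype=bool)
    masks[np.arange(n_perm)[:, None], hit_idx] = True
    absw = np.abs(scores) ** weight
    hit_tot = (absw * masks).sum(axis=1)
    hit_tot[hit_tot == 0] = 1.0
    n_miss = n - m
    steps = np.where(
        masks, absw / hit_tot[:, None], (-1.0 / n_miss) if n_miss else 0.0
    )
    running = np.cumsum(steps, axis=1)
    null_es = running[np.arange(n_perm), np.abs(running).argmax(axis=1)]

    same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if same.size == 0 or np.mean(np.abs(same)) == 0:
        nes = float("nan")
        p = 1.0
    else:
        nes = float(es / np.mean(np.abs(same)))
        p = float((1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size))
    return GseaResult(
        set_name="", es=es, nes=nes, p=p, leading_edge=leading, n_perm=n_perm
    )


def gsea_collection(
    ranks: Mapping[str, float],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 2,
) -> pd.DataFrame:
    """GSEA over every set in a collection, with BH q across sets.

    Sets with fewer than ``min_size`` ranked members are skipped.
    """
    rows = []
    rng = np.random.default_rng(seed)
    ranked = set(ranks)
    for s in collection:
        if len(set(s.members) & ranked) < min_size:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        r = gsea_preranked(ranks, s.members, n_perm=n_perm, seed=sub_seed)
        rows.append(
            {"set": s.name, "es": r.es, "nes": r.nes, "p": r.p,
             "leading_edge": ",".join(r.leading_edge)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (shared by the single-cell marker test)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U for ``x`` (vs ``y``) with a two-sided p-value.

    Exact enumeration when n_x + n_y <= 12 and the data are tie-free;
    otherwise the normal approximation with midranks, tie correction and
    continuity correction. A completely tied comparison returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Dual post-hoc glyco-pathway test


def glyco_posthoc_dual_test(
    enriched: GeneSetCollection,
    glyco: GlycogeneTable,
    effect_table: pd.DataFrame,
    fdr: float = 0.05,
    background: str = "pathway",
) -> pd.DataFrame:
    """Which glycosylation pathways drive which enriched pathways.

    For each (glycosylation pathway, enriched pathway) pair, two tests
    are run over the meta-analyzed gene universe (``effect_table`` rows,
    columns ``gene`` and ``mu``):

    * hypergeometric over-representation of the glyco-pathway members
      within the enriched pathway, and
    * Wilcoxon rank-sum comparing |combined effect| of the enriched
      pathway's glyco members against its non-glyco members
      (``background="pathway"``) or against all non-members of the glyco
      pathway (``background="global"``).

    BH is applied within each test family; a pair passes iff both
    q-values are <= ``fdr`` (inclusive). Glyco pathways with no member
    in the universe are skipped with a warning.
    """
    universe = dict.fromkeys(effect_table["gene"])
    abs_mu = dict(zip(effect_table["gene"], np.abs(effect_table["mu"].to_numpy())))
    N = len(universe)

    rows = []
    for pathway, members in glyco.by_pathway().items():
        glyco_in = [g for g in members if g in universe]
        if not glyco_in:
            warnings.warn(f"glyco pathway {pathway!r} has no member in universe; skipped")
            continue
        gset = set(glyco_in)
        for s in enriched:
            set_in = [g for g in s.members if g in universe]
            overlap = [g for g in set_in if g in gset]
            K = len(set_in)
            k = len(overlap)
            p_hyper = (
                float(stats.hypergeom.sf(k - 1, N, K, len(glyco_in))) if K else 1.0
            )
            in_effects = [abs_mu[g] for g in overlap]
            if background == "pathway":
                out_effects = [abs_mu[g] for g in set_in if g not in gset]
            else:
                out_effects = [abs_mu[g] for g in universe if g not in gset]
            if in_effects and out_effects:
                _, p_wil = wilcoxon_rank_sum(in_effects, out_effects)
            else:
                p_wil = 1.0
            rows.append(
                {
                    "glyco_pathway": pathway,
                    "enriched_set": s.name,
                    "k": k,
                    "p_hyper": min(p_hyper, 1.0),
                    "p_wilcoxon": p_wil,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_hyper"] = bh_fdr(out["p_hyper"].to_numpy())
    out["q_wilcoxon"] = bh_fdr(out["p_wilcoxon"].to_numpy())
    out["passes"] = (out["q_hyper"] <= fdr) & (out["q_wilcoxon"] <= fdr)
    return out
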