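"""Pathway-activity association with an ECM outcome, plus gene and
eigengene correlation analyses.

Per cohort x region stratum, the ECM outcome is a pathway activity
(mean or eigengene of the ECM signature genes) and each candidate
pathway is summarized by the leading principal components of its
member submatrix; a permutation F-test gives a per-stratum p-value and
Fisher's method combines strata into one p per pathway. This is an
ordinary-PCA analogue of adaptive elastic-net sparse pathway PCA
regression: the sparsity refinement is dropped in favour of a
deterministic, dependency-light estimator (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from glycohub.io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "PathwayActivity",
    "pathway_activity",
    "ecm_pathway_signature",
    "pca_regression_association",
    "fisher_combine",
    "gene_signature_correlation",
    "signature_effect_summary",
]

ECM_TOKENS = ("ECM", "Extracellular", "Collagen")


@dataclass
class PathwayActivity:
    """Per-sample activity summary of a gene set."""

    name: str
    scores: pd.Series  # indexed by sample id
    method: str  # "mean" | "eigengene"


def _standardize(mat: np.ndarray) -> np.ndarray:
    """Row-standardize (per gene); zero-variance rows become zeros."""
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def _pc_scores(mat_std: np.ndarray, n_pc: int) -> np.ndarray:
    """First ``n_pc`` principal-component scores (samples x n_pc).

    ``mat_std`` is genes x samples, already standardized per gene.
    Scores are centered; the deterministic sign is fixed downstream.
    """
    x = mat_std.T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return x @ vt[:n_pc].T


def pathway_activity(
    expr: ExpressionMatrix, gene_set: Sequence[str], method: str = "mean"
) -> PathwayActivity:
    """Per-sample pathway activity: member mean or first eigengene.

    The eigengene (first PC score of the standardized member submatrix)
    is sign-aligned so that its correlation with the member mean is
    non-negative, making the score invariant to the sign ambiguity of
    the SVD.
    """
    members = [g for g in dict.fromkeys(gene_set) if g in expr.genes]
    if not members:
        raise ValueError("no pathway members present in the expression matrix")
    sub = expr.values.loc[members]
    if method == "mean":
        scores = sub.mean(axis=0)
    elif method == "eigengene":
        if len(members) < 2:
            raise ValueError("eigengene requires >=2 member genes")
        pc1 = _pc_scores(_standardize(sub.to_numpy()), 1)[:, 0]
        mean_act = sub.mean(axis=0).to_numpy()
        if np.std(mean_act) > 0 and np.corrcoef(pc1, mean_act)[0, 1] < 0:
            pc1 = -pc1
        scores = pd.Series(pc1, index=sub.columns)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PathwayActivity(name="", scores=scores, method=method)


def ecm_pathway_signature(
    collection: GeneSetCollection, tokens: Sequence[str] = ECM_TOKENS
) -> tuple[list[str], list[str]]:
    """ECM pathway names and their union gene signature.

    A set matches if its name contains any token, case-insensitively
    ("ECM", "Extracellular", "Collagen" by default).
    """
    lowered = [t.lower() for t in tokens]
    names = [s.name for s in collection if any(t in s.name.lower() for t in lowered)]
    if not names:
        warnings.warn("no pathway name matched the ECM tokens")
        return [], []
    signature: dict[str, None] = {}
    for n in names:
        for g in collection.members(n):
            signature.setdefault(g)
    return names, list(signature)


def pca_regression_association(
    expr: ExpressionMatrix,
    outcome: PathwayActivity | pd.Series,
    predictor_set: Sequence[str],
    n_pc: int = 1,
    n_perm: int = 999,
    seed: int = 0,
    exclude: Sequence[str] = (),
) -> float:
    """Permutation p-value for outcome ~ predictor-pathway PC scores.

    Predictor genes also present in ``exclude`` (typically the ECM
    signature itself) are removed before computing PCs. The observed
    statistic is the regression F; significance comes from permuting the
    outcome across samples: p = (1 + #{F_perm >= F_obs})/(1 + n_perm).
    """
    y = outcome.scores if isinstance(outcome, PathwayActivity) else outcome
    excl = set(exclude)
    members = [
        g for g in dict.fromkeys(predictor_set) if g in expr.genes and g not in excl
    ]
    if not members:
        raise ValueError("no usable predictor genes")
    shared = [s for s in expr.sample_ids if s in y.index]
    n = len(shared)
    if n < n_pc + 2:
        raise ValueError(f"need >= {n_pc + 2} samples, got {n}")

    sub = expr.values.loc[members, shared].to_numpy()
    pcs = _pc_scores(_standardize(sub), min(n_pc, len(members)))
    yv = y.loc[shared].to_numpy(dtype=float)
    yc = yv - yv.mean()

    # orthonormal basis of the centered predictor space; F is monotone in
    # R^2 for fixed dimensions, so tail counts use R^2 directly
    xc = pcs - pcs.mean(axis=0, keepdims=True)
    qmat, rmat = np.linalg.qr(xc)
    keep = np.abs(np.diag(rmat)) > 1e-12
    qmat = qmat[:, keep]
    p_dim = qmat.shape[1]
    if p_dim == 0:
        raise ValueError("predictor PCs are degenerate")

    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("outcome has zero variance")
    r2_obs = float(np.sum((qmat.T @ yc) ** 2)) / tss

    rng = np.random.default_rng(seed)
    perm = np.empty((n, n_perm))
    for b in range(n_perm):
        perm[:, b] = yc[rng.permutation(n)]
    r2_perm = np.sum((qmat.T @ perm) ** 2, axis=0) / tss
    return float((1 + np.sum(r2_perm >= r2_obs - 1e-15)) / (1 + n_perm))


def fisher_combine(p: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: X^2 = -2 sum(ln p) on 2k degrees of freedom."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return x2, df, float(stats.chi2.sf(x2, df))


def gene_signature_correlation(
    expr: ExpressionMatrix,
    gene: str,
    partner: str | PathwayActivity,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-stratum Pearson correlation of a gene with a gene or activity.

    Returns one row per cohort x region stratum: cohort, region, r, p,
    n. Strata with fewer than ``min_samples`` shared samples are
    skipped; zero-variance vectors raise.
    """
    if gene not in expr.genes:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    rows = []
    for cohort, region in expr.strata():
        sub = expr.subset_stratum(cohort, region)
        x = sub.values.loc[gene]
        if isinstance(partner, PathwayActivity):
            shared = [s for s in sub.sample_ids if s in partner.scores.index]
            y = partner.scores.loc[shared]
            x = x.loc[shared]
        else:
            if partner not in expr.genes:
                raise KeyError(f"gene {partner!r} not in expression matrix")
            y = sub.values.loc[partner]
        if len(x) < min_samples:
            continue
        if np.std(x.to_numpy()) == 0 or np.std(y.to_numpy()) == 0:
            raise ValueError(f"zero-variance vector in stratum {(cohort, region)}")
        r, p = stats.pearsonr(x.to_numpy(), y.to_numpy())
        rows.append(
            {"cohort": cohort, "region": region, "r": float(r), "p": float(p),
             "n": len(x)}
        )
    return pd.DataFrame(rows)


def signature_effect_summary(
    effects: pd.DataFrame, signature: Sequence[str]
) -> pd.DataFrame:
    """Forest-plot input: mean effect and 95% CI per stratum.

    ``effects`` is the long per-stratum table (gene, cohort, region, g,
    se). With m >= 2 signature genes in a stratum the CI is
    mean +/- 1.96 sd/sqrt(m); a single gene passes through with a CI
    from its own standard error. A signature disjoint from the table is
    an error.
    """
    sig = set(signature)
    sub = effects[effects["gene"].isin(sig)]
    if sub.empty:
        raise ValueError("signature has no overlap with the effect table")
    rows = []
    for (cohort, region), grp in sub.groupby(["cohort", "region"], sort=True):
        g = grp["g"].to_numpy()
        m = g.size
        if m >= 2:
            mean = float(g.mean())
            half = 1.96 * float(g.std(ddof=1)) / np.sqrt(m)
        else:
            mean = float(g[0])
            half = 1.96 * float(grp["se"].iloc[0])
        rows.append(
            {"cohort": cohort, "region": region, "estimate": mean,
             "lo": mean - half, "hi": mean + half, "m": m}
        )
    return pd.DataFrame(rows)
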