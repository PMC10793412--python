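"""Per-gene standardized-mean-difference meta-analysis across cohorts.

Each cohort x brain-region stratum contributes a Hedges' g (bias-
corrected standardized mean difference between case and control arms on
log-scale expression). Strata are combined per gene under a random-
effects model with the between-study variance tau^2 estimated by
restricted maximum likelihood (default) or DerSimonian-Laird, and the
resulting p-values are corrected by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from glycohub.io import ExpressionMatrix, GlycogeneTable

__all__ = [
    "EffectSize",
    "hedges_g",
    "combine_random_effects",
    "bh_fdr",
    "per_stratum_effects",
    "meta_differential_expression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSize:
    """Hedges' g for one cohort x region stratum."""

    g: float
    se: float
    n_case: int
    n_control: int
    cohort: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each arm requires at least 2 samples")


def _hedges_arrays(
    mean_case: np.ndarray,
    var_case: np.ndarray,
    n1: int,
    mean_ctrl: np.ndarray,
    var_ctrl: np.ndarray,
    n0: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Hedges' g and its SE from per-arm summary statistics.

    d = (m1 - m0) / s_pooled, with s_pooled from unbiased per-arm
    variances; the small-sample correction is J = 1 - 3/(4(n1+n0) - 9)
    and se(g)^2 = J^2 * [(n1+n0)/(n1*n0) + d^2/(2(n1+n0))].
    Zero pooled SD yields NaN (callers decide whether that is an error).
    """
    n = n1 + n0
    sp2 = ((n1 - 1) * var_case + (n0 - 1) * var_ctrl) / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sp2 > 0, (mean_case - mean_ctrl) / np.sqrt(sp2), np.nan)
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    g = j * d
    se = j * np.sqrt(n / (n1 * n0) + d**2 / (2.0 * n))
    return g, se


def hedges_g(
    case: Sequence[float],
    control: Sequence[float],
    cohort: str = "",
    region: str = "",
) -> EffectSize:
    """Bias-corrected standardized mean difference of case vs control."""
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each arm requires at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    g, se = _hedges_arrays(
        x.mean(), x.var(ddof=1), x.size, y.mean(), y.var(ddof=1), y.size
    )
    if not np.isfinite(g):
        raise ValueError("degenerate input: pooled standard deviation is zero")
    return EffectSize(float(g), float(se), x.size, y.size, cohort, region)


# ---------------------------------------------------------------------------
# Random-effects combination


def _dl_tau2(g: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator, truncated at zero."""
    w = 1.0 / v
    mu_fe = np.sum(w * g) / np.sum(w)
    q = float(np.sum(w * (g - mu_fe) ** 2))
    df = g.size - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (q - df) / denom)


def _reml_tau2(
    g: np.ndarray, v: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[float, bool]:
    """REML estimate of tau^2 by fixed-point iteration, floored at zero.

    Iterates tau2 <- sum(w^2 [(g-mu)^2 - v]) / sum(w^2) + 1/sum(w) with
    w = 1/(v + tau2), the stationarity condition of the restricted
    likelihood. Returns (tau2, converged).
    """
    tau2 = _dl_tau2(g, v)  # moment start
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * g) / np.sum(w)
        new = np.sum(w**2 * ((g - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(0.0, float(new))
        if abs(new - tau2) < tol:
            return new, True
        tau2 = new
    return tau2, False


def combine_random_effects(
    effects: Sequence[EffectSize], method: str = "reml"
) -> dict:
    """Combine per-stratum effects under a random-effects model.

    Weights are w_i = 1/(se_i^2 + tau^2); the combined effect is the
    weighted mean with se = (sum w_i)^(-1/2). A single stratum passes
    through unchanged with tau^2 = 0. If REML fails to converge the
    DerSimonian-Laird estimate is used with a logged warning.

    The two-sided p-value compares z = mu/se against a t reference with
    the total residual degrees of freedom, sum_i (n_case_i +
    n_control_i - 2): each stratum's standard error is itself
    estimated, and a plain normal reference is anti-conservative in the
    far tail, which matters when many genes are screened at once. With
    typical arm sizes the reference is close to normal.

    Returns a dict with keys ``mu``, ``se``, ``tau2``, ``Q``, ``z``,
    ``p``, ``k`` and ``method``.
    """
    if len(effects) == 0:
        raise ValueError("no effects to combine")
    if method not in ("reml", "dl"):
        raise ValueError(f"unknown method {method!r}")
    g = np.array([e.g for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    v = se**2

    k = g.size
    w_fe = 1.0 / v
    mu_fe = np.sum(w_fe * g) / np.sum(w_fe)
    q = float(np.sum(w_fe * (g - mu_fe) ** 2))

    used = method
    if k == 1:
        tau2 = 0.0
    elif method == "dl":
        tau2 = _dl_tau2(g, v)
    else:
        tau2, converged = _reml_tau2(g, v)
        if not converged:
            logger.warning("REML did not converge; falling back to DerSimonian-Laird")
            tau2 = _dl_tau2(g, v)
            used = "dl"

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * g) / np.sum(w))
    se_mu = float(1.0 / np.sqrt(np.sum(w)))
    z = mu / se_mu
    df = sum(e.n_case + e.n_control - 2 for e in effects)
    p = float(2.0 * stats.t.sf(abs(z), df))
    return {
        "mu": mu,
        "se": se_mu,
        "tau2": float(tau2),
        "Q": q,
        "z": float(z),
        "p": p,
        "k": int(k),
        "method": used,
    }


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Whole-transcriptome meta-analysis


def per_stratum_effects(
    cohorts: Iterable[ExpressionMatrix],
    genes: Sequence[str] | None = None,
    min_per_arm: int = 2,
) -> pd.DataFrame:
    """Hedges' g per gene per cohort x region stratum (long format).

    Strata where either arm has fewer than ``min_per_arm`` samples are
    skipped; genes with zero pooled SD in a stratum are dropped from
    that stratum. Columns: gene, cohort, region, g, se, n_case,
    n_control.
    """
    rows: list[pd.DataFrame] = []
    for expr in cohorts:
        use = expr.genes if genes is None else [g for g in genes if g in expr.genes]
        if len(use) == 0:
            continue
        for cohort, region in expr.strata():
            sub = expr.subset_stratum(cohort, region)
            case_ids, ctrl_ids = sub.condition_arms()
            if len(case_ids) < min_per_arm or len(ctrl_ids) < min_per_arm:
                continue
            xc = sub.values.loc[use, case_ids].to_numpy()
            x0 = sub.values.loc[use, ctrl_ids].to_numpy()
            g, se = _hedges_arrays(
                xc.mean(axis=1),
                xc.var(axis=1, ddof=1),
                xc.shape[1],
                x0.mean(axis=1),
                x0.var(axis=1, ddof=1),
                x0.shape[1],
            )
            ok = np.isfinite(g)
            rows.append(
                pd.DataFrame(
                    {
                        "gene": np.asarray(use)[ok],
                        "cohort": cohort,
                        "region": region,
                        "g": g[ok],
                        "se": se[ok],
                        "n_case": len(case_ids),
                        "n_control": len(ctrl_ids),
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "cohort", "region", "g", "se", "n_case", "n_control"]
        )
    return pd.concat(rows, ignore_index=True)


def _combine_table(effects: pd.DataFrame, method: str) -> pd.DataFrame:
    """Vectorized random-effects combination of a long effect table."""
    records = []
    for gene, sub in effects.groupby("gene", sort=True):
        es = [
            EffectSize(r.g, r.se, int(r.n_case), int(r.n_control), r.cohort, r.region)
            for r in sub.itertuples()
        ]
        row = combine_random_effects(es, method=method)
        row["gene"] = gene
        records.append(row)
    return pd.DataFrame.from_records(records)


def meta_differential_expression(
    cohorts: Sequence[ExpressionMatrix],
    glycogenes: GlycogeneTable | None = None,
    method: str = "reml",
    fdr: float = 0.05,
    per_region: bool = False,
    correction_universe: str = "filtered",
) -> pd.DataFrame:
    """Random-effects meta-analysis of case vs control across cohorts.

    When a glycogene table is supplied, the analysis (and by default the
    BH correction) is restricted to glycogenes present in at least one
    cohort; set ``correction_universe="global"`` to correct over all
    genes and then subset. ``per_region=True`` combines within each
    region separately and returns one row per gene x region.

    Returns a table with columns gene, k, mu, se, tau2, Q, z, p, q,
    is_deg (q < ``fdr``) plus ``region`` in per-region mode.
    """
    if len(cohorts) == 0:
        raise ValueError("at least one cohort is required")

    all_genes: dict[str, None] = {}
    for expr in cohorts:
        for g in expr.genes:
            all_genes.setdefault(g)

    if glycogenes is not None and correction_universe == "filtered":
        wanted = [g for g in glycogenes.genes if g in all_genes]
        dropped = [g for g in glycogenes.genes if g not in all_genes]
        if dropped:
            warnings.warn(f"{len(dropped)} glycogenes absent from all cohorts; dropped")
        universe = wanted
    else:
        universe = list(all_genes)

    effects = per_stratum_effects(cohorts, genes=universe)
    if effects.empty:
        raise ValueError("no usable strata (need >=2 samples per arm)")

    def finish(tab: pd.DataFrame) -> pd.DataFrame:
        tab = tab.copy()
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        if glycogenes is not None and correction_universe == "global":
            keep = set(glycogenes.genes)
            tab = tab[tab["gene"].isin(keep)].reset_index(drop=True)
        tab["is_deg"] = tab["q"] < fdr
        cols = ["gene", "k", "mu", "se", "tau2", "Q", "z", "p", "q", "is_deg"]
        if "region" in tab.columns:
            cols = ["gene", "region"] + cols[1:]
        return tab[cols + ["method"]]

    if per_region:
        pieces = []
        for region, sub in effects.groupby("region", sort=True):
            tab = _combine_table(sub, method)
            tab["region"] = region
            pieces.append(tab)
        return finish(pd.concat(pieces, ignore_index=True))
    return finish(_combine_table(effects, method))
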