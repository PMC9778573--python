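"""Per-dataset differential expression and cross-dataset meta-analysis.

The two-group comparison uses a pooled linear model with empirical-Bayes
variance moderation: per-gene residual variances s_g^2 are shrunk toward a
prior s0^2 by treating the s_g^2 as draws from a scaled inverse-chi-square
distribution whose hyperparameters (d0, s0^2) are estimated by matching the
first two moments of log s_g^2. The moderated t-statistic

    t_g = log2FC_g / sqrt(s~_g^2 * (1/n1 + 1/n2)),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

is referred to a t distribution with d_g + d0 degrees of freedom. A gene is
called differential when its BH-adjusted p-value passes ``alpha`` AND its
absolute log2 fold change passes log2(fc_threshold) — both filters, always.

Cross-dataset meta-analysis is intersection by gene id, ignoring direction
for membership but recording per-dataset directions and flagging conflicts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["log2fc", "t", "df_total", "p", "p_adj", "direction"]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges from
    x0 = 0.5 + 1/y for all y > 0.
    """
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Hyperparameters (d0, s0^2) of the scaled inverse-chi-square prior.

    Method of moments on z = log s^2: under the hierarchical model,
    E z = log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    Var z = trigamma(df/2) + trigamma(d0/2).
    A sample variance of z not exceeding trigamma(df/2) means no excess
    dispersion: the prior df is infinite (all variances equal s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; cannot fit variance prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def moderated_ttest(
    data: ExpressionDataset,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test for every gene (case minus control).

    Parameters
    ----------
    data
        Expression dataset with >= 3 samples per phenotype.
    prior_df, prior_var
        Override the estimated hyperparameters. ``prior_df=0`` reduces to the
        ordinary pooled t-test; ``prior_df=inf`` replaces every s_g^2 by the
        prior variance.

    Returns
    -------
    DataFrame indexed by gene with columns log2fc, t, df_total, p, p_adj
    (p_adj filled by :func:`bh_adjust`), direction (set by
    :func:`call_degs`; ``"ns"`` here).
    """
    case = data.case_matrix().to_numpy(dtype=float)
    ctrl = data.control_matrix().to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    df_resid = n1 + n2 - 2
    if df_resid < 2:
        raise ValueError("need >= 2 residual degrees of freedom")

    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    if np.all(s2 == 0):
        raise ValueError("all genes have zero within-group variance")

    d0_hat, s0_hat = fit_variance_prior(s2, df_resid)
    d0 = d0_hat if prior_df is None else float(prior_df)
    s0_sq = s0_hat if prior_var is None else float(prior_var)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    elif d0 == 0:
        # no shrinkage; zero-variance genes fall back to the prior variance
        s2_post = np.where(s2 > 0, s2, s0_sq)
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(df_resid + d0)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = lfc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "df_total": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
            "direction": "ns",
        },
        index=data.genes,
    )
    out.index.name = "gene"
    out.attrs["dataset"] = data.name
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    results: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 2.0
) -> pd.DataFrame:
    """Filter to differential genes: p_adj < alpha AND |log2fc| >= log2(fc_threshold).

    Returns the surviving rows with ``direction`` set to up/down by the sign
    of the fold change.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (fold scale)")
    lfc_cut = math.log2(fc_threshold)
    keep = (results["p_adj"] < alpha) & (results["log2fc"].abs() >= lfc_cut)
    degs = results.loc[keep].copy()
    degs["direction"] = np.where(degs["log2fc"] > 0, "up", "down")
    degs.attrs.update(results.attrs)
    return degs


@dataclass
class CommonDEGSet:
    """Genes differential in every input dataset, with per-dataset directions."""

    genes: set[str]
    directions: pd.DataFrame  # genes x datasets, values in {"up", "down"}
    conflicting: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.genes)


def intersect_degs(per_dataset: dict[str, pd.DataFrame]) -> CommonDEGSet:
    """Intersect called DEG tables by gene id across >= 2 datasets.

    Membership ignores direction; genes whose direction disagrees between
    datasets are retained but listed in ``conflicting``.
    """
    if len(per_dataset) == 0:
        raise ValueError("need at least one called DEG table")
    sets = [set(df.index) for df in per_dataset.values()]
    common = set.intersection(*sets)
    directions = pd.DataFrame(
        {name: df["direction"].reindex(sorted(common)) for name, df in per_dataset.items()}
    )
    directions.index.name = "gene"
    conflicting = {
        g for g, row in directions.iterrows() if len(set(row.dropna())) > 1
    }
    if conflicting:
        logger.info("%d common DEGs have conflicting directions across datasets", len(conflicting))
    return CommonDEGSet(genes=common, directions=directions, conflicting=conflicting)


def hypergeometric_ora(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set (one-sided hypergeometric).

    Each gene set is intersected with the universe before testing; the
    p-value is the upper tail P(X >= observed overlap). BH adjustment across
    sets; significant iff adjusted p < alpha.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not set(query) <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        overlap = len(query & members)
        # P(X >= overlap) with X ~ Hypergeom(N=universe, K=set size, n=query size)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"]).set_index(
        "gene_set"
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values(["p", "gene_set"], kind="stable")


def fisher_combine(pmatrix: pd.DataFrame) -> pd.Series:
    """Combine per-dataset unadjusted p-values per gene by Fisher's method.

    ``pmatrix`` is genes x datasets; rows with any missing value are dropped.
    """
    clean = pmatrix.dropna()
    if clean.shape[1] == 1:
        return clean.iloc[:, 0]
    stat = -2.0 * np.log(np.clip(clean.to_numpy(dtype=float), 1e-300, 1.0)).sum(axis=1)
    p = stats.chi2.sf(stat, df=2 * clean.shape[1])
    return pd.Series(p, index=clean.index, name="p_combined")
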