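"""Pre-clinical validation on an independent cohort.

Diagnostics: per-gene ROC AUC computed as the Mann-Whitney probability
(concordant pairs plus half the ties over all case-control pairs),
orientation-maximized to max(AUC, 1 - AUC) so down-regulated markers are
treated symmetrically; a gene is diagnostic at AUC >= 0.70.

Prognostics: a univariate Cox proportional-hazards fit (Breslow ties,
Newton iterations) gives each sample a prognostic index PI = beta * x; the
cohort is split at the median PI into high/low risk, compared by the
log-rank test, and the hazard ratio is reported as the ratio of relative
mortality rates HR = (O1/E1)/(O2/E2) with O and E the observed and expected
deaths per group accumulated over event times. A gene is prognostic at
log-rank p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .datasets import ExpressionDataset, SurvivalTable

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# diagnostics


def auc(scores, labels) -> float:
    """Area under the ROC curve via ranks (Mann-Whitney probability).

    ``labels`` is boolean/0-1 with True = case. Ties contribute half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def screen_diagnostic(
    expr: ExpressionDataset,
    candidates: set[str] | list[str],
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Orientation-maximized AUC for each candidate gene, flagged at ``threshold``.

    ``orientation`` is ``+`` when higher expression indicates case, ``-``
    when the raw AUC was below 0.5 and the complement is reported.
    """
    measured = [g for g in sorted(set(candidates)) if g in expr.genes]
    if not measured:
        raise ValueError("no candidate gene is measured in the validation cohort")
    skipped = set(candidates) - set(measured)
    if skipped:
        logger.info("%d candidate(s) not measured in validation cohort", len(skipped))
    is_case = (expr.labels == "case").to_numpy()
    rows = []
    for gene in measured:
        raw = auc(expr.values.loc[gene].to_numpy(), is_case)
        oriented = max(raw, 1.0 - raw)
        rows.append((gene, oriented, "+" if raw >= 0.5 else "-"))
    table = pd.DataFrame(rows, columns=["gene", "auc", "orientation"]).set_index("gene")
    table["diagnostic_flag"] = table["auc"] >= threshold
    return table.sort_values(["auc", "gene"], ascending=[False, True], kind="stable")


# --------------------------------------------------------------------------
# survival machinery


def fit_univariate_cox(
    x, time, event, tol: float = 1e-8, max_iter: int = 100
) -> float:
    """Maximum partial-likelihood estimate of the Cox log-hazard coefficient.

    Single covariate, Breslow handling of tied event times, Newton-Raphson
    until |delta beta| < tol. Raises on no events, constant covariate, or a
    monotone likelihood (perfect separation).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events observed")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    order = np.argsort(-time, kind="stable")  # descending: risk sets are prefixes
    x, time, event = x[order], time[order], event[order]
    # risk set of an event at t = all with time >= t; with descending sort that
    # is the prefix ending at the LAST index sharing the same time value
    last_tie = np.searchsorted(-time, -time, side="right") - 1

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)[last_tie]
        s1 = np.cumsum(w * x)[last_tie]
        s2 = np.cumsum(w * x * x)[last_tie]
        mean = s1 / s0
        ev = event.astype(bool)
        score = float((x[ev] - mean[ev]).sum())
        info = float((s2[ev] / s0[ev] - mean[ev] ** 2).sum())
        if info <= 0:
            raise ValueError("non-positive information; cannot fit Cox model")
        delta = score / info
        beta += delta
        if abs(beta) > 50:
            raise ValueError("monotone partial likelihood: beta diverging")
        if abs(delta) < tol:
            return float(beta)
    raise ValueError(f"Cox fit did not converge in {max_iter} iterations")


def split_risk_groups(pi: pd.Series) -> pd.Series:
    """Median split of the prognostic index: high = PI > median, ties go low."""
    if len(pi) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(pi.median())
    return pd.Series(np.where(pi > med, "high", "low"), index=pi.index, name="risk_group")


def kaplan_meier(surv: SurvivalTable) -> pd.DataFrame:
    """Product-limit survival curve: DataFrame (time, survival), right-continuous."""
    if len(surv.time) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time.to_numpy(), surv.event.to_numpy())
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


@dataclass
class LogrankResult:
    o1: float
    e1: float
    o2: float
    e2: float
    variance: float
    chi2: float
    p: float
    hr: float


def logrank(
    time1, event1, time2, event2
) -> LogrankResult:
    """Two-group log-rank test with O/E accumulation and the mortality-ratio HR.

    At each distinct event time t with d_t total deaths, n1t and n2t at risk:
    E1 accumulates d_t * n1t / (n1t + n2t) (hypergeometric expectation) and
    the variance accumulates the hypergeometric variance. chi2 =
    (O1 - E1)^2 / V with a chi-square(1) p-value, and
    HR = (O1/E1) / (O2/E2).
    """
    t1 = np.asarray(time1, dtype=float)
    d1 = np.asarray(event1, dtype=int)
    t2 = np.asarray(time2, dtype=float)
    d2 = np.asarray(event2, dtype=int)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be nonempty")
    total_events = int(d1.sum() + d2.sum())
    if total_events == 0:
        raise ValueError("no events observed")

    event_times = np.unique(np.concatenate([t1[d1 == 1], t2[d2 == 1]]))
    o1 = float(d1.sum())
    o2 = float(d2.sum())
    e1 = 0.0
    var = 0.0
    for t in event_times:
        n1t = float((t1 >= t).sum())
        n2t = float((t2 >= t).sum())
        nt = n1t + n2t
        dt = float(((t1 == t) & (d1 == 1)).sum() + ((t2 == t) & (d2 == 1)).sum())
        e1 += dt * n1t / nt
        if nt > 1:
            var += dt * (n1t / nt) * (n2t / nt) * (nt - dt) / (nt - 1)
    e2 = total_events - e1
    if var == 0:
        raise ValueError("zero log-rank variance")
    chi2 = (o1 - e1) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    if e1 == 0 or e2 == 0 or o2 == 0:
        hr = math.inf if (e2 == 0 or o2 == 0) and o1 > 0 else 0.0
        logger.warning("degenerate O/E; hazard ratio reported as %s", hr)
    else:
        hr = (o1 / e1) / (o2 / e2)
    return LogrankResult(o1=o1, e1=e1, o2=o2, e2=e2, variance=var, chi2=chi2, p=p, hr=hr)


def plot_kaplan_meier(
    high: SurvivalTable, low: SurvivalTable, path, title: str = ""
) -> None:
    """Write a two-group Kaplan-Meier plot (high risk red, low risk blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for surv, label, color in ((high, "high risk", "tab:red"), (low, "low risk", "tab:blue")):
        km = kaplan_meier(surv)
        ax.step(km["time"], km["survival"], where="post", label=label, color=color)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# prognostic screen

PROGNOSTIC_COLUMNS = [
    "beta",
    "o1",
    "e1",
    "o2",
    "e2",
    "hr",
    "logrank_p",
    "mean_expr_high",
    "mean_expr_low",
    "prognostic_flag",
]


def screen_prognostic(
    expr: ExpressionDataset,
    surv: SurvivalTable,
    candidates: set[str] | list[str],
    alpha: float = 0.05,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-gene prognostic screen: Cox fit -> PI median split -> log-rank + HR.

    Expression is z-scored per gene before the Cox fit by default, so beta is
    a per-standard-deviation log-hazard. Genes whose fit fails yield NA rows
    (the screen continues). Group mean expression (original scale) is
    reported for the high/low risk groups.
    """
    shared = expr.samples.intersection(surv.samples)
    if len(shared) == 0:
        raise ValueError("no samples shared between expression and survival tables")
    time = surv.time.loc[shared].to_numpy()
    event = surv.event.loc[shared].to_numpy()
    rows: dict[str, list] = {}
    for gene in sorted(set(candidates)):
        if gene not in expr.genes:
            rows[gene] = [np.nan] * (len(PROGNOSTIC_COLUMNS) - 1) + [False]
            continue
        raw = expr.values.loc[gene, shared].astype(float)
        x = raw.to_numpy()
        if standardize:
            sd = x.std(ddof=1)
            x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        try:
            beta = fit_univariate_cox(x, time, event)
            pi = pd.Series(beta * x, index=shared)
            groups = split_risk_groups(pi)
            hi = groups == "high"
            res = logrank(time[hi.to_numpy()], event[hi.to_numpy()],
                          time[~hi.to_numpy()], event[~hi.to_numpy()])
        except ValueError as exc:
            logger.warning("gene %s: prognostic fit failed (%s)", gene, exc)
            rows[gene] = [np.nan] * (len(PROGNOSTIC_COLUMNS) - 1) + [False]
            continue
        rows[gene] = [
            beta,
            res.o1,
            res.e1,
            res.o2,
            res.e2,
            res.hr,
            res.p,
            float(raw[hi].mean()),
            float(raw[~hi].mean()),
            bool(res.p < alpha),
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=PROGNOSTIC_COLUMNS)
    table.index.name = "gene"
    return table.sort_values(["logrank_p", "gene"], kind="stable", na_position="last")
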