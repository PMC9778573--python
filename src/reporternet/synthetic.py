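"""Synthetic study generator with planted ground truth.

Emulates the full input suite of the discovery pipeline: several
case/control expression cohorts sharing a planted set of differential
genes, a scale-free protein-interaction network, bipartite TF-target and
receptor-protein networks whose planted "active" regulators draw their
targets preferentially from the differential genes, and a validation cohort
with survival times drawn from a proportional-hazards model around planted
prognostic genes.

Expression is generated directly on the log2 scale: per-gene baseline means
are drawn once, planted differential genes are shifted by +/- effect_log2fc
in cases (sign Bernoulli(0.5) per gene), and i.i.d. Gaussian noise with the
given standard deviation is added. Every generator is a pure function of
its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import CASE, CONTROL, ExpressionDataset, SurvivalTable
from .reporters import BipartiteNetwork


@dataclass
class GroundTruth:
    """Planted signal underlying a synthetic bundle."""

    deg_genes: set[str] = field(default_factory=set)
    active_features: set[str] = field(default_factory=set)
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    diagnostic_genes: set[str] = field(default_factory=set)
    deg_signs: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1 in cases

    def to_json(self, path: str | Path) -> None:
        payload = {
            "deg_genes": sorted(self.deg_genes),
            "active_features": sorted(self.active_features),
            "prognostic_genes": {g: self.prognostic_genes[g] for g in sorted(self.prognostic_genes)},
            "diagnostic_genes": sorted(self.diagnostic_genes),
            "deg_signs": {g: self.deg_signs[g] for g in sorted(self.deg_signs)},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            deg_genes=set(d["deg_genes"]),
            active_features=set(d["active_features"]),
            prognostic_genes={g: float(v) for g, v in d["prognostic_genes"].items()},
            diagnostic_genes=set(d["diagnostic_genes"]),
            deg_signs={g: int(v) for g, v in d.get("deg_signs", {}).items()},
        )


def gene_universe(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i + 1:0{width}d}" for i in range(n_genes)]


def generate_expression(
    n_genes: int,
    n_case: int,
    n_control: int,
    deg_fraction: float,
    effect_log2fc: float,
    noise_sd: float,
    seed: int,
    name: str = "synthetic",
    deg_genes: set[str] | None = None,
    deg_signs: dict[str, int] | None = None,
    baseline: pd.Series | None = None,
) -> tuple[ExpressionDataset, GroundTruth]:
    """One case/control cohort on log2 scale with planted differential genes.

    ``deg_genes``/``deg_signs``/``baseline`` allow several cohorts to share
    the same planted signal (as independent studies of one disease would);
    when omitted they are drawn from this cohort's seed.
    """
    if n_genes <= 0 or n_case <= 0 or n_control <= 0:
        raise ValueError("counts must be positive")
    if n_case < 3 or n_control < 3:
        raise ValueError("need >= 3 samples per phenotype")
    if not 0 <= deg_fraction <= 1:
        raise ValueError("deg_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)

    if baseline is None:
        baseline = pd.Series(rng.uniform(4.0, 12.0, size=n_genes), index=genes)
    else:
        baseline = baseline.reindex(genes)

    if deg_genes is None:
        n_deg = int(round(deg_fraction * n_genes))
        deg_genes = set(rng.choice(genes, size=n_deg, replace=False)) if n_deg else set()
    else:
        deg_genes = set(deg_genes)
    if deg_signs is None:
        deg_signs = {g: (1 if rng.random() < 0.5 else -1) for g in sorted(deg_genes)}

    n_samples = n_case + n_control
    mat = np.tile(baseline.to_numpy()[:, None], (1, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in sorted(deg_genes):
        mat[gene_pos[g], :n_case] += deg_signs[g] * effect_log2fc
    mat += rng.normal(0.0, noise_sd, size=mat.shape)

    samples = [f"{name}_case{i + 1:03d}" for i in range(n_case)] + [
        f"{name}_ctrl{i + 1:03d}" for i in range(n_control)
    ]
    labels = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)
    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    truth = GroundTruth(deg_genes=deg_genes, deg_signs=dict(deg_signs))
    return ExpressionDataset(values, labels, name=name), truth


def generate_ppi(n_nodes: int, attach_m: int, seed: int) -> nx.Graph:
    """Scale-free (preferential-attachment) protein-interaction network."""
    if attach_m < 1 or n_nodes <= attach_m:
        raise ValueError("need n_nodes > attach_m >= 1")
    g = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
    ids = gene_universe(n_nodes)
    return nx.relabel_nodes(g, {i: ids[i] for i in range(n_nodes)})


def generate_bipartite(
    n_features: int,
    genes: list[str],
    targets_per_feature: tuple[int, int],
    n_active: int,
    deg_genes: set[str],
    enrichment: float,
    seed: int,
    prefix: str = "TF",
    mode: str = "tf_target",
) -> tuple[BipartiteNetwork, set[str]]:
    """Bipartite regulator -> gene network with planted active regulators.

    Active regulators draw a fraction ``enrichment`` of their targets from
    ``deg_genes``; inactive regulators draw uniformly from the universe.
    """
    if not genes:
        raise ValueError("empty gene universe")
    if not 0 <= enrichment <= 1:
        raise ValueError("enrichment must be in [0, 1]")
    if n_active > n_features:
        raise ValueError("n_active cannot exceed n_features")
    lo, hi = targets_per_feature
    if lo < 1 or hi < lo:
        raise ValueError("invalid targets_per_feature range")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_features)))
    features = [f"{prefix}{i + 1:0{width}d}" for i in range(n_features)]
    active = set(features[:n_active])
    deg_list = sorted(set(deg_genes) & set(genes))
    non_deg = sorted(set(genes) - set(deg_genes))
    targets: dict[str, set[str]] = {}
    for f in features:
        k = int(rng.integers(lo, hi + 1))
        if f in active and deg_list:
            k_deg = min(int(round(enrichment * k)), len(deg_list))
            chosen = set(rng.choice(deg_list, size=k_deg, replace=False))
            # remaining targets drawn uniformly from the rest of the universe,
            # so enrichment=0 makes active features indistinguishable from nulls
            pool = sorted(set(genes) - chosen)
            rest = min(k - k_deg, len(pool))
            if rest:
                chosen |= set(rng.choice(pool, size=rest, replace=False))
        else:
            chosen = set(rng.choice(genes, size=min(k, len(genes)), replace=False))
        targets[f] = chosen
    return BipartiteNetwork(targets, mode=mode), active


def generate_survival(
    expr: ExpressionDataset,
    coefs: dict[str, float],
    baseline_hazard: float,
    censor_time_max: float,
    seed: int,
) -> SurvivalTable:
    """Proportional-hazards event times with independent uniform censoring.

    Each sample's event time is exponential with rate
    h0 * exp(sum_g beta_g * x_g) where x is the per-gene standardized
    expression; censoring is Uniform(0, censor_time_max), with event = 0
    when censoring comes first.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    unknown = set(coefs) - set(expr.genes)
    if unknown:
        raise ValueError(f"coefficient genes not in expression matrix: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    n = len(expr.samples)
    lp = np.zeros(n)
    for g, beta in sorted(coefs.items()):
        x = expr.values.loc[g].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        lp += beta * z
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, censor_time_max, size=n) if censor_time_max > 0 else np.zeros(n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return SurvivalTable(
        pd.Series(time, index=expr.samples, name="time_days"),
        pd.Series(event, index=expr.samples, name="event"),
    )


# --------------------------------------------------------------------------
# full bundle


@dataclass
class SyntheticBundle:
    datasets: list[ExpressionDataset]
    ppi: nx.Graph
    tf_net: BipartiteNetwork
    receptor_net: BipartiteNetwork
    validation: ExpressionDataset
    survival: SurvivalTable
    truth: GroundTruth
    seed: int


# Study conditions of the default bundle: three discovery cohorts with a
# case-heavy 3:1 ratio, a 100/30 validation cohort, 5% planted DEGs at
# |log2FC| = 2 over noise sd 0.5, and 5 planted prognostic genes at beta = 1
# per sd with ~1000-day baseline survival and uniform censoring to 2000 days.
DEFAULT_BUNDLE_PARAMS: dict = {
    "n_genes": 2000,
    "dataset_sizes": [(30, 10), (30, 10), (30, 10)],
    "deg_fraction": 0.05,
    "effect_log2fc": 2.0,
    "noise_sd": 0.5,
    "ppi_attach_m": 2,
    "n_tfs": 50,
    "n_active_tfs": 5,
    "n_receptors": 40,
    "n_active_receptors": 4,
    "targets_per_feature": (5, 20),
    "enrichment": 0.9,
    "n_validation_case": 100,
    "n_validation_control": 30,
    "n_prognostic": 5,
    "prognostic_beta": 1.0,
    "baseline_hazard": 1.0 / 1000.0,
    "censor_time_max": 2000.0,
}


def generate_bundle(seed: int, **overrides) -> SyntheticBundle:
    """Generate the full synthetic study (see ``DEFAULT_BUNDLE_PARAMS``).

    All sub-generators receive child seeds derived from ``seed``, so the
    bundle is a pure function of (seed, parameters).
    """
    p = {**DEFAULT_BUNDLE_PARAMS, **overrides}
    child = np.random.SeedSequence(seed).spawn(10)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child]
    genes = gene_universe(p["n_genes"])

    # planted DEG identity and direction shared across cohorts
    rng = np.random.default_rng(seeds[0])
    n_deg = int(round(p["deg_fraction"] * p["n_genes"]))
    deg_genes = set(rng.choice(genes, size=n_deg, replace=False)) if n_deg else set()
    deg_signs = {g: (1 if rng.random() < 0.5 else -1) for g in sorted(deg_genes)}

    datasets = []
    for i, (n_case, n_control) in enumerate(p["dataset_sizes"]):
        ds, _ = generate_expression(
            p["n_genes"],
            n_case,
            n_control,
            p["deg_fraction"],
            p["effect_log2fc"],
            p["noise_sd"],
            seed=seeds[1] + i,
            name=f"cohort{i + 1}",
            deg_genes=deg_genes,
            deg_signs=deg_signs,
        )
        datasets.append(ds)

    ppi = generate_ppi(p["n_genes"], p["ppi_attach_m"], seed=seeds[4])
    tf_net, active_tfs = generate_bipartite(
        p["n_tfs"], genes, p["targets_per_feature"], p["n_active_tfs"],
        deg_genes, p["enrichment"], seed=seeds[5], prefix="TF", mode="tf_target",
    )
    receptor_net, active_receptors = generate_bipartite(
        p["n_receptors"], genes, p["targets_per_feature"], p["n_active_receptors"],
        deg_genes, p["enrichment"], seed=seeds[6], prefix="R", mode="receptor_protein",
    )

    validation, _ = generate_expression(
        p["n_genes"],
        p["n_validation_case"],
        p["n_validation_control"],
        p["deg_fraction"],
        p["effect_log2fc"],
        p["noise_sd"],
        seed=seeds[7],
        name="validation",
        deg_genes=deg_genes,
        deg_signs=deg_signs,
    )
    # regulators are genes too: the validation cohort measures TF/receptor
    # expression, with the planted-active regulators carrying a case shift
    active = active_tfs | active_receptors
    feat_ids = sorted(tf_net.targets) + sorted(receptor_net.targets)
    rng_f = np.random.default_rng(seeds[2])
    n_val = len(validation.samples)
    n_case_val = len(validation.case_samples)
    fmat = np.tile(rng_f.uniform(4.0, 12.0, size=len(feat_ids))[:, None], (1, n_val))
    feat_signs = {f: (1 if rng_f.random() < 0.5 else -1) for f in feat_ids}
    for fi, f in enumerate(feat_ids):
        if f in active:
            fmat[fi, :n_case_val] += feat_signs[f] * p["effect_log2fc"]
    fmat += rng_f.normal(0.0, p["noise_sd"], size=fmat.shape)
    feat_df = pd.DataFrame(fmat, index=pd.Index(feat_ids, name="gene"),
                           columns=validation.samples)
    validation = ExpressionDataset(
        pd.concat([validation.values, feat_df]), validation.labels, name="validation"
    )

    rng_pg = np.random.default_rng(seeds[8])
    pg_pool = sorted(deg_genes) if deg_genes else genes
    n_pg = min(p["n_prognostic"], len(pg_pool))
    prognostic = {
        str(g): p["prognostic_beta"]
        for g in rng_pg.choice(pg_pool, size=n_pg, replace=False)
    }
    # one planted-active regulator per network also drives survival
    if active_tfs:
        prognostic[sorted(active_tfs)[0]] = p["prognostic_beta"]
    if active_receptors:
        prognostic[sorted(active_receptors)[0]] = p["prognostic_beta"]
    # survival follow-up exists for tumor samples only, as in tumor registries
    survival = generate_survival(
        _case_only_view(validation), prognostic,
        p["baseline_hazard"], p["censor_time_max"], seed=seeds[9],
    )

    truth = GroundTruth(
        deg_genes=deg_genes,
        active_features=active,
        prognostic_genes=prognostic,
        diagnostic_genes=set(deg_genes) | active,
        deg_signs=deg_signs,
    )
    return SyntheticBundle(
        datasets=datasets,
        ppi=ppi,
        tf_net=tf_net,
        receptor_net=receptor_net,
        validation=validation,
        survival=survival,
        truth=truth,
        seed=seed,
    )


class _case_only_view:
    """Minimal expression view over the case samples (survival generation only)."""

    def __init__(self, ds: ExpressionDataset):
        self.values = ds.values[ds.case_samples]
        self.samples = ds.case_samples
        self.genes = ds.genes


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write the bundle in the pipeline's plain-TSV dialect plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, ds in enumerate(bundle.datasets, start=1):
        ds.write(out / f"expression_{i}.tsv", out / f"labels_{i}.tsv")
    with open(out / "ppi.tsv", "w") as fh:
        for u, v in sorted(bundle.ppi.edges()):
            fh.write(f"{u}\t{v}\n")
    bundle.tf_net.write(out / "tf_targets.tsv")
    bundle.receptor_net.write(out / "receptor_net.tsv")
    bundle.validation.write(out / "expression_validation.tsv", out / "labels_validation.tsv")
    bundle.survival.write(out / "survival.tsv")
    bundle.truth.to_json(out / "truth.json")
    meta = {"seed": bundle.seed, "n_datasets": len(bundle.datasets)}
    (out / "bundle.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
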