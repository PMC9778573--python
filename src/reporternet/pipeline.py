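"""End-to-end orchestration of the biomarker-discovery flow.

Stages, in order: per-cohort differential expression -> cross-cohort
intersection -> (optional) over-representation -> DEG-centred PPI
sub-network and hub selection -> reporter TFs -> reporter receptors ->
diagnostic screen -> prognostic screen -> candidate biomarkers (union rule:
a hub or significant reporter flagged diagnostic OR prognostic) -> novelty
annotation against a local known-gene list -> panel classification.

Every intermediate is written as TSV and a manifest JSON records the
thresholds, seed and per-stage counts, with no timestamps, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, diffexpr, networks, reporters, validation
from .datasets import read_expression, read_gene_list, read_gmt, read_survival

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Input paths and the thresholds of every stage."""

    expression_paths: list[str]
    label_paths: list[str]
    ppi_path: str
    tf_net_path: str
    receptor_net_path: str
    validation_expr_path: str
    validation_labels_path: str
    survival_path: str
    gmt_path: str | None = None
    known_genes_path: str | None = None
    deg_alpha: float = 0.05
    fc_threshold: float = 2.0
    ora_alpha: float = 0.01
    reporter_alpha: float = 0.001
    reporter_use_adjusted: bool = True
    auc_threshold: float = 0.70
    logrank_alpha: float = 0.05
    hub_k: int = 10
    reporter_n_samples: int = 100_000
    classify_folds: int = 5
    classifiers: list[str] = field(default_factory=lambda: ["knn", "decision_tree", "random_forest"])
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.expression_paths) != len(self.label_paths):
            raise ValueError("expression_paths and label_paths must pair up")
        if len(self.expression_paths) < 2:
            raise ValueError("need >= 2 discovery datasets")
        for name, val, lo, hi in [
            ("deg_alpha", self.deg_alpha, 0, 1),
            ("ora_alpha", self.ora_alpha, 0, 1),
            ("reporter_alpha", self.reporter_alpha, 0, 1),
            ("logrank_alpha", self.logrank_alpha, 0, 1),
            ("auc_threshold", self.auc_threshold, 0.5, 1),
        ]:
            if not lo < val <= hi:
                raise ValueError(f"{name}={val} outside ({lo}, {hi}]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.hub_k <= 0:
            raise ValueError("hub_k must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate_paths(self) -> None:
        paths = [*self.expression_paths, *self.label_paths, self.ppi_path,
                 self.tf_net_path, self.receptor_net_path,
                 self.validation_expr_path, self.validation_labels_path,
                 self.survival_path]
        if self.gmt_path:
            paths.append(self.gmt_path)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written to manifest.json)."""
    config.validate_paths()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    # --- differential expression per cohort
    results = {}
    degs = {}
    for expr_path, lab_path in zip(config.expression_paths, config.label_paths):
        ds = read_expression(expr_path, lab_path)
        res = diffexpr.moderated_ttest(ds)
        results[ds.name] = res
        called = diffexpr.call_degs(res, alpha=config.deg_alpha, fc_threshold=config.fc_threshold)
        degs[ds.name] = called
        _write_tsv(res, out / f"degs_{ds.name}.tsv")
    manifest["stages"]["diffexpr"] = {name: int(len(df)) for name, df in degs.items()}

    # --- intersection
    common = diffexpr.intersect_degs(degs)
    (out / "common_degs.txt").write_text("".join(f"{g}\n" for g in sorted(common.genes)))
    _write_tsv(common.directions, out / "common_deg_directions.tsv")
    manifest["stages"]["common_degs"] = {
        "n": len(common.genes),
        "n_conflicting": len(common.conflicting),
    }

    # --- over-representation (optional)
    if config.gmt_path:
        universe = set.intersection(*(set(r.index) for r in results.values()))
        ora = diffexpr.hypergeometric_ora(
            common.genes & universe, read_gmt(config.gmt_path), universe,
            alpha=config.ora_alpha,
        )
        _write_tsv(ora, out / "ora.tsv")
        manifest["stages"]["ora"] = {"n_significant": int(ora["significant"].sum())}

    # --- PPI sub-network and hubs
    ppi = networks.load_edge_list(config.ppi_path, directed=False)
    sub = networks.reconstruct_subnetwork(common.genes, ppi)
    networks.write_edge_list(sub, out / "subnetwork.tsv")
    hub_table = networks.select_hubs(networks.centralities(sub), k=config.hub_k)
    _write_tsv(hub_table, out / "hubs.tsv")
    hubs = networks.hub_nodes(hub_table)
    manifest["stages"]["ppi"] = {
        "subnetwork_nodes": sub.number_of_nodes(),
        "subnetwork_edges": sub.number_of_edges(),
        "n_hubs": len(hubs),
    }

    # --- reporter features over combined gene significance
    pmat = pd.DataFrame({name: res["p"] for name, res in results.items()}).dropna()
    combined_p = diffexpr.fisher_combine(pmat)
    combined_p.rename_axis("gene").to_frame().to_csv(
        out / "combined_gene_p.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    rep_tables = {}
    for mode, path in (("tf", config.tf_net_path), ("receptor", config.receptor_net_path)):
        net = reporters.load_bipartite(path, mode=mode)
        table = reporters.score_reporters(
            combined_p, net,
            alpha=config.reporter_alpha,
            n_samples=config.reporter_n_samples,
            seed=config.seed,
            use_adjusted=config.reporter_use_adjusted,
        )
        rep_tables[mode] = table
        _write_tsv(table, out / f"reporters_{mode}.tsv")
    manifest["stages"]["reporters"] = {
        mode: int(t["significant"].sum()) for mode, t in rep_tables.items()
    }

    # --- candidate biomolecules = hubs + significant reporters
    biomolecules = sorted(
        set(hubs)
        | set(rep_tables["tf"].index[rep_tables["tf"]["significant"]])
        | set(rep_tables["receptor"].index[rep_tables["receptor"]["significant"]])
    )
    manifest["stages"]["biomolecules"] = {"n": len(biomolecules)}

    # --- validation cohort screens; reporters (TFs/receptors) are screened
    # through their measured selves when present, otherwise skipped by the screens
    vds = read_expression(config.validation_expr_path, config.validation_labels_path,
                          name="validation")
    surv = read_survival(config.survival_path)
    diag = validation.screen_diagnostic(vds, biomolecules, threshold=config.auc_threshold)
    _write_tsv(diag, out / "diagnostic.tsv")
    prog = validation.screen_prognostic(vds, surv, biomolecules, alpha=config.logrank_alpha)
    _write_tsv(prog, out / "prognostic.tsv")
    manifest["stages"]["validation"] = {
        "n_diagnostic": int(diag["diagnostic_flag"].sum()),
        "n_prognostic": int(prog["prognostic_flag"].fillna(False).sum()),
    }

    # --- biomarker candidates: diagnostic OR prognostic (union rule)
    diag_set = set(diag.index[diag["diagnostic_flag"]])
    prog_set = set(prog.index[prog["prognostic_flag"].fillna(False)])
    candidates = sorted(diag_set | prog_set)
    cand = pd.DataFrame(
        {
            "diagnostic": [g in diag_set for g in candidates],
            "prognostic": [g in prog_set for g in candidates],
        },
        index=pd.Index(candidates, name="gene"),
    )
    known = read_gene_list(config.known_genes_path) if (
        config.known_genes_path and Path(config.known_genes_path).is_file()
    ) else None
    if config.known_genes_path and known is None:
        logger.warning("known-gene list %s missing; novelty unknown", config.known_genes_path)
    cand = annotate_known(cand, known)
    _write_tsv(cand, out / "candidates.tsv")
    manifest["stages"]["candidates"] = {
        "n": len(cand),
        "n_novel": int(cand["novel"].sum()) if known is not None else None,
    }

    # --- panel classification: case/control and alive/dead
    panel = [g for g in candidates if g in vds.genes]
    clf_report = {}
    if panel:
        backends = {
            name: fac
            for name, fac in classify.default_classifiers(seed=config.seed).items()
            if name in config.classifiers
        }
        X = vds.values.loc[panel].T
        reports = classify.evaluate_panel(
            X, vds.labels, classifiers=backends,
            n_folds=config.classify_folds, seed=config.seed, positive="case",
        )
        frame = classify.reports_to_frame(reports)
        _write_tsv(frame, out / "classification_case_control.tsv")
        clf_report["case_control"] = {
            row.Index: round(row.accuracy, 6) for row in frame.itertuples()
        }
        # alive/dead over samples with survival follow-up
        shared = vds.samples.intersection(surv.samples)
        status = pd.Series(
            ["dead" if e else "alive" for e in surv.event.loc[shared]], index=shared
        )
        if status.nunique() == 2 and status.value_counts().min() >= 2:
            reports2 = classify.evaluate_panel(
                vds.values.loc[panel, shared].T, status, classifiers=backends,
                n_folds=config.classify_folds, seed=config.seed, positive="dead",
            )
            frame2 = classify.reports_to_frame(reports2)
            _write_tsv(frame2, out / "classification_alive_dead.tsv")
            clf_report["alive_dead"] = {
                row.Index: round(row.accuracy, 6) for row in frame2.itertuples()
            }
    manifest["stages"]["classification"] = clf_report

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def annotate_known(candidates: pd.DataFrame, known: list[str] | None) -> pd.DataFrame:
    """Flag candidates absent from a known-gene list as novel (case-insensitive).

    With no known-gene list available every candidate is flagged novel
    (nothing screened it out); the caller logs the warning.
    """
    out = candidates.copy()
    if known is None:
        out["novel"] = True
        return out
    known_lc = {k.lower() for k in known}
    out["novel"] = [g.lower() not in known_lc for g in out.index]
    return out
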