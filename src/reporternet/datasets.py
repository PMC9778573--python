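"""Expression dataset container and plain-text readers.

All expression matrices are log2-scale, genes x samples. Phenotype labels are
binary ("case" / "control"). Files are uncompressed TSV throughout:

* expression: first column = gene id, header row = sample ids
* labels: two columns ``sample`` and ``phenotype``
* survival: three columns ``sample``, ``time_days``, ``event`` (1 = death)
* gene sets: GMT (name, description, then member genes, tab-separated)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """One normalized gene x sample matrix with binary phenotype labels.

    Invariants enforced at construction: unique gene ids, every sample
    labeled with a valid phenotype, and at least 3 samples per phenotype
    (the cohort inclusion criterion used throughout).
    """

    values: pd.DataFrame  # genes x samples, log2 intensities
    labels: pd.Series  # sample -> "case" | "control"
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene ids in {self.name!r}: {dup}")
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()][:5].tolist()
            raise ValueError(f"unlabeled samples in {self.name!r}: {missing}")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown phenotype labels {sorted(bad)}; expected case/control")
        counts = self.labels.value_counts()
        for phen in (CASE, CONTROL):
            if counts.get(phen, 0) < 3:
                raise ValueError(
                    f"{self.name!r}: phenotype {phen!r} has {counts.get(phen, 0)} samples, need >= 3"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def case_samples(self) -> pd.Index:
        return self.labels.index[self.labels == CASE]

    @property
    def control_samples(self) -> pd.Index:
        return self.labels.index[self.labels == CONTROL]

    def case_matrix(self) -> pd.DataFrame:
        return self.values[self.case_samples]

    def control_matrix(self) -> pd.DataFrame:
        return self.values[self.control_samples]

    def write(self, expr_path: str | Path, labels_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(expr_path, sep="\t", float_format="%.6f")
        lab = self.labels.rename("phenotype").rename_axis("sample")
        lab.to_frame().to_csv(labels_path, sep="\t")


def read_expression(
    expr_path: str | Path, labels_path: str | Path, name: str | None = None
) -> ExpressionDataset:
    """Load a genes x samples TSV plus a sample/phenotype label TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.strip()
    lab = pd.read_csv(labels_path, sep="\t", index_col=0)
    if lab.shape[1] < 1:
        raise ValueError(f"label file {labels_path} needs a phenotype column")
    labels = lab.iloc[:, 0].astype(str).str.strip().str.lower()
    return ExpressionDataset(values, labels, name=name or Path(expr_path).stem)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days) and event indicator (1 = death observed)."""

    time: pd.Series  # sample -> days, >= 0
    event: pd.Series  # sample -> {0, 1}

    def __post_init__(self) -> None:
        self.event = self.event.reindex(self.time.index)
        if (self.time < 0).any():
            raise ValueError("negative follow-up times")
        vals = set(pd.unique(self.event.dropna()))
        if not vals <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, got {sorted(vals)}")

    @property
    def samples(self) -> pd.Index:
        return self.time.index

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"time_days": self.time, "event": self.event.astype(int)}
        ).rename_axis("sample")
        df.to_csv(path, sep="\t", float_format="%.4f")


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"time_days", "event"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_days, event")
    return SurvivalTable(df["time_days"].astype(float), df["event"].astype(int))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            sets[parts[0]] = {g.strip() for g in parts[2:] if g.strip()}
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments and blanks ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def standardize_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) across samples; constant rows map to 0."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    out = values.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return out.fillna(0.0)
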