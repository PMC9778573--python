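"""Diagnostic (AUC) and prognostic (Cox PI / log-rank / HR) validation.

Screens the biomolecule list (hubs + significant reporters) in the
validation cohort and writes diagnostic.tsv, prognostic.tsv and
candidates.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from reporternet import validation
from reporternet.datasets import read_expression, read_survival
from reporternet.pipeline import annotate_known

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    vds = read_expression(
        ROOT / "study" / "expression_validation.tsv",
        ROOT / "study" / "labels_validation.tsv",
        name="validation",
    )
    surv = read_survival(ROOT / "study" / "survival.tsv")
    hubs = pd.read_csv(ROOT / "hubs.tsv", sep="\t", index_col=0)
    biomolecules = set(hubs.index[hubs["hub_flag"]])
    for mode in ("tf", "receptor"):
        rep = pd.read_csv(ROOT / f"reporters_{mode}.tsv", sep="\t", index_col=0)
        biomolecules |= set(rep.index[rep["significant"]])

    diag = validation.screen_diagnostic(vds, biomolecules)
    diag.to_csv(ROOT / "diagnostic.tsv", sep="\t", float_format="%.6g")
    prog = validation.screen_prognostic(vds, surv, biomolecules)
    prog.to_csv(ROOT / "prognostic.tsv", sep="\t", float_format="%.6g")

    diag_set = set(diag.index[diag["diagnostic_flag"]])
    prog_set = set(prog.index[prog["prognostic_flag"].fillna(False)])
    cand = pd.DataFrame(
        {
            "diagnostic": [g in diag_set for g in sorted(diag_set | prog_set)],
            "prognostic": [g in prog_set for g in sorted(diag_set | prog_set)],
        },
        index=pd.Index(sorted(diag_set | prog_set), name="gene"),
    )
    cand = annotate_known(cand, None)
    cand.to_csv(ROOT / "candidates.tsv", sep="\t")
    print(f"screened {len(biomolecules)} biomolecules: "
          f"{len(diag_set)} diagnostic, {len(prog_set)} prognostic")
    print(f"candidates (diagnostic OR prognostic): {len(cand)}")
    print(cand)


if __name__ == "__main__":
    main()
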