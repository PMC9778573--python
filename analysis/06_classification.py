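"""Cross-validated classification of the candidate panel.

Evaluates how well the candidate genes separate case/control and
alive/dead samples in the validation cohort; writes
results/classification_{case_control,alive_dead}.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from reporternet import classify
from reporternet.datasets import read_expression, read_survival

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    vds = read_expression(
        ROOT / "study" / "expression_validation.tsv",
        ROOT / "study" / "labels_validation.tsv",
    )
    surv = read_survival(ROOT / "study" / "survival.tsv")
    cand = pd.read_csv(ROOT / "candidates.tsv", sep="\t", index_col=0)
    panel = [g for g in cand.index if g in vds.genes]

    reports = classify.evaluate_panel(vds.values.loc[panel].T, vds.labels, seed=SEED)
    frame = classify.reports_to_frame(reports)
    frame.to_csv(ROOT / "classification_case_control.tsv", sep="\t", float_format="%.4f")
    print("case/control:")
    print(frame.round(3))

    shared = vds.samples.intersection(surv.samples)
    status = pd.Series(
        np.where(surv.event.loc[shared] == 1, "dead", "alive"), index=shared
    )
    reports2 = classify.evaluate_panel(
        vds.values.loc[panel, shared].T, status, seed=SEED, positive="dead"
    )
    frame2 = classify.reports_to_frame(reports2)
    frame2.to_csv(ROOT / "classification_alive_dead.tsv", sep="\t", float_format="%.4f")
    print("alive/dead:")
    print(frame2.round(3))


if __name__ == "__main__":
    main()
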