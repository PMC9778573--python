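"""Per-cohort moderated differential expression and cross-cohort intersection.

Reads the study from results/study/, writes degs_<cohort>.tsv and
common_degs.txt under results/, and reports recovery of the planted signal.
"""

from pathlib import Path

from reporternet import diffexpr
from reporternet.datasets import read_expression
from reporternet.synthetic import GroundTruth

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = ROOT / "study"


def main() -> None:
    truth = GroundTruth.from_json(STUDY / "truth.json")
    called = {}
    for i in (1, 2, 3):
        ds = read_expression(STUDY / f"expression_{i}.tsv", STUDY / f"labels_{i}.tsv")
        res = diffexpr.moderated_ttest(ds)
        degs = diffexpr.call_degs(res)
        called[ds.name] = degs
        res.to_csv(ROOT / f"degs_{ds.name}.tsv", sep="\t", float_format="%.6g")
        tp = len(set(degs.index) & truth.deg_genes)
        print(f"{ds.name}: {len(degs)} DEGs "
              f"(recovered {tp}/{len(truth.deg_genes)} planted)")
    common = diffexpr.intersect_degs(called)
    (ROOT / "common_degs.txt").write_text("".join(f"{g}\n" for g in sorted(common.genes)))
    print(f"common DEGs across cohorts: {len(common.genes)} "
          f"({len(common.conflicting)} direction conflicts)")


if __name__ == "__main__":
    main()
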