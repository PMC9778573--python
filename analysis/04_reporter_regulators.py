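"""Reporter TFs and receptors from combined gene significance.

Combines per-cohort p-values by Fisher's method, scores both bipartite
networks, writes results/reporters_{tf,receptor}.tsv, and reports recovery
of the planted active regulators.
"""

from pathlib import Path

import pandas as pd

from reporternet import diffexpr, reporters
from reporternet.synthetic import GroundTruth

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    truth = GroundTruth.from_json(ROOT / "study" / "truth.json")
    pmat = pd.DataFrame(
        {
            f"expression_{i}": pd.read_csv(
                ROOT / f"degs_expression_{i}.tsv", sep="\t", index_col=0
            )["p"]
            for i in (1, 2, 3)
        }
    )
    combined = diffexpr.fisher_combine(pmat)
    for mode, fname in (("tf", "tf_targets.tsv"), ("receptor", "receptor_net.tsv")):
        net = reporters.load_bipartite(ROOT / "study" / fname, mode=mode)
        table = reporters.score_reporters(combined, net, seed=SEED)
        table.to_csv(ROOT / f"reporters_{mode}.tsv", sep="\t", float_format="%.6g")
        sig = set(table.index[table["significant"]])
        planted = truth.active_features & set(net.targets)
        print(f"{mode}: {len(sig)} significant reporters "
              f"(planted {len(planted)}, recovered {len(sig & planted)})")


if __name__ == "__main__":
    main()
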