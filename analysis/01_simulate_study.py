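"""Generate the synthetic study: three discovery cohorts, networks, validation.

Writes the full input bundle (expression + labels per cohort, PPI, TF-target
and receptor-protein networks, validation cohort with survival, planted
truth) under results/study/.
"""

from pathlib import Path

from reporternet import synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 42


def main() -> None:
    bundle = synthetic.generate_bundle(SEED)
    synthetic.write_bundle(bundle, OUT)
    t = bundle.truth
    print(f"study written to {OUT} (seed {SEED})")
    print(f"  cohorts: {len(bundle.datasets)}  "
          f"genes: {len(bundle.datasets[0].genes)}  "
          f"validation samples: {len(bundle.validation.samples)}")
    print(f"  planted DEGs: {len(t.deg_genes)}  "
          f"active regulators: {len(t.active_features)}  "
          f"prognostic genes: {len(t.prognostic_genes)}")


if __name__ == "__main__":
    main()
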