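"""DEG-centred PPI sub-network and hub selection (top-10 degree U betweenness).

Reads common DEGs and the PPI edge list, writes results/hubs.tsv.
"""

from pathlib import Path

from reporternet import networks
from reporternet.datasets import read_gene_list

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ppi = networks.load_edge_list(ROOT / "study" / "ppi.tsv")
    seeds = read_gene_list(ROOT / "common_degs.txt")
    sub = networks.reconstruct_subnetwork(seeds, ppi)
    table = networks.select_hubs(networks.centralities(sub), k=10)
    table.to_csv(ROOT / "hubs.tsv", sep="\t", float_format="%.6g")
    hubs = networks.hub_nodes(table)
    print(f"sub-network: {sub.number_of_nodes()} nodes, {sub.number_of_edges()} edges")
    print(f"hubs ({len(hubs)}): {', '.join(hubs)}")


if __name__ == "__main__":
    main()
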