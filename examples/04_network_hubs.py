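"""Zero-order PPI subnetwork extraction and hub ranking.

Builds a scale-free interactome, takes the DE-selected genes as seeds,
keeps only interactome edges with both endpoints among the seeds (the
zero-order rule: no neighbour expansion), and ranks hubs by degree.
"""

from butyrnet import rank_hubs, select_candidates, zero_order_subnetwork
from butyrnet.de import PRESETS
from butyrnet.simulate import (
    SimulationConfig,
    generate_de_table,
    generate_ppi_edges,
    gene_ids,
)

config = SimulationConfig(seed=3, n_mrna=2000, interactome_size=800,
                          frac_regulated=0.25)
records, truth = generate_de_table(config, "protein_coding")
seeds = {r.gene_id for r in select_candidates(records, PRESETS["mrna"])}
interactome = generate_ppi_edges(config, gene_ids(config.n_mrna))

net = zero_order_subnetwork(seeds, interactome)
print(f"interactome: 800 proteins, {len(interactome)} interactions")
print(f"seed genes (DE-selected): {len(seeds)}")
print(f"zero-order subnetwork: {len(net.nodes)} nodes, {len(net.edges())} edges")
print("top hubs (degree = connection count):")
for node, degree in rank_hubs(net, 3):
    print(f"  {node}: degree {degree}")
# Hubs are the proteins whose regulation propagates most widely through
# direct physical interactions among the responsive genes.
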