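"""Differential-expression candidate selection on a simulated DE table.

Simulates a DESeq2-style result table with 10% of genes planted as
regulated, then applies the mRNA selection preset (|log2FC| > 1.5,
adjusted p < 0.01, > 0.7 reads per million in at least one condition).
"""

from butyrnet import PRESETS, select_candidates
from butyrnet.de import classify_de
from butyrnet.simulate import SimulationConfig, generate_de_table

config = SimulationConfig(seed=1, n_mrna=2000, frac_regulated=0.1)
records, truth = generate_de_table(config, "protein_coding")

thresholds = PRESETS["mrna"]
selected = select_candidates(records, thresholds)
n_up = sum(1 for r in selected if classify_de(r, thresholds) == "up")
n_down = len(selected) - n_up

print(f"genes in table: {len(records)}")
print(f"planted regulated genes: {len(truth.regulated_mrnas)}")
print(f"selected candidates: {len(selected)} ({n_up} up, {n_down} down)")
print(f"planted but below the expression floor: {len(truth.subfloor_mrnas)}")
# Selected ~= planted minus the sub-floor genes, plus the rare null gene
# whose noise fold-change and p-value both clear the cuts.
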