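"""Cluster DEGs, chromosome composition and disease-table intersection.

Calls one-vs-rest DEGs per true stage, summarizes their chromosomal
composition, and intersects them with toy disease gene sets.
"""

import pandas as pd

from prophasex import (
    ScenarioConfig,
    deg_composition,
    disease_intersection,
    find_degs,
    simulate,
)

bundle, _ = simulate(ScenarioConfig(scenario="NULL", cells_per_stage=30, seed=4))
degs = find_degs(bundle, bundle.cells["stage"], min_pct1=0.6, max_p_adj=0.05)
print(f"{len(degs)} DEG records across {degs['cluster'].nunique()} stage clusters")
print(degs.head(5).round(4).to_string(index=False), "\n")

comp = deg_composition(degs, bundle.genes)
print("DEG composition by chromosome (count, % of DEG total):")
print(comp["by_chromosome"], "\n")

unique_degs = degs.drop_duplicates("gene_id")
tables = {
    "azoospermia": set(unique_degs["gene_id"].iloc[:4]),
    "male infertility": set(unique_degs["gene_id"].iloc[2:6]),
}
hits = disease_intersection(unique_degs, tables)
print("disease-table intersection (genes in >= 2 sets -> 'multiple diseases'):")
print(hits.to_string(index=False))
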