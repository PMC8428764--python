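"""Balancing two datasets and correlating cluster profiles.

Simulates a small 'female' and a large 'male' bundle, balances them by
seeded subsampling, and computes the Spearman correlation structure
between stage clusters.
"""

from prophasex import (
    ScenarioConfig,
    balance_datasets,
    cluster_correlation,
    simulate,
)

small, _ = simulate(ScenarioConfig(scenario="NULL", cells_per_stage=10, seed=1))
big, _ = simulate(ScenarioConfig(scenario="NULL", cells_per_stage=40, seed=2))
big.tpm.columns = [f"b_{c}" for c in big.tpm.columns]
big.cells.index = big.tpm.columns
if big.spliced is not None:
    big.spliced.columns = big.tpm.columns
    big.unspliced.columns = big.tpm.columns

merged = balance_datasets(small, big, target_n=100, seed=0)
print(f"balanced bundle: {merged.n_cells} cells "
      f"({small.n_cells} kept + 100 sampled from {big.n_cells})\n")

res = cluster_correlation(merged, merged.cells["stage"], top_n=100)
print("Spearman correlation between stage mean-profiles (top 100 variable genes):")
print(res.matrix.round(3))
# neighbouring stages correlate most strongly; the dendrogram (res.dendrogram)
# is a scipy complete-linkage tree on 1 - correlation.
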