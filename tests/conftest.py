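import numpy as np
import pandas as pd
import pytest

from prophasex import ExpressionBundle, ScenarioConfig, classify_genes, simulate


def make_bundle(tpm, chromosomes=None, sexes=None, stages=None, spliced=None, unspliced=None):
    """Build a small ExpressionBundle from a 2-D array."""
    tpm = np.asarray(tpm, dtype=float)
    n_genes, n_cells = tpm.shape
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{j}" for j in range(n_cells)]
    if chromosomes is None:
        chromosomes = ["1"] * n_genes
    genes = classify_genes(
        pd.DataFrame({"gene_id": gene_ids, "chromosome": chromosomes, "biotype": "protein_coding"})
    )
    cells = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    if sexes is not None:
        cells["sex"] = sexes
    if stages is not None:
        cells["stage"] = stages
    wrap = lambda m: None if m is None else pd.DataFrame(
        np.asarray(m, dtype=float), index=gene_ids, columns=cell_ids
    )
    return ExpressionBundle(
        tpm=pd.DataFrame(tpm, index=gene_ids, columns=cell_ids),
        cells=cells,
        genes=genes,
        spliced=wrap(spliced),
        unspliced=wrap(unspliced),
    )


@pytest.fixture(scope="session")
def sim_null():
    """One NULL simulation shared across tests (50 cells/stage, seed 1)."""
    return simulate(ScenarioConfig(scenario="NULL", cells_per_stage=50, seed=1))


@pytest.fixture(scope="session")
def sim_turnover():
    return simulate(ScenarioConfig(scenario="TURNOVER", cells_per_stage=50, seed=11))


@pytest.fixture(scope="session")
def sim_xcu():
    return simulate(ScenarioConfig(scenario="XCU", cells_per_stage=50, seed=7))
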