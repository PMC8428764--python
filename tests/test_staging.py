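"""Stage scoring, seeded clustering, and DEG filter semantics."""

import numpy as np
import pandas as pd
import pytest

from prophasex import staging
from prophasex.staging import MarkerPanel
from conftest import make_bundle


# ---------------------------------------------------------------------------
# score_stage
# ---------------------------------------------------------------------------

def _two_stage_panels():
    return [
        MarkerPanel(stage="leptotene", positive_markers=("g0", "g1")),
        MarkerPanel(stage="zygotene", positive_markers=("g2", "g3")),
    ]


def test_score_stage_forced_argmax():
    # cells 0-2 express only leptotene markers, cells 3-5 only zygotene ones
    mat = np.zeros((5, 6))
    mat[0:2, 0:3] = 50.0
    mat[2:4, 3:6] = 50.0
    b = make_bundle(mat)
    calls = staging.score_stage(b, _two_stage_panels())
    assert list(calls["stage"]) == ["leptotene"] * 3 + ["zygotene"] * 3


def test_score_stage_all_zero_cell_unassigned():
    mat = np.zeros((5, 3))
    mat[0:2, 0] = 50.0
    mat[2:4, 1] = 50.0
    b = make_bundle(mat)
    calls = staging.score_stage(b, _two_stage_panels())
    assert calls["stage"].iloc[2] == "unassigned"


def test_score_stage_missing_markers_skipped():
    mat = np.zeros((3, 2))
    mat[0, 0] = 10.0
    mat[2, 1] = 10.0
    b = make_bundle(mat)
    panels = [
        MarkerPanel(stage="leptotene", positive_markers=("g0", "absent_gene")),
        MarkerPanel(stage="zygotene", positive_markers=("g2",)),
    ]
    calls = staging.score_stage(b, panels)
    assert list(calls["stage"]) == ["leptotene", "zygotene"]
    with pytest.raises(ValueError):
        staging.score_stage(b, [MarkerPanel(stage="x", positive_markers=("nope",))])


def test_score_stage_recovers_truth_on_simulation(sim_null):
    bundle, truth = sim_null
    calls = staging.score_stage(bundle, truth.marker_panels)
    accuracy = (calls["stage"] == truth.true_stage).mean()
    assert accuracy >= 0.95


# ---------------------------------------------------------------------------
# cluster_cells
# ---------------------------------------------------------------------------

def _blob_bundle():
    rng = np.random.default_rng(10)
    n = 30
    mat = np.empty((10, 2 * n))
    mat[:5, :n] = rng.normal(200, 2, size=(5, n))
    mat[5:, :n] = rng.normal(5, 2, size=(5, n))
    mat[:5, n:] = rng.normal(5, 2, size=(5, n))
    mat[5:, n:] = rng.normal(200, 2, size=(5, n))
    return make_bundle(np.clip(mat, 0, None)), n


def test_cluster_cells_separates_blobs():
    b, n = _blob_bundle()
    labels = staging.cluster_cells(b, k=2, n_pcs=3, seed=0)
    first, second = labels.iloc[:n], labels.iloc[n:]
    assert first.nunique() == 1 and second.nunique() == 1
    assert first.iloc[0] != second.iloc[0]


def test_cluster_cells_deterministic():
    b, _ = _blob_bundle()
    l1 = staging.cluster_cells(b, k=2, n_pcs=3, seed=7)
    l2 = staging.cluster_cells(b, k=2, n_pcs=3, seed=7)
    assert l1.equals(l2)


def test_cluster_cells_contract_errors():
    b, _ = _blob_bundle()
    with pytest.raises(ValueError):
        staging.cluster_cells(b, k=1)
    with pytest.raises(ValueError):
        staging.cluster_cells(b, k=1000)


# ---------------------------------------------------------------------------
# find_degs
# ---------------------------------------------------------------------------

def _planted_deg_bundle():
    """100 cells: 20-cell cluster A with 10 planted genes, plus controls.

    Non-planted genes are built rank-balanced across the two clusters
    (cluster A's values are one copy of the cycle that cluster B holds
    four copies of), so their rank-sum statistic sits at the null centre
    and they can never be retained, independent of any seed.
    """
    n_in, n_out = 20, 80
    rows = []
    # 10 planted: strong in cluster A, zero elsewhere
    for _ in range(10):
        rows.append(np.concatenate([np.full(n_in, 100.0), np.zeros(n_out)]))
    # boundary gene: detected in exactly 60% of in-cluster cells
    boundary = np.zeros(n_in + n_out)
    boundary[:12] = 100.0  # 12/20 = 0.6 exactly
    rows.append(boundary)
    # constant gene
    rows.append(np.full(n_in + n_out, 7.0))
    # rank-balanced background genes at varying scales and phases
    cycle = np.arange(1.0, 21.0)
    for k in range(30):
        vals = np.concatenate([np.roll(cycle, k), np.tile(np.roll(cycle, 2 * k), 4)])
        rows.append(vals * (0.5 + 0.1 * k))
    labels = ["A"] * n_in + ["B"] * n_out
    return make_bundle(np.array(rows)), labels


def test_find_degs_recovers_planted_and_respects_strict_pct():
    b, labels = _planted_deg_bundle()
    degs = staging.find_degs(b, labels)
    in_a = degs[degs["cluster"] == "A"]
    assert set(in_a["gene_id"]) == {f"g{i}" for i in range(10)}
    assert (in_a["pct_1"] == 1.0).all()
    assert (in_a["p_adjusted"] < 0.05).all()
    # boundary gene (g10): pct_1 == 0.6 exactly -> excluded by strict filter
    assert "g10" not in set(degs["gene_id"])


def test_find_degs_constant_gene_not_retained():
    b, labels = _planted_deg_bundle()
    degs = staging.find_degs(b, labels)
    assert "g11" not in set(degs["gene_id"])  # identical everywhere -> p = 1


def test_find_degs_invariant_to_cell_permutation():
    b, labels = _planted_deg_bundle()
    rng = np.random.default_rng(12)
    perm = rng.permutation(b.tpm.columns.to_numpy())
    b_perm = b.subset_cells(perm)
    # subset_cells keeps original order; rebuild with permuted order instead
    from dataclasses import replace
    b_perm = replace(b, tpm=b.tpm[perm], cells=b.cells.loc[perm])
    labels_s = pd.Series(labels, index=b.tpm.columns)
    d1 = staging.find_degs(b, labels_s).sort_values(["cluster", "gene_id"]).reset_index(drop=True)
    d2 = staging.find_degs(b_perm, labels_s.loc[perm]).sort_values(["cluster", "gene_id"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(d1, d2)


def test_find_degs_skips_tiny_cluster():
    b, labels = _planted_deg_bundle()
    labels = list(labels)
    labels[0] = "C"  # 1-cell cluster
    degs = staging.find_degs(b, labels)
    assert "C" not in set(degs["cluster"])


def test_find_degs_requires_two_clusters():
    b, _ = _planted_deg_bundle()
    with pytest.raises(ValueError):
        staging.find_degs(b, ["A"] * b.n_cells)


# ---------------------------------------------------------------------------
# sex_degs
# ---------------------------------------------------------------------------

def _sexed_bundles(n_cells=100, boost=8.0, n_planted=30, seed=3):
    """Negative-binomial bundles with planted female-enriched genes."""
    rng = np.random.default_rng(seed)
    n_genes = 120
    base_mu = rng.uniform(5, 50, size=n_genes)

    def draw(mu):
        size = 2.0
        return rng.negative_binomial(size, size / (size + mu[:, None]), size=(n_genes, n_cells)).astype(float)

    mu_f = base_mu.copy()
    mu_f[:n_planted] *= boost
    f = make_bundle(draw(mu_f))
    m_mat = draw(base_mu)
    m = make_bundle(m_mat)
    # distinct cell ids
    m.tpm.columns = [f"m{j}" for j in range(n_cells)]
    m.cells.index = m.tpm.columns
    return f, m


def test_sex_degs_recover_planted_female_genes():
    f, m = _sexed_bundles()
    female, male = staging.sex_degs(f, m)
    planted = {f"g{i}" for i in range(30)}
    assert set(female["gene_id"]) == planted
    assert len(male) == 0


def test_sex_degs_logfc_threshold_is_strict():
    # identical bundles -> nothing enriched
    f, m = _sexed_bundles(boost=1.0, n_planted=0)
    female, male = staging.sex_degs(f, m)
    assert len(female) == 0 and len(male) == 0
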