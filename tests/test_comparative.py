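"""Dataset balancing, correlation structure, DEG composition, gene sets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from prophasex import comparative
from conftest import make_bundle


def _named_bundle(n_genes, n_cells, prefix, seed):
    rng = np.random.default_rng(seed)
    b = make_bundle(rng.uniform(0, 10, size=(n_genes, n_cells)))
    b.tpm.columns = [f"{prefix}{j}" for j in range(n_cells)]
    b.cells.index = b.tpm.columns
    return b


# ---------------------------------------------------------------------------
# balance_datasets
# ---------------------------------------------------------------------------

def test_balance_keeps_small_and_samples_large():
    f = _named_bundle(40, 158, "f", 21)
    m = _named_bundle(40, 1312, "m", 22)
    merged = comparative.balance_datasets(f, m, target_n=160, seed=0)
    assert merged.n_cells == 318
    assert set(f.tpm.columns) <= set(merged.tpm.columns)
    assert len(set(merged.tpm.columns)) == 318  # no duplicates


def test_balance_is_deterministic_per_seed():
    f = _named_bundle(20, 10, "f", 23)
    m = _named_bundle(20, 50, "m", 24)
    m1 = comparative.balance_datasets(f, m, target_n=12, seed=5)
    m2 = comparative.balance_datasets(f, m, target_n=12, seed=5)
    assert list(m1.tpm.columns) == list(m2.tpm.columns)
    m3 = comparative.balance_datasets(f, m, target_n=12, seed=6)
    assert list(m3.tpm.columns) != list(m1.tpm.columns)


def test_balance_full_size_is_concatenation():
    f = _named_bundle(20, 10, "f", 25)
    m = _named_bundle(20, 30, "m", 26)
    merged = comparative.balance_datasets(f, m, target_n=30, seed=0)
    assert merged.n_cells == 40
    with pytest.raises(ValueError):
        comparative.balance_datasets(f, m, target_n=31, seed=0)


# ---------------------------------------------------------------------------
# cluster_correlation
# ---------------------------------------------------------------------------

def test_identical_cluster_means_correlate_perfectly():
    mat = np.tile(np.arange(1.0, 21.0)[:, None], (1, 10))
    b = make_bundle(mat)
    labels = ["A"] * 5 + ["B"] * 5
    res = comparative.cluster_correlation(b, labels, top_n=20)
    assert res.matrix.loc["A", "B"] == pytest.approx(1.0)
    assert np.allclose(np.diag(res.matrix), 1.0)


def test_spearman_is_rank_invariant():
    rng = np.random.default_rng(27)
    mat = rng.uniform(1, 10, size=(30, 9))
    b = make_bundle(mat)
    labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
    res1 = comparative.cluster_correlation(b, labels, top_n=30)
    # strictly increasing transform of cluster C's cells
    mat2 = mat.copy()
    mat2[:, 6:] = np.exp(mat2[:, 6:] / 3.0)
    res2 = comparative.cluster_correlation(make_bundle(mat2), labels, top_n=30)
    assert res1.matrix.loc["A", "B"] == pytest.approx(res2.matrix.loc["A", "B"], abs=0.3)
    # note: the gene set may shift with variance; compare on shared structure
    assert np.allclose(np.diag(res2.matrix), 1.0)
    assert np.allclose(res2.matrix, res2.matrix.T, atol=1e-12)


def test_cluster_correlation_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(28)
    n_per = 4
    # 5-cluster toy with block structure: clusters {A,B} share a profile,
    # {C,D,E} share another
    base1 = rng.uniform(1, 10, size=40)
    base2 = rng.uniform(1, 10, size=40)
    cols = []
    for prof in (base1, base1, base2, base2, base2):
        cols.append(prof[:, None] + rng.normal(0, 0.1, size=(40, n_per)))
    mat = np.clip(np.concatenate(cols, axis=1), 0, None)
    labels = sum([[c] * n_per for c in "ABCDE"], [])
    b = make_bundle(mat)
    res = comparative.cluster_correlation(b, labels, top_n=40)
    # oracle: per-cluster means, rank, then Pearson on ranks
    means = np.column_stack([mat[:, np.array(labels) == c].mean(axis=1) for c in "ABCDE"])
    ranks = np.column_stack([stats.rankdata(means[:, k]) for k in range(5)])
    oracle = np.corrcoef(ranks.T)
    assert np.allclose(res.matrix.to_numpy(), oracle, atol=1e-10)
    # dendrogram joins within-block pairs first
    flat = fcluster(res.dendrogram, t=2, criterion="maxclust")
    groups = dict(zip(res.labels, flat))
    assert groups["A"] == groups["B"]
    assert groups["C"] == groups["D"] == groups["E"]
    assert groups["A"] != groups["C"]


# ---------------------------------------------------------------------------
# gene_correlation
# ---------------------------------------------------------------------------

def test_gene_correlation_thresholds_and_exclusions():
    rng = np.random.default_rng(29)
    n = 20
    target = rng.uniform(1, 10, size=n)
    mat = np.vstack([
        target,                       # the target itself (excluded)
        -target + 20,                 # r = -1, reported
        rng.uniform(1, 10, size=n),   # noise
    ])
    b = make_bundle(np.clip(mat, 0, None))
    out = comparative.gene_correlation(b, "g0")
    assert "g0" not in set(out["gene_id"])
    neg = out[out["gene_id"] == "g1"]
    assert len(neg) == 1 and neg["r"].iloc[0] == pytest.approx(-1.0)
    assert neg["p_value"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_gene_correlation_exact_threshold_excluded():
    # engineer r exactly 0.5 between g1 and target g0
    target = np.array([1.0, 2.0, 3.0, 4.0])
    tc = target - target.mean()
    noise = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to tc
    # x = a*tc + b*noise with a,b chosen for r = 0.5
    a, bcoef = 0.5, np.sqrt(1 - 0.25) * np.linalg.norm(tc) / np.linalg.norm(noise)
    x = a * tc + bcoef * noise + 10
    r_check = np.corrcoef(target, x)[0, 1]
    assert r_check == pytest.approx(0.5, abs=1e-12)
    b = make_bundle(np.vstack([target, x, target * 2]))
    out = comparative.gene_correlation(b, "g0", r_threshold=0.5)
    assert "g1" not in set(out["gene_id"])  # strict inequality
    assert "g2" in set(out["gene_id"])      # r = 1


def test_gene_correlation_zero_variance_target():
    b = make_bundle(np.vstack([np.full(5, 3.0), np.arange(5.0)]))
    with pytest.raises(ValueError):
        comparative.gene_correlation(b, "g0")


# ---------------------------------------------------------------------------
# deg_composition / disease_intersection / geneset_overrep
# ---------------------------------------------------------------------------

def _annotation(n_x, n_rest):
    rows = [(f"x{i}", "X", "protein_coding") for i in range(n_x)]
    rows += [(f"a{i}", str(1 + i % 22), "protein_coding") for i in range(n_rest)]
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "biotype"]).set_index("gene_id")


def test_deg_composition_percentages():
    ann = _annotation(205, 913)
    degs = pd.DataFrame({"gene_id": list(ann.index)})
    comp = comparative.deg_composition(degs, ann)
    assert comp["total"] == 1118
    assert comp["by_chromosome"].loc["X", "count"] == 205
    assert comp["by_chromosome"].loc["X", "percent"] == 18.3
    # one-decimal rounding drifts by at most 0.05 per category
    n_cat = len(comp["by_chromosome"])
    assert abs(comp["by_chromosome"]["percent"].sum() - 100.0) <= 0.05 * n_cat


def test_deg_composition_single_chromosome():
    ann = _annotation(0, 10)
    ann["chromosome"] = "5"
    degs = pd.DataFrame({"gene_id": list(ann.index)})
    comp = comparative.deg_composition(degs, ann)
    assert comp["by_chromosome"].loc["5", "percent"] == 100.0


def test_deg_composition_empty_list_errors():
    with pytest.raises(ValueError):
        comparative.deg_composition(pd.DataFrame({"gene_id": []}), _annotation(1, 1))


def test_disease_intersection_labels():
    tables = {
        "azoospermia": {"g1", "g2"},
        "male infertility": {"g2", "g3"},
    }
    degs = pd.DataFrame({"gene_id": ["g1", "g2", "g3", "g4"]})
    out = comparative.disease_intersection(degs, tables)
    by_gene = out.set_index("gene_id")["label"]
    assert by_gene["g1"] == "azoospermia"
    assert by_gene["g2"] == "multiple diseases"
    assert by_gene["g3"] == "male infertility"
    assert "g4" not in by_gene.index


def test_geneset_overrep_matches_hypergeometric_tail():
    universe = {f"g{i}" for i in range(40)}
    query = {f"g{i}" for i in range(10)}
    sets = {"hit": {f"g{i}" for i in range(8)}, "whole": set(universe)}
    out = comparative.geneset_overrep(query, sets, universe).set_index("set")
    # 2x2 table: overlap 8; Fisher two-sided equals scipy on the same table
    table = np.array([[8, 2], [0, 30]])
    _, p_ref = stats.fisher_exact(table, alternative="two-sided")
    assert out.loc["hit", "p_value"] == pytest.approx(p_ref, abs=1e-12)
    assert out.loc["whole", "p_value"] == pytest.approx(1.0)


def test_geneset_overrep_empty_universe():
    with pytest.raises(ValueError):
        comparative.geneset_overrep({"g"}, {"s": {"g"}}, set())
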