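"""Cross-dataset and gene-list comparative analyses.

Balancing two datasets by seeded subsampling, Spearman correlation
structure between cluster mean profiles (with a complete-linkage
dendrogram), single-gene (e.g. XIST) Pearson co-expression screens, DEG
composition by chromosome and biotype, disease-table intersection, and a
generic gene-set over-representation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._stats import bh_adjust
from .annotation_io import ExpressionBundle

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "balance_datasets",
    "cluster_correlation",
    "gene_correlation",
    "deg_composition",
    "disease_intersection",
    "geneset_overrep",
    "read_disease_tables",
    "read_gmt",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Cluster-by-cluster correlation matrix and its complete-linkage tree."""

    labels: tuple
    matrix: pd.DataFrame
    dendrogram: np.ndarray  # scipy linkage matrix on (1 - correlation)


def balance_datasets(bundle_a, bundle_b, target_n: int, seed: int = 0) -> ExpressionBundle:
    """Merge two bundles, downsampling the larger to ``target_n`` cells.

    All cells of the smaller bundle are kept; ``target_n`` cells are drawn
    without replacement (seeded) from the larger; gene universes are
    intersected. Deterministic per seed.
    """
    small, large = (bundle_a, bundle_b) if bundle_a.n_cells <= bundle_b.n_cells else (bundle_b, bundle_a)
    if target_n > large.n_cells:
        raise ValueError(f"target_n={target_n} exceeds the {large.n_cells} cells available")
    shared = small.tpm.index.intersection(large.tpm.index)
    if shared.empty:
        raise ValueError("bundles share no genes")
    small = small.subset_genes(shared)
    large = large.subset_genes(shared)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(large.tpm.columns.to_numpy(), size=target_n, replace=False)
    large = large.subset_cells(chosen)
    overlap = set(small.tpm.columns) & set(large.tpm.columns)
    if overlap:
        raise ValueError(f"duplicate cell ids across bundles: {sorted(overlap)[:5]}")
    has_vel = small.has_velocity() and large.has_velocity()
    # align large's gene order to small's before concatenating
    large_tpm = large.tpm.loc[small.tpm.index]
    cells = pd.concat([small.cells, large.cells.reindex(columns=small.cells.columns)])
    return ExpressionBundle(
        tpm=pd.concat([small.tpm, large_tpm], axis=1),
        cells=cells,
        genes=small.genes,
        spliced=pd.concat([small.spliced, large.spliced.loc[small.tpm.index]], axis=1) if has_vel else None,
        unspliced=pd.concat([small.unspliced, large.unspliced.loc[small.tpm.index]], axis=1) if has_vel else None,
    )


def cluster_correlation(bundle, labels, top_n: int = 100) -> CorrelationResult:
    """Spearman correlation between cluster mean-expression profiles.

    Per-cluster gene means are computed, the ``top_n`` genes with the most
    variable means (plain sample variance across clusters) are kept, and
    the Spearman correlation between cluster mean-vectors is assembled
    into a matrix with a complete-linkage dendrogram on 1 - correlation.
    """
    labels = pd.Series(labels, index=bundle.tpm.columns) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(bundle.tpm.columns)
    uniq = list(pd.unique(labels.dropna()))
    if len(uniq) < 2:
        raise ValueError("cluster_correlation requires at least 2 clusters")
    means = pd.DataFrame(
        {c: bundle.tpm.loc[:, (labels == c).to_numpy()].mean(axis=1) for c in uniq}
    )
    if top_n > len(means):
        logger.warning("top_n=%d exceeds gene count %d; using all genes", top_n, len(means))
        top_n = len(means)
    var = means.var(axis=1, ddof=1)
    keep = var.sort_values(ascending=False, kind="stable").index[:top_n]
    sub = means.loc[keep]
    rho = sub.corr(method="spearman").to_numpy()
    mat = pd.DataFrame((rho + rho.T) / 2.0, index=uniq, columns=uniq)
    np.fill_diagonal(mat.values, 1.0)
    dist = squareform(1.0 - mat.to_numpy(), checks=False)
    tree = linkage(dist, method="complete")
    return CorrelationResult(labels=tuple(uniq), matrix=mat, dendrogram=tree)


def gene_correlation(bundle, target_gene_id: str, cells=None, r_threshold: float = 0.5) -> pd.DataFrame:
    """Genes whose expression correlates with a target gene (Pearson).

    Over the given cell subset (default: all cells), every other gene's
    Pearson r and two-sided p against the target are computed; genes with
    ``r > r_threshold`` or ``r < -r_threshold`` (strict) are reported,
    the target itself excluded.
    """
    if target_gene_id not in bundle.tpm.index:
        raise ValueError(f"target gene {target_gene_id!r} not in bundle")
    tpm = bundle.tpm if cells is None else bundle.tpm[list(cells)]
    n = tpm.shape[1]
    if n < 3:
        raise ValueError("gene_correlation requires at least 3 cells")
    target = tpm.loc[target_gene_id].to_numpy(dtype=float)
    if np.var(target) == 0:
        raise ValueError(f"target gene {target_gene_id!r} has zero variance over the subset")
    mat = tpm.to_numpy(dtype=float)
    tc = target - target.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((mc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ tc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    df = pd.DataFrame({"gene_id": tpm.index, "r": r, "p_value": p})
    df = df[(df["gene_id"] != target_gene_id) & (df["r"].abs() > r_threshold) & df["r"].notna()]
    return df.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)


def deg_composition(degs: pd.DataFrame, annotation: pd.DataFrame) -> dict:
    """Chromosome and biotype composition of a DEG list.

    Returns per-chromosome and per-biotype counts with percentages of the
    DEG total rounded to one decimal place, plus a BED-like locus table of
    the X-linked entries when the annotation carries coordinates. DEGs
    absent from the annotation fall into an ``unannotated`` bucket.
    """
    if degs is None or len(degs) == 0:
        raise ValueError("empty DEG list")
    gene_ids = degs["gene_id"] if "gene_id" in getattr(degs, "columns", []) else pd.Series(list(degs))
    gene_ids = pd.Index(gene_ids)
    ann = annotation.reindex(gene_ids)
    missing = ann["chromosome"].isna()
    if missing.any():
        logger.warning("%d DEGs missing from annotation -> 'unannotated'", int(missing.sum()))
    chrom = ann["chromosome"].fillna("unannotated")
    biotype = ann["biotype"].fillna("unannotated") if "biotype" in ann.columns else pd.Series("unannotated", index=gene_ids)
    total = len(gene_ids)

    def _tally(series: pd.Series) -> pd.DataFrame:
        counts = series.value_counts()
        return pd.DataFrame(
            {"count": counts, "percent": (100.0 * counts / total).round(1)}
        )

    result = {
        "total": total,
        "by_chromosome": _tally(chrom),
        "by_biotype": _tally(biotype),
    }
    x_mask = (chrom == "X").to_numpy()
    x_ids = gene_ids[x_mask]
    loci_cols = [c for c in ("chromosome", "start", "end") if c in ann.columns]
    if {"start", "end"}.issubset(loci_cols):
        loci = ann.loc[x_ids, ["chromosome", "start", "end"]].copy()
        loci["gene_id"] = x_ids
        result["x_loci"] = loci.reset_index(drop=True)[["chromosome", "start", "end", "gene_id"]]
    else:
        result["x_loci"] = pd.DataFrame({"gene_id": x_ids})
    return result


def disease_intersection(degs, disease_tables: dict[str, set]) -> pd.DataFrame:
    """Match DEGs against disease gene sets.

    ``disease_tables`` maps a disease-term label to its gene set. Each DEG
    matching at least one term is reported with its matched terms; genes
    matching two or more terms get the label ``multiple diseases``; genes
    matching none are omitted.
    """
    if not disease_tables:
        raise ValueError("at least one disease table is required")
    gene_ids = degs["gene_id"] if "gene_id" in getattr(degs, "columns", []) else list(degs)
    rows = []
    for gid in gene_ids:
        matched = sorted(term for term, members in disease_tables.items() if gid in members)
        if not matched:
            continue
        label = "multiple diseases" if len(matched) >= 2 else matched[0]
        rows.append({"gene_id": gid, "diseases": matched, "label": label})
    return pd.DataFrame(rows, columns=["gene_id", "diseases", "label"])


def geneset_overrep(query: set, sets: dict[str, set], universe: set) -> pd.DataFrame:
    """Fisher exact over-representation of a query gene set, BH adjusted.

    Each named set is intersected with the universe; per set, the 2x2
    table (in query x in set) is tested two-sided; q-values are BH across
    the sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        overlap = len(query & members)
        table = np.array(
            [
                [overlap, len(query) - overlap],
                [len(members) - overlap, len(universe) - len(query) - len(members) + overlap],
            ]
        )
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"set": name, "set_size": len(members), "overlap": overlap, "p_value": p})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def read_disease_tables(path) -> dict[str, set]:
    """Read a two-column (term_label, gene_id) TSV into term -> gene set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    term_col, gene_col = df.columns[:2]
    return {term: set(grp[gene_col]) for term, grp in df.groupby(term_col, sort=False)}


def read_gmt(path) -> dict[str, set]:
    """Read GMT lines (name, description, members...) into name -> gene set."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(g for g in parts[2:] if g)
    return out
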