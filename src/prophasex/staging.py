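"""Meiotic stage assignment and differential expression.

Stage labels come from marker-panel scoring (pre-meiotic, leptotene,
zygotene, pachytene, diplotene/dictyate); seeded k-means on principal
components is provided as clustering plumbing. DEG calling is one-vs-rest
Wilcoxon rank-sum with Benjamini-Hochberg adjustment and the
``p_adjusted < 0.05``, ``pct_1 > 0.6`` filters; sex-enriched DEGs use the
stricter ``p_adjusted < 0.01`` with ``|ln fold change| > 1.5``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._stats import bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "MarkerPanel",
    "score_stage",
    "cluster_cells",
    "find_degs",
    "sex_degs",
    "read_marker_panels",
    "write_degs",
]

STAGES = ("pre_meiotic", "leptotene", "zygotene", "pachytene", "diplotene")

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class MarkerPanel:
    """Positive (and optional negative) marker genes defining one stage."""

    stage: str
    positive_markers: tuple[str, ...]
    negative_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.positive_markers:
            raise ValueError(f"marker panel for {self.stage!r} has no positive markers")


def read_marker_panels(path) -> list[MarkerPanel]:
    """Read panels from a TSV with columns stage, gene_id, direction (+/-)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    panels = []
    for stage, grp in df.groupby("stage", sort=False):
        direction = grp.get("direction", pd.Series("+", index=grp.index)).fillna("+")
        pos = tuple(grp.loc[direction != "-", "gene_id"])
        neg = tuple(grp.loc[direction == "-", "gene_id"])
        panels.append(MarkerPanel(stage=stage, positive_markers=pos, negative_markers=neg))
    return panels


def _zscore_log1p(tpm: pd.DataFrame) -> pd.DataFrame:
    logx = np.log1p(tpm)
    mu = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)  # constant genes -> z = 0
    return logx.sub(mu, axis=0).div(sd, axis=0)


def score_stage(bundle, panels: list[MarkerPanel]) -> pd.DataFrame:
    """Score each cell against each stage panel and call the argmax stage.

    Per-stage score = mean z-scored (across cells, of log1p TPM) expression
    of the panel's positive markers minus the mean for negative markers.
    Cells whose top two scores tie within 1e-9, or whose scores are all
    <= 0, are labelled ``unassigned``.

    Returns a DataFrame indexed by cell id with one score column per stage
    and a ``stage`` column holding the call.
    """
    if not panels:
        raise ValueError("no marker panels given")
    stage_names = [p.stage for p in panels]
    if len(set(stage_names)) != len(stage_names):
        raise ValueError("duplicate stages in marker panel set")
    z = _zscore_log1p(bundle.tpm)
    scores = {}
    usable = 0
    for panel in panels:
        pos = [g for g in panel.positive_markers if g in z.index]
        missing = set(panel.positive_markers) - set(pos)
        if missing:
            logger.warning("panel %s: %d positive markers absent, skipped", panel.stage, len(missing))
        neg = [g for g in panel.negative_markers if g in z.index]
        if not pos and not neg:
            scores[panel.stage] = pd.Series(np.nan, index=z.columns)
            continue
        usable += 1
        s = z.loc[pos].mean(axis=0) if pos else pd.Series(0.0, index=z.columns)
        if neg:
            s = s - z.loc[neg].mean(axis=0)
        scores[panel.stage] = s
    if usable == 0:
        raise ValueError("all marker panels are empty after matching against the bundle")
    table = pd.DataFrame(scores)
    vals = table.to_numpy()
    order = np.argsort(-np.where(np.isnan(vals), -np.inf, vals), axis=1)
    best = vals[np.arange(len(table)), order[:, 0]]
    labels = table.columns.to_numpy()[order[:, 0]].astype(object)
    if table.shape[1] > 1:
        second = vals[np.arange(len(table)), order[:, 1]]
        tied = np.abs(best - second) <= _TIE_TOL
        labels[tied] = "unassigned"
    labels[~(best > 0)] = "unassigned"
    out = table.copy()
    out["stage"] = labels
    out.index.name = "cell_id"
    return out


def cluster_cells(bundle, k: int, n_pcs: int = 10, seed: int = 0) -> pd.Series:
    """Seeded k-means on the top principal components of log1p expression.

    Cells are log1p-transformed, genes standardized, projected to
    ``n_pcs`` components and clustered; deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if k > bundle.n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({bundle.n_cells})")
    z = _zscore_log1p(bundle.tpm).to_numpy().T  # cells x genes
    n_pcs = min(n_pcs, min(z.shape) - 1) or 1
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(z)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pcs)
    return pd.Series(km.labels_, index=bundle.tpm.columns, name="cluster")


def _group_stats(mat: np.ndarray, in_mask: np.ndarray) -> tuple[np.ndarray, ...]:
    x_in = mat[:, in_mask]
    x_out = mat[:, ~in_mask]
    mean_in = x_in.mean(axis=1)
    mean_out = x_out.mean(axis=1)
    pct1 = (x_in > 0).mean(axis=1)
    pct2 = (x_out > 0).mean(axis=1)
    lfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
    return x_in, x_out, mean_in, mean_out, pct1, pct2, lfc


def _ranksum_pvalues(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene (rows), via the shared policy.

    Vectorized asymptotic path when the combined size rules out the exact
    method for every gene; otherwise per-gene dispatch.
    """
    n = x_in.shape[1] + x_out.shape[1]
    if n > 25:
        res = stats.mannwhitneyu(x_in, x_out, alternative="two-sided", method="asymptotic", axis=1)
        return np.asarray(res.pvalue, dtype=float)
    return np.array([rank_sum_test(a, b)[1] for a, b in zip(x_in, x_out)])


def find_degs(bundle, labels, min_pct1: float = 0.6, max_p_adj: float = 0.05) -> pd.DataFrame:
    """One-vs-rest Wilcoxon DEGs per cluster with the pct/p filters.

    For every gene and cluster: two-sided rank-sum of in-cluster versus
    all other cells, BH adjustment within the cluster's gene list, natural
    log fold change ``ln((mean_in + 1)/(mean_out + 1))``. Records are kept
    when ``p_adjusted < max_p_adj`` and ``pct_1 > min_pct1`` (both strict),
    sorted by cluster then ascending p. Clusters with fewer than 3 cells
    are skipped with a warning.
    """
    labels = pd.Series(labels, index=bundle.tpm.columns) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(bundle.tpm.columns)
    uniq = [c for c in pd.unique(labels.dropna())]
    if len(uniq) < 2:
        raise ValueError("find_degs requires at least 2 clusters")
    mat = bundle.tpm.to_numpy()
    genes = bundle.tpm.index.to_numpy()
    records = []
    for cluster in uniq:
        in_mask = (labels == cluster).to_numpy()
        if in_mask.sum() < 3:
            logger.warning("cluster %r has < 3 cells; skipped", cluster)
            continue
        x_in, x_out, _, _, pct1, pct2, lfc = _group_stats(mat, in_mask)
        pvals = _ranksum_pvalues(x_in, x_out)
        padj = bh_adjust(pvals)
        keep = (padj < max_p_adj) & (pct1 > min_pct1)
        df = pd.DataFrame(
            {
                "gene_id": genes[keep],
                "cluster": cluster,
                "p_value": pvals[keep],
                "p_adjusted": padj[keep],
                "avg_logFC": lfc[keep],
                "pct_1": pct1[keep],
                "pct_2": pct2[keep],
            }
        )
        records.append(df.sort_values("p_value", kind="stable"))
    if not records:
        raise ValueError("no cluster had enough cells for DEG calling")
    return pd.concat(records, ignore_index=True)


def sex_degs(
    bundle_f,
    bundle_m,
    max_p_adj: float = 0.01,
    min_abs_logfc: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Female- and male-enriched DEGs between two bundles.

    Two-group Wilcoxon per gene on the shared gene universe, BH adjusted
    across genes; records kept when ``|avg_logFC| > min_abs_logfc`` and
    ``p_adjusted < max_p_adj`` (both strict). The sign of the natural-log
    fold change (female over male) decides the enriched side.
    """
    shared = bundle_f.tpm.index.intersection(bundle_m.tpm.index)
    if shared.empty:
        raise ValueError("bundles share no genes")
    f = bundle_f.tpm.loc[shared].to_numpy()
    m = bundle_m.tpm.loc[shared].to_numpy()
    mean_f = f.mean(axis=1)
    mean_m = m.mean(axis=1)
    lfc = np.log((mean_f + 1.0) / (mean_m + 1.0))
    pct_f = (f > 0).mean(axis=1)
    pct_m = (m > 0).mean(axis=1)
    pvals = _ranksum_pvalues(f, m)
    padj = bh_adjust(pvals)
    df = pd.DataFrame(
        {
            "gene_id": shared,
            "p_value": pvals,
            "p_adjusted": padj,
            "avg_logFC": lfc,
            "pct_1": pct_f,
            "pct_2": pct_m,
        }
    )
    kept = df[(df["p_adjusted"] < max_p_adj) & (df["avg_logFC"].abs() > min_abs_logfc)]
    female = kept[kept["avg_logFC"] > 0].sort_values("p_value", kind="stable").reset_index(drop=True)
    male = kept[kept["avg_logFC"] < 0].copy()
    # report male-enriched records from the male perspective
    male["avg_logFC"] = -male["avg_logFC"]
    male[["pct_1", "pct_2"]] = male[["pct_2", "pct_1"]].to_numpy()
    male = male.sort_values("p_value", kind="stable").reset_index(drop=True)
    return female, male


def write_degs(degs: pd.DataFrame, path) -> None:
    """Write DEG records as TSV (mirrors the DEGRecord fields)."""
    degs.to_csv(path, sep="\t", index=False)
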