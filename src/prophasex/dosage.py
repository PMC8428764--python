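"""Per-cell chromosome:autosome dosage ratios and their stage comparisons.

For every cell, the mean TPM over each chromosome class (Chr7, ChrX
escapees, ChrX subject-to-XCI) is divided by the mean over the autosome
universe (chr1-22, chromosome 7 included; Y and excluded genes never
enter the denominator). A rising female pachytene X:A ratio with a flat
Chr7:A control is the dosage signature this table exists to expose; stage
contrasts use the two-sided Wilcoxon rank-sum test and within-cell class
contrasts the paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import rank_sum_test, signed_rank_test
from .annotation_io import AUTOSOME, CHR7, CHRX_E, CHRX_S

__all__ = [
    "RATIO_CLASSES",
    "class_means",
    "compare_across_stages",
    "compare_within_cells",
    "PairedTestResult",
]

RATIO_CLASSES = (CHR7, CHRX_E, CHRX_S)

_MIN_CLASS_GENES = 5


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a paired within-cell class comparison."""

    class_a: str
    class_b: str
    stratum: tuple[str, str]
    n: int
    statistic: float
    p_value: float
    median_a: float
    median_b: float


def _surviving_genes(bundle, detect_frac: float, universe=None) -> pd.Index:
    detected = (bundle.tpm > 0).mean(axis=1)
    keep = bundle.tpm.index[detected >= detect_frac]
    if universe is not None:
        uni = set(universe)
        keep = pd.Index([g for g in keep if g in uni])
    return keep


def class_means(bundle, detect_frac: float = 0.05, universe=None) -> pd.DataFrame:
    """Per-cell class means and class/autosome ratios.

    The gene universe is first restricted to genes detected (TPM > 0) in at
    least ``detect_frac`` of cells (0 reproduces "all genes"), then
    optionally intersected with ``universe`` (e.g. ubiquitously expressed
    genes). Per cell, ``mean_c`` is the arithmetic mean of TPM over the
    surviving class-c genes, zeros included; ``ratio_c = mean_c / mean_A``
    with the autosome universe (chromosome 7 included) as denominator.
    Cells with ``mean_A == 0`` are flagged ``valid=False`` and should be
    excluded from tests.
    """
    if "chrom_class" not in bundle.genes.columns:
        raise ValueError("bundle genes carry no chrom_class; run classify_genes/attach_annotation first")
    keep = _surviving_genes(bundle, detect_frac, universe)
    genes = bundle.genes.loc[keep]
    tpm = bundle.tpm.loc[keep]

    groups = {
        "A": genes.index[genes["chrom_class"].isin([AUTOSOME, CHR7])],
        CHR7: genes.index[genes["chrom_class"] == CHR7],
        CHRX_E: genes.index[genes["chrom_class"] == CHRX_E],
        CHRX_S: genes.index[genes["chrom_class"] == CHRX_S],
    }
    for name, idx in groups.items():
        if len(idx) < _MIN_CLASS_GENES:
            label = "autosome universe" if name == "A" else name
            raise ValueError(
                f"{label} has only {len(idx)} genes after filtering (>= {_MIN_CLASS_GENES} required)"
            )

    out = pd.DataFrame(index=bundle.tpm.columns)
    for col in ("sex", "stage"):
        out[col] = bundle.cells[col] if col in bundle.cells.columns else np.nan
    mean_a = tpm.loc[groups["A"]].mean(axis=0)
    out["mean_A"] = mean_a
    valid = mean_a > 0
    for cls in RATIO_CLASSES:
        mc = tpm.loc[groups[cls]].mean(axis=0)
        out[f"mean_{cls}"] = mc
        out[f"ratio_{cls}"] = np.where(valid, mc / mean_a.where(valid, 1.0), np.nan)
    out["valid"] = valid
    out.index.name = "cell_id"
    return out


def _stratum_mask(table: pd.DataFrame, stratum: tuple[str, str]) -> np.ndarray:
    sex, stage = stratum
    mask = (table["sex"] == sex) & (table["stage"] == stage) & table["valid"]
    if not mask.any():
        raise ValueError(f"unknown or empty stratum {stratum!r}")
    return mask.to_numpy()


def compare_across_stages(
    table: pd.DataFrame,
    class_c: str,
    strata_pairs,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise rank-sum tests of ``ratio_{class_c}`` between strata.

    ``strata_pairs`` is an iterable of ((sex, stage), (sex, stage)) pairs;
    each stratum needs at least 3 valid cells. Returns one row per pair
    with the U statistic, p-value and group medians.
    """
    col = f"ratio_{class_c}"
    if col not in table.columns:
        raise ValueError(f"unknown ratio class {class_c!r}")
    rows = []
    for stratum_a, stratum_b in strata_pairs:
        a = table.loc[_stratum_mask(table, tuple(stratum_a)), col].dropna().to_numpy()
        b = table.loc[_stratum_mask(table, tuple(stratum_b)), col].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"strata {stratum_a}/{stratum_b} have < 3 cells")
        stat, p = rank_sum_test(a, b, alternative=alternative)
        rows.append(
            {
                "stratum_a": tuple(stratum_a),
                "stratum_b": tuple(stratum_b),
                "class": class_c,
                "n_a": len(a),
                "n_b": len(b),
                "statistic": stat,
                "p_value": p,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
            }
        )
    return pd.DataFrame(rows)


def compare_within_cells(
    table: pd.DataFrame,
    class_a: str,
    class_b: str,
    stratum: tuple[str, str],
    alternative: str = "two-sided",
) -> PairedTestResult:
    """Paired signed-rank test of ``ratio_{class_a}`` vs ``ratio_{class_b}``
    within one stratum (zero differences dropped; all-zero -> p = 1)."""
    cols = (f"ratio_{class_a}", f"ratio_{class_b}")
    for c in cols:
        if c not in table.columns:
            raise ValueError(f"unknown ratio class in {c!r}")
    sub = table.loc[_stratum_mask(table, tuple(stratum)), list(cols)].dropna()
    if len(sub) < 6:
        raise ValueError(f"stratum {stratum!r} has only {len(sub)} paired cells (>= 6 required)")
    a = sub[cols[0]].to_numpy()
    b = sub[cols[1]].to_numpy()
    stat, p = signed_rank_test(a, b, alternative=alternative)
    return PairedTestResult(
        class_a=class_a,
        class_b=class_b,
        stratum=tuple(stratum),
        n=len(sub),
        statistic=stat,
        p_value=p,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
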