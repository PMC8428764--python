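"""Unspliced/total RNA fractions and the XCU-vs-stability verdict.

At kinetic steady state the unspliced fraction of a gene's RNA is
``gamma/(beta + gamma)`` — independent of the transcription rate. A
per-cell, per-class pooled fraction ``sum(u) / sum(u + s)`` therefore
separates the two explanations for an elevated X:A dosage ratio:
transcriptional upregulation (XCU) leaves the fraction at autosomal
levels, while increased transcript stability (lower degradation)
depresses it. ``discriminate_mechanism`` formalizes that argument as a
two-test decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import rank_sum_test, signed_rank_test
from .annotation_io import AUTOSOME, CHR7, CHRX_E, CHRX_S

__all__ = [
    "FRACTION_CLASSES",
    "unspliced_fractions",
    "class_fraction_test",
    "discriminate_mechanism",
    "MechanismVerdict",
]

FRACTION_CLASSES = (AUTOSOME, CHR7, CHRX_E, CHRX_S)

_MIN_PAIRED_CELLS = 6


@dataclass(frozen=True)
class MechanismVerdict:
    """Decision for one stratum: XCU, TURNOVER, NONE or AMBIGUOUS.

    The verdict is a pure function of two tests: (1) X dosage elevation
    (rank-sum of ChrX-S:A in the stratum vs the reference stratum,
    one-sided greater) and (2) X turnover deficit (paired signed-rank of
    the ChrX-S unspliced fraction vs the autosomal one within the stratum,
    one-sided less).
    """

    stratum: tuple[str, str]
    reference_stratum: tuple[str, str]
    verdict: str
    dosage_p: float
    turnover_p: float | None
    alpha_dosage: float
    alpha_turnover: float


def unspliced_fractions(bundle, detect_frac: float = 0.05, per_gene_mean: bool = False) -> pd.DataFrame:
    """Per-cell unspliced/total fraction per chromosome class.

    The default pooled form is ``frac_c = u_sum_c / (u_sum_c + s_sum_c)``
    over the class's surviving genes (same detection filter as the dosage
    module: detected in >= ``detect_frac`` of cells on TPM);
    ``per_gene_mean=True`` instead averages per-gene fractions
    ``u/(u+s)`` over genes with nonzero totals. Fractions with a zero
    denominator are NaN. ``AUTOSOME`` here means the full autosome
    universe (chromosome 7 included), matching the dosage denominator.
    """
    if not bundle.has_velocity():
        raise ValueError(
            "bundle has no spliced/unspliced matrices; this analysis requires "
            "velocyto-style spliced and unspliced counts"
        )
    if "chrom_class" not in bundle.genes.columns:
        raise ValueError("bundle genes carry no chrom_class; run classify_genes/attach_annotation first")
    detected = (bundle.tpm > 0).mean(axis=1)
    keep = bundle.tpm.index[detected >= detect_frac]
    genes = bundle.genes.loc[keep]
    u = bundle.unspliced.loc[keep]
    s = bundle.spliced.loc[keep]

    groups = {
        AUTOSOME: genes.index[genes["chrom_class"].isin([AUTOSOME, CHR7])],
        CHR7: genes.index[genes["chrom_class"] == CHR7],
        CHRX_E: genes.index[genes["chrom_class"] == CHRX_E],
        CHRX_S: genes.index[genes["chrom_class"] == CHRX_S],
    }
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"no genes left in class {name} after the detection filter")

    out = pd.DataFrame(index=bundle.tpm.columns)
    for col in ("sex", "stage"):
        out[col] = bundle.cells[col] if col in bundle.cells.columns else np.nan
    for cls, idx in groups.items():
        u_c = u.loc[idx]
        s_c = s.loc[idx]
        if per_gene_mean:
            tot = u_c + s_c
            frac_gene = u_c.where(tot > 0) / tot.where(tot > 0)
            frac = frac_gene.mean(axis=0)
            u_sum = u_c.sum(axis=0)
            t_sum = tot.sum(axis=0)
        else:
            u_sum = u_c.sum(axis=0)
            t_sum = u_sum + s_c.sum(axis=0)
            frac = u_sum.where(t_sum > 0) / t_sum.where(t_sum > 0)
        out[f"u_sum_{cls}"] = u_sum
        out[f"t_sum_{cls}"] = t_sum
        out[f"frac_{cls}"] = frac
    out.index.name = "cell_id"
    return out


def _stratum_mask(table: pd.DataFrame, stratum: tuple[str, str]) -> np.ndarray:
    sex, stage = stratum
    mask = (table["sex"] == sex) & (table["stage"] == stage)
    if not mask.any():
        raise ValueError(f"unknown or empty stratum {stratum!r}")
    return mask.to_numpy()


def class_fraction_test(
    table: pd.DataFrame,
    class_a: str,
    class_b: str,
    stratum: tuple[str, str],
    alternative: str = "two-sided",
):
    """Paired signed-rank test of ``frac_{class_a}`` vs ``frac_{class_b}``
    within one stratum. Returns a result with statistic, p and medians."""
    from .dosage import PairedTestResult

    cols = (f"frac_{class_a}", f"frac_{class_b}")
    for c in cols:
        if c not in table.columns:
            raise ValueError(f"unknown fraction class in {c!r}")
    sub = table.loc[_stratum_mask(table, tuple(stratum)), list(cols)].dropna()
    if len(sub) < _MIN_PAIRED_CELLS:
        raise ValueError(
            f"stratum {stratum!r} has only {len(sub)} cells with defined fractions "
            f"(>= {_MIN_PAIRED_CELLS} required)"
        )
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


def discriminate_mechanism(
    dosage_table: pd.DataFrame,
    turnover_table: pd.DataFrame,
    stratum: tuple[str, str],
    reference_stratum: tuple[str, str] | None = None,
    alpha_dosage: float = 0.05,
    alpha_turnover: float = 0.05,
) -> MechanismVerdict:
    """Classify a stratum's X-dosage elevation as XCU or transcript stability.

    Rule: (1) test ChrX-S:A elevation in ``stratum`` vs
    ``reference_stratum`` (default: same-sex zygotene) with a one-sided
    greater rank-sum at ``alpha_dosage``; (2) test a ChrX-S unspliced
    fraction deficit vs autosomes within ``stratum`` with a one-sided less
    paired signed-rank at ``alpha_turnover``. Elevated and deficient ->
    TURNOVER; elevated only -> XCU; not elevated -> NONE; elevated but
    deficit test under-powered (too few paired cells) -> AMBIGUOUS.
    """
    stratum = tuple(stratum)
    if reference_stratum is None:
        reference_stratum = (stratum[0], "zygotene")
    reference_stratum = tuple(reference_stratum)

    col = f"ratio_{CHRX_S}"
    a = dosage_table.loc[
        dosage_table.index[_stratum_mask_dosage(dosage_table, stratum)], col
    ].dropna().to_numpy()
    b = dosage_table.loc[
        dosage_table.index[_stratum_mask_dosage(dosage_table, reference_stratum)], col
    ].dropna().to_numpy()
    _, dosage_p = rank_sum_test(a, b, alternative="greater")
    elevated = dosage_p < alpha_dosage

    if not elevated:
        return MechanismVerdict(stratum, reference_stratum, "NONE", dosage_p, None,
                                alpha_dosage, alpha_turnover)

    cols = [f"frac_{CHRX_S}", f"frac_{AUTOSOME}"]
    sub = turnover_table.loc[_stratum_mask(turnover_table, stratum), cols].dropna()
    if len(sub) < _MIN_PAIRED_CELLS:
        return MechanismVerdict(stratum, reference_stratum, "AMBIGUOUS", dosage_p, None,
                                alpha_dosage, alpha_turnover)
    _, turnover_p = signed_rank_test(
        sub[cols[0]].to_numpy(), sub[cols[1]].to_numpy(), alternative="less"
    )
    verdict = "TURNOVER" if turnover_p < alpha_turnover else "XCU"
    return MechanismVerdict(stratum, reference_stratum, verdict, dosage_p, turnover_p,
                            alpha_dosage, alpha_turnover)


def _stratum_mask_dosage(table: pd.DataFrame, stratum: tuple[str, str]) -> np.ndarray:
    sex, stage = stratum
    mask = (table["sex"] == sex) & (table["stage"] == stage)
    if "valid" in table.columns:
        mask &= table["valid"]
    if not mask.any():
        raise ValueError(f"unknown or empty stratum {stratum!r}")
    return mask.to_numpy()
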