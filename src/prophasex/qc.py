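"""Per-cell quality control.

Cells are filtered on total transcripts (TPM units, as deposited) and the
number of detected genes (TPM > 0). Two named presets mirror the
Smart-Seq2 studies this pipeline targets: ``female_fetal`` keeps cells
with 100,000-1,500,000 transcripts (inclusive) and more than 2000
expressed genes; ``male_adult`` keeps cells with strictly more than
10,000 transcripts and more than 2000 expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._stats import welch_t_test

__all__ = ["QCThresholds", "PRESETS", "qc_stats", "filter_cells", "welch_t"]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds.

    ``min_total``/``max_total`` bound the per-cell transcript total
    (inclusive by default; ``min_total_strict`` switches the lower bound
    to a strict "above"); ``min_genes`` is always strict ("above").
    """

    min_total: float | None = None
    max_total: float | None = None
    min_genes: float = 0
    min_total_strict: bool = False

    def __post_init__(self) -> None:
        if self.min_total is not None and self.max_total is not None and self.min_total > self.max_total:
            raise ValueError("min_total must be <= max_total")

    def retain(self, total: float, genes: float) -> bool:
        if self.min_total is not None:
            if self.min_total_strict:
                if not total > self.min_total:
                    return False
            elif not total >= self.min_total:
                return False
        if self.max_total is not None and not total <= self.max_total:
            return False
        return genes > self.min_genes


PRESETS: dict[str, QCThresholds] = {
    "female_fetal": QCThresholds(min_total=100_000, max_total=1_500_000, min_genes=2000),
    "male_adult": QCThresholds(min_total=10_000, min_genes=2000, min_total_strict=True),
}


def qc_stats(bundle) -> pd.DataFrame:
    """Per-cell total transcripts (column sum of TPM) and genes detected (> 0)."""
    if bundle.n_cells == 0 or bundle.n_genes == 0:
        raise ValueError("qc_stats requires a non-empty bundle")
    return pd.DataFrame(
        {
            "total_transcripts": bundle.tpm.sum(axis=0),
            "genes_detected": (bundle.tpm > 0).sum(axis=0),
        }
    ).rename_axis("cell_id")


def filter_cells(stats: pd.DataFrame, thresholds: QCThresholds | str) -> list[str]:
    """Cell ids retained under the thresholds (or a named preset)."""
    if isinstance(thresholds, str):
        thresholds = PRESETS[thresholds]
    mask = [
        thresholds.retain(row.total_transcripts, row.genes_detected)
        for row in stats.itertuples()
    ]
    return list(stats.index[mask])


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided), e.g. germ-cell vs somatic
    genes-detected comparison. Returns (t, p)."""
    return welch_t_test(group_a, group_b)
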