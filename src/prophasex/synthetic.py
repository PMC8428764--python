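"""Synthetic staged germ-cell transcriptomes from steady-state RNA kinetics.

Each gene is a transcription -> splicing -> degradation chain with rates
(alpha, beta, gamma). At steady state the expected unspliced and spliced
abundances are alpha/beta and alpha/gamma, so the unspliced fraction of
total RNA is gamma/(beta + gamma) — independent of alpha. That
independence is the identifiability lever the whole package exploits: a
transcription boost (XCU) raises X dosage but leaves the unspliced
fraction untouched, whereas increased transcript stability (lower gamma)
raises dosage *and* depresses the unspliced fraction.

The generator emits staged, sexed cells (pre-meiotic through diplotene,
female and male) with TPM plus matched spliced/unspliced counts, under
four scenarios:

* ``NULL`` — X and autosomal genes share the same rate distributions.
* ``MSCI`` — transcriptional silencing of X-linked genes in male pachytene
  (and, by default, diplotene).
* ``XCU`` — transcription boost on X-linked genes in female pachytene.
* ``TURNOVER`` — degradation slow-down on X-linked genes in female
  pachytene.

Chromosome classes are exchangeable by construction: per-gene alpha is
drawn by stratified quantile sampling *within* each class from one shared
log-normal, and baseline beta/gamma are global constants, so under NULL
every class mean matches the autosome mean in expectation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import (
    AUTOSOME,
    CHR7,
    CHRX_E,
    CHRX_S,
    ExpressionBundle,
    classify_genes,
)
from .staging import STAGES, MarkerPanel

__all__ = [
    "SCENARIOS",
    "KineticParams",
    "ScenarioConfig",
    "SyntheticTruth",
    "steady_state",
    "simulate",
    "truth_report",
]

SCENARIOS = ("NULL", "MSCI", "XCU", "TURNOVER")
SEXES = ("F", "M")

_ESCAPE_CYCLE = ("PAR", "E", "mostly E", "mostly VE", "VE")


@dataclass
class KineticParams:
    """Per-gene transcription (alpha), splicing (beta) and degradation
    (gamma) rates; all strictly positive and finite."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        for name, arr in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} rates must be strictly positive and finite")

    def copy(self) -> "KineticParams":
        return KineticParams(self.alpha.copy(), self.beta.copy(), self.gamma.copy())


def steady_state(params: KineticParams) -> tuple[np.ndarray, np.ndarray]:
    """Expected unspliced and spliced abundances at steady state.

    ``u = alpha/beta``, ``s = alpha/gamma``; the unspliced fraction
    ``u/(u+s)`` equals ``gamma/(beta+gamma)`` for any alpha.
    """
    return params.alpha / params.beta, params.alpha / params.gamma


def _default_genes_per_chrom() -> dict[str, int]:
    # 500 genes: three plain autosomes, the Chr7 control, X and Y
    return {"1": 100, "2": 100, "3": 80, "7": 60, "X": 140, "Y": 20}


@dataclass
class ScenarioConfig:
    """Stated world of one simulation.

    Scenario effects touch only X-linked genes in the stated sex/stage:
    ``msci_factor`` multiplies alpha in male pachytene (and diplotene when
    ``msci_include_diplotene``), ``xcu_factor`` multiplies alpha in female
    pachytene, ``stability_factor`` divides gamma in female pachytene.
    """

    scenario: str = "NULL"
    msci_factor: float = 0.1
    xcu_factor: float = 1.5
    stability_factor: float = 2.0
    cells_per_stage: int = 50
    n_genes_per_chrom: dict[str, int] = field(default_factory=_default_genes_per_chrom)
    marker_genes_per_stage: int = 8
    dropout_rate: float = 0.1
    libsize_cv: float = 0.3
    seed: int = 0
    # observation / kinetics details of the stated world
    nb_size: float = 2.0           # negative-binomial dispersion (Smart-Seq2-like)
    alpha_log_mean: float = math.log(10.0)
    alpha_log_sd: float = 0.8
    beta: float = 2.0              # baseline splicing rate, shared across genes
    gamma: float = 1.0             # baseline degradation rate, shared across genes
    marker_on_boost: float = 4.5   # alpha multiplier for a marker in its own stage
    escape_frac: float = 0.25      # fraction of X genes in the escape class
    msci_include_diplotene: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        for name in ("msci_factor", "xcu_factor", "stability_factor", "nb_size",
                     "beta", "gamma", "marker_on_boost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")
        if self.cells_per_stage < 1:
            raise ValueError("cells_per_stage must be >= 1")
        if self.marker_genes_per_stage < 1:
            raise ValueError("marker_genes_per_stage must be >= 1")
        # balanced on/off marker multipliers require k_on below the stage count
        if self.marker_on_boost >= len(STAGES):
            raise ValueError("marker_on_boost must be below the number of stages (balance constraint)")


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated bundle.

    ``stage_params`` maps (sex, stage) to the effective per-gene kinetics
    (scenario and marker programs applied), so every cell's generating
    parameters are recoverable via its true stage label.
    """

    scenario: str
    config: ScenarioConfig
    base_params: KineticParams
    stage_params: dict[tuple[str, str], KineticParams]
    true_stage: pd.Series
    marker_panels: list[MarkerPanel]

    def to_json(self) -> str:
        cfg = asdict(self.config)
        return json.dumps(
            {
                "scenario": self.scenario,
                "config": cfg,
                "true_stage": self.true_stage.to_dict(),
                "marker_panels": {p.stage: list(p.positive_markers) for p in self.marker_panels},
            },
            indent=2,
        )


def _stratified_lognormal(n: int, log_mean: float, log_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stratified quantile sample from a log-normal, shuffled.

    One draw per equal-probability stratum keeps the class-level empirical
    rate distribution pinned to the population distribution, which is what
    makes chromosome classes exchangeable under NULL.
    """
    q = (np.arange(n) + rng.uniform(size=n)) / n
    vals = np.exp(log_mean + log_sd * stats.norm.ppf(q))
    rng.shuffle(vals)
    return vals


def _build_gene_table(config: ScenarioConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for chrom, count in config.n_genes_per_chrom.items():
        for _ in range(count):
            rows.append((f"g{i:04d}", str(chrom)))
            i += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome"])
    genes["biotype"] = "protein_coding"
    x_ids = genes.loc[genes["chromosome"] == "X", "gene_id"].tolist()
    n_escape = int(round(config.escape_frac * len(x_ids)))
    escape_rows = [
        {"gene_id": gid, "category": _ESCAPE_CYCLE[j % len(_ESCAPE_CYCLE)]}
        for j, gid in enumerate(x_ids[:n_escape])
    ]
    escape = pd.DataFrame(escape_rows, columns=["gene_id", "category"])
    return classify_genes(genes, escape if len(escape) else None)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate(config: ScenarioConfig) -> tuple[ExpressionBundle, SyntheticTruth]:
    """Simulate a staged, sexed bundle under the configured scenario.

    Per cell, spliced and unspliced counts are negative-binomial draws
    around the steady-state means of that cell's (sex, stage) kinetics,
    scaled by a log-normal library factor; Bernoulli dropout hits a gene's
    spliced and unspliced counts together; TPM is the library-normalized
    total (u + s) rescaled to 1e6 per cell. Random streams are split per
    (purpose, sex, stage, cell) from the master seed, so adding cells
    never perturbs existing draws. Identical configs reproduce
    bit-identical output.
    """
    genes = _build_gene_table(config)
    n_genes = len(genes)
    classes = genes["chrom_class"]
    for cls in (AUTOSOME, CHR7, CHRX_E, CHRX_S):
        if (classes == cls).sum() == 0:
            raise ValueError(f"no genes on required chromosome class {cls}")

    # --- baseline kinetics: stratified alpha per class, constant beta/gamma
    alpha = np.empty(n_genes)
    class_masks = {}
    for ci, cls in enumerate(pd.unique(classes)):
        mask = (classes == cls).to_numpy()
        class_masks[cls] = mask
        alpha[mask] = _stratified_lognormal(
            int(mask.sum()), config.alpha_log_mean, config.alpha_log_sd, _rng(config.seed, 0, ci)
        )
    beta = np.full(n_genes, config.beta)
    gamma = np.full(n_genes, config.gamma)

    # --- marker program: autosomal (non-chr7) genes at the population mean
    # rate, boosted k_on in their own stage and damped k_off elsewhere with
    # k_on + (S-1) k_off = S, so each stage sees the same total marker output
    n_stages = len(STAGES)
    total_markers = n_stages * config.marker_genes_per_stage
    auto_idx = np.flatnonzero((classes == AUTOSOME).to_numpy())
    if total_markers > auto_idx.size:
        raise ValueError("not enough plain-autosome genes to host the marker panels")
    marker_idx = _rng(config.seed, 1).choice(auto_idx, size=total_markers, replace=False)
    alpha_star = math.exp(config.alpha_log_mean + config.alpha_log_sd**2 / 2.0)
    alpha[marker_idx] = alpha_star
    # pin each class's mean rate to the population mean: this completes the
    # exchangeability construction (class:autosome rate ratios are 1 by
    # construction; the lognormal tail otherwise dominates small classes)
    for mask in class_masks.values():
        alpha[mask] *= alpha_star / alpha[mask].mean()
    k_on = config.marker_on_boost
    k_off = (n_stages - k_on) / (n_stages - 1)
    stage_markers = {
        stage: marker_idx[i * config.marker_genes_per_stage:(i + 1) * config.marker_genes_per_stage]
        for i, stage in enumerate(STAGES)
    }
    panels = [
        MarkerPanel(stage=stage, positive_markers=tuple(genes.index[idx] for idx in stage_markers[stage]))
        for stage in STAGES
    ]

    base = KineticParams(alpha, beta, gamma)
    x_mask = (genes["chromosome"] == "X").to_numpy()

    # --- effective kinetics per (sex, stage)
    stage_params: dict[tuple[str, str], KineticParams] = {}
    for sex in SEXES:
        for stage in STAGES:
            p = base.copy()
            for other, idx in stage_markers.items():
                p.alpha[idx] *= k_on if other == stage else k_off
            if config.scenario == "MSCI" and sex == "M":
                targeted = stage == "pachytene" or (
                    config.msci_include_diplotene and stage == "diplotene"
                )
                if targeted:
                    p.alpha[x_mask] *= config.msci_factor
            elif config.scenario == "XCU" and sex == "F" and stage == "pachytene":
                p.alpha[x_mask] *= config.xcu_factor
            elif config.scenario == "TURNOVER" and sex == "F" and stage == "pachytene":
                p.gamma[x_mask] /= config.stability_factor
            stage_params[(sex, stage)] = p

    # --- observation model, one stream per cell
    size = config.nb_size
    sigma = math.sqrt(math.log(1.0 + config.libsize_cv**2)) if config.libsize_cv > 0 else 0.0
    cell_ids, sexes_col, stages_col = [], [], []
    u_cols, s_cols = [], []
    for si, sex in enumerate(SEXES):
        for ti, stage in enumerate(STAGES):
            u_mean, s_mean = steady_state(stage_params[(sex, stage)])
            for ci in range(config.cells_per_stage):
                rng = _rng(config.seed, 2, si, ti, ci)
                lib = math.exp(rng.normal(-sigma**2 / 2.0, sigma)) if sigma > 0 else 1.0
                mu_u = u_mean * lib
                mu_s = s_mean * lib
                u = rng.negative_binomial(size, size / (size + mu_u))
                s = rng.negative_binomial(size, size / (size + mu_s))
                if config.dropout_rate > 0:
                    drop = rng.uniform(size=n_genes) < config.dropout_rate
                    u = np.where(drop, 0, u)
                    s = np.where(drop, 0, s)
                u_cols.append(u)
                s_cols.append(s)
                cell_ids.append(f"{sex}_{stage}_{ci:03d}")
                sexes_col.append(sex)
                stages_col.append(stage)

    u_mat = np.column_stack(u_cols).astype(float)
    s_mat = np.column_stack(s_cols).astype(float)
    total = u_mat + s_mat
    col_sums = total.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    tpm = total / col_sums * 1e6

    cells = pd.DataFrame(
        {"sex": sexes_col, "stage": stages_col},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    gene_index = genes.index
    bundle = ExpressionBundle(
        tpm=pd.DataFrame(tpm, index=gene_index, columns=cells.index),
        cells=cells,
        genes=genes,
        spliced=pd.DataFrame(s_mat, index=gene_index, columns=cells.index),
        unspliced=pd.DataFrame(u_mat, index=gene_index, columns=cells.index),
    )
    truth = SyntheticTruth(
        scenario=config.scenario,
        config=config,
        base_params=base,
        stage_params=stage_params,
        true_stage=cells["stage"].copy(),
        marker_panels=panels,
    )
    return bundle, truth


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Scenario effect multipliers per (sex, stage, chromosome class).

    Marker programs are gene-level and excluded; the report shows the
    class-level alpha multiplier and gamma divisor the scenario applied
    (all 1.0 under NULL).
    """
    cfg = truth.config
    rows = []
    for sex in SEXES:
        for stage in STAGES:
            for cls in (AUTOSOME, CHR7, CHRX_E, CHRX_S):
                a_mult, g_div = 1.0, 1.0
                if cls in (CHRX_E, CHRX_S):
                    if cfg.scenario == "MSCI" and sex == "M" and (
                        stage == "pachytene" or (cfg.msci_include_diplotene and stage == "diplotene")
                    ):
                        a_mult = cfg.msci_factor
                    elif cfg.scenario == "XCU" and sex == "F" and stage == "pachytene":
                        a_mult = cfg.xcu_factor
                    elif cfg.scenario == "TURNOVER" and sex == "F" and stage == "pachytene":
                        g_div = cfg.stability_factor
                rows.append((sex, stage, cls, a_mult, g_div))
    return pd.DataFrame(
        rows, columns=["sex", "stage", "chrom_class", "alpha_multiplier", "gamma_divisor"]
    )
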