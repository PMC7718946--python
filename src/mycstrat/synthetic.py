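"""Synthetic cohorts, screens and dose-response series with planted structure.

The generators emulate the statistical shape of the study data this pipeline
analyses: a tumor cohort in which ~10% of samples coordinately over-express
the genes of three overlapping MYC-target signatures, a cell-line screen in
which a known subset of drugs acts preferentially on MYC-high lines, 4PL
dose-response curves, exponential survival with a group hazard ratio, and a
binary (squamous-like) subtype enriched in the MYC-high group.

Everything is a pure function of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import DrugResponseTable, ExpressionMatrix, GeneSet

__all__ = [
    "CohortSimConfig",
    "SyntheticCohort",
    "ScreenSimConfig",
    "simulate_cohort",
    "simulate_screen",
    "simulate_dose_response",
    "four_pl",
]

#: names for the three planted MYC-target signatures, mirroring the panel a
#: MYC stratification analysis would use (two hallmark collections plus a
#: direct-target list).
SIGNATURE_NAMES = ("MYC_TARGETS_V1", "MYC_TARGETS_V2", "MYC_TARGETS_DIRECT")


@dataclass
class CohortSimConfig:
    """Study conditions for a simulated tumor cohort.

    effect_size is the shift (in noise-SD units) added to signature genes in
    MYC-high samples; hazard_ratio is the death hazard of high vs low samples;
    subtype_enrichment is the probability that a MYC-high sample carries the
    squamous-like subtype (baseline_subtype_rate applies to the rest).
    censor_horizon=None chooses the administrative censoring time so that
    ~30% of low-group samples are censored.
    """

    n_genes: int = 1000
    n_samples: int = 80
    frac_myc_high: float = 0.10
    effect_size: float = 1.5
    noise_sd: float = 1.0
    signature_sizes: Sequence[int] = (50, 50, 50)
    signature_overlap: float = 0.2
    hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 600.0  # per day; median survival ~416 d in the low group
    censor_horizon: float | None = None
    subtype_enrichment: float = 0.8
    baseline_subtype_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_myc_high < 1:
            raise ValueError("frac_myc_high must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if sum(self.signature_sizes) > self.n_genes:
            raise ValueError("signature sizes exceed n_genes")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    truth_high: dict[str, bool]
    signatures: list[GeneSet]
    survival_time: dict[str, float]
    survival_event: dict[str, bool]
    subtype: dict[str, str]  # "squamous" | "nonsquamous"

    @property
    def truth_high_set(self) -> set[str]:
        return {s for s, hi in self.truth_high.items() if hi}


@dataclass
class ScreenSimConfig:
    """Study conditions for a single-dose drug screen.

    The screen works in response space (response = 100 - viability): non-hit
    drugs elicit the same mean response in both groups; for hit drugs the
    MYC-high mean response is hit_ratio x the low-group response. Replicate
    noise is multiplicative with coefficient of variation replicate_cv.
    """

    n_drugs: int = 129
    n_hits: int = 10
    hit_ratio: float = 2.5
    baseline_response: float = 30.0
    replicate_cv: float = 0.10
    n_replicates: int = 3
    dose: float = 600.0  # nM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hits > self.n_drugs:
            raise ValueError("n_hits must be <= n_drugs")
        if self.hit_ratio <= 0:
            raise ValueError("hit_ratio must be > 0")
        if self.baseline_response * self.hit_ratio > 100:
            raise ValueError(
                "hit_ratio x baseline_response exceeds 100% response; lower baseline_response"
            )


def _sample_signatures(rng: np.random.Generator, config: CohortSimConfig, gene_ids: list[str]) -> list[GeneSet]:
    """Three overlapping signatures: a core shared by all three is drawn first."""
    sizes = list(config.signature_sizes)
    n_shared = int(round(config.signature_overlap * min(sizes)))
    pool = list(rng.permutation(gene_ids))
    shared = pool[:n_shared]
    cursor = n_shared
    sets = []
    for name, size in zip(SIGNATURE_NAMES, sizes):
        own = pool[cursor:cursor + (size - n_shared)]
        cursor += size - n_shared
        sets.append(GeneSet(name, set(shared) | set(own), "planted MYC target signature"))
    return sets


def simulate_cohort(config: CohortSimConfig) -> SyntheticCohort:
    """Simulate a tumor cohort with a planted MYC-high subgroup.

    Background expression is Normal(0, noise_sd) per gene and sample (log2
    scale, centered); the union of signature genes is shifted up by
    effect_size x noise_sd in the exactly round(frac_myc_high x n_samples)
    MYC-high samples. Survival is exponential with administrative censoring;
    the subtype label is drawn with the enriched rate in high samples.
    """
    rng = np.random.default_rng(config.seed)
    n_high = int(round(config.frac_myc_high * config.n_samples))
    if n_high < 1:
        raise ValueError("configuration yields zero MYC-high samples")

    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    signatures = _sample_signatures(rng, config, gene_ids)
    sig_union = set().union(*(s.genes for s in signatures))

    high_idx = np.sort(rng.choice(config.n_samples, size=n_high, replace=False))
    is_high = np.zeros(config.n_samples, dtype=bool)
    is_high[high_idx] = True

    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    sig_rows = np.array([g in sig_union for g in gene_ids])
    values[np.ix_(sig_rows, is_high)] += config.effect_size * config.noise_sd

    # survival: exponential, rate scaled by the hazard ratio in the high group
    rate = np.where(is_high, config.baseline_hazard * config.hazard_ratio, config.baseline_hazard)
    t_event = rng.exponential(1.0 / rate)
    horizon = config.censor_horizon
    if horizon is None:
        # P(T > h) = 0.3 for the low group => ~30% administratively censored
        horizon = -np.log(0.3) / config.baseline_hazard
    time = np.minimum(t_event, horizon)
    event = t_event <= horizon

    p_sq = np.where(is_high, config.subtype_enrichment, config.baseline_subtype_rate)
    squamous = rng.random(config.n_samples) < p_sq

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    return SyntheticCohort(
        expression=expr,
        truth_high=dict(zip(sample_ids, map(bool, is_high))),
        signatures=signatures,
        survival_time=dict(zip(sample_ids, map(float, time))),
        survival_event=dict(zip(sample_ids, map(bool, event))),
        subtype={s: ("squamous" if q else "nonsquamous") for s, q in zip(sample_ids, squamous)},
    )


def simulate_screen(
    config: ScreenSimConfig, truth_high: dict[str, bool]
) -> tuple[DrugResponseTable, set[str]]:
    """Simulate the single-dose screen; returns the table and the planted hit set.

    ``truth_high`` maps cell-line ID -> MYC-high truth. The first n_hits drug
    IDs (after a seeded shuffle) are planted hits.
    """
    lines = list(truth_high)
    is_high = np.array([truth_high[ln] for ln in lines])
    if not (is_high.any() and (~is_high).any()):
        raise ValueError("need at least one MYC-high and one MYC-low cell line")
    rng = np.random.default_rng(config.seed)
    drug_ids = [f"drug{i + 1:03d}" for i in range(config.n_drugs)]
    hit_ids = set(rng.choice(drug_ids, size=config.n_hits, replace=False).tolist())

    response = np.full((config.n_drugs, len(lines)), config.baseline_response)
    for d, drug in enumerate(drug_ids):
        if drug in hit_ids:
            response[d, is_high] = config.baseline_response * config.hit_ratio
    viability = 100.0 - response
    cube = np.repeat(viability[:, :, None], config.n_replicates, axis=2)
    if config.replicate_cv > 0:
        cube = cube * (1.0 + rng.normal(0.0, config.replicate_cv, size=cube.shape))
    cube = np.clip(cube, 0.0, None)
    table = DrugResponseTable(drug_ids, lines, cube, np.full(config.n_drugs, config.dose))
    return table, hit_ids


def four_pl(dose: np.ndarray, bottom: float, top: float, gi50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic viability curve, decreasing with dose for hill > 0.

    v(d) = bottom + (top - bottom) / (1 + (d / gi50)^hill); v(gi50) is the
    midpoint (bottom+top)/2 and v -> top as d -> 0.
    """
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / gi50) ** hill)


def simulate_dose_response(
    params_4pl: tuple[float, float, float, float],
    doses: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Viability at each dose from a 4PL curve with multiplicative noise.

    ``params_4pl`` is (bottom, top, gi50, hill); doses must be positive and at
    least 4 points are required so the series is fittable downstream.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if doses.size < 4:
        raise ValueError("need >= 4 dose points")
    v = four_pl(doses, *params_4pl)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=v.shape))
    return np.clip(v, 0.0, None)
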