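"""Survival and association statistics for characterizing the MYC-high group.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines; the two-sided Fisher exact test is computed by direct
hypergeometric enumeration (probability-mass definition: sum the
probabilities of all same-margin tables no more probable than the observed
one, with a 1e-12 relative tie tolerance), and relative qPCR quantification
follows the delta-delta-Ct rule against a housekeeping gene and a reference
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import hypergeom

__all__ = [
    "SurvivalRecord",
    "ContingencyTable2x2",
    "CtTable",
    "KaplanMeierCurve",
    "km_estimate",
    "logrank_test",
    "fisher_exact",
    "delta_delta_ct",
]


@dataclass
class SurvivalRecord:
    sample_id: str
    time: float
    event: bool  # True = death observed, False = censored
    group: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]], e.g. rows = MYC-high/other, cols = squamous/non."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")


@dataclass
class CtTable:
    """qPCR Ct values: ct[sample][gene]; one housekeeping gene, one reference sample."""

    ct: dict[str, dict[str, float]]
    target_genes: list[str]
    housekeeping_gene: str
    reference_sample: str


@dataclass
class KaplanMeierCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def km_estimate(records: list[SurvivalRecord]) -> KaplanMeierCurve:
    """Product-limit survival estimate over the event times of ``records``.

    Censored observations tied with an event time count as at risk at that
    time (event-before-censor convention); S(0) = 1 and the curve is
    non-increasing.
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    event_times = tab.index.values[tab["observed"].values > 0]
    surv = kmf.survival_function_at_times(event_times).values
    at_risk = tab.loc[event_times, "at_risk"].values
    return KaplanMeierCurve(np.asarray(event_times, dtype=float), np.asarray(surv, dtype=float), at_risk.astype(int))


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test (1 df). Returns (chi_square, p_value)."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {groups}")
    if not any(r.event for r in records):
        raise ValueError("log-rank undefined with zero observed events")
    g0 = [r for r in records if r.group == groups[0]]
    g1 = [r for r in records if r.group == groups[1]]
    res = _ll_logrank(
        [r.time for r in g0],
        [r.time for r in g1],
        event_observed_A=[r.event for r in g0],
        event_observed_B=[r.event for r in g1],
    )
    return float(res.test_statistic), float(res.p_value)


def fisher_exact(table: ContingencyTable2x2, rel_tol: float = 1e-12) -> float:
    """Two-sided Fisher exact p by the probability-mass definition.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the observed
    table (ties admitted within ``rel_tol`` relative tolerance). A zero
    margin gives p = 1 by convention (with a warning).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, n - r1, c1, n - c1) == 0:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return 1.0
    k = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = hypergeom.pmf(k, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, probs[probs <= p_obs * (1.0 + rel_tol)].sum()))


def delta_delta_ct(ct: CtTable) -> dict[str, dict[str, float]]:
    """Fold changes per sample and target by the delta-delta-Ct rule.

    fold = 2^-[(Ct_target,s - Ct_hk,s) - (Ct_target,ref - Ct_hk,ref)]; the
    reference sample's fold is exactly 1. Missing housekeeping Ct for any
    sample is an error.
    """
    hk = ct.housekeeping_gene
    for sample, row in ct.ct.items():
        if hk not in row or not np.isfinite(row[hk]):
            raise ValueError(f"missing housekeeping Ct for sample {sample!r}")
    ref = ct.ct[ct.reference_sample]
    folds: dict[str, dict[str, float]] = {}
    for sample, row in ct.ct.items():
        folds[sample] = {}
        for gene in ct.target_genes:
            ddct = (row[gene] - row[hk]) - (ref[gene] - ref[hk])
            folds[sample][gene] = float(2.0 ** (-ddct))
    return folds
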