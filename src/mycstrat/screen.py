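"""Drug-screen statistics: hit calling, 4PL dose-response fits, AUC, quartiles.

The single-dose hit statistic works in response space: response = 100 -
viability (% of control), clamped at 0. A drug is a hit when the mean
response of the MYC-high lines exceeds twice the mean response of the MYC-low
lines (ratio > 2). Note the direction: had the ratio been formed on viability
instead of response, more sensitive high lines would *lower* the ratio and
the >2 rule would invert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .dataio import DrugResponseTable, PhenotypeLabels
from .synthetic import four_pl

__all__ = [
    "ScreenResult",
    "DoseResponseFit",
    "SensitivityPhenotype",
    "HIT_RATIO_THRESHOLD",
    "score_single_dose_screen",
    "fit_4pl",
    "dose_response_auc",
    "quartile_stratify",
    "correlate_sensitivities",
]

#: a drug is a hit when mean response (high) / mean response (low) exceeds this
HIT_RATIO_THRESHOLD = 2.0


@dataclass
class ScreenResult:
    drug_id: str
    mean_response_high: float
    mean_response_low: float
    ratio: float
    rank: int
    is_hit: bool
    unstable: bool = False  # near-zero low-group response, ratio epsilon-guarded


@dataclass
class DoseResponseFit:
    drug_id: str
    cell_line_id: str
    bottom: float
    top: float
    gi50: float  # relative GI50: curve inflection (nM)
    hill: float
    rss: float
    converged: bool
    gi50_absolute: float  # dose where fitted viability = 50% of control
    gi50_censored: bool  # absolute GI50 censored at max tested dose
    auc: float


@dataclass
class SensitivityPhenotype:
    metric_name: str
    values: dict[str, float]
    lower_is_sensitive: bool
    quartile_boundary: float
    sensitive_set: set[str]

    def to_labels(self) -> PhenotypeLabels:
        """Binary phenotype (sensitive vs rest) for enrichment analysis."""
        lines = list(self.values)
        labels = ["sensitive" if ln in self.sensitive_set else "rest" for ln in lines]
        return PhenotypeLabels(lines, labels, ("sensitive", "rest"))


def score_single_dose_screen(
    table: DrugResponseTable,
    groups: PhenotypeLabels,
    epsilon: float = 1.0,
) -> list[ScreenResult]:
    """Rank drugs by the MYC-high / MYC-low mean-response ratio; hits have ratio > 2.

    Replicates are averaged first (missing wells excluded); responses are
    clamped at 0. When the low-group mean response falls below ``epsilon``
    percentage points, the ratio is computed against ``epsilon`` and flagged
    unstable. Drugs with no usable response in either group are skipped with
    a warning. Results are sorted by descending ratio, ties by drug ID.
    """
    aligned = groups.aligned_to(list(table.cell_line_ids))
    high = aligned.mask()
    means, _ = table.mean_viability()
    response = np.clip(100.0 - means, 0.0, None)
    results = []
    for d, drug in enumerate(table.drug_ids):
        r_high = response[d, high]
        r_low = response[d, ~high]
        r_high, r_low = r_high[~np.isnan(r_high)], r_low[~np.isnan(r_low)]
        if r_high.size == 0 or r_low.size == 0:
            warnings.warn(f"drug {drug!r} skipped: all responses missing in a group", stacklevel=2)
            continue
        m_high, m_low = float(r_high.mean()), float(r_low.mean())
        unstable = m_low < epsilon
        ratio = m_high / (epsilon if unstable else m_low)
        results.append(
            ScreenResult(drug, m_high, m_low, ratio, 0, ratio > HIT_RATIO_THRESHOLD, unstable)
        )
    results.sort(key=lambda r: (-r.ratio, r.drug_id))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def fit_4pl(
    doses: np.ndarray,
    viabilities: np.ndarray,
    drug_id: str = "",
    cell_line_id: str = "",
) -> DoseResponseFit:
    """Least-squares 4PL fit v(d) = bottom + (top - bottom)/(1 + (d/gi50)^hill).

    Requires >= 4 distinct positive doses. The fit runs on log10 dose with
    bounds bottom >= 0 and hill in [0.1, 10], restarting from three Hill-slope
    seeds to escape local minima. Reported are the relative GI50 (inflection)
    and the absolute GI50 (dose where the fitted curve crosses 50% of
    control), the latter censored at the maximum tested dose when the curve
    never crosses.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    keep = np.isfinite(doses) & np.isfinite(viab)
    doses, viab = doses[keep], viab[keep]
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct doses to fit a 4PL")
    order = np.argsort(doses)
    doses, viab = doses[order], viab[order]
    log_d = np.log10(doses)

    v_top, v_bot = float(viab.max()), float(viab.min())
    half = (v_top + v_bot) / 2.0
    gi50_init = doses[int(np.argmin(np.abs(viab - half)))]

    def model(theta: np.ndarray) -> np.ndarray:
        bottom, top, log_gi50, hill = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_d - log_gi50)))

    lo = np.array([0.0, 0.0, log_d.min() - 3.0, 0.1])
    hi = np.array([np.inf, np.inf, log_d.max() + 3.0, 10.0])
    best = None
    for hill0 in (0.5, 1.0, 3.0):
        theta0 = np.clip(
            np.array([max(v_bot, 0.0), v_top, np.log10(gi50_init), hill0]), lo, hi
        )
        try:
            res = optimize.least_squares(
                lambda t: model(t) - viab, theta0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-8:
            best = res
    if best is None:
        raise RuntimeError("4PL optimizer failed from every start")
    bottom, top, log_gi50, hill = best.x
    if bottom > top:  # enforce the bottom <= top orientation of the reported fit
        bottom, top = top, bottom
    gi50 = float(10.0**log_gi50)
    rss = float(2.0 * best.cost)
    converged = bool(best.success)

    # absolute GI50: fitted viability = 50% of control
    if bottom < 50.0 < top:
        gi50_abs = float(gi50 * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill))
        censored = gi50_abs > doses.max()
        if censored:
            gi50_abs = float(doses.max())
    else:
        gi50_abs, censored = float(doses.max()), True

    return DoseResponseFit(
        drug_id=drug_id,
        cell_line_id=cell_line_id,
        bottom=float(bottom),
        top=float(top),
        gi50=gi50,
        hill=float(hill),
        rss=rss,
        converged=converged,
        gi50_absolute=gi50_abs,
        gi50_censored=bool(censored),
        auc=dose_response_auc(doses, viab),
    )


def dose_response_auc(doses: np.ndarray, viabilities: np.ndarray) -> float:
    """Normalized area under the viability curve over log10 dose, in [0, 1].

    Trapezoidal integral of viability/100 (clipped to [0, 100]) against log10
    dose, divided by the log10 dose span; 1 = fully resistant, 0 = fully
    sensitive. Duplicate doses are averaged before integration.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.clip(np.asarray(viabilities, dtype=float), 0.0, 100.0)
    if doses.size < 2:
        raise ValueError("need >= 2 doses for an AUC")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    uniq, inv = np.unique(doses, return_inverse=True)
    if uniq.size < doses.size:
        viab = np.array([viab[inv == i].mean() for i in range(uniq.size)])
        doses = uniq
    else:
        order = np.argsort(doses)
        doses, viab = doses[order], viab[order]
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct doses for an AUC")
    x = np.log10(doses)
    return float(np.trapezoid(viab / 100.0, x) / (x[-1] - x[0]))


def quartile_stratify(
    values: dict[str, float],
    lower_is_sensitive: bool = True,
    metric_name: str = "sensitivity",
    quantile: float = 0.25,
) -> SensitivityPhenotype:
    """Split a cell-line panel at the most-sensitive quartile of a metric.

    The boundary is the linear-interpolation (type-7) quantile; ties at the
    boundary fall into the sensitive set. With ``lower_is_sensitive`` the
    sensitive set is {metric <= 25th percentile}, otherwise
    {metric >= 75th percentile}.
    """
    if len(values) < 4:
        raise ValueError("need >= 4 lines to stratify into quartiles")
    vals = np.array(list(values.values()), dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError("all metric values identical; no stratification possible")
    if lower_is_sensitive:
        boundary = float(np.quantile(vals, quantile))
        sensitive = {ln for ln, v in values.items() if v <= boundary}
    else:
        boundary = float(np.quantile(vals, 1.0 - quantile))
        sensitive = {ln for ln, v in values.items() if v >= boundary}
    return SensitivityPhenotype(metric_name, dict(values), lower_is_sensitive, boundary, sensitive)


def correlate_sensitivities(
    gi50_a: np.ndarray,
    gi50_b: np.ndarray,
    log_scale: bool = True,
) -> tuple[float, float, float, float]:
    """Pearson correlation and least-squares line between paired GI50 vectors.

    Computed on log10 GI50 by default (dose-response potencies are
    log-normally distributed). Returns (r, two-sided p, slope, intercept).
    """
    a = np.asarray(gi50_a, dtype=float)
    b = np.asarray(gi50_b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if log_scale:
        a, b = np.log10(a), np.log10(b)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("zero variance in a GI50 vector")
    lin = stats.linregress(a, b)
    return float(lin.rvalue), float(lin.pvalue), float(lin.slope), float(lin.intercept)
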