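import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mycstrat.dataio import DrugResponseTable, PhenotypeLabels
from mycstrat.screen import (
    correlate_sensitivities,
    dose_response_auc,
    fit_4pl,
    quartile_stratify,
    score_single_dose_screen,
)
from mycstrat.synthetic import four_pl, simulate_dose_response


def _table(viab_rows, lines=("h1", "h2", "l1", "l2")):
    return DrugResponseTable(
        [f"d{i}" for i in range(len(viab_rows))], list(lines),
        np.array(viab_rows, dtype=float), np.full(len(viab_rows), 600.0),
    )


GROUPS = PhenotypeLabels(["h1", "h2", "l1", "l2"], ["high", "high", "low", "low"], ("high", "low"))


class TestHitCalling:
    def test_worked_ratio_example(self):
        """Viabilities (20,40) vs (70,70): responses (80,60) vs (30,30) -> ratio 7/3, a hit."""
        (r,) = score_single_dose_screen(_table([[20, 40, 70, 70]]), GROUPS)
        assert r.mean_response_high == pytest.approx(70.0)
        assert r.mean_response_low == pytest.approx(30.0)
        assert r.ratio == pytest.approx(70.0 / 30.0)
        assert r.is_hit

    def test_equal_responses_not_a_hit(self):
        (r,) = score_single_dose_screen(_table([[50, 50, 50, 50]]), GROUPS)
        assert r.ratio == pytest.approx(1.0) and not r.is_hit

    def test_scale_invariance_of_ratio(self):
        base = _table([[20, 40, 70, 70]])
        # halve all responses: viability = 100 - response/2
        halved = _table([[60, 70, 85, 85]])
        r1 = score_single_dose_screen(base, GROUPS)[0]
        r2 = score_single_dose_screen(halved, GROUPS)[0]
        assert r1.ratio == pytest.approx(r2.ratio) and r1.is_hit == r2.is_hit

    def test_epsilon_guard_flags_unstable(self):
        (r,) = score_single_dose_screen(_table([[60, 60, 100, 100]]), GROUPS)
        assert r.unstable and r.ratio == pytest.approx(40.0 / 1.0)

    def test_ranking_descending_with_id_ties(self):
        results = score_single_dose_screen(
            _table([[50, 50, 50, 50], [20, 20, 60, 60], [50, 50, 50, 50]]), GROUPS
        )
        assert [r.drug_id for r in results] == ["d1", "d0", "d2"]
        assert [r.rank for r in results] == [1, 2, 3]

    def test_all_missing_drug_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            results = score_single_dose_screen(
                _table([[np.nan, np.nan, 50, 50], [50, 50, 50, 50]]), GROUPS
            )
        assert [r.drug_id for r in results] == ["d1"]


class TestFourPL:
    DOSES = 10.0 ** np.linspace(-2, 2, 7) * 10.0  # 7-point dilution around gi50=10

    def test_noiseless_parameter_recovery(self):
        viab = four_pl(self.DOSES, 0.0, 100.0, 10.0, 1.0)
        fit = fit_4pl(self.DOSES, viab)
        assert fit.converged
        assert fit.gi50 == pytest.approx(10.0, rel=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-4)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.gi50_absolute == pytest.approx(10.0, rel=1e-4)

    def test_flat_resistant_curve_censors_absolute_gi50(self):
        fit = fit_4pl(self.DOSES, np.full(7, 100.0))
        assert fit.gi50_censored
        assert fit.gi50_absolute == pytest.approx(self.DOSES.max())

    def test_noisy_recovery_median_error_under_ten_percent(self):
        errors = []
        for seed in range(100):
            viab = simulate_dose_response((0.0, 100.0, 10.0, 1.0), self.DOSES,
                                          noise_cv=0.02, seed=seed)
            errors.append(abs(fit_4pl(self.DOSES, viab).gi50 - 10.0) / 10.0)
        assert np.median(errors) < 0.10

    def test_order_invariance(self):
        viab = four_pl(self.DOSES, 5.0, 95.0, 10.0, 1.5)
        perm = np.random.default_rng(0).permutation(7)
        a = fit_4pl(self.DOSES, viab)
        b = fit_4pl(self.DOSES[perm], viab[perm])
        assert a.gi50 == pytest.approx(b.gi50, rel=1e-8)

    def test_too_few_doses_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_4pl([1, 10, 100], [90, 50, 10])


class TestAuc:
    def test_extremes(self):
        doses = [1, 10, 100]
        assert dose_response_auc(doses, [100, 100, 100]) == pytest.approx(1.0)
        assert dose_response_auc(doses, [0, 0, 0]) == pytest.approx(0.0)

    def test_half_span_step_approaches_half(self):
        doses = 10.0 ** np.linspace(0, 2, 2001)
        viab = np.where(np.log10(doses) < 1.0, 100.0, 0.0)
        assert dose_response_auc(doses, viab) == pytest.approx(0.5, abs=0.01)

    def test_duplicate_doses_averaged(self):
        auc = dose_response_auc([1, 1, 10], [80, 40, 60])
        assert auc == pytest.approx(dose_response_auc([1, 10], [60, 60]))

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dose_scale_invariance(self, factor):
        doses = np.array([1.0, 3.0, 10.0, 30.0])
        viab = np.array([95.0, 70.0, 30.0, 5.0])
        assert dose_response_auc(doses * factor, viab) == pytest.approx(
            dose_response_auc(doses, viab)
        )


class TestQuartile:
    def test_quartile_of_eight(self):
        values = {f"L{i}": float(i) for i in range(1, 9)}
        pheno = quartile_stratify(values, lower_is_sensitive=True)
        assert pheno.sensitive_set == {"L1", "L2"}

    def test_boundary_ties_included(self):
        values = dict(zip("abcdefgh", [1, 1, 1, 1, 5, 6, 7, 8]))
        pheno = quartile_stratify(values)
        assert pheno.sensitive_set == {"a", "b", "c", "d"}

    def test_direction_flip(self):
        values = {f"L{i}": float(i) for i in range(1, 9)}
        pheno = quartile_stratify(values, lower_is_sensitive=False)
        assert pheno.sensitive_set == {"L7", "L8"}

    def test_partition_with_complement(self):
        values = {f"L{i}": float(i) for i in range(12)}
        pheno = quartile_stratify(values)
        labels = pheno.to_labels()
        sens = {s for s, l in zip(labels.sample_ids, labels.labels) if l == "sensitive"}
        assert sens == pheno.sensitive_set
        assert sens | {s for s, l in zip(labels.sample_ids, labels.labels) if l == "rest"} == set(values)

    def test_constant_metric_errors(self):
        with pytest.raises(ValueError, match="identical"):
            quartile_stratify({c: 1.0 for c in "abcd"})


class TestCorrelation:
    def test_perfect_lines(self):
        x = np.array([1.0, 10.0, 100.0, 1000.0])
        r, _, slope, _ = correlate_sensitivities(x, x**2)
        assert r == pytest.approx(1.0) and slope == pytest.approx(2.0)
        r_neg, *_ = correlate_sensitivities(x, 1.0 / x)
        assert r_neg == pytest.approx(-1.0)

    def test_null_rejection_rate_at_n38(self):
        """|r| > 0.32 in ~5% of independent-pair sims at n=38."""
        rng = np.random.default_rng(0)
        extreme = 0
        for _ in range(1000):
            a, b = np.exp(rng.normal(size=38)), np.exp(rng.normal(size=38))
            r, *_ = correlate_sensitivities(a, b)
            extreme += abs(r) > 0.32
        assert 0.025 < extreme / 1000 < 0.085

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_sensitivities([1, 1, 1, 1], [1, 2, 3, 4])
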