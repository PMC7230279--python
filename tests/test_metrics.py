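import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedree.errors import DataContractError, DegenerateVariableError
from pedree.metrics import (
    FitMetrics, correlation_matrix, fit_metrics, imprecision_pct,
    subgroup_report, tendency_line,
)


class TestImprecision:
    def test_zero_error(self):
        assert imprecision_pct(0.0, 1500.0) == 0.0

    def test_hand_values(self):
        assert imprecision_pct(224.16, 1417.6) == pytest.approx(15.81, abs=0.01)
        assert imprecision_pct(109.8, 1006.4) == pytest.approx(10.91, abs=0.01)

    def test_scale_invariance(self):
        a = imprecision_pct(100.0, 1400.0)
        assert imprecision_pct(100.0 * 3.7, 1400.0 * 3.7) == pytest.approx(a)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DataContractError):
            imprecision_pct(10.0, 0.0)


class TestFitMetrics:
    def test_perfect_prediction(self):
        t = np.array([1200.0, 1400.0, 1600.0])
        m = fit_metrics(t, t)
        assert m.mae == 0 and m.rmse == 0 and m.nmse == 0
        assert m.pearson_r2 == pytest.approx(1.0)
        assert m.imprecision_pct == 0.0
        assert m.real_error == 0.0

    def test_cancelling_errors_hand_case(self):
        # +100, -100, 0: MAE 66.67, signed error 0, paired t = 0
        pred = np.array([1500.0, 1400.0, 1450.0])
        true = np.array([1400.0, 1500.0, 1450.0])
        m = fit_metrics(pred, true)
        assert m.mae == pytest.approx(200.0 / 3)
        assert m.real_error == pytest.approx(0.0, abs=1e-12)
        assert m.paired_t == pytest.approx(0.0, abs=1e-12)

    def test_r2_is_square_of_r(self):
        r = np.random.default_rng(0)
        p, t = r.normal(size=50), r.normal(size=50)
        m = fit_metrics(p, t + 1500)
        assert m.pearson_r2 == pytest.approx(m.pearson_r**2, abs=1e-12)

    def test_length_and_size_contracts(self):
        with pytest.raises(DataContractError):
            fit_metrics([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DataContractError):
            fit_metrics([1.0, 2.0, 3.0], [1.0, 2.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_rmse_dominates_mae(self, seed):
        r = np.random.default_rng(seed)
        p = r.normal(1400, 300, 25)
        t = r.normal(1400, 300, 25)
        m = fit_metrics(p, t)
        assert m.rmse >= m.mae - 1e-12

    def test_agrees_with_closed_form_reference(self):
        # independent implementation of r, tau-b, paired t from definitions
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            p = rng.normal(1400, 250, n).round(int(rng.integers(0, 3)))
            t = p * rng.uniform(0.5, 1.5) + rng.normal(0, 150, n)
            t = np.abs(t) + 1.0
            m = fit_metrics(p, t)
            assert m.pearson_r == pytest.approx(_pearson(p, t), abs=1e-9)
            assert m.kendall_tau == pytest.approx(_tau_b(p, t), abs=1e-9)
            tstat = _paired_t(p, t)
            assert m.paired_t == pytest.approx(tstat, abs=1e-9)

    def test_average_of_two_runs(self):
        r = np.random.default_rng(1)
        t = r.normal(1400, 300, 30)
        m1 = fit_metrics(t + 50, t, method="run1")
        m2 = fit_metrics(t - 30, t, method="run2")
        avg = FitMetrics.average(m1, m2, method="avg")
        assert avg.mae == pytest.approx((m1.mae + m2.mae) / 2)
        assert avg.n == 60


def _pearson(x, y):
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def _tau_b(x, y):
    n = len(x)
    conc = disc = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                tx += 1
                ty += 1
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return float((conc - disc) / np.sqrt((n0 - tx) * (n0 - ty)))


def _paired_t(x, y):
    d = x - y
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(len(d))))


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self):
        r = np.random.default_rng(0)
        out = correlation_matrix(
            {"a": r.normal(size=30), "b": r.normal(size=30)}, r.normal(size=30))
        assert np.allclose(np.diag(out), 1.0)
        assert np.allclose(out, out.T)
        assert out.abs().le(1.0 + 1e-12).all().all()
        assert "measured_ree" in out.columns

    def test_anticorrelation(self):
        x = np.arange(10.0)
        out = correlation_matrix({"a": x, "b": -x})
        assert out.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_series_named_in_error(self):
        with pytest.raises(DegenerateVariableError, match="flat"):
            correlation_matrix({"flat": np.ones(10), "x": np.arange(10.0)})

    def test_length_mismatch(self):
        with pytest.raises(DataContractError):
            correlation_matrix({"a": np.ones(5) + np.arange(5), "b": np.arange(6.0)})


class TestTendencyLine:
    def test_nested_polynomial_recovered(self):
        x = np.arange(30.0)
        y = 2.0 + 0.5 * x - 0.03 * x**2
        coeffs, fitted = tendency_line(y, degree=5)
        assert np.allclose(fitted, y, atol=1e-6)
        assert np.allclose(coeffs[3:], 0.0, atol=1e-6)

    def test_constant_series(self):
        coeffs, fitted = tendency_line(np.full(20, 7.0), degree=5)
        assert np.allclose(fitted, 7.0)

    def test_residual_orthogonality(self):
        r = np.random.default_rng(0)
        y = r.normal(size=40)
        coeffs, fitted = tendency_line(y, degree=5)
        resid = y - fitted
        x = np.arange(40.0)
        for k in range(6):
            assert abs(np.dot(resid, x**k)) < 1e-6 * np.linalg.norm(x**k) * 40

    def test_too_few_points(self):
        with pytest.raises(DataContractError):
            tendency_line(np.arange(5.0), degree=5)


class TestSubgroupReport:
    def test_all_normal_flags_other_panels(self):
        r = np.random.default_rng(0)
        t = r.normal(1400, 200, 30)
        rep = subgroup_report({"m": t + 10}, t, np.array(["normal"] * 30))
        assert "obese" in rep.unavailable and "wasted" in rep.unavailable
        assert "overall" in rep.panels and "normal" in rep.panels

    def test_subgroup_sizes_sum_to_overall(self):
        r = np.random.default_rng(1)
        n = 60
        t = r.normal(1400, 200, n)
        status = np.array(["normal"] * 40 + ["obese"] * 15 + ["wasted"] * 5)
        rep = subgroup_report({"m": t + 10}, t, status)
        total = sum(rep.panels[g][0].n for g in ("normal", "obese", "wasted"))
        assert total == rep.panels["overall"][0].n == n

    def test_label_coverage_contract(self):
        with pytest.raises(DataContractError):
            subgroup_report({"m": np.ones(5)}, np.ones(5), np.array(["normal"] * 4))
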