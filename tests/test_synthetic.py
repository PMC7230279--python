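import numpy as np
import pandas as pd
import pytest

from pedree.anthropometry import FEATURE_NAMES
from pedree.errors import InvalidConfigError
from pedree.synthetic import (
    BENCHMARK_INFORMATIVE, CohortConfig, cohort_to_frame, generate_cohort,
    generate_selection_benchmark, generate_trace, latent_ree, read_cohort_csv,
    read_trace_csv, write_cohort_csv, write_trace_csv,
)


class TestCohortConfig:
    def test_negative_n(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(n=-1)

    def test_infeasible_fractions(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(obese_fraction=0.7, underweight_fraction=0.5)

    def test_age_range_bounds(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(age_range=(1.0, 17.0))

    def test_rq_range_bounds(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(rq_range=(0.5, 0.9))


class TestGenerateCohort:
    def test_empty_cohort(self):
        assert generate_cohort(CohortConfig(n=0)) == []

    def test_deterministic(self):
        a = generate_cohort(CohortConfig(n=40, seed=7))
        b = generate_cohort(CohortConfig(n=40, seed=7))
        assert a == b

    def test_seed_changes_output(self):
        a = generate_cohort(CohortConfig(n=40, seed=7))
        b = generate_cohort(CohortConfig(n=40, seed=8))
        assert a != b

    def test_target_marginals_at_full_size(self, full_cohort):
        df = cohort_to_frame(full_cohort)
        assert df["weight_kg"].mean() == pytest.approx(62.8, rel=0.05)
        assert df["ree_kcal_d"].mean() == pytest.approx(1417.6, rel=0.05)
        assert df["age"].mean() == pytest.approx(13.0, rel=0.05)
        assert df["height_cm"].mean() == pytest.approx(156.5, rel=0.05)
        male_frac = (df["sex"] == "M").mean()
        assert male_frac == pytest.approx(0.675, abs=0.01)

    def test_all_measurements_positive(self, full_cohort):
        df = cohort_to_frame(full_cohort).drop(columns=["subject_id", "sex"])
        assert (df > 0).all().all()

    def test_rq_within_configured_range(self, full_cohort):
        df = cohort_to_frame(full_cohort)
        rq = df["vco2_lmin"] / df["vo2_lmin"]
        assert rq.between(0.71, 0.95).all()

    def test_qc_fail_injection(self):
        cohort = generate_cohort(CohortConfig(n=100, seed=3, qc_fail_fraction=0.1))
        rq = np.array([r.vco2 / r.vo2 for r in cohort])
        n_out = np.sum((rq < 0.67) | (rq > 1.3))
        assert n_out == 10

    def test_latent_ree_increasing_in_weight(self):
        # finite differences on the generative law at fixed age/sex/fat
        w = np.linspace(15, 90, 50)
        r = latent_ree(w, 45.0, 1, 10.0)
        assert np.all(np.diff(r) > 0)


class TestGenerateTrace:
    def test_zero_jitter_constant(self, small_cohort):
        tr = generate_trace(small_cohort[0], duration=10, sampling=1, jitter=0.0)
        assert np.allclose(tr.vo2_series, small_cohort[0].vo2)
        assert np.allclose(tr.vco2_series, small_cohort[0].vco2)

    def test_trace_shape_and_cv(self, small_cohort):
        tr = generate_trace(small_cohort[0], duration=20, sampling=1,
                            jitter=0.02, seed=4)
        assert len(tr.timestamps) == 20
        rq = tr.vco2_series / tr.vo2_series
        assert np.std(rq) / np.mean(rq) < 0.05

    def test_degenerate_sampling(self, small_cohort):
        with pytest.raises(InvalidConfigError):
            generate_trace(small_cohort[0], duration=10, sampling=0)

    def test_deterministic(self, small_cohort):
        t1 = generate_trace(small_cohort[0], seed=9)
        t2 = generate_trace(small_cohort[0], seed=9)
        assert np.array_equal(t1.vo2_series, t2.vo2_series)


class TestSelectionBenchmark:
    def test_shapes_and_mask(self, benchmark_problem):
        X, y, mask = benchmark_problem
        assert list(X.columns) == FEATURE_NAMES
        assert len(X) == len(y) == 561
        assert mask.sum() == 7
        assert set(np.array(FEATURE_NAMES)[mask]) == set(BENCHMARK_INFORMATIVE)

    def test_informative_columns_predict(self, benchmark_problem):
        # dropping an informative column must hurt a linear fit more than
        # dropping a noise column
        X, y, mask = benchmark_problem
        x = X.to_numpy()
        full = _lstsq_mae(x, y)
        without_weight = _lstsq_mae(x[:, [i for i in range(13) if FEATURE_NAMES[i] != "weight"]], y)
        without_noise = _lstsq_mae(x[:, [i for i in range(13) if FEATURE_NAMES[i] != "height"]], y)
        assert without_weight > full * 2
        assert without_noise < full * 1.05


def _lstsq_mae(x, y):
    a = np.c_[x, np.ones(len(x))]
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    return float(np.mean(np.abs(a @ coef - y)))


class TestCsvContracts:
    def test_cohort_roundtrip(self, small_cohort, tmp_path):
        p = tmp_path / "cohort.csv"
        write_cohort_csv(small_cohort, p)
        header = p.read_text().splitlines()[0]
        assert header == ("subject_id,age,sex,weight_kg,height_cm,arm_circ_cm,"
                          "biceps_mm,triceps_mm,subscapular_mm,suprailiac_mm,"
                          "vo2_lmin,vco2_lmin,ree_kcal_d")
        back = read_cohort_csv(p)
        assert len(back) == len(small_cohort)
        assert back[0].subject_id == small_cohort[0].subject_id
        assert back[0].weight == pytest.approx(small_cohort[0].weight)
        # the latent column is synthetic-only and must not survive export
        assert back[0].ree_true_latent is None

    def test_trace_roundtrip(self, small_cohort, tmp_path):
        traces = [generate_trace(r, seed=i) for i, r in enumerate(small_cohort[:3])]
        p = tmp_path / "traces.csv"
        write_trace_csv(traces, p)
        assert p.read_text().splitlines()[0] == "subject_id,t_min,vo2,vco2,ve"
        back = read_trace_csv(p)
        assert len(back) == 3
        assert np.allclose(back[0].vo2_series, traces[0].vo2_series)
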