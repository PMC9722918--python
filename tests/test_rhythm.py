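"""Cosinor and JTK statistics: exact recovery, invariances, calibration
and agreement with independent references (statsmodels OLS, dense grid
search)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitorhythm import (
    Cosinor,
    ParameterError,
    RhythmSimSpec,
    TimeSeries,
    acrophase_hours,
    batch_rhythm,
    generate_timeseries,
    jtk_test,
)
from mitorhythm.rhythm import SingularDesignError


def _random_dataset(rng, n=12):
    t = np.sort(rng.uniform(0, 48, n))
    y = rng.normal(10, 3, n)
    return t, y


class TestCosinorFit:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0, 48, 4.0)
        y = 10 + 3 * np.cos(2 * np.pi * (t - 8) / 24)
        res = Cosinor(t, y).fit()
        assert res.mesor == pytest.approx(10.0, abs=1e-9)
        assert res.amplitude == pytest.approx(3.0, abs=1e-9)
        assert res.acrophase_h == pytest.approx(8.0, abs=1e-9)
        assert res.ss_resid < 1e-12
        assert res.p_zero_amplitude < 1e-12

    def test_constant_series_flat_fit(self):
        res = Cosinor(np.arange(0, 48, 4.0), np.full(12, 5.0)).fit()
        assert res.mesor == pytest.approx(5.0)
        assert res.amplitude == pytest.approx(0.0, abs=1e-9)
        assert res.p_zero_amplitude == 1.0
        assert np.isnan(res.acrophase_h)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(5):
            t, y = _random_dataset(rng)
            w = 2 * np.pi * t / 24
            X = sm.add_constant(np.column_stack([np.cos(w), np.sin(w)]))
            ref = sm.OLS(y, X).fit()
            res = Cosinor(t, y).fit()
            np.testing.assert_allclose(res.params, ref.params, rtol=1e-9)
            np.testing.assert_allclose(res.bse, ref.bse, rtol=1e-7)
            assert res.p_zero_amplitude == pytest.approx(ref.f_pvalue, rel=1e-8)

    def test_monte_carlo_parameter_recovery(self):
        amps, phases = [], []
        for seed in range(300):
            ts = generate_timeseries(
                RhythmSimSpec(
                    mesor=10, amplitude=2, acrophase_h=6, noise_sd=1,
                    times_h=tuple(range(0, 45, 4)), replicates=3, seed=seed,
                )
            )
            res = Cosinor.from_timeseries(ts).fit()
            amps.append(res.amplitude)
            phases.append(res.acrophase_h)
        assert abs(np.mean(amps) - 2.0) < 0.1
        assert abs(np.mean(phases) - 6.0) < 0.25

    def test_twelve_hour_sampling_design_is_rank_two_but_fits(self):
        t = np.array([0.0, 12, 24, 36, 48])
        y = 10 - 2 * np.cos(2 * np.pi * t / 24)
        res = Cosinor(t, y).fit()
        assert res.rank == 2
        assert res.gamma == pytest.approx(0.0, abs=1e-12)
        assert res.amplitude == pytest.approx(2.0, abs=1e-9)
        assert res.acrophase_h == pytest.approx(12.0, abs=1e-9)

    def test_too_few_distinct_times_raises(self):
        with pytest.raises(SingularDesignError):
            Cosinor([0, 0, 12, 12], [1, 2, 3, 4])

    def test_summary_and_predict(self):
        t = np.arange(0, 48, 4.0)
        res = Cosinor(t, 10 + np.cos(2 * np.pi * t / 24)).fit()
        text = res.summary()
        assert "amplitude" in text and "acrophase" in text
        assert res.predict([0.0])[0] == pytest.approx(11.0, abs=1e-9)


class TestAcrophase:
    @pytest.mark.parametrize(
        "beta,gamma,expected",
        [(2, 0, 0.0), (0, 2, 6.0), (0, -2, 18.0), (-2, 0, 12.0)],
    )
    def test_quadrants(self, beta, gamma, expected):
        assert acrophase_hours(beta, gamma, 24.0) == pytest.approx(expected)

    def test_undefined_for_flat_curve(self):
        assert np.isnan(acrophase_hours(0.0, 0.0))

    def test_peak_location_matches_convention(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            beta, gamma = rng.normal(size=2)
            phi = acrophase_hours(beta, gamma, 24.0)
            tt = np.linspace(0, 24, 2401, endpoint=False)
            curve = beta * np.cos(2 * np.pi * tt / 24) + gamma * np.sin(2 * np.pi * tt / 24)
            assert abs(tt[np.argmax(curve)] - phi) < 0.02


class TestInvariances:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_amplitude_identity(self, seed):
        rng = np.random.default_rng(seed)
        t, y = _random_dataset(rng)
        res = Cosinor(t, y).fit()
        assert res.amplitude**2 == pytest.approx(res.beta**2 + res.gamma**2, rel=1e-12)

    def test_time_shift_equivariance(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            t, y = _random_dataset(rng)
            delta = rng.uniform(-24, 24)
            a = Cosinor(t, y).fit()
            b = Cosinor(t + delta, y).fit()
            assert b.mesor == pytest.approx(a.mesor, rel=1e-8)
            assert b.amplitude == pytest.approx(a.amplitude, rel=1e-8)
            assert b.p_zero_amplitude == pytest.approx(a.p_zero_amplitude, rel=1e-6)
            assert (b.acrophase_h - (a.acrophase_h + delta)) % 24 == pytest.approx(0, abs=1e-6) or (
                (b.acrophase_h - (a.acrophase_h + delta)) % 24 == pytest.approx(24, abs=1e-6)
            )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            t, y = _random_dataset(rng)
            c = rng.uniform(0.1, 10)
            a, b = Cosinor(t, y).fit(), Cosinor(t, c * y).fit()
            assert b.mesor == pytest.approx(c * a.mesor, rel=1e-9)
            assert b.amplitude == pytest.approx(c * a.amplitude, rel=1e-9)
            assert b.p_zero_amplitude == pytest.approx(a.p_zero_amplitude, rel=1e-7)

    def test_ols_beats_dense_grid(self):
        # independent oracle: exhaustive search over (M, A, Phi)
        rng = np.random.default_rng(3)
        for _ in range(5):
            t, y = _random_dataset(rng)
            res = Cosinor(t, y).fit()
            M = np.linspace(y.min(), y.max(), 101)
            A = np.linspace(0, np.ptp(y), 101)
            best = np.inf
            for phi in np.linspace(0, 24, 121, endpoint=False):
                c = np.cos(2 * np.pi * (t - phi) / 24)
                sy, syc = y.sum(), (y * c).sum()
                sc, sc2, n = c.sum(), (c * c).sum(), t.size
                sse = (
                    (y * y).sum()
                    - 2 * M[:, None] * sy
                    - 2 * A[None, :] * syc
                    + n * M[:, None] ** 2
                    + 2 * M[:, None] * A[None, :] * sc
                    + A[None, :] ** 2 * sc2
                )
                best = min(best, sse.min())
            assert res.ss_resid <= best + 1e-9


class TestJTK:
    def test_perfect_concordance_at_phase_zero(self):
        t = np.arange(0, 48, 4.0)
        # data identical to the phase-0 cosine (incl. its exact value ties)
        y = np.round(np.cos(2 * np.pi * (t % 24) / 24), 12)
        res = jtk_test(TimeSeries(t, y))
        assert res.best_phase_h == 0.0
        assert res.tau == pytest.approx(1.0)
        row0 = res.table[res.table.phase_h == 0.0].iloc[0]
        assert res.p_adjusted == pytest.approx(min(1.0, row0.p * res.n_phases))

    def test_antiphase_symmetry(self):
        t = np.arange(0, 48, 4.0)
        y = np.cos(2 * np.pi * t / 24) + 0.01 * np.sin(t)  # break ties deterministically
        a, b = jtk_test(TimeSeries(t, y)), jtk_test(TimeSeries(t, -y))
        assert (b.best_phase_h - a.best_phase_h) % 24 == pytest.approx(12.0)
        assert b.tau == pytest.approx(a.tau)

    def test_tau_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 48, 4.0)
        y = rng.normal(size=t.size)
        a = jtk_test(TimeSeries(t, y))
        b = jtk_test(TimeSeries(t, np.exp(y)))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_all_tied_values_flagged(self):
        res = jtk_test(TimeSeries(np.arange(0, 48, 4.0), np.ones(12)))
        assert res.tie_flag and res.p_adjusted == 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ParameterError):
            jtk_test(TimeSeries(np.arange(5.0), np.arange(5.0)))

    def test_exact_small_sample_null_p(self):
        # n=8 distinct values on an irregular grid (no reference ties):
        # p must come from the exact Kendall null
        from scipy.stats import kendalltau

        t = np.array([0.0, 3, 5, 7, 11, 13, 17, 19])
        y = np.array([3.0, 1, 4, 1.5, 5, 9, 2.6, 5.3])
        res = jtk_test(TimeSeries(t, y), phase_step_h=3.0)
        for _, row in res.table.iterrows():
            ref = np.round(np.cos(2 * np.pi * ((t - row.phase_h) % 24) / 24), 12)
            ties = np.unique(ref).size < ref.size
            expected = kendalltau(
                ref, y, method="exact" if not ties else "asymptotic", alternative="greater"
            ).pvalue
            assert row.p == pytest.approx(expected)


class TestBatchRhythm:
    def test_rhythmic_and_flat_analytes_flagged(self):
        t = np.tile(np.arange(0, 48, 4.0), 2)
        rng = np.random.default_rng(0)
        rows = []
        for analyte, amp in (("per2", 3.0), ("flatgene", 0.0)):
            y = 10 + amp * np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.5, t.size)
            rows.append(pd.DataFrame({"analyte": analyte, "time_h": t, "value": y}))
        report = batch_rhythm(pd.concat(rows), method="cosinor").set_index("analyte")
        assert bool(report.loc["per2", "rhythmic"]) is True
        assert bool(report.loc["flatgene", "rhythmic"]) is False
        assert report.loc["per2", "n"] == t.size

    def test_empty_table(self):
        assert batch_rhythm(pd.DataFrame(columns=["analyte", "time_h", "value"])).empty

    def test_insufficient_data_reported_not_dropped(self):
        df = pd.DataFrame({"analyte": "x", "time_h": [0, 12], "value": [1.0, 2.0]})
        report = batch_rhythm(df)
        assert report.loc[0, "status"] == "insufficient data"
        assert bool(report.loc[0, "rhythmic"]) is False
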