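import numpy as np
import pandas as pd
import pytest

from bioscatter.gam import Linear, PenalizedGAM, RandomIntercept, Smooth, Smooth2D


@pytest.fixture
def frame(rng):
    n = 800
    return pd.DataFrame(
        {
            "x": rng.uniform(0, 10, n),
            "z": rng.uniform(-5, 5, n),
            "g": rng.choice(list("abcdef"), n),
        }
    )


class TestFitBasics:
    def test_sine_recovery(self, frame, rng):
        y = np.sin(frame.x.to_numpy()) + 0.1 * rng.standard_normal(len(frame))
        m = PenalizedGAM(terms=[Smooth("x", k=10)]).fit(frame, y)
        effect = m.partial_effect("s(x)", frame)
        truth = np.sin(frame.x.to_numpy())
        assert np.corrcoef(effect, truth - truth.mean())[0, 1] > 0.99
        assert m.deviance_explained_ > 0.9

    def test_noise_free_linear_with_select_shrinks_other_terms(self, frame):
        y = 2.0 * frame.x.to_numpy()
        m = PenalizedGAM(terms=[Smooth("x"), Smooth("z")], select=True).fit(frame, y)
        assert np.sqrt(np.mean((m.fitted_values_ - y) ** 2)) < 1e-6
        # the irrelevant term is effectively removed: its contribution is
        # numerically zero and its dof are far below a single parameter
        assert m.edf_by_term_["s(z)"] < 0.5
        assert np.max(np.abs(m.partial_effect("s(z)", frame))) < 1e-6

    def test_pure_noise_low_deviance(self, frame, rng):
        y = rng.standard_normal(len(frame))
        m = PenalizedGAM(terms=[Smooth("x"), Smooth("z")], select=True).fit(frame, y)
        assert m.deviance_explained_ < 0.05

    def test_intercept_only_zero_deviance(self, frame, rng):
        y = rng.standard_normal(len(frame)) + 3.0
        m = PenalizedGAM(terms=[]).fit(frame, y)
        assert m.deviance_explained_ == pytest.approx(0.0, abs=1e-12)
        assert m.fitted_values_ == pytest.approx(y.mean())

    def test_random_intercept_recovers_group_means(self, frame, rng):
        effects = dict(zip("abcdef", [0.0, 0.5, -0.5, 1.0, -1.0, 0.25]))
        y = frame.g.map(effects).to_numpy() + 0.05 * rng.standard_normal(len(frame))
        m = PenalizedGAM(terms=[RandomIntercept("g")]).fit(frame, y)
        got = m.predict(frame)
        expected = frame.g.map(effects).to_numpy() + 0.0
        assert np.corrcoef(got, expected)[0, 1] > 0.99

    def test_validation_errors(self, frame):
        with pytest.raises(TypeError):
            PenalizedGAM(terms=[Smooth("x")]).fit(frame.x.to_numpy(), np.zeros(len(frame)))
        with pytest.raises(ValueError):
            PenalizedGAM(terms=[Smooth("x")]).fit(frame, np.zeros(3))


class TestPredict:
    def test_prediction_at_training_equals_fitted(self, frame, rng):
        y = np.sin(frame.x.to_numpy()) + 0.1 * rng.standard_normal(len(frame))
        m = PenalizedGAM(terms=[Smooth("x"), RandomIntercept("g")]).fit(frame, y)
        np.testing.assert_allclose(m.predict(frame), m.fitted_values_, rtol=1e-10)

    def test_unseen_factor_level_is_population(self, frame, rng):
        y = np.sin(frame.x.to_numpy()) + 0.1 * rng.standard_normal(len(frame))
        m = PenalizedGAM(terms=[Smooth("x"), RandomIntercept("g")]).fit(frame, y)
        new = frame.head(10).assign(g="unseen")
        base = frame.head(10)
        mu_new = m.predict(new)
        mu_re = m.partial_effect("re(g)", base)
        np.testing.assert_allclose(mu_new, m.predict(base) - mu_re, rtol=1e-10)

    def test_se_positive_and_extrapolation_flagged(self, frame, rng):
        y = np.sin(frame.x.to_numpy()) + 0.1 * rng.standard_normal(len(frame))
        m = PenalizedGAM(terms=[Smooth("x")]).fit(frame, y)
        new = pd.DataFrame({"x": [5.0, 25.0]})
        mu, se, ex = m.predict(new, return_se=True, return_extrapolation=True)
        assert (se > 0).all()
        assert list(ex) == [False, True]

    def test_sklearn_get_set_params(self):
        m = PenalizedGAM(terms=[Smooth("x")], select=True)
        params = m.get_params()
        assert params["select"] is True
        m.set_params(ar_rho=0.5)
        assert m.ar_rho == 0.5


class TestAr1Whitening:
    def test_ar1_noise_handled(self, rng):
        # smooth signal + AR(1) noise: pre-whitening at the true rho gives
        # near-white innovations
        n_series, t_len, rho = 40, 50, 0.7
        rows, ys = [], []
        for s in range(n_series):
            x = np.linspace(0, 10, t_len)
            eps = np.empty(t_len)
            eps[0] = rng.normal(0, 0.2 / np.sqrt(1 - rho**2))
            for t in range(1, t_len):
                eps[t] = rho * eps[t - 1] + rng.normal(0, 0.2)
            rows.append(pd.DataFrame({"x": x, "s": f"s{s}"}))
            ys.append(np.sin(x) + eps)
        df = pd.concat(rows, ignore_index=True)
        y = np.concatenate(ys)
        m = PenalizedGAM(terms=[Smooth("x", k=10)], ar_rho=rho, series="s").fit(df, y)
        effect = m.partial_effect("s(x)", df)
        truth = np.sin(df.x.to_numpy())
        assert np.corrcoef(effect, truth - truth.mean())[0, 1] > 0.98


class TestTermTypes:
    def test_varying_coefficient_smooth(self, rng):
        n = 1500
        df = pd.DataFrame({"lat": rng.uniform(-30, 30, n), "t": rng.uniform(-4, 4, n)})
        slope = -0.05 * df.lat.to_numpy() / 30.0
        y = slope * df.t.to_numpy() + 0.05 * rng.standard_normal(n)
        m = PenalizedGAM(terms=[Smooth("lat", k=6, by="t")]).fit(df, y)
        assert m.deviance_explained_ > 0.5
        got = m.predict(df)
        assert np.corrcoef(got, slope * df.t.to_numpy())[0, 1] > 0.95

    def test_by_factor_smooth(self, rng):
        n = 1200
        df = pd.DataFrame({"x": rng.uniform(0, 10, n), "g": rng.choice(["a", "b"], n)})
        truth = np.where(df.g == "a", np.sin(df.x), -np.sin(df.x))
        y = truth + 0.1 * rng.standard_normal(n)
        # level means are excluded from factor-by smooths, so the factor
        # itself enters as a random intercept
        m = PenalizedGAM(terms=[Smooth("x", k=8, by="g"), RandomIntercept("g")]).fit(df, y)
        assert np.corrcoef(m.predict(df), truth)[0, 1] > 0.98

    def test_linear_term(self, rng):
        n = 500
        df = pd.DataFrame({"x": rng.uniform(0, 10, n)})
        y = 1.5 * df.x.to_numpy() + rng.standard_normal(n)
        m = PenalizedGAM(terms=[Linear("x")]).fit(df, y)
        assert m.coef_[1] == pytest.approx(1.5, abs=0.1)

    def test_smooth2d_surface(self, rng):
        n = 1200
        df = pd.DataFrame({"x": rng.uniform(-30, 30, n), "y": rng.uniform(-30, 30, n)})
        truth = np.sin(df.x / 12) * np.cos(df.y / 12)
        y = truth + 0.1 * rng.standard_normal(n)
        m = PenalizedGAM(terms=[Smooth2D("x", "y", k=36)]).fit(df, y)
        assert np.corrcoef(m.predict(df), truth)[0, 1] > 0.95

    def test_cyclic_smooth_periodicity(self, rng):
        n = 600
        t = rng.uniform(0, 24, n)
        y = np.cos(2 * np.pi * t / 24) + 0.1 * rng.standard_normal(n)
        m = PenalizedGAM(terms=[Smooth("t", k=10, cyclic=True, period=24.0)]).fit(
            pd.DataFrame({"t": t}), y
        )
        ends = m.predict(pd.DataFrame({"t": [0.0, 24.0 - 1e-9]}))
        assert ends[0] == pytest.approx(ends[1], abs=1e-6)


class TestAgainstMgcv:
    def test_matches_mgcv_reference_fit(self, tmp_path, rng):
        # independent oracle: the same penalized-spline model fitted by
        # R/mgcv (REML) must produce essentially the same curve
        import subprocess

        n = 400
        df = pd.DataFrame({"x": rng.uniform(0, 10, n)})
        y = np.sin(df.x.to_numpy()) + 0.2 * rng.standard_normal(n)
        df.assign(y=y).to_csv(tmp_path / "d.csv", index=False)
        script = (
            "d <- read.csv('" + str(tmp_path / "d.csv") + "');"
            "library(mgcv);"
            "m <- gam(y ~ s(x, k=10, bs='ps'), data=d, method='REML');"
            "write.csv(data.frame(f=fitted(m)), '" + str(tmp_path / "f.csv") + "',"
            "row.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "f.csv").f.to_numpy()
        m = PenalizedGAM(terms=[Smooth("x", k=10)]).fit(df, y)
        assert np.corrcoef(m.fitted_values_, ref)[0, 1] > 0.999
        assert np.sqrt(np.mean((m.fitted_values_ - ref) ** 2)) < 0.05


class TestModelScores:
    def test_aic_prefers_true_structure(self, frame, rng):
        y = np.sin(frame.x.to_numpy()) + 0.1 * rng.standard_normal(len(frame))
        m_true = PenalizedGAM(terms=[Smooth("x")]).fit(frame, y)
        m_null = PenalizedGAM(terms=[]).fit(frame, y)
        assert m_true.aic_ < m_null.aic_ - 2

    def test_deviance_non_decreasing_with_nesting(self, frame, rng):
        y = np.sin(frame.x.to_numpy()) + 0.2 * frame.z.to_numpy() \
            + 0.1 * rng.standard_normal(len(frame))
        fits = [
            PenalizedGAM(terms=[]).fit(frame, y),
            PenalizedGAM(terms=[Smooth("x")]).fit(frame, y),
            PenalizedGAM(terms=[Smooth("x"), Smooth("z")]).fit(frame, y),
        ]
        devs = [f.deviance_explained_ for f in fits]
        assert devs[0] <= devs[1] + 1e-9 <= devs[2] + 2e-9
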