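"""Model suite: PCNM axes, logistic MLE, mixed fits, AME, bootstrap, R2."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from landclim import models as md


def toy_data(rng, n=200):
    return pd.DataFrame({
        "land_conversion": rng.uniform(0, 1, n),
        "temperature_trend": rng.normal(0.2, 0.08, n),
        "effort": rng.gamma(4, 0.25, n),
        "microclimate": rng.normal(0, 1, n),
        "pcnm1": rng.normal(0, 0.1, n),
        "pcnm2": rng.normal(0, 0.1, n),
    })


class TestPCNM:
    @pytest.fixture()
    def centroids(self, rng):
        return pd.DataFrame({"x": rng.uniform(0, 100, 30),
                             "y": rng.uniform(0, 100, 30)})

    def test_axes_orthogonal(self, centroids):
        ax = md.pcnm_axes(centroids)
        assert abs(ax["pcnm1"] @ ax["pcnm2"]) < 1e-10
        assert np.linalg.norm(ax["pcnm1"]) == pytest.approx(1.0)

    def test_matches_dense_pcoa_oracle(self, centroids):
        """Same truncated matrix through scikit-bio's PCoA."""
        import networkx as nx
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa

        D = squareform(pdist(centroids[["x", "y"]].to_numpy()))
        G = nx.from_numpy_array(D)
        mst = nx.minimum_spanning_tree(G)
        t = max(d["weight"] for _, _, d in mst.edges(data=True))
        Dt = np.where(D > t, 4 * t, D)
        np.fill_diagonal(Dt, 0.0)
        ref = pcoa(DistanceMatrix(Dt), method="eigh")
        ours = md.pcnm_axes(centroids)
        for k in range(2):
            v_ref = ref.samples.iloc[:, k].to_numpy()
            v_ref = v_ref / np.linalg.norm(v_ref)
            dot = abs(v_ref @ ours.iloc[:, k].to_numpy())
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_translation_invariance(self, centroids):
        shifted = centroids + 1234.5
        a = md.pcnm_axes(centroids)
        b = md.pcnm_axes(shifted)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            md.pcnm_axes(pd.DataFrame({"x": [0, 1], "y": [0, 0]}))


class TestLogisticFit:
    def _design(self, x):
        return pd.DataFrame({"const": 1.0, "x": x})

    def test_intercept_only_balanced(self):
        y = np.array([0, 1, 0, 1, 0, 1], float)
        X = pd.DataFrame({"const": np.ones(6)})
        fit = md.fit_logistic(pd.DataFrame(index=range(6)), y,
                              md.ModelSpec(1, controls=()), design=X)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_three_quarters(self):
        y = np.array([1, 1, 1, 0, 1, 1, 1, 0], float)
        X = pd.DataFrame({"const": np.ones(8)})
        fit = md.fit_logistic(pd.DataFrame(index=range(8)), y,
                              md.ModelSpec(1, controls=()), design=X)
        assert fit.params["const"] == pytest.approx(np.log(3), abs=1e-8)

    def test_loglik_matches_grid_search(self):
        """Two-stage grid search over (b0, b1) as an independent oracle."""
        x = np.array([-1.2, -0.4, 0.1, 0.6, 1.3, 2.0])
        y = np.array([0, 0, 1, 0, 1, 1], float)
        fit = md.fit_logistic(pd.DataFrame({"x": x}), y,
                              md.ModelSpec(1, controls=()),
                              design=self._design(x))

        def loglik(b0, b1):
            eta = b0[:, None, None] + b1[None, :, None] * x[None, None, :]
            return (y * eta - np.logaddexp(0, eta)).sum(axis=-1)

        centre = np.zeros(2)
        width = 8.0
        best = -np.inf
        for _ in range(6):
            b0 = np.linspace(centre[0] - width, centre[0] + width, 201)
            b1 = np.linspace(centre[1] - width, centre[1] + width, 201)
            ll = loglik(b0, b1)
            i, j = np.unravel_index(ll.argmax(), ll.shape)
            best = ll[i, j]
            centre = np.array([b0[i], b1[j]])
            width /= 20
        assert fit.llf == pytest.approx(best, abs=1e-6)

    def test_aic_invariant_to_affine_rescaling(self, rng):
        data = toy_data(rng, 300)
        eta = 0.5 + 2 * data["temperature_trend"] - data["land_conversion"]
        y = (rng.random(300) < expit(eta)).astype(float)
        fit1 = md.fit_logistic(data, y, md.ModelSpec(4))
        scaled = data.copy()
        scaled["temperature_trend"] = data["temperature_trend"] * 37 - 4
        scaled["land_conversion"] = data["land_conversion"] * 0.01 + 5
        fit2 = md.fit_logistic(scaled, y, md.ModelSpec(4))
        assert fit1.llf == pytest.approx(fit2.llf, abs=1e-8)

    def test_needs_enough_rows(self, rng):
        data = toy_data(rng, 6)
        with pytest.raises(ValueError):
            md.fit_logistic(data, np.ones(6), md.ModelSpec(5))


class TestMixedLogistic:
    def test_sigma_zero_matches_pooled(self, rng):
        data = toy_data(rng, 400)
        y = (rng.random(400) < 0.6).astype(float)
        groups = np.repeat([0, 1], 200)
        mixed = md.fit_mixed_logistic(data, y, groups, md.ModelSpec(4),
                                      fix_sigma=0)
        pooled = md.fit_logistic(data, y, md.ModelSpec(4))
        assert (mixed.params - pooled.params).abs().max() < 1e-4

    def test_duplicated_species_zero_variance(self, rng):
        data = toy_data(rng, 250)
        eta = 0.3 + data["temperature_trend"]
        y = (rng.random(250) < expit(eta)).astype(float)
        data2 = pd.concat([data, data], ignore_index=True)
        y2 = np.r_[y, y]
        groups = np.repeat([0, 1], 250)
        fit = md.fit_mixed_logistic(data2, y2, groups, md.ModelSpec(3))
        assert fit.sigma2_u < 0.01

    def test_matches_lme4_glmer(self, rng, tmp_path):
        """Cross-check ML estimates against R lme4 with adaptive quadrature."""
        nsp, nper = 25, 120
        u = rng.normal(0, 0.8, nsp)
        base = toy_data(rng, nper)
        data = pd.concat([base] * nsp, ignore_index=True)
        groups = np.repeat(np.arange(nsp), nper)
        eta = (0.8 + 2.0 * data["temperature_trend"]
               - 1.0 * data["land_conversion"] + u[groups])
        y = (rng.random(len(data)) < expit(eta)).astype(float)
        fit = md.fit_mixed_logistic(data, y, groups, md.ModelSpec(4))

        df = data.copy()
        df["y"], df["sp"] = y, groups
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ land_conversion + temperature_trend + effort +
                       microclimate + pcnm1 + pcnm2 + (1|sp),
                       data=d, family=binomial, nAGQ=25)
            cat(sprintf("%.8f", as.numeric(logLik(m))), "\\n")
            cat(sprintf("%.8f", unname(summary(m)$varcor$sp[1])), "\\n")
            cat(sprintf("%.8f", unname(fixef(m))), sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-"], input=rscript, text=True,
                             capture_output=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [float(v) for v in out.stdout.split()]
        llf_r, sigma2_r, beta_r = lines[0], lines[1], lines[2:]
        assert fit.llf == pytest.approx(llf_r, abs=0.01)
        assert fit.sigma2_u == pytest.approx(sigma2_r, abs=0.02)
        ours = fit.params[["const", "land_conversion", "temperature_trend",
                           "effort", "microclimate", "pcnm1", "pcnm2"]]
        np.testing.assert_allclose(ours.to_numpy(), beta_r, atol=0.01)

    def test_variance_recovery(self, rng):
        """Species intercepts ~ N(0,1): estimate lands in a sane band."""
        nsp, nper = 50, 400
        u = rng.normal(0, 1.0, nsp)
        base = toy_data(rng, nper)
        data = pd.concat([base] * nsp, ignore_index=True)
        groups = np.repeat(np.arange(nsp), nper)
        eta = 0.5 + 1.5 * data["temperature_trend"] + u[groups]
        y = (rng.random(len(data)) < expit(eta)).astype(float)
        fit = md.fit_mixed_logistic(data, y, groups, md.ModelSpec(3))
        assert 0.5 <= fit.sigma2_u <= 1.6

    def test_r2_closed_forms(self):
        spec = md.ModelSpec(1, controls=())
        X = pd.DataFrame({"const": np.ones(4)})
        base = md.ModelFit(spec=spec, params=pd.Series({"const": 0.0}),
                           llf=0.0, k=2, converged=True, n=4, design=X,
                           y=np.zeros(4), sigma2_u=0.0)
        assert md.r2_mixed(base) == pytest.approx((0.0, 0.0))
        base.sigma2_u = np.pi ** 2 / 3
        assert md.r2_mixed(base) == pytest.approx((0.0, 0.5))
        X2 = pd.DataFrame({"const": np.ones(4), "x": [-1, -1, 1, 1.0]})
        fit2 = md.ModelFit(spec=spec,
                           params=pd.Series({"const": 0.0,
                                             "x": np.pi / np.sqrt(3)}),
                           llf=0.0, k=3, converged=True, n=4, design=X2,
                           y=np.zeros(4), sigma2_u=np.pi ** 2 / 3)
        assert md.r2_mixed(fit2) == pytest.approx((1 / 3, 2 / 3))


class TestSelection:
    def test_tie_broken_toward_fewer_parameters(self, rng):
        data = toy_data(rng, 300)
        y = (rng.random(300) < 0.6).astype(float)
        f4 = md.fit_logistic(data, y, md.ModelSpec(4))
        f5 = md.fit_logistic(data, y, md.ModelSpec(5))
        f5.llf = f4.llf - (f5.k - f4.k)     # engineered exact AIC tie
        assert md.select_best({4: f4, 5: f5}).spec.formulation_id == 4

    def test_minimum_aic_wins(self, rng):
        data = toy_data(rng, 500)
        eta = 0.5 + 3.0 * (data["temperature_trend"] - 0.2) / 0.08
        y = (rng.random(500) < expit(eta)).astype(float)
        fits = md.fit_formulations(data, y)
        best = md.select_best(fits)
        assert best.aic == min(f.aic for f in fits.values())

    def test_no_fits_raises(self):
        with pytest.raises(ValueError):
            md.select_best({})


class TestAME:
    def test_zero_coefficient_zero_ame(self, rng):
        data = toy_data(rng, 100)
        X = pd.DataFrame({"const": np.ones(100),
                          "temperature_trend": data["temperature_trend"]})
        fit = md.ModelFit(spec=md.ModelSpec(3, controls=()),
                          params=pd.Series({"const": 0.3,
                                            "temperature_trend": 0.0}),
                          llf=0.0, k=2, converged=True, n=100, design=X,
                          y=np.zeros(100))
        assert md.average_marginal_effect(fit, "temperature_trend", 0.1).ame == 0

    def test_single_point_closed_form(self):
        # p = 0.5, slope 1, unit 0.1: AME = 0.25 * 1 * 0.1 = 0.025
        X = pd.DataFrame({"const": [1.0], "temperature_trend": [0.0]})
        fit = md.ModelFit(spec=md.ModelSpec(3, controls=()),
                          params=pd.Series({"const": 0.0,
                                            "temperature_trend": 1.0}),
                          llf=0.0, k=2, converged=True, n=1, design=X,
                          y=np.zeros(1))
        res = md.average_marginal_effect(fit, "temperature_trend", 0.1)
        assert res.ame == pytest.approx(0.025)

    @pytest.mark.parametrize("fid", [2, 3, 4, 5])
    def test_matches_finite_difference_oracle(self, rng, fid):
        data = toy_data(rng, 400)
        eta = (0.5 + 2 * data["temperature_trend"] - data["land_conversion"]
               + 3 * data["land_conversion"] * data["temperature_trend"])
        y = (rng.random(400) < expit(eta)).astype(float)
        fit = md.fit_logistic(data, y, md.ModelSpec(fid))
        for var in md.FORMULATIONS[fid]:
            if var == md.INTERACTION:
                continue
            unit = 0.1
            res = md.average_marginal_effect(fit, var, unit)
            h = 1e-6 * unit
            up, dn = data.copy(), data.copy()
            up[var] += h
            dn[var] -= h
            fd = (fit.predict(md.build_design(up, fit.spec))
                  - fit.predict(md.build_design(dn, fit.spec))) / (2 * h)
            assert res.ame == pytest.approx(unit * fd.mean(), abs=1e-6)

    def test_absent_variable_errors(self, rng):
        data = toy_data(rng, 200)
        y = (rng.random(200) < 0.7).astype(float)
        fit = md.fit_logistic(data, y, md.ModelSpec(1))
        with pytest.raises(KeyError):
            md.average_marginal_effect(fit, md.ENV_L, 0.1)


class TestBootstrap:
    def test_reproducible_with_seed(self, rng):
        data = toy_data(rng, 250)
        eta = 1.0 + 2 * data["temperature_trend"]
        y = (rng.random(250) < expit(eta)).astype(float)
        fit = md.fit_logistic(data, y, md.ModelSpec(3))
        ci1, _, _ = md.bootstrap_ci(fit, n_sim=30, rng=99)
        ci2, _, _ = md.bootstrap_ci(fit, n_sim=30, rng=99)
        pd.testing.assert_frame_equal(ci1, ci2)

    def test_interval_brackets_estimate(self, rng):
        data = toy_data(rng, 400)
        eta = 0.5 + 3 * data["temperature_trend"]
        y = (rng.random(400) < expit(eta)).astype(float)
        fit = md.fit_logistic(data, y, md.ModelSpec(3))
        ci, _, failed = md.bootstrap_ci(fit, n_sim=50, rng=1)
        assert failed < 10
        b = fit.params["temperature_trend"]
        assert ci.loc["temperature_trend", "lo"] < b < \
            ci.loc["temperature_trend", "hi"]


class TestCollinearity:
    def test_identical_vectors(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        rep = md.collinearity_report(t)
        assert rep.iloc[0]["r"] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        t = pd.DataFrame({"a": [-1.0, 1, -1, 1], "b": [-1.0, -1, 1, 1]})
        assert md.collinearity_report(t).iloc[0]["r"] == pytest.approx(0.0)

    def test_matches_hand_formula(self):
        a = np.array([1.0, 2, 4, 3, 7])
        b = np.array([2.0, 1, 5, 4, 6])
        rep = md.collinearity_report(pd.DataFrame({"a": a, "b": b}))
        r_hand = (((a - a.mean()) * (b - b.mean())).sum()
                  / np.sqrt(((a - a.mean()) ** 2).sum()
                            * ((b - b.mean()) ** 2).sum()))
        row = rep.iloc[0]
        assert row["r"] == pytest.approx(r_hand, abs=1e-12)
        assert row["df"] == 3
        from scipy import stats as st
        t_stat = r_hand * np.sqrt(3) / np.sqrt(1 - r_hand ** 2)
        p_hand = 2 * st.t.sf(abs(t_stat), 3)
        assert row["p"] == pytest.approx(p_hand, abs=1e-10)

    def test_constant_flagged(self):
        t = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        assert np.isnan(md.collinearity_report(t).iloc[0]["r"])
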