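import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from fernfusion import (build_mesh, generate_domain, get_config,
                        joint_loglik, loglik_counts, loglik_presence,
                        projector, redistribute_counts)
from fernfusion.likelihood import (assemble_predictor, cloglog_derivs,
                                   cloglog_logpmf, count_family_derivs,
                                   negbin_logpmf, poisson_logpmf, year_codes)
from fernfusion.observations import _largest_remainder


class TestRedistribution:
    domain = generate_domain(0, 400, 100, 2)

    def _counts(self, pop="p1", species=0, year=2014, count=10.0):
        return pd.DataFrame([{"population": pop, "species": species,
                              "year": year, "count": count}])

    def test_population_within_one_cell(self):
        poly = box(10, 10, 60, 60)
        out = redistribute_counts(self._counts(), {"p1": poly}, self.domain)
        assert len(out) == 1
        assert out.iloc[0]["count"] == 10
        assert out.iloc[0]["area"] == pytest.approx(2500.0)

    def test_even_split_symmetric(self):
        poly = box(50, 10, 150, 60)  # straddles cells 0 and 1 evenly
        out = redistribute_counts(self._counts(), {"p1": poly}, self.domain)
        assert sorted(out["count"]) == [5, 5]

    def test_largest_remainder_rounding(self):
        # 7 split 0.6/0.4 -> exact shares 4.2/2.8 -> 4 and 3
        assert list(_largest_remainder(7, np.array([0.6, 0.4]))) == [4, 3]
        rng = np.random.default_rng(8)
        for _ in range(50):
            w = rng.dirichlet(np.ones(5))
            total = int(rng.integers(0, 100))
            alloc = _largest_remainder(total, w)
            assert alloc.sum() == total
            assert (alloc >= np.floor(total * w)).all()

    def test_missing_year_propagates(self):
        counts = self._counts(count=np.nan)
        poly = box(10, 10, 60, 60)
        out = redistribute_counts(counts, {"p1": poly}, self.domain)
        assert out["missing"].all() and out["count"].isna().all()

    def test_no_intersection_rejected(self):
        poly = box(5000, 5000, 5100, 5100)
        with pytest.raises(ValueError):
            redistribute_counts(self._counts(), {"p1": poly}, self.domain)


class TestPredictorAssembly:
    domain = generate_domain(0, 400, 100, 3)
    mesh = build_mesh(domain.boundary, max_edge_inner=200,
                      max_edge_outer=400, extension=200, cutoff=40)
    A = projector(mesh, domain.centroids)
    X = np.linspace(-1, 1, domain.n_cells)[:, None]

    def _state(self):
        rng = np.random.default_rng(3)
        n, T = self.mesh.n_nodes, 3
        return {"beta": np.array([0.5]), "intercepts": np.array([-1., 0., 1.]),
                "u": rng.standard_normal(n * T),
                "delta": rng.standard_normal((3, n * T)),
                "omega": rng.standard_normal(n),
                "svc_scales": np.array([1.0, 0.7, -0.2])}

    def test_zero_state_zero_eta(self):
        cfg = get_config("M21")
        state = {"beta": np.zeros(1), "intercepts": np.zeros(3),
                 "u": np.zeros(self.mesh.n_nodes * 3),
                 "delta": np.zeros((3, self.mesh.n_nodes * 3))}
        eta = assemble_predictor(cfg, state, self.X, self.A,
                                 self.domain.years)
        assert np.all(eta == 0.0)

    def test_fixed_effect_linearity(self):
        cfg = get_config("M21")
        state = self._state()
        eta0 = assemble_predictor(cfg, state, self.X, self.A,
                                  self.domain.years)
        state2 = dict(state, beta=state["beta"] + 2.0)
        eta1 = assemble_predictor(cfg, state2, self.X, self.A,
                                  self.domain.years)
        shift = 2.0 * self.X[:, 0]
        assert np.allclose(eta1 - eta0, shift[None, :, None], atol=1e-12)

    def test_single_cell_hand_computation(self):
        cfg = get_config("M19")  # all components incl. SVC active
        state = self._state()
        eta = assemble_predictor(cfg, state, self.X, self.A,
                                 self.domain.years)
        j, c, t = 1, 5, 2
        n = self.mesh.n_nodes
        a = self.A[c].toarray().ravel()
        tc = year_codes(self.domain.years)[t]
        by_hand = (self.X[c, 0] * 0.5 + state["intercepts"][j]
                   + a @ state["u"][t * n:(t + 1) * n]
                   + a @ state["delta"][j][t * n:(t + 1) * n]
                   + 0.7 * (a @ state["omega"]) * tc)
        assert eta[j, c, t] == pytest.approx(by_hand, abs=1e-12)

    def test_inactive_components_contribute_nothing(self):
        cfg = get_config("M3")  # shared ST only
        state = self._state()
        eta_full = assemble_predictor(cfg, state, self.X, self.A,
                                      self.domain.years)
        slim = {k: state[k] for k in ("beta", "intercepts", "u")}
        eta_slim = assemble_predictor(cfg, slim, self.X, self.A,
                                      self.domain.years)
        assert np.allclose(eta_full, eta_slim, atol=1e-15)


class TestCountLikelihood:
    def test_poisson_closed_form(self):
        # y=2, mu=3: log pmf = 2 log 3 - 3 - log 2
        val = poisson_logpmf(2.0, np.log(3.0))
        assert val == pytest.approx(2 * np.log(3) - 3 - np.log(2), abs=1e-12)

    def test_offset_doubling_law(self):
        counts = pd.DataFrame({"species": [0], "count": [4.0],
                               "area": [100.0], "missing": [False]})
        c2 = counts.assign(area=200.0)
        eta = np.array([0.3])
        l1 = loglik_counts(counts, eta, psi=None)
        # doubling the area adds log 2 to log mu: same as adding log2 to eta
        l2 = loglik_counts(c2, eta - np.log(2.0), psi=None)
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_negbin_poisson_limit(self):
        y, log_mu = 7.0, np.log(5.0)
        nb = negbin_logpmf(y, log_mu, psi=1e6)
        po = poisson_logpmf(y, log_mu)
        assert nb == pytest.approx(po, abs=1e-4)

    def test_negbin_matches_scipy(self):
        from scipy.stats import nbinom
        psi, mu, y = 2.5, 4.0, 6
        p = psi / (psi + mu)
        assert negbin_logpmf(float(y), np.log(mu), psi) == pytest.approx(
            nbinom.logpmf(y, psi, p), abs=1e-10)

    def test_derivatives_match_finite_differences(self):
        h, h2 = 1e-6, 1e-4  # larger step for the curvature (cancellation)
        for fam, psi in (("poisson", None), ("negbin", 0.8)):
            for y in (0.0, 3.0):
                _, g, w = count_family_derivs(y, 0.4, np.log(50.0), fam, psi)
                lp, _, _ = count_family_derivs(y, 0.4 + h, np.log(50.0), fam,
                                               psi)
                lm, _, _ = count_family_derivs(y, 0.4 - h, np.log(50.0), fam,
                                               psi)
                assert g == pytest.approx((lp - lm) / (2 * h), rel=1e-4)
                ll, _, _ = count_family_derivs(y, 0.4, np.log(50.0), fam, psi)
                lp, _, _ = count_family_derivs(y, 0.4 + h2, np.log(50.0),
                                               fam, psi)
                lm, _, _ = count_family_derivs(y, 0.4 - h2, np.log(50.0),
                                               fam, psi)
                assert -w == pytest.approx((lp - 2 * ll + lm) / h2 ** 2,
                                           rel=1e-3)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"species": [0], "count": [-1.0],
                               "area": [10.0], "missing": [False]})
        with pytest.raises(ValueError):
            loglik_counts(counts, np.zeros(1), psi=None)

    def test_missing_rows_contribute_zero(self):
        counts = pd.DataFrame({"species": [0, 0], "count": [4.0, np.nan],
                               "area": [10.0, 10.0],
                               "missing": [False, True]})
        both = loglik_counts(counts, np.zeros(2), psi=None)
        one = loglik_counts(counts.iloc[[0]], np.zeros(1), psi=None)
        assert both == pytest.approx(one, abs=1e-12)


class TestPresenceLikelihood:
    def test_eta_zero_probability(self):
        # p = 1 - e^{-1}
        val = cloglog_logpmf(1.0, 0.0)
        assert val == pytest.approx(np.log(1 - np.exp(-1)), abs=1e-12)
        assert np.exp(val) == pytest.approx(0.632121, abs=1e-6)

    def test_absence_contribution(self):
        eta = 0.7
        assert cloglog_logpmf(0.0, eta) == pytest.approx(-np.exp(eta),
                                                         abs=1e-12)

    def test_batch_matches_bernoulli_oracle(self):
        rng = np.random.default_rng(9)
        eta = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40).astype(float)
        p = 1 - np.exp(-np.exp(eta))
        oracle = np.where(y > 0, np.log(p), np.log1p(-p))
        pres = pd.DataFrame({"presence": y})
        ours = loglik_presence(pres, eta, pointwise=True)
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_monotone_in_eta(self):
        # below the float-saturation point of p = 1 - exp(-exp(eta))
        etas = np.linspace(-4, 1.2, 100)
        p = 1 - np.exp(-np.exp(etas))
        assert np.all(np.diff(p) > 0)

    def test_derivatives_match_finite_differences(self):
        h = 1e-6
        for y in (0.0, 1.0):
            ll, g, w = cloglog_derivs(np.array([y]), np.array([0.3]))
            lp = cloglog_logpmf(y, 0.3 + h)
            lm = cloglog_logpmf(y, 0.3 - h)
            assert g[0] == pytest.approx((lp - lm) / (2 * h), rel=1e-4)

    def test_extreme_eta_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            val = cloglog_logpmf(1.0, 10.0)
        assert np.isfinite(val)


class TestJointLikelihood:
    def test_fusion_off_drops_presence_with_warning(self):
        cfg = get_config("M21")
        with pytest.warns(RuntimeWarning):
            out = joint_loglik(cfg, {"counts": -10.0, "presence": -5.0})
        assert out["total"] == pytest.approx(-10.0)
        assert "presence" not in out

    def test_additive_decomposition(self):
        cfg = get_config("M13")
        parts = {"counts": -10.0, "presence": -5.0, "field_u": -2.5,
                 "priors": -1.25}
        out = joint_loglik(cfg, parts)
        assert out["total"] == pytest.approx(sum(parts.values()), abs=1e-12)

    def test_two_cell_toy_matches_scalar_oracle(self):
        # 2 cells, 2 years, 2 species; fully hand-computed scalar evaluation
        cfg = get_config("M9")
        counts = pd.DataFrame({
            "species": [0, 1], "count": [3.0, 2.0], "area": [100.0, 50.0],
            "missing": [False, False]})
        pres = pd.DataFrame({"presence": [1.0, 0.0]})
        eta_c = np.array([0.2, -0.1])
        eta_p = np.array([0.5, -0.5])
        psi = 2.0
        lc = loglik_counts(counts, eta_c, psi,
                           families=("poisson", "negbin"))
        lp = loglik_presence(pres, eta_p)
        out = joint_loglik(cfg, {"counts": lc, "presence": lp})
        mu0 = 100 * np.exp(0.2)
        hand_pois = 3 * np.log(mu0) - mu0 - np.log(6)
        mu1 = 50 * np.exp(-0.1)
        from scipy.stats import nbinom
        hand_nb = nbinom.logpmf(2, psi, psi / (psi + mu1))
        p1 = 1 - np.exp(-np.exp(0.5))
        hand_pres = np.log(p1) - np.exp(-0.5)
        assert out["total"] == pytest.approx(hand_pois + hand_nb + hand_pres,
                                             abs=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame({
            "species": rng.integers(0, 3, 30),
            "count": rng.poisson(5, 30).astype(float),
            "area": rng.uniform(10, 100, 30), "missing": False})
        eta = rng.normal(0, 0.5, 30)
        base = loglik_counts(counts, eta, psi=1.5)
        perm = rng.permutation(30)
        shuffled = loglik_counts(counts.iloc[perm].reset_index(drop=True),
                                 eta[perm], psi=1.5)
        assert base == pytest.approx(shuffled, abs=1e-10)
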