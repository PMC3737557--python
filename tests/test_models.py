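"""Closed-form model equations: identities, limits, slopes and curvature."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddcbind.models import (
    BindingParams,
    DesignConstants,
    RetentionParams,
    enhancement_factor,
    fraction_bound,
    has_inflection,
    kc_from_params,
    loglog_slope,
    retention,
    rho_asymptotic,
    rho_complete,
    rho_ctsd,
    rho_langmuir,
)


class TestLangmuir:
    @pytest.mark.parametrize(
        "T, K_d, rho, f_B",
        [
            (1e-6, 1e-6, 1.0, 0.5),      # half saturation at T = K_d
            (0.0, 1e-6, 0.0, 0.0),       # no target, no binding
            (9e-6, 1e-6, 9.0, 0.9),      # f_B = T/(T+K_d)
        ],
    )
    def test_mass_action_identities(self, T, K_d, rho, f_B):
        assert rho_langmuir(T, K_d) == pytest.approx(rho)
        assert fraction_bound(rho_langmuir(T, K_d)) == pytest.approx(f_B)

    @pytest.mark.parametrize("rho, f", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.75)])
    def test_fraction_bound(self, rho, f):
        assert fraction_bound(rho) == pytest.approx(f)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rho_langmuir(1e-6, 0.0)
        with pytest.raises(ValueError):
            rho_langmuir(-1e-6, 1e-6)
        with pytest.raises(ValueError):
            fraction_bound(-0.1)


class TestAsymptotic:
    def test_no_cooperativity_collapses_to_langmuir(self):
        p = BindingParams(K_nc=2e-6, kappa_inf=0.0)
        T = np.geomspace(1e-9, 1e-4, 20)
        np.testing.assert_allclose(
            rho_asymptotic(T, 0.06, p), rho_langmuir(T, p.K_nc), rtol=1e-15
        )

    def test_unit_load_gives_e(self):
        # T/K_nc = 1 and kappa_inf*T/s = 1 --> rho = e
        T, s = 1e-6, 0.06
        p = BindingParams(K_nc=T, kappa_inf=s / T)
        assert float(rho_asymptotic(T, s, p)) == pytest.approx(math.e, abs=1e-12)

    def test_doubling_T_multiplies_by_2_exp_load(self):
        T, s = 3e-6, 0.05
        p = BindingParams(K_nc=1e-6, kappa_inf=4000.0)
        load = p.kappa_inf * T / s
        ratio = float(rho_asymptotic(2 * T, s, p) / rho_asymptotic(T, s, p))
        assert ratio == pytest.approx(2.0 * math.exp(load), rel=1e-12)

    def test_s_zero_with_positive_T_rejected(self):
        p = BindingParams(K_nc=1e-6, kappa_inf=100.0)
        with pytest.raises(ValueError):
            rho_asymptotic(1e-6, 0.0, p)


class TestComplete:
    @pytest.mark.parametrize("kappa, N", [(0.0, 4.0), (9000.0, 1.0)])
    def test_collapses_to_langmuir(self, kappa, N):
        # kappa = 0 (no cooperativity) or N = 1 (no extra sites)
        p = BindingParams(K_nc=5e-6, kappa=kappa, N=N)
        T = np.geomspace(1e-9, 1e-4, 20)
        np.testing.assert_allclose(
            rho_complete(T, 0.06, p), rho_langmuir(T, p.K_nc), rtol=1e-15
        )

    def test_large_N_approaches_asymptotic(self):
        T, s, K, kap = 5e-6, 0.06, 1e-6, 20000.0
        big = BindingParams(K_nc=K, kappa=kap, N=1e6)
        asym = BindingParams(K_nc=K, kappa_inf=kap)
        rel = abs(
            float(rho_complete(T, s, big)) / float(rho_asymptotic(T, s, asym)) - 1
        )
        assert rel < 1e-4

    def test_N_below_one_rejected(self):
        with pytest.raises(ValueError):
            BindingParams(K_nc=1e-6, kappa=100.0, N=0.5)


class TestCtsdLinearity:
    def test_rho_over_T_constant(self, coop_params, consts):
        T = np.geomspace(1e-9, consts.T_star, 50)
        ratio = rho_ctsd(T, coop_params, consts) / T
        assert np.ptp(ratio) / ratio[0] < 1e-12

    def test_designs_coincide_at_T_star(self, coop_params, consts):
        top_ctsd = float(rho_ctsd(consts.T_star, coop_params, consts))
        top_vtsd = float(rho_complete(consts.T_star, consts.s_star, coop_params))
        assert top_ctsd == pytest.approx(top_vtsd, rel=1e-12)


class TestKcAndEnhancement:
    def test_kappa_zero_keeps_K_nc(self, consts):
        p = BindingParams(K_nc=3e-6, kappa=0.0, N=4.0)
        assert kc_from_params(p, consts) == pytest.approx(p.K_nc)
        assert enhancement_factor(p, consts) == pytest.approx(1.0)

    def test_two_site_halving(self):
        # N = 2 with unit per-slot load: K_c = K_nc / (1+1)^(2-1) = K_nc/2
        consts = DesignConstants(s_star=0.06, T_star=50e-6)
        kappa = 2 * consts.s_star / consts.T_star  # kappa*T*/(N*s*) = 1
        p = BindingParams(K_nc=8e-6, kappa=kappa, N=2.0)
        assert kc_from_params(p, consts) == pytest.approx(p.K_nc / 2, rel=1e-12)

    def test_single_site_no_enhancement(self, consts):
        p = BindingParams(K_nc=1e-6, kappa=5000.0, N=1.0)
        assert enhancement_factor(p, consts) == pytest.approx(1.0)

    @given(
        kappa=st.floats(10.0, 1e5),
        K=st.floats(1e-7, 1e-4),
        N=st.floats(1.5, 12.0),
    )
    def test_enhancement_strictly_increasing_in_kappa(self, kappa, K, N):
        consts = DesignConstants(s_star=0.06, T_star=50e-6)
        p1 = BindingParams(K_nc=K, kappa=kappa, N=N)
        p2 = BindingParams(K_nc=K, kappa=2 * kappa, N=N)
        assert enhancement_factor(p2, consts) > enhancement_factor(p1, consts)
        assert kc_from_params(p1, consts) <= p1.K_nc


class TestRetention:
    def test_background_only_at_zero_target(self, coop_params, ret_params):
        assert retention(0.0, 0.06, coop_params, ret_params, "complete_ddc") == (
            pytest.approx(ret_params.b)
        )

    def test_saturation_approaches_r(self, consts):
        p = BindingParams(K_nc=1e-9, kappa=0.0, N=1.0)
        ret = RetentionParams(b=0.02, r=0.8)
        val = float(retention(1e-2, 0.06, p, ret, "complete_ddc"))
        assert val == pytest.approx(ret.r, rel=1e-5)

    def test_ideal_assay_returns_f_B(self, coop_params):
        ideal = RetentionParams(b=0.0, r=1.0)
        T = np.geomspace(1e-8, 1e-4, 9)
        f_B = fraction_bound(rho_complete(T, 0.06, coop_params))
        np.testing.assert_allclose(
            retention(T, 0.06, coop_params, ideal, "complete_ddc"), f_B, rtol=1e-15
        )

    def test_bounded_by_b_and_r(self, coop_params, ret_params, rng):
        T = 10 ** rng.uniform(-9, -4, 50)
        vals = retention(T, 0.06, coop_params, ret_params, "complete_ddc")
        assert np.all(vals >= min(ret_params.b, ret_params.r) - 1e-15)
        assert np.all(vals <= max(ret_params.b, ret_params.r) + 1e-15)

    def test_unknown_model_rejected(self, coop_params, ret_params):
        with pytest.raises(ValueError):
            retention(1e-6, 0.06, coop_params, ret_params, "hill")


class TestLoglogSlope:
    def test_low_T_limit_is_one_for_all_models(self, coop_params):
        for model in ("langmuir", "asymptotic_ddc", "complete_ddc"):
            slope = float(loglog_slope(1e-15, 0.06, coop_params, model))
            assert slope == pytest.approx(1.0, abs=1e-6)

    def test_ctsd_slope_identically_one(self, coop_params):
        T = np.geomspace(1e-9, 5e-5, 7)
        np.testing.assert_array_equal(
            loglog_slope(T, 0.06, coop_params, "complete_ddc", design="ctsd"),
            np.ones_like(T),
        )

    def test_vtsd_complete_saturates_at_N(self, coop_params):
        slope = float(loglog_slope(1e3, 0.06, coop_params, "complete_ddc"))
        assert slope == pytest.approx(coop_params.N, rel=1e-6)

    @pytest.mark.parametrize("model", ["asymptotic_ddc", "complete_ddc"])
    def test_matches_central_difference(self, model, coop_params):
        # analytic slope vs numerical d ln rho / d ln T
        s = 0.06
        for T in (1e-7, 2e-6, 3e-5):
            h = 1e-6
            lo = np.log(
                rho_complete(T * (1 - h), s, coop_params)
                if model == "complete_ddc"
                else rho_asymptotic(T * (1 - h), s, coop_params)
            )
            hi = np.log(
                rho_complete(T * (1 + h), s, coop_params)
                if model == "complete_ddc"
                else rho_asymptotic(T * (1 + h), s, coop_params)
            )
            num = float((hi - lo) / (np.log1p(h) - np.log1p(-h)))
            ana = float(loglog_slope(T, s, coop_params, model))
            assert ana == pytest.approx(num, rel=1e-6)

    def test_nonpositive_T_rejected(self, coop_params):
        with pytest.raises(ValueError):
            loglog_slope(0.0, 0.06, coop_params, "langmuir")


class TestInflection:
    def test_langmuir_never_inflects(self):
        p = BindingParams(K_nc=1e-6)
        assert has_inflection(p, 0.06, "langmuir") == (False, None)
        p0 = BindingParams(K_nc=1e-6, kappa_inf=0.0)
        assert has_inflection(p0, 0.06, "asymptotic_ddc") == (False, None)

    def test_strong_cooperativity_inflects(self):
        # kappa_inf*K_nc/s >> 1: convex onset at low T, so an inflection exists
        p = BindingParams(K_nc=1e-4, kappa_inf=5e4)
        flag, T_inf = has_inflection(p, 0.06, "asymptotic_ddc")
        assert flag and T_inf is not None and T_inf > 0

    def test_inflection_location_is_a_curvature_root(self):
        p = BindingParams(K_nc=5e-5, kappa=3e4, N=4.0)
        flag, T_inf = has_inflection(p, 0.06, "complete_ddc")
        assert flag
        # second derivative of f_B by central differences changes sign at T_inf

        def f_B(T):
            return float(fraction_bound(rho_complete(T, 0.06, p)))

        h = T_inf * 1e-3
        d2 = (f_B(T_inf + h) - 2 * f_B(T_inf) + f_B(T_inf - h)) / h**2
        d2_lo = (f_B(T_inf * 0.5 + h) - 2 * f_B(T_inf * 0.5) + f_B(T_inf * 0.5 - h)) / h**2
        assert abs(d2) < abs(d2_lo) * 1e-2  # nearly zero at the detected root

    def test_threshold_monotone_in_kappa_inf(self, rng):
        # if an inflection exists at kappa_inf, it exists at any larger value
        for _ in range(20):
            K = 10 ** rng.uniform(-7, -4)
            kaps = np.sort(10 ** rng.uniform(1, 6, 4))
            flags = [
                has_inflection(
                    BindingParams(K_nc=K, kappa_inf=k), 0.06, "asymptotic_ddc"
                )[0]
                for k in kaps
            ]
            # once True, stays True
            assert flags == sorted(flags)


class TestDesignInequality:
    def test_ctsd_binds_more_than_vtsd_interior(self, rng):
        # constant high TSD beats varying TSD at every interior T
        consts = DesignConstants(s_star=0.06, T_star=50e-6)
        T = np.geomspace(1e-9, consts.T_star * 0.999, 25)
        for _ in range(50):
            p = BindingParams(
                K_nc=10 ** rng.uniform(-6, -4),
                kappa=10 ** rng.uniform(2, 4.7),
                N=rng.uniform(1.5, 8.0),
            )
            # rho scale avoids float saturation of f_B at 1.0; monotone map
            assert np.all(rho_ctsd(T, p, consts) > rho_complete(T, consts.s_star, p))

    def test_rho_strictly_increasing_in_T(self, coop_params):
        T = np.geomspace(1e-9, 1e-3, 200)
        for model in ("asymptotic_ddc", "complete_ddc"):
            r = (
                rho_complete(T, 0.06, coop_params)
                if model == "complete_ddc"
                else rho_asymptotic(T, 0.06, coop_params)
            )
            assert np.all(np.diff(r) > 0)
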