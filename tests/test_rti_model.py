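"""Forward point-source model: closed forms, limits, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from ecsastro.rti_model import (DiffusionParams, SourceConfig, concentration_on,
                                concentration_pulse, source_rate, steady_state)
from ecsastro.units import FARADAY, mM_to_mol_per_cm3, um_to_cm


class TestSourceRate:
    def test_hand_evaluation(self):
        cfg = SourceConfig(i_step=200e-9, i_bias=0.0)
        q = source_rate(cfg, n_transport=0.5, use_step_only=False)
        assert q == pytest.approx(200e-9 * 0.5 / FARADAY)
        assert q == pytest.approx(1.0364e-12, rel=1e-4)

    def test_zero_transport_number(self):
        cfg = SourceConfig()
        assert source_rate(cfg, n_transport=0.0, use_step_only=False) == 0.0

    def test_bias_superposition_scales_linearly(self):
        cfg = SourceConfig(i_step=200e-9, i_bias=20e-9)
        q_step = source_rate(cfg, n_transport=0.4, use_step_only=True)
        q_full = source_rate(cfg, n_transport=0.4, use_step_only=False)
        assert q_step / q_full == pytest.approx(180.0 / 200.0)

    def test_invalid_source_config_rejected(self):
        # step current must exceed the bias
        with pytest.raises(ValueError):
            SourceConfig(i_step=20e-9, i_bias=20e-9)
        with pytest.raises(ValueError):
            SourceConfig(duration_s=0.0)


class TestConcentrationOn:
    def test_zero_at_t0(self, tissue_params):
        assert concentration_on(0.01, 0.0, 1e-12, tissue_params) == 0.0

    def test_free_medium_closed_form(self, free_params):
        """alpha=1, lam=1, k'=0 reduces to Q/(4πDr)·erfc(r/(2√(Dt)))."""
        Q = 1e-12
        r_grid = um_to_cm(np.linspace(50, 200, 10))
        t_grid = np.geomspace(0.5, 200, 10)
        for r in r_grid:
            c = concentration_on(r, t_grid, Q, free_params)
            expected = (Q / (4 * np.pi * free_params.D * r)
                        * erfc(r / (2 * np.sqrt(free_params.D * t_grid))))
            np.testing.assert_allclose(c, expected, rtol=1e-12)

    def test_monotone_in_time_and_distance(self, tissue_params):
        Q = 1e-12
        t = np.linspace(0.5, 100, 50)
        c = concentration_on(0.01, t, Q, tissue_params)
        assert np.all(np.diff(c) > 0)
        r = um_to_cm(np.linspace(50, 300, 30))
        c_r = np.array([concentration_on(ri, 24.0, Q, tissue_params) for ri in r])
        assert np.all(np.diff(c_r) < 0)

    @pytest.mark.parametrize("field,lo,hi", [
        ("kprime", 1e-3, 2e-2),
        ("alpha", 0.1, 0.4),
    ])
    def test_monotone_decreasing_in_uptake_and_alpha(self, field, lo, hi):
        base = dict(alpha=0.2, lam=1.6, kprime=5e-3, D=1.2e-5, n_transport=0.35)
        vals = []
        for x in np.linspace(lo, hi, 5):
            p = DiffusionParams(**{**base, field: x})
            vals.append(concentration_on(0.01, 24.0, 1e-12, p))
        assert np.all(np.diff(vals) < 0)

    def test_overflow_regime_is_finite(self):
        """rλ√(k'/D) > 700 must not overflow (erfcx evaluation)."""
        p = DiffusionParams(alpha=0.05, lam=3.0, kprime=0.1, D=1e-7,
                            n_transport=0.35)
        r = 0.3
        assert p.lam * r * np.sqrt(p.kprime / p.D) > 700
        c = concentration_on(r, np.array([0.1, 1.0, 1e3, 1e7]), 1e-12, p)
        assert np.all(np.isfinite(c))
        assert np.all(c >= 0)

    def test_r_zero_and_unphysical_r_rejected(self, tissue_params):
        with pytest.raises(ValueError):
            concentration_on(0.0, 1.0, 1e-12, tissue_params)
        with pytest.raises(ValueError):
            concentration_on(um_to_cm(0.5), 1.0, 1e-12, tissue_params)


class TestPulse:
    def test_full_decay_returns_baseline(self, source, tissue_params):
        c = concentration_pulse(source.r, 1e7, source, tissue_params)
        assert c == pytest.approx(source.c_baseline, rel=1e-6)

    def test_continuity_at_pulse_end(self, source, tissue_params):
        eps = 1e-9
        before = concentration_pulse(source.r, source.duration_s - eps,
                                     source, tissue_params)
        after = concentration_pulse(source.r, source.duration_s + eps,
                                    source, tissue_params)
        assert after == pytest.approx(before, rel=1e-6)

    def test_free_medium_decay_is_erfc_difference(self, source, free_params):
        """At t = 2·duration the off-phase equals two free-medium terms."""
        t = 2 * source.duration_s
        Q = source_rate(source, n_transport=free_params.n_transport)
        D, r = free_params.D, source.r
        amp = Q / (4 * np.pi * D * r)
        expected = (amp * erfc(r / (2 * np.sqrt(D * t)))
                    - amp * erfc(r / (2 * np.sqrt(D * (t - source.duration_s)))))
        got = concentration_pulse(r, t, source, free_params) - source.c_baseline
        assert got == pytest.approx(expected, rel=1e-12)

    def test_superposition_identity(self, source, tissue_params):
        """pulse(t) + on(t − dur) == baseline + on(t) exactly for t > dur."""
        Q = source_rate(source, n_transport=tissue_params.n_transport)
        t = np.linspace(source.duration_s + 0.1, 120, 40)
        lhs = (concentration_pulse(source.r, t, source, tissue_params)
               + concentration_on(source.r, t - source.duration_s, Q, tissue_params))
        rhs = source.c_baseline + concentration_on(source.r, t, Q, tissue_params)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-13)


class TestSteadyState:
    def test_no_uptake_form_and_r_scaling(self, free_params):
        Q = 1e-12
        r = 0.01
        assert steady_state(r, Q, free_params) == pytest.approx(
            Q / (4 * np.pi * free_params.D * r))
        assert steady_state(2 * r, Q, free_params) == pytest.approx(
            steady_state(r, Q, free_params) / 2)

    def test_limit_consistency_with_uptake(self, tissue_params):
        """With uptake the transient converges exponentially fast."""
        Q = 1e-12
        c_inf = steady_state(0.01, Q, tissue_params)
        c_t = concentration_on(0.01, 1e6, Q, tissue_params)
        assert c_t == pytest.approx(c_inf, rel=1e-6)

    def test_limit_consistency_without_uptake(self, free_params):
        """k'=0 converges like erfc(r/2√(Dt)) — algebraically, not exp."""
        Q = 1e-12
        r = 0.01
        c_inf = steady_state(r, Q, free_params)
        t = 1e10
        expected_ratio = erfc(r / (2 * np.sqrt(free_params.D * t)))
        assert concentration_on(r, t, Q, free_params) / c_inf == pytest.approx(
            expected_ratio, rel=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(alpha=st.floats(0.05, 1.0), lam=st.floats(1.0, 3.0),
       kprime=st.floats(0.0, 0.1), t=st.floats(0.01, 500.0))
def test_concentration_nonnegative_and_below_steady_state(alpha, lam, kprime, t):
    """0 <= C(r,t) <= C(r,∞) for any admissible parameters."""
    p = DiffusionParams(alpha=alpha, lam=lam, kprime=kprime, D=1.2e-5,
                        n_transport=0.35)
    c = concentration_on(0.008, t, 1e-12, p)
    assert 0.0 <= c <= steady_state(0.008, 1e-12, p) * (1 + 1e-9)


class TestUnits:
    def test_roundtrips(self):
        assert um_to_cm(100.0) == pytest.approx(0.01)
        assert mM_to_mol_per_cm3(0.1) == pytest.approx(1e-7)


class TestValidation:
    def test_param_invariants(self):
        with pytest.raises(ValueError):
            DiffusionParams(alpha=0.0, lam=1.6, kprime=0, D=1e-5, n_transport=0.3)
        with pytest.raises(ValueError):
            DiffusionParams(alpha=0.2, lam=0.9, kprime=0, D=1e-5, n_transport=0.3)
        with pytest.raises(ValueError):
            DiffusionParams(alpha=0.2, lam=1.6, kprime=-1e-3, D=1e-5,
                            n_transport=0.3)

    def test_free_medium_constructor(self):
        p = DiffusionParams.free_medium(1.2e-5, 0.4)
        assert (p.alpha, p.lam, p.kprime) == (1.0, 1.0, 0.0)
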