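"""Hill regulation, secretion/growth rates, and the named circuit schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphogrow.circuits import (
    Chemical,
    Circuit,
    CircuitError,
    GrowthLink,
    SecretionLink,
    build_named_scheme,
    growth_rate,
    hill,
    secretion_rate,
)


class TestHill:
    @pytest.mark.parametrize("c,K,n,expected,tol", [
        (1.0, 1.0, 100, 0.5, 1e-12),            # midpoint of any Hill curve
        (2.0, 2.0, -100, 0.5, 1e-12),
        (0.0, 1.0, -100, 1.0, 1e-12),           # absent inhibitor: no inhibition
        (0.0, 1.0, 100, 0.0, 1e-12),            # absent activator: no activation
        (1.1, 1.0, -100, 1.0 / (1.0 + 1.1**100), 1e-9),   # ≈ 7.26e-5
        (0.5, 1.0, 0, 1.0, 0),                  # n = 0: does not participate
    ])
    def test_values(self, c, K, n, expected, tol):
        assert hill(c, K, n) == pytest.approx(expected, abs=tol)

    def test_negative_concentration_rejected(self):
        with pytest.raises(CircuitError):
            hill(-0.1, 1.0, 100)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c1=st.floats(0.0, 10.0), c2=st.floats(0.0, 10.0),
           K=st.floats(0.1, 5.0), n=st.sampled_from([-100, -2, 2, 100]))
    def test_monotone_and_bounded(self, c1, c2, K, n):
        lo, hi = sorted([c1, c2])
        h_lo, h_hi = hill(lo, K, n), hill(hi, K, n)
        assert 0.0 <= h_lo <= 1.0 and 0.0 <= h_hi <= 1.0
        if n > 0:
            assert h_lo <= h_hi + 1e-12
        else:
            assert h_lo >= h_hi - 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(K=st.floats(0.2, 5.0), ratio=st.floats(0.0, 3.0).filter(
        lambda r: abs(r - 1.0) > 0.1))
    def test_threshold_regime(self, K, ratio):
        """At |n| = 100 the Hill curve is a threshold function to within 1%
        whenever c is more than 10% away from the threshold."""
        c = ratio * K
        step_up = 1.0 if c > K else 0.0
        assert abs(hill(c, K, 100) - step_up) < 1e-2
        assert abs(hill(c, K, -100) - (1.0 - step_up)) < 1e-2


class TestRates:
    def test_single_inhibitor_secretes_constantly(self):
        circ = build_named_scheme("single_inhibitor", {"mu_X": 8.0})
        for cX in (0.0, 0.5, 5.0):
            assert secretion_rate(circ, "X", {"X": cX}) == pytest.approx(8.0)

    def test_two_inhibitors_Y_shut_off_above_threshold(self):
        circ = build_named_scheme("two_inhibitors",
                                  {"mu_X": 8, "mu_Y0": 65, "Ks": 1, "gamma_r": 1})
        assert secretion_rate(circ, "Y", {"X": 1.2}) < 1e-7 * 65
        assert secretion_rate(circ, "Y", {"X": 0.5}) == pytest.approx(65.0, rel=1e-9)

    def test_secretion_max_clamp(self):
        """μ̃_max = mu0·max(1 + b·c̃, 0) clamps to zero at c̃ = −1/b."""
        circ = build_named_scheme("threshold_regulator",
                                  {"mu_X": 8, "mu_Y0": 48, "Ks": 2.0,
                                   "gamma_r": 0.2, "b": -0.8})
        assert secretion_rate(circ, "Y", {"X": 1.25}) == 0.0
        assert secretion_rate(circ, "Y", {"X": 0.0}) == pytest.approx(48.0)

    def test_missing_concentration_raises(self):
        circ = build_named_scheme("two_inhibitors",
                                  {"mu_X": 8, "mu_Y0": 65, "Ks": 1, "gamma_r": 1})
        with pytest.raises(CircuitError):
            secretion_rate(circ, "Y", {})
        with pytest.raises(CircuitError):
            growth_rate(circ, {"X": 0.5})

    def test_growth_step_behaviour(self):
        circ = build_named_scheme("single_inhibitor", {"mu_X": 8.0})
        assert growth_rate(circ, {"X": 0.5}) >= 1 - 1e-12
        assert growth_rate(circ, {"X": 2.0}) < 1e-20

    def test_threshold_modifier_lowers_growth_threshold(self):
        circ = build_named_scheme("threshold_regulator",
                                  {"mu_X": 8, "mu_Y0": 48, "Ks": 0.9,
                                   "gamma_r": 0.2, "b": -0.8})
        # c̃Y = 0.5 halves the effective threshold: c̃X = 0.7 now inhibits
        assert growth_rate(circ, {"X": 0.7, "Y": 0.5}) < 1e-10
        assert growth_rate(circ, {"X": 0.3, "Y": 0.5}) > 1 - 1e-10
        # threshold clamps at zero when c̃Y ≥ 1
        assert growth_rate(circ, {"X": 0.1, "Y": 1.5}) < 1e-10

    def test_rates_vectorize_over_arrays(self):
        circ = build_named_scheme("two_inhibitors",
                                  {"mu_X": 8, "mu_Y0": 65, "Ks": 1, "gamma_r": 1})
        cX = np.array([0.5, 1.5])
        mu = secretion_rate(circ, "Y", {"X": cX})
        assert mu.shape == (2,)
        assert mu[0] == pytest.approx(65.0, rel=1e-9) and mu[1] < 1e-5
        g = growth_rate(circ, {"X": cX, "Y": np.array([0.2, 0.2])})
        assert g[0] > 0.99 and g[1] < 1e-10


class TestSchemes:
    def test_none_scheme_grows_everywhere(self):
        circ = build_named_scheme("none")
        assert growth_rate(circ, {}) == 1.0

    def test_unknown_scheme_and_missing_params(self):
        with pytest.raises(CircuitError):
            build_named_scheme("mystery")
        with pytest.raises(CircuitError):
            build_named_scheme("two_inhibitors", {"mu_X": 8})

    def test_fig4_configuration(self):
        circ = build_named_scheme("two_inhibitors",
                                  {"mu_X": 8, "mu_Y0": 65, "Ks": 1, "gamma_r": 1})
        X, Y = circ.chemical("X"), circ.chemical("Y")
        assert (X.mu0, X.gamma_r) == (8.0, 1.0)
        assert (Y.mu0, Y.gamma_r) == (65.0, 1.0)
        assert Y.secretion_links[0].Ks == 1.0
        assert len(circ.growth_links) == 2

    def test_cascade_2_equals_two_inhibitors(self):
        casc = build_named_scheme("inhibitor_cascade",
                                  {"q": 2, "mu": [8.0, 65.0], "Ks": 1.0,
                                   "gamma_r": [1.0, 1.0]})
        two = build_named_scheme("two_inhibitors",
                                 {"mu_X": 8, "mu_Y0": 65, "Ks": 1, "gamma_r": 1})
        rng = np.random.default_rng(0)
        for _ in range(10):
            c = {"X": rng.uniform(0, 2), "Y": rng.uniform(0, 2)}
            assert secretion_rate(casc, "Y", c) == pytest.approx(
                secretion_rate(two, "Y", c))
            assert growth_rate(casc, c) == pytest.approx(growth_rate(two, c))

    def test_order_invariance(self):
        """Growth and secretion rates do not depend on chemical ordering."""
        X = Chemical("X", mu0=8.0)
        Y = Chemical("Y", mu0=65.0, secretion_links=(SecretionLink("X", Ks=1.0),))
        links = (GrowthLink("X"), GrowthLink("Y"))
        a = Circuit(chemicals=(X, Y), growth_links=links)
        b = Circuit(chemicals=(Y, X), growth_links=links[::-1])
        c_vec = {"X": 0.8, "Y": 1.3}
        assert growth_rate(a, c_vec) == pytest.approx(growth_rate(b, c_vec))
        assert secretion_rate(a, "Y", c_vec) == pytest.approx(
            secretion_rate(b, "Y", c_vec))

    def test_cyclic_circuit_rejected(self):
        X = Chemical("X", mu0=1.0, secretion_links=(SecretionLink("Y", Ks=1.0),))
        Y = Chemical("Y", mu0=1.0, secretion_links=(SecretionLink("X", Ks=1.0),))
        with pytest.raises(CircuitError):
            Circuit(chemicals=(X, Y))

    def test_activator_scheme_roles(self):
        circ = build_named_scheme("activator_s2",
                                  {"mu_X0": 48, "mu_Y": 7 / 1.2, "gamma_r": 0.5})
        # growth requires the activator X above threshold
        assert growth_rate(circ, {"X": 1.5, "Y": 0.0}) > 1 - 1e-10
        assert growth_rate(circ, {"X": 0.5, "Y": 0.0}) < 1e-10
        # Y shuts down X secretion above its threshold
        assert secretion_rate(circ, "X", {"Y": 1.5}) < 1e-5
        assert circ.secretion_order() == ["Y", "X"]

    def test_invalid_chemical_parameters(self):
        with pytest.raises(CircuitError):
            Chemical("X", mu0=-1.0)
        with pytest.raises(CircuitError):
            Chemical("X", mu0=1.0, gamma_r=0.0)
        with pytest.raises(CircuitError):
            Chemical("X", mu0=1.0, b=0.5, b_regulator="X")
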