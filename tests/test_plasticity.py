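"""Hebbian LTP/LTD rule: branch semantics, clipping, and association
growth on a driven network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hebbca import DynamicsParams, PlasticityParams, Simulator, hebbian_update


@pytest.fixture()
def params():
    return PlasticityParams(
        delta_w=0.01, theta_pre=0.1, theta_plus=0.2, theta_minus=0.05, w_max=1.0
    )


def literal_rule(w, o, v, p):
    """Direct transcription of the four-branch conditional (test oracle)."""
    if o >= p.theta_pre and v >= p.theta_plus:
        w = w + p.delta_w
    elif o >= p.theta_pre and p.theta_minus <= v < p.theta_plus:
        w = w - p.delta_w
    elif o < p.theta_pre and v >= p.theta_plus:
        w = w - p.delta_w
    return min(max(w, 0.0), p.w_max)


class TestHebbianUpdate:
    def test_ltp_at_inclusive_boundary(self, params):
        """Both thresholds met exactly: potentiation applies."""
        w = hebbian_update(0.5, params.theta_pre, params.theta_plus, params)
        assert w == pytest.approx(0.51)

    def test_no_change_when_pre_silent_and_post_in_ltd_band(self, params):
        w = hebbian_update(0.5, 0.0, 0.1, params)
        assert w == pytest.approx(0.5)

    def test_homosynaptic_ltd_at_lower_boundary(self, params):
        w = hebbian_update(0.5, 0.3, params.theta_minus, params)
        assert w == pytest.approx(0.49)

    def test_heterosynaptic_ltd(self, params):
        w = hebbian_update(0.5, 0.0, 0.9, params)
        assert w == pytest.approx(0.49)

    def test_clipping_at_floor_and_ceiling(self, params):
        assert hebbian_update(0.005, 0.0, 0.9, params) == 0.0
        assert hebbian_update(0.995, 0.9, 0.9, params) == params.w_max

    def test_truth_table_equivalence_on_grid(self, params):
        """Exhaustive comparison with the literal conditional oracle over a
        grid straddling all threshold boundaries."""
        os = np.array([0.0, 0.05, 0.1, 0.1 + 1e-9, 0.5, 1.0])
        vs = np.array([-0.5, 0.0, 0.05, 0.1, 0.2, 0.200001, 0.7])
        ws = np.array([0.0, 0.005, 0.5, 0.995, 1.0])
        for w in ws:
            for o in os:
                for v in vs:
                    got = float(hebbian_update(w, o, v, params))
                    want = literal_rule(w, o, v, params)
                    assert got == pytest.approx(want), (w, o, v)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(-1, 1.5)
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_literal_oracle_everywhere(self, w, o, v):
        p = PlasticityParams(delta_w=0.01, theta_pre=0.1, theta_plus=0.2,
                             theta_minus=0.05, w_max=1.0)
        assert float(hebbian_update(w, o, v, p)) == pytest.approx(
            literal_rule(w, o, v, p)
        )

    def test_vectorised_update_matches_scalar(self, params):
        rng = np.random.default_rng(0)
        w = rng.random(64)
        o = rng.random(64)
        v = rng.uniform(-0.5, 1.0, 64)
        out = hebbian_update(w, o, v, params)
        for k in range(64):
            assert out[k] == pytest.approx(literal_rule(w[k], o[k], v[k], params))


class TestNetworkPlasticity:
    def test_disabled_plasticity_leaves_weights_bit_identical(self, small_net):
        sim = Simulator(small_net, DynamicsParams(k2=1.0, Vb=0.1), seed=2)
        before = small_net.W_ee.data.copy()
        off = PlasticityParams(enabled=False)
        for _ in range(50):
            sim.step(plasticity=off)
        assert np.array_equal(before, small_net.W_ee.data)

    def test_quiescent_network_no_weight_changes(self, small_net, quiet_dynamics):
        sim = Simulator(small_net, quiet_dynamics, seed=2)
        before = small_net.W_ee.data.copy()
        p = PlasticityParams(delta_w=0.01, theta_pre=0.1, theta_plus=0.2,
                             theta_minus=0.05, w_max=1.0)
        for _ in range(50):
            sim.step(plasticity=p)
        assert np.array_equal(before, small_net.W_ee.data)

    def test_co_driven_links_gain_exactly_k_delta_w(self, small_net, quiet_dynamics):
        """Mutually linked cells held above both thresholds for k steps
        add exactly k * delta_w per link (below the ceiling)."""
        sim = Simulator(small_net, quiet_dynamics, seed=2)
        p = PlasticityParams(delta_w=0.001, theta_pre=0.5, theta_plus=0.5,
                             theta_minus=0.2, w_max=10.0)
        pre, post = small_net.edge_arrays()
        p1 = small_net.area_slice("P1")
        driven = np.arange(p1.start, p1.start + 10)
        stim = sim.stimulus_vector(driven, 50.0)
        before = small_net.W_ee.data.copy()
        # warm up so driven outputs and potentials are saturated, then
        # count steps in the fully-on state
        for _ in range(10):
            sim.step(stim=stim)
        w_start = small_net.W_ee.data.copy()
        k = 7
        for _ in range(k):
            sim.step(stim=stim, plasticity=p)
        both = np.isin(pre, driven) & np.isin(post, driven)
        assert both.any()
        gained = small_net.W_ee.data[both] - w_start[both]
        assert np.allclose(gained, k * p.delta_w)

    def test_paired_stimulation_strengthens_only_associated_sets(
        self, small_net, quiet_dynamics
    ):
        """Repeated co-activation raises the mean weight between the
        stimulated sets; weights onto unrelated quiet cells do not rise
        above their initial mean (heterosynaptic LTD may lower them)."""
        sim = Simulator(small_net, quiet_dynamics, seed=2)
        p = PlasticityParams(delta_w=0.002, theta_pre=0.1, theta_plus=0.1,
                             theta_minus=0.05, w_max=0.5)
        pre, post = small_net.edge_arrays()
        p1 = small_net.area_slice("P1")
        setA = np.arange(p1.start, p1.start + 8)
        stim = sim.stimulus_vector(setA, 50.0)
        before = small_net.W_ee.data.copy()
        for rep in range(30):
            sim.reset()
            for _ in range(8):
                sim.step(stim=stim, plasticity=p)
        within = np.isin(pre, setA) & np.isin(post, setA)
        quiet = ~np.isin(pre, setA) & ~np.isin(post, setA)
        d = small_net.W_ee.data
        assert d[within].mean() > before[within].mean() + 10 * p.delta_w
        assert d[quiet].mean() <= before[quiet].mean() + p.delta_w
        # restore pristine weights for other tests sharing the fixture
        small_net.W_ee.data[:] = before

    def test_weights_stay_in_bounds_on_noisy_trajectory(self, small_net):
        sim = Simulator(small_net, DynamicsParams(k2=2.0, Vb=0.1), seed=8)
        p = PlasticityParams(delta_w=0.05, theta_pre=0.05, theta_plus=0.05,
                             theta_minus=0.02, w_max=0.3)
        before = small_net.W_ee.data.copy()
        for _ in range(150):
            sim.step(plasticity=p)
            d = small_net.W_ee.data
            assert d.min() >= 0.0 and d.max() <= p.w_max
        small_net.W_ee.data[:] = before


def test_invalid_plasticity_params_rejected():
    with pytest.raises(ValueError):
        PlasticityParams(theta_pre=0.0).validate()
    with pytest.raises(ValueError):
        PlasticityParams(theta_minus=0.5, theta_plus=0.2).validate()
    with pytest.raises(ValueError):
        PlasticityParams(delta_w=1.0, w_max=0.5).validate()
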