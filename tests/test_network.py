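"""Connectivity, exact integration, single-neuron physics and synchrony flags."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spikemeta.network import (PopulationActivity, SimulationConfig,
                               build_connectivity, propagator, simulate,
                               synchrony_flags)
from spikemeta.parameters import (ParameterDomain, ParameterPoint,
                                  latin_hypercube_sample)


@pytest.fixture
def point():
    return ParameterPoint(eta=1.0, g=5.0, q_s=50.0, tau_m=20.0, c_m=200.0,
                          t_d=1.5, t_ref=2.0, tau_syn=5.0, v_thr=20.0,
                          v_reset=10.0)


def single_neuron_config(t_sim=1000.0, t_transient=0.1):
    return SimulationConfig(n_e=1, n_i=0, epsilon=1.0, t_sim=t_sim,
                            t_transient=t_transient, record_spikes=False)


class TestConnectivity:
    def test_exact_in_degrees(self):
        config = SimulationConfig(n_e=100, n_i=25, epsilon=0.2)
        conn = build_connectivity(config, seed=0)
        assert conn.exc_sources.shape == (125, 20)
        assert conn.inh_sources.shape == (125, 5)
        assert conn.exc_sources.max() < 100
        assert conn.inh_sources.min() >= 100

    def test_single_source_case(self):
        config = SimulationConfig(n_e=10, n_i=10, epsilon=0.1)
        conn = build_connectivity(config, seed=1)
        assert conn.c_e == 1 and conn.c_i == 1

    def test_source_frequencies_binomial(self):
        # each candidate source should be picked uniformly with replacement
        config = SimulationConfig(n_e=200, n_i=50, epsilon=0.2)
        conn = build_connectivity(config, seed=2)
        n_draws = conn.exc_sources.size
        counts = np.bincount(conn.exc_sources.ravel(), minlength=200)
        p = 1.0 / 200
        se = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 5 * se)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_e=10, n_i=10, epsilon=0.0)

    def test_target_lists_invert_sources(self):
        config = SimulationConfig(n_e=20, n_i=5, epsilon=0.2)
        conn = build_connectivity(config, seed=3)
        indptr, targets = conn.target_lists()
        total = conn.exc_sources.size + conn.inh_sources.size
        assert indptr[-1] == total == len(targets)
        # neuron 0's out-targets are exactly the rows listing it as a source
        expected = sorted(
            np.where((conn.exc_sources == 0))[0].tolist())
        got = sorted(targets[indptr[0]:indptr[1]].tolist())
        assert got == expected

    def test_reproducible(self):
        config = SimulationConfig(n_e=50, n_i=20, epsilon=0.1)
        a = build_connectivity(config, seed=9)
        b = build_connectivity(config, seed=9)
        np.testing.assert_array_equal(a.exc_sources, b.exc_sources)


class TestExactIntegration:
    def test_propagator_matches_adaptive_ode(self, point):
        rng = np.random.default_rng(0)
        dom = ParameterDomain()
        design = latin_hypercube_sample(dom, 20, seed=5)
        for row in design:
            p = dom.point(row)
            mat = propagator(p, 0.1)
            state = rng.standard_normal(3) * np.array([10.0, 50.0, 50.0])

            def rhs(_, s, p=p):
                return [-s[0] / p.tau_m + s[1] / p.c_m,
                        -s[1] / p.tau_syn + s[2],
                        -s[2] / p.tau_syn]

            sol = solve_ivp(rhs, [0.0, 0.1], state, method="DOP853",
                            rtol=1e-12, atol=1e-14)
            ref = sol.y[:, -1]
            rel = np.abs(mat @ state - ref) / np.maximum(np.abs(ref), 1e-9)
            assert rel.max() < 1e-8

    def test_free_membrane_decay_exact(self, point):
        # V(t) = V(0) exp(-t/tau_m) with no synaptic input
        mat = propagator(point, 0.1)
        v = 17.0
        state = np.array([v, 0.0, 0.0])
        for _ in range(1000):
            state = mat @ state
        expected = v * np.exp(-100.0 / point.tau_m)
        assert abs(state[0] - expected) / expected < 1e-10

    def test_alpha_current_peaks_at_j(self, point):
        # one synaptic event: current reaches J at tau_syn after activation
        dt = 0.01
        mat = propagator(point, dt)
        w = np.e * point.j / point.tau_syn
        state = np.array([0.0, 0.0, w])
        best_t, best_i, charge = 0.0, 0.0, 0.0
        for k in range(int(20 * point.tau_syn / dt)):
            state = mat @ state
            charge += state[1] * dt
            if state[1] > best_i:
                best_i, best_t = state[1], (k + 1) * dt
        assert best_i == pytest.approx(point.j, rel=1e-3)
        assert best_t == pytest.approx(point.tau_syn, abs=2 * dt)
        assert charge == pytest.approx(np.e * point.tau_syn * point.j, rel=1e-3)

    def test_rheobase_drive_reaches_threshold_mean(self, point):
        # a threshold-free neuron driven at nu_ext = nu_thr settles at a mean
        # membrane potential of V_thr
        config = single_neuron_config(t_sim=100_500.0, t_transient=500.0)
        result = simulate(point, config, None, seed=3, apply_threshold=False)
        assert result.mean_v[0] == pytest.approx(point.v_thr, rel=0.02)


class TestSimulation:
    def test_refractory_period_respected(self, point):
        config = SimulationConfig(n_e=80, n_i=20, epsilon=0.2, t_sim=800.0,
                                  t_transient=100.0, record_spikes=True)
        conn = build_connectivity(config, seed=0)
        hot = ParameterPoint(**{**{n: getattr(point, n) for n in
                                   point.__dataclass_fields__}, "eta": 3.0})
        result = simulate(hot, config, conn, seed=1)
        assert result.n_spikes_total > 0
        for nid in np.unique(result.spike_ids):
            times = np.sort(result.spike_times[result.spike_ids == nid])
            if len(times) > 1:
                assert np.min(np.diff(times)) > hot.t_ref

    def test_bit_reproducible_and_seed_sensitive(self, point):
        config = SimulationConfig(n_e=100, n_i=25, epsilon=0.2, t_sim=700.0,
                                  t_transient=100.0, record_spikes=False)
        conn = build_connectivity(config, seed=0)
        a = simulate(point, config, conn, seed=5)
        b = simulate(point, config, conn, seed=5)
        np.testing.assert_array_equal(a.activity.counts_e,
                                      b.activity.counts_e)
        c = simulate(point, config, conn, seed=6)
        assert not np.array_equal(a.activity.counts_e, c.activity.counts_e)

    def test_activity_bookkeeping(self, point):
        config = SimulationConfig(n_e=100, n_i=25, epsilon=0.2, t_sim=600.0,
                                  t_transient=100.0, record_spikes=True)
        conn = build_connectivity(config, seed=0)
        result = simulate(point, config, conn, seed=2)
        act = result.activity
        assert act.n_bins == 500
        assert act.total.sum() == len(result.spike_times)
        assert np.all(act.counts_e >= 0)

    def test_delay_below_resolution_rejected(self, point):
        config = SimulationConfig(n_e=10, n_i=5, epsilon=0.2, t_sim=300.0,
                                  t_transient=10.0)
        conn = build_connectivity(config, seed=0)
        fast = ParameterPoint(**{**{n: getattr(point, n) for n in
                                    point.__dataclass_fields__}, "t_d": 0.01})
        with pytest.raises(ValueError):
            simulate(fast, config, conn, seed=0)

    def test_spikes_to_text(self, point, tmp_path):
        config = SimulationConfig(n_e=50, n_i=15, epsilon=0.2, t_sim=500.0,
                                  t_transient=100.0, record_spikes=True)
        conn = build_connectivity(config, seed=0)
        result = simulate(point, config, conn, seed=2)
        path = tmp_path / "spikes.txt"
        result.spikes_to_text(path)
        data = np.loadtxt(path)
        # the text export covers the recorded (post-transient) window
        assert len(np.atleast_2d(data)) == result.activity.total.sum()


def test_reduced_network_mostly_asynchronous_irregular(corpus):
    """Across a Latin-hypercube sweep of the domain, the reduced network
    stays in the asynchronous-irregular regime (no exclusion flag) for the
    majority of draws."""
    flags = corpus["flags"]
    assert flags.mean() < 0.5


class TestSynchronyFlags:
    @staticmethod
    def _activity(fracs_e, n_e=8000, n_i=2000):
        counts = np.asarray(fracs_e) * (n_e + n_i)
        return PopulationActivity(counts_e=counts.astype(int),
                                  counts_i=np.zeros(len(counts), int),
                                  bin_width=1.0, n_e=n_e, n_i=n_i)

    def test_both_criteria_exceeded_excludes(self):
        fracs = np.concatenate([np.full(200, 0.15), np.full(600, 0.001),
                                np.full(9200, 0.02)])
        excluded, n_high, n_silent = synchrony_flags(self._activity(fracs))
        assert (excluded, n_high, n_silent) == (True, 200, 600)

    def test_homogeneous_activity_not_excluded(self):
        excluded, n_high, n_silent = synchrony_flags(
            self._activity(np.full(10000, 0.02)))
        assert (excluded, n_high, n_silent) == (False, 0, 0)

    def test_conjunctive_reading(self):
        # many high-synchrony bins but too few silent bins: kept
        fracs = np.concatenate([np.full(200, 0.15), np.full(100, 0.001),
                                np.full(9700, 0.02)])
        excluded, n_high, n_silent = synchrony_flags(self._activity(fracs))
        assert excluded is False
        assert (n_high, n_silent) == (200, 100)

    def test_empty_activity_rejected(self):
        with pytest.raises(ValueError):
            synchrony_flags(self._activity(np.zeros(0)))
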