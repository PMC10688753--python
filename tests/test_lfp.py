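"""Alpha PSC, kernel bank, interpolation, composition and LFP convolution."""

import numpy as np
import pytest

from spikemeta.lfp import (CM_GRID, TAU_M_GRID, KernelBank,
                           alpha_psc_waveform, cm_scale_query,
                           compose_population_kernel, compute_lfp,
                           interpolate_kernel, synthetic_kernel_bank)
from spikemeta.network import PopulationActivity


def _activity(counts_e, counts_i=None):
    counts_e = np.asarray(counts_e, dtype=int)
    if counts_i is None:
        counts_i = np.zeros_like(counts_e)
    return PopulationActivity(counts_e=counts_e, counts_i=counts_i,
                              bin_width=1.0, n_e=800, n_i=200)


class TestAlphaPSC:
    def test_peak_value_and_location(self):
        dt = 0.01
        w = alpha_psc_waveform(10.0, 5.0, dt, 100.0)
        k = np.argmax(w)
        assert w[k] == pytest.approx(10.0, rel=1e-4)
        assert k * dt == pytest.approx(5.0, abs=2 * dt)

    def test_charge_equals_e_tau_j(self):
        dt = 0.1
        j, tau = 7.0, 4.0
        w = alpha_psc_waveform(j, tau, dt, 80.0)
        assert np.sum(w) * dt == pytest.approx(np.e * tau * j, rel=1e-3)

    def test_zero_amplitude_zero_waveform(self):
        assert not np.any(alpha_psc_waveform(0.0, 5.0, 0.1, 60.0))

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            alpha_psc_waveform(1.0, 5.0, 0.1, 20.0)


class TestSyntheticBank:
    def test_invariants_any_seed(self):
        for seed in (0, 7, 123):
            bank = synthetic_kernel_bank(seed)
            assert bank.validate_causal_decay()
            for arr in bank.kernels.values():
                assert arr.shape[:3] == (5, 6, 6)
                assert np.all(arr[..., 0] == 0.0)  # causal: zero at lag 0-

    def test_deterministic_under_seed(self):
        a = synthetic_kernel_bank(42)
        b = synthetic_kernel_bank(42)
        for pop in ("E", "I"):
            np.testing.assert_array_equal(a.kernels[pop], b.kernels[pop])

    def test_slow_membrane_decays_slower(self):
        bank = synthetic_kernel_bank(3)
        arr = bank.kernels["E"]
        lags = np.arange(arr.shape[-1])
        for ch in range(6):
            # half-decay time of |kernel| relative to its peak
            def half_time(kern):
                a = np.abs(kern)
                peak = a.argmax()
                below = np.where(a[peak:] < 0.5 * a[peak])[0]
                return lags[peak + below[0]]
            fast = half_time(arr[2, 0, ch])   # tau_m = 15 ms
            slow = half_time(arr[2, -1, ch])  # tau_m = 30 ms
            assert slow > fast

    def test_dipole_profile_changes_sign(self):
        bank = synthetic_kernel_bank(1)
        for pop in ("E", "I"):
            peaks = bank.kernels[pop][2, 2, :, :].sum(axis=-1)
            assert np.min(peaks) < 0 < np.max(peaks)

    def test_cm_query_mapping(self):
        assert cm_scale_query(200.0) == 1.0
        assert cm_scale_query(100.0) == 0.5


class TestInterpolation:
    def test_grid_node_exact(self):
        bank = synthetic_kernel_bank(0)
        got = interpolate_kernel(bank, CM_GRID[2], TAU_M_GRID[3], "E")
        np.testing.assert_array_equal(got, bank.kernels["E"][2, 3])

    def test_midpoint_is_arithmetic_mean(self):
        bank = synthetic_kernel_bank(0)
        mid_tau = 0.5 * (TAU_M_GRID[1] + TAU_M_GRID[2])
        got = interpolate_kernel(bank, CM_GRID[0], mid_tau, "I")
        expected = 0.5 * (bank.kernels["I"][0, 1] + bank.kernels["I"][0, 2])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_linear_field_interpolated_exactly(self):
        # a bank whose kernels are linear in (c_m, tau_m) is reproduced
        # everywhere by bilinear interpolation
        lags = np.arange(50.0)
        base = np.exp(-lags / 5.0)[None, :] * np.ones((6, 1))
        kernels = {}
        for pop in ("E", "I"):
            arr = np.empty((5, 6, 6, 50))
            for a, cm in enumerate(CM_GRID):
                for b, tm in enumerate(TAU_M_GRID):
                    arr[a, b] = (2.0 * cm + 0.1 * tm) * base
            kernels[pop] = arr
        bank = KernelBank(kernels=kernels)
        rng = np.random.default_rng(0)
        for _ in range(10):
            cm = rng.uniform(CM_GRID[0], CM_GRID[-1])
            tm = rng.uniform(TAU_M_GRID[0], TAU_M_GRID[-1])
            got = interpolate_kernel(bank, cm, tm, "E")
            np.testing.assert_allclose(got, (2 * cm + 0.1 * tm) * base,
                                       rtol=1e-12)

    def test_out_of_range_rejected(self):
        bank = synthetic_kernel_bank(0)
        with pytest.raises(ValueError):
            interpolate_kernel(bank, 0.3, 20.0)
        with pytest.raises(ValueError):
            interpolate_kernel(bank, 1.0, 31.0)


class TestComposition:
    def test_unit_impulse_psc_gives_delayed_kernel(self):
        unit = np.zeros((6, 40))
        unit[:, 3] = 1.0
        psc = np.zeros(100)
        psc[0] = 10.0  # one sample of height 10 at dt=0.1 -> integral 1.0
        out = compose_population_kernel(unit, psc, t_d=2.0, psc_dt=0.1)
        np.testing.assert_allclose(out[:, 5], 1.0, rtol=1e-9)
        assert np.allclose(out[:, :5], 0.0, atol=1e-12)

    def test_linear_in_amplitude(self):
        unit = synthetic_kernel_bank(0).kernels["E"][2, 2]
        psc1 = alpha_psc_waveform(5.0, 3.0, 0.1, 60.0)
        psc2 = alpha_psc_waveform(10.0, 3.0, 0.1, 60.0)
        h1 = compose_population_kernel(unit, psc1, 1.0, 0.1)
        h2 = compose_population_kernel(unit, psc2, 1.0, 0.1)
        np.testing.assert_allclose(h2, 2.0 * h1, rtol=1e-10)

    def test_lag_sum_factorizes(self):
        # sum over lags of the composed kernel = (kernel sum) * (PSC charge)
        unit = synthetic_kernel_bank(1).kernels["I"][1, 4]
        j, tau = 6.0, 4.0
        psc = alpha_psc_waveform(j, tau, 0.1, 120.0)
        h = compose_population_kernel(unit, psc, 1.0, 0.1)
        expected = unit.sum(axis=-1) * (np.e * tau * j)
        np.testing.assert_allclose(h.sum(axis=-1), expected, rtol=1e-3)

    def test_resolution_mismatch_rejected(self):
        unit = np.zeros((6, 10))
        with pytest.raises(ValueError):
            compose_population_kernel(unit, np.ones(30), 1.0, psc_dt=0.3)


class TestComputeLFP:
    def test_impulse_response_recovers_kernel(self):
        h_e = synthetic_kernel_bank(0).kernels["E"][2, 2]
        h_i = np.zeros_like(h_e)
        counts = np.zeros(300, int)
        counts[0] = 1
        sig = compute_lfp(_activity(counts), h_e, h_i)
        np.testing.assert_allclose(sig.data[:, :h_e.shape[1]],
                                   h_e[:, :300][:, :h_e.shape[1]],
                                   rtol=1e-9, atol=1e-12)

    def test_pipeline_linearity_exact(self):
        bank = synthetic_kernel_bank(2)
        h_e, h_i = bank.kernels["E"][1, 1], bank.kernels["I"][1, 1]
        rng = np.random.default_rng(0)
        a = rng.integers(0, 30, 400)
        b = rng.integers(0, 30, 400)
        both = compute_lfp(_activity(a + b, a), h_e, h_i)
        s1 = compute_lfp(_activity(a, np.zeros_like(a)), h_e, h_i)
        s2 = compute_lfp(_activity(b, a), h_e, h_i)
        np.testing.assert_allclose(both.data, s1.data + s2.data, atol=1e-8)

    def test_rate_scaling(self):
        bank = synthetic_kernel_bank(2)
        h_e, h_i = bank.kernels["E"][1, 1], bank.kernels["I"][1, 1]
        counts = np.random.default_rng(1).integers(0, 10, 300)
        one = compute_lfp(_activity(counts, counts), h_e, h_i)
        three = compute_lfp(_activity(3 * counts, 3 * counts), h_e, h_i)
        np.testing.assert_allclose(three.data, 3.0 * one.data, rtol=1e-9,
                                   atol=1e-12)

    def test_constant_rate_steady_state(self):
        bank = synthetic_kernel_bank(0)
        h_e, h_i = bank.kernels["E"][0, 0], bank.kernels["I"][0, 0]
        rate = 7
        counts = np.full(600, rate)
        sig = compute_lfp(_activity(counts, counts), h_e, h_i)
        expected = rate * (h_e.sum(axis=-1) + h_i.sum(axis=-1))
        np.testing.assert_allclose(sig.data[:, -1], expected, rtol=1e-8)

    def test_synchronous_run_has_sharp_spectral_peak(self):
        # qualitative regression: the LFP of a strongly synchronous
        # (periodically bursting) activity shows a sharp spectral peak that
        # an asynchronous-irregular run lacks
        from spikemeta.spectra import welch_psd
        bank = synthetic_kernel_bank(0)
        h_e, h_i = bank.kernels["E"][2, 2], bank.kernels["I"][2, 2]
        rng = np.random.default_rng(0)
        n = 4000
        sync = np.zeros(n, int)
        sync[::25] = 400                      # 40 Hz population bursts
        ai = rng.poisson(16, n)               # same mean rate, asynchronous

        def peakiness(counts):
            sig = compute_lfp(_activity(counts, counts // 4), h_e, h_i)
            p = welch_psd(sig.data[0] - sig.data[0].mean()).power[1:]
            return p.max() / np.median(p)

        assert peakiness(sync) > 10 * peakiness(ai)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            KernelBank(kernels={"E": np.zeros((5, 6, 6, 10))},
                       cm_grid=np.array([1.0, 0.5, 2.0]))
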