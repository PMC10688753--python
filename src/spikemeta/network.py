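"""Two-population leaky integrate-and-fire network with alpha-current synapses.

The membrane potential obeys ``tau_m dV/dt = -V + R_m I`` with ``R_m =
tau_m / C_m`` (leak reversal at 0 mV).  Each synaptic event injects an
alpha-shaped current ``I(t) = J (t/tau_syn) exp(1 - t/tau_syn)`` with peak
amplitude J for excitatory sources and -gJ for inhibitory sources; the total
charge per event is ``e * tau_syn * J``.  The alpha current is realised as two
cascaded first-order stages, so the full subthreshold state (V, I, z) is
linear and is advanced with the exact propagator (matrix exponential) of the
system, evaluated once per parameter point:

    dV/dt = -V/tau_m + I/C_m
    dI/dt = -I/tau_syn + z
    dz/dt = -z/tau_syn

A spike event adds ``e*J/tau_syn`` (excitatory; times -g for inhibitory) to z
of each target after the delay t_d.  External drive is an independent Poisson
process per neuron at rate nu_ext with excitatory weight J, folded into the
same synaptic channel as per-step Poisson counts.

Spike handling follows grid-constrained simulators: a neuron whose V reaches
threshold at a grid point fires there (no interpolation), is clamped to
V_reset for t_ref, and t_d / t_ref are rounded to the nearest multiple of dt
(at least one step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.linalg import expm

from .parameters import ParameterPoint

__all__ = [
    "SimulationConfig",
    "Connectivity",
    "PopulationActivity",
    "SimulationResult",
    "build_connectivity",
    "propagator",
    "simulate",
    "synchrony_flags",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration grid, network size and recording window."""

    dt: float = 0.1            # ms
    t_sim: float = 10500.0     # ms
    t_transient: float = 500.0  # ms
    n_e: int = 8000
    n_i: int = 2000
    epsilon: float = 0.1
    bin_width: float = 1.0     # ms, activity resolution
    record_spikes: bool = True
    max_recorded_spikes: int = 5_000_000

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.t_transient < self.t_sim:
            raise ValueError("t_transient must be smaller than t_sim")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    @property
    def n_bins(self) -> int:
        return int(round((self.t_sim - self.t_transient) / self.bin_width))


@dataclass
class Connectivity:
    """Fixed in-degree random convergent connections.

    ``exc_sources[i]`` / ``inh_sources[i]`` list the presynaptic neuron
    indices of postsynaptic neuron i (drawn uniformly with replacement, so
    multapses and autapses occur).  Excitatory neurons occupy indices
    [0, n_e), inhibitory [n_e, n_e + n_i).
    """

    exc_sources: np.ndarray   # (N, C_E) int32
    inh_sources: np.ndarray   # (N, C_I) int32
    n_e: int
    n_i: int

    @property
    def c_e(self) -> int:
        return self.exc_sources.shape[1]

    @property
    def c_i(self) -> int:
        return self.inh_sources.shape[1]

    def target_lists(self):
        """Invert source lists into CSR-style per-source target lists."""
        n = self.n_e + self.n_i
        src = np.concatenate(
            [self.exc_sources.ravel(), self.inh_sources.ravel()])
        tgt = np.concatenate([
            np.repeat(np.arange(n, dtype=np.int32), self.c_e),
            np.repeat(np.arange(n, dtype=np.int32), self.c_i),
        ])
        order = np.argsort(src, kind="stable")
        src_sorted = src[order]
        targets = tgt[order].astype(np.int32)
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr[1:], src_sorted, 1)
        np.cumsum(indptr, out=indptr)
        return indptr, targets


@dataclass
class PopulationActivity:
    """Per-population spike counts in contiguous bins over the recording window."""

    counts_e: np.ndarray  # (n_bins,) int64
    counts_i: np.ndarray
    bin_width: float      # ms
    n_e: int
    n_i: int
    t_start: float = 0.0  # ms, left edge of the first (half-open] bin

    def __post_init__(self):
        if len(self.counts_e) != len(self.counts_i):
            raise ValueError("population count arrays must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.counts_e)

    @property
    def total(self) -> np.ndarray:
        return self.counts_e + self.counts_i

    def rate(self, population: str = "E") -> np.ndarray:
        """Population-averaged rate (spikes/s) per bin."""
        counts = {"E": self.counts_e, "I": self.counts_i}[population]
        size = {"E": self.n_e, "I": self.n_i}[population]
        return counts / size / (self.bin_width * 1e-3)


@dataclass
class SimulationResult:
    activity: PopulationActivity
    spike_times: Optional[np.ndarray]  # ms, sorted ascending
    spike_ids: Optional[np.ndarray]
    mean_v: np.ndarray                 # per-neuron time-averaged V (post-transient)
    n_spikes_total: int

    def spikes_to_text(self, path):
        """Write spikes as two-column (neuron id, time ms) sorted text."""
        ids = self.spike_ids
        times = self.spike_times
        if ids is None:
            raise ValueError("spikes were not recorded")
        order = np.lexsort((times, ids))
        np.savetxt(path, np.column_stack([ids[order], times[order]]),
                   fmt="%d %.4f")


def build_connectivity(config: SimulationConfig, seed: int) -> Connectivity:
    """Draw fixed in-degree connectivity: C_E = eps*N_E excitatory and
    C_I = eps*N_I inhibitory sources per neuron, uniform with replacement."""
    if not 0 < config.epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    c_e = int(round(config.epsilon * config.n_e))
    c_i = int(round(config.epsilon * config.n_i))
    n = config.n_total
    rng = np.random.default_rng(seed)
    exc = rng.integers(0, config.n_e, size=(n, c_e), dtype=np.int32)
    inh = rng.integers(config.n_e, n, size=(n, c_i), dtype=np.int32)
    return Connectivity(exc_sources=exc, inh_sources=inh,
                        n_e=config.n_e, n_i=config.n_i)


def propagator(point: ParameterPoint, dt: float) -> np.ndarray:
    """Exact one-step propagator expm(A dt) of the (V, I, z) system."""
    a = np.array([
        [-1.0 / point.tau_m, 1.0 / point.c_m, 0.0],
        [0.0, -1.0 / point.tau_syn, 1.0],
        [0.0, 0.0, -1.0 / point.tau_syn],
    ])
    return expm(a * dt)


@njit(cache=True)
def _run_core(p, n_steps, steps_per_bin, transient_steps, n_e, n,
              indptr, targets, w_spike, d_steps, lam_ext, w_ext,
              v_thr, v_reset, ref_steps, v0, seed,
              record, max_spikes):  # pragma: no cover - exercised via simulate()
    np.random.seed(seed)
    v = v0.copy()
    cur = np.zeros(n)
    z = np.zeros(n)
    refrac = np.zeros(n, np.int64)

    buf_len = d_steps + 1
    ring = np.zeros((buf_len, n))

    n_bins = (n_steps - transient_steps) // steps_per_bin
    counts_e = np.zeros(n_bins, np.int64)
    counts_i = np.zeros(n_bins, np.int64)
    v_sum = np.zeros(n)

    rec_t = np.empty(max_spikes if record else 1, np.float64)
    rec_id = np.empty(max_spikes if record else 1, np.int32)
    n_rec = 0
    n_spk = 0

    p00, p01, p02 = p[0, 0], p[0, 1], p[0, 2]
    p11, p12 = p[1, 1], p[1, 2]
    p22 = p[2, 2]

    for k in range(n_steps):
        # exact propagator step for the subthreshold state
        for i in range(n):
            if refrac[i] > 0:
                refrac[i] -= 1
                v[i] = v_reset
            else:
                v[i] = p00 * v[i] + p01 * cur[i] + p02 * z[i]
            cur[i] = p11 * cur[i] + p12 * z[i]
            z[i] = p22 * z[i]

        # deliver recurrent events due at this step, then clear the slot
        slot = k % buf_len
        for i in range(n):
            z[i] += ring[slot, i]
            ring[slot, i] = 0.0

        # external Poisson drive, folded into the same synaptic channel
        if lam_ext > 0.0:
            for i in range(n):
                c = np.random.poisson(lam_ext)
                if c > 0:
                    z[i] += c * w_ext

        # threshold crossing at the grid point
        in_window = k >= transient_steps
        b = (k - transient_steps) // steps_per_bin if in_window else 0
        for i in range(n):
            if refrac[i] == 0 and v[i] >= v_thr:
                v[i] = v_reset
                refrac[i] = ref_steps
                n_spk += 1
                if in_window:
                    if i < n_e:
                        counts_e[b] += 1
                    else:
                        counts_i[b] += 1
                    if record and n_rec < max_spikes:
                        rec_t[n_rec] = k  # step index, scaled to ms by the caller
                        rec_id[n_rec] = i
                        n_rec += 1
                dest = (k + d_steps) % buf_len
                w = w_spike[i]
                for jj in range(indptr[i], indptr[i + 1]):
                    ring[dest, targets[jj]] += w
            if in_window:
                v_sum[i] += v[i]

    return counts_e, counts_i, rec_t[:n_rec], rec_id[:n_rec], v_sum, n_spk


def simulate(point: ParameterPoint, config: SimulationConfig,
             conn: Optional[Connectivity], seed: int,
             apply_threshold: bool = True,
             external_rate: Optional[float] = None) -> SimulationResult:
    """Simulate the network at one parameter point.

    ``conn=None`` runs unconnected neurons driven only by the external
    Poisson input (used for single-neuron checks).  With
    ``apply_threshold=False`` the threshold/reset mechanism is disabled and
    the membrane integrates freely (rheobase consistency checks).

    Initial membrane potentials are uniform in [V_reset, V_thr); bins of the
    returned activity are half-open (t, t + bin_width] covering
    (t_transient, t_sim].
    """
    dt = config.dt
    if point.t_d < dt and conn is not None:
        raise ValueError("synaptic delay t_d must be at least one step dt")
    n = config.n_total
    p = propagator(point, dt)

    if conn is None:
        indptr = np.zeros(n + 1, dtype=np.int64)
        targets = np.zeros(0, dtype=np.int32)
    else:
        indptr, targets = conn.target_lists()

    j = point.j
    w_unit = np.e * j / point.tau_syn      # z-increment giving peak current J
    w_spike = np.full(n, w_unit)
    w_spike[config.n_e:] = -point.g * w_unit

    d_steps = max(1, int(round(point.t_d / dt)))
    ref_steps = max(1, int(round(point.t_ref / dt)))
    nu = point.nu_ext if external_rate is None else external_rate
    lam_ext = nu * 1e-3 * dt               # expected events per step
    v_thr = point.v_thr if apply_threshold else np.inf

    n_steps = int(round(config.t_sim / dt))
    transient_steps = int(round(config.t_transient / dt))
    steps_per_bin = int(round(config.bin_width / dt))

    rng = np.random.default_rng(seed)
    v0 = rng.uniform(point.v_reset, point.v_thr, size=n)
    core_seed = int(rng.integers(0, 2**31 - 1))

    out = _run_core(p, n_steps, steps_per_bin, transient_steps,
                    config.n_e, n, indptr, targets, w_spike, d_steps,
                    lam_ext, w_unit, v_thr, point.v_reset, ref_steps,
                    v0, core_seed, config.record_spikes,
                    config.max_recorded_spikes)
    counts_e, counts_i, rec_steps, rec_ids, v_sum, n_spk = out

    if not np.all(np.isfinite(v_sum)):
        raise FloatingPointError("non-finite membrane state encountered")

    activity = PopulationActivity(
        counts_e=counts_e, counts_i=counts_i, bin_width=config.bin_width,
        n_e=config.n_e, n_i=config.n_i, t_start=config.t_transient)
    n_window_steps = n_steps - transient_steps
    mean_v = v_sum / n_window_steps
    spike_times = rec_steps * dt if config.record_spikes else None
    spike_ids = rec_ids if config.record_spikes else None
    return SimulationResult(activity=activity, spike_times=spike_times,
                            spike_ids=spike_ids, mean_v=mean_v,
                            n_spikes_total=int(n_spk))


def synchrony_flags(activity: PopulationActivity,
                    high_fraction: float = 0.10,
                    silent_fraction: float = 0.0025,
                    high_bin_threshold: int = 150,
                    silent_bin_threshold: int = 500):
    """Count pathological bins and decide exclusion.

    A bin is *high-synchrony* when more than ``high_fraction`` of all neurons
    fire in it, and *silent* when fewer than ``silent_fraction`` do; the
    fractions are network-wide.  A run is excluded when the number of
    high-synchrony bins exceeds ``high_bin_threshold`` AND the number of
    silent bins exceeds ``silent_bin_threshold`` (conjunctive reading; both
    counts are returned so the disjunctive reading can be audited).
    """
    if activity.n_bins == 0:
        raise ValueError("activity is empty")
    n = activity.n_e + activity.n_i
    frac = activity.total / n
    n_high = int(np.sum(frac > high_fraction))
    n_silent = int(np.sum(frac < silent_fraction))
    excluded = (n_high > high_bin_threshold) and (n_silent > silent_bin_threshold)
    return excluded, n_high, n_silent
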