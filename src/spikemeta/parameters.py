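"""Parameter domain of the two-population network and space-filling designs.

The network is controlled by ten varied parameters.  All internal computation
uses one consistent unit system: ms, mV, pA, pF (charge in fC = pA*ms).  Rates
are returned in spikes/s.

Varied parameters (bounds in :data:`DEFAULT_BOUNDS`):

==========  =====================================  ========
name        meaning                                unit
==========  =====================================  ========
eta         external input rate in units of the   --
            rheobase rate nu_thr
g           relative strength of inhibition        --
q_s         total synaptic charge transfer         fC
tau_m       membrane time constant                 ms
c_m         membrane capacitance                   pF
t_d         synaptic delay                         ms
t_ref       absolute refractory period             ms
tau_syn     synaptic time constant                 ms
v_thr       firing threshold                       mV
v_reset     reset potential                        mV
==========  =====================================  ========

Derived quantities: the peak synaptic current amplitude ``J = Q_s / tau_syn``
(pA), the rheobase rate ``nu_thr = V_thr * C_m / (J * tau_m * e * tau_syn)``
(the minimum constant Poisson input rate that drives the mean membrane
potential to threshold), and the external rate ``nu_ext = eta * nu_thr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import qmc

__all__ = [
    "PARAMETER_NAMES",
    "DEFAULT_BOUNDS",
    "FIXED_CONSTANTS",
    "ParameterDomain",
    "ParameterPoint",
    "latin_hypercube_sample",
    "nu_thr",
    "external_rate",
]

PARAMETER_NAMES = (
    "eta", "g", "q_s", "tau_m", "c_m", "t_d", "t_ref", "tau_syn",
    "v_thr", "v_reset",
)

# units: q_s fC, times ms, c_m pF, voltages mV
DEFAULT_BOUNDS = {
    "eta": (1.0, 3.5),
    "g": (4.5, 8.0),
    "q_s": (25.0, 100.0),
    "tau_m": (15.0, 30.0),
    "c_m": (100.0, 300.0),
    "t_d": (0.1, 3.0),
    "t_ref": (0.1, 4.0),
    "tau_syn": (1.0, 8.0),
    "v_thr": (15.0, 25.0),
    "v_reset": (0.0, 10.0),
}

UNITS = {
    "eta": "", "g": "", "q_s": "fC", "tau_m": "ms", "c_m": "pF",
    "t_d": "ms", "t_ref": "ms", "tau_syn": "ms", "v_thr": "mV",
    "v_reset": "mV",
}

#: fixed network constants: leak reversal (mV), population sizes, connection
#: probability.
FIXED_CONSTANTS = {"E_L": 0.0, "N_E": 8000, "N_I": 2000, "epsilon": 0.1}

# the external-input regime is restricted to eta <= 3.5 to stay clear of the
# strongly synchronous, unbalanced regimes
ETA_MAX = 3.5


@dataclass(frozen=True)
class ParameterDomain:
    """Box domain over the ten varied parameters plus fixed constants."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    constants: dict = field(default_factory=lambda: dict(FIXED_CONSTANTS))

    def __post_init__(self):
        missing = set(PARAMETER_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"missing bounds for parameters: {sorted(missing)}")
        for name in PARAMETER_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")
        if self.bounds["eta"][1] > ETA_MAX:
            raise ValueError(f"eta upper bound must be <= {ETA_MAX}")

    @property
    def names(self):
        return PARAMETER_NAMES

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAMETER_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAMETER_NAMES])

    def contains(self, theta: np.ndarray) -> np.ndarray:
        """Elementwise membership of parameter vectors in the box."""
        theta = np.atleast_2d(np.asarray(theta, float))
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)

    def point(self, theta) -> "ParameterPoint":
        """Build a :class:`ParameterPoint` from a length-10 vector."""
        theta = np.asarray(theta, float)
        if theta.shape != (len(PARAMETER_NAMES),):
            raise ValueError("theta must be a length-10 vector")
        if not self.contains(theta)[0]:
            raise ValueError("theta lies outside the domain bounds")
        return ParameterPoint(**dict(zip(PARAMETER_NAMES, theta)))

    # -- plain-text config round trip ------------------------------------
    def to_yaml(self, path):
        doc = {
            "parameters": [
                {"name": n, "lower": float(self.bounds[n][0]),
                 "upper": float(self.bounds[n][1]), "unit": UNITS[n]}
                for n in PARAMETER_NAMES
            ],
            "constants": {k: float(v) for k, v in self.constants.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterDomain":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        bounds = {p["name"]: (float(p["lower"]), float(p["upper"]))
                  for p in doc["parameters"]}
        constants = dict(doc.get("constants", FIXED_CONSTANTS))
        return cls(bounds=bounds, constants=constants)


@dataclass(frozen=True)
class ParameterPoint:
    """One draw of the varied parameters, with derived quantities."""

    eta: float
    g: float
    q_s: float
    tau_m: float
    c_m: float
    t_d: float
    t_ref: float
    tau_syn: float
    v_thr: float
    v_reset: float

    def __post_init__(self):
        for name in ("q_s", "tau_m", "c_m", "tau_syn", "v_thr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def j(self) -> float:
        """Peak synaptic current amplitude J = Q_s / tau_syn (pA)."""
        return self.q_s / self.tau_syn

    @property
    def nu_thr(self) -> float:
        """Rheobase external rate (spikes/s)."""
        return nu_thr(self)

    @property
    def nu_ext(self) -> float:
        """External Poisson rate eta * nu_thr (spikes/s)."""
        return external_rate(self)

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])


def nu_thr(point: ParameterPoint) -> float:
    """Minimum constant input rate driving the mean potential to threshold.

    ``nu_thr = V_thr * C_m / (J * tau_m * e * tau_syn)``.  In (mV, pF, pA, ms)
    units the formula yields a rate in 1/ms; the returned value is in
    spikes/s.
    """
    j = point.q_s / point.tau_syn
    if j <= 0 or point.tau_m <= 0 or point.tau_syn <= 0:
        raise ValueError("J, tau_m and tau_syn must be positive")
    rate_per_ms = point.v_thr * point.c_m / (j * point.tau_m * math.e * point.tau_syn)
    return rate_per_ms * 1000.0


def external_rate(point: ParameterPoint) -> float:
    """External Poisson rate nu_ext = eta * nu_thr (spikes/s)."""
    return point.eta * nu_thr(point)


def latin_hypercube_sample(domain: ParameterDomain, n: int, seed: int) -> np.ndarray:
    """Latin hypercube design over the domain box.

    For each parameter the n samples occupy the n equal-width strata of its
    range exactly once, with uniform jitter within each stratum.  Strata are
    permuted independently per dimension (no secondary optimization
    criterion).

    Returns an (n, 10) design matrix in the units of the domain bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(PARAMETER_NAMES), seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, domain.lower, domain.upper)
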