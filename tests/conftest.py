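"""Shared fixtures: a reduced-scale simulation corpus and a metamodel
trained on it, built once per session and reused by the model-skill and
parameter-recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from spikemeta.network import (SimulationConfig, build_connectivity, simulate,
                               synchrony_flags)
from spikemeta.parameters import ParameterDomain, latin_hypercube_sample
from spikemeta.spectra import assemble_dataset

# study conditions of the reduced (desk-scale) network: one tenth of the
# full population sizes, a quarter of the simulated duration, same transient
REDUCED_CONFIG = SimulationConfig(n_e=800, n_i=200, t_sim=2500.0,
                                  t_transient=500.0, record_spikes=False)
CORPUS_SIZE = 250
CORPUS_TRAIN = 200
CORPUS_SEED = 101


@pytest.fixture(scope="session")
def domain():
    return ParameterDomain()


@pytest.fixture(scope="session")
def corpus(domain):
    """250 reduced-network simulations over a Latin hypercube design,
    assembled into the spike-variant spectra dataset (first 200 rows train)."""
    theta = latin_hypercube_sample(domain, CORPUS_SIZE, seed=CORPUS_SEED)
    conn = build_connectivity(REDUCED_CONFIG, seed=7)
    activities, flags = [], []
    for i, row in enumerate(theta):
        point = domain.point(row)
        result = simulate(point, REDUCED_CONFIG, conn, seed=1000 + i)
        activities.append(result.activity)
        excluded, _, _ = synchrony_flags(result.activity)
        flags.append(excluded)
    dataset = assemble_dataset(list(theta), activities=activities,
                               flags=flags, kind="spikes")
    train = dataset.subset(np.arange(CORPUS_TRAIN))
    test = dataset.subset(np.arange(CORPUS_TRAIN, dataset.n))
    return {"dataset": dataset, "train": train, "test": test,
            "activities": activities, "flags": np.asarray(flags),
            "theta": theta}


@pytest.fixture(scope="session")
def trained_dgpr(corpus, domain):
    """Deep-GP metamodel trained on the 200-run training split."""
    from spikemeta.dgpr import DGPRConfig, train_dgpr
    config = DGPRConfig(n_layers=2, n_hidden_gps=10, n_latent=16,
                        n_inducing=64, epochs=300, lr=0.01, seed=0,
                        noise_init=0.05)
    return train_dgpr(corpus["train"], config, domain=domain)
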