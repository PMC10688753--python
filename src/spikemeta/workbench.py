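"""Orchestration: study configuration, staged pipeline, seeding and CLI.

A study is a directory of stage artifacts derived from one master seed.  Each
stage reads the outputs of the previous stage from the study's HDF5/CSV
store, is idempotent (skipped when its manifest hash matches the current
config), and derives its randomness from a named substream of the master
seed, so any stage can be reproduced in isolation.

Stages: sample -> simulate -> lfp -> spectra -> train -> infer -> evaluate.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import click
import h5py
import numpy as np
import yaml

from . import dgpr as dgpr_mod
from . import maf as maf_mod
from .inference import MCMCConfig, adaptive_metropolis, log_posterior
from .lfp import compose_population_kernel, compute_lfp, cm_scale_query, \
    interpolate_kernel, synthetic_kernel_bank, alpha_psc_waveform
from .network import PopulationActivity, SimulationConfig, build_connectivity, \
    simulate, synchrony_flags
from .parameters import ParameterDomain, latin_hypercube_sample
from .spectra import SpectraDataset, assemble_dataset
from .evaluation import posterior_summaries

__all__ = ["StudyConfig", "run_stage", "derive_seed", "STAGES", "cli"]

STAGES = ("sample", "simulate", "lfp", "spectra", "train", "infer", "evaluate")

#: desk-scale defaults keep the full pipeline runnable on one CPU while
#: preserving the qualitative behaviour of the full-scale study
DESK_SCALE = {
    "n_simulations": 60,
    "n_e": 800, "n_i": 200,
    "t_sim": 2500.0, "t_transient": 500.0,
    "dgpr_epochs": 150, "maf_epochs": 300,
    "n_inducing": 32, "n_latent": 8,
    "mcmc_proposals": 4000, "mcmc_burn_in": 1500, "mcmc_chains": 4,
    "n_posteriors": 2,
}

PAPER_SCALE = {
    "n_simulations": 10000,
    "n_e": 8000, "n_i": 2000,
    "t_sim": 10500.0, "t_transient": 500.0,
    "dgpr_epochs": 400, "maf_epochs": 800,
    "n_inducing": 128, "n_latent": 16,
    "mcmc_proposals": 40000, "mcmc_burn_in": 12000, "mcmc_chains": 5,
    "n_posteriors": 100,
}


def derive_seed(master_seed: int, name: str, index: int = 0) -> int:
    """Deterministic named substream seed below 2**31."""
    key = f"{master_seed}:{name}:{index}".encode()
    return zlib.crc32(key) % (2**31 - 1)


@dataclass
class StudyConfig:
    out_root: Path
    master_seed: int = 0
    scale: str = "desk"
    domain: ParameterDomain = field(default_factory=ParameterDomain)
    model: str = "dgpr"               # metamodel for train/infer stages
    signal: str = "spikes"            # conditioning signal for infer
    test_fraction: float = 0.2
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        self.out_root = Path(self.out_root)
        if self.scale not in ("desk", "paper"):
            raise ValueError("scale must be 'desk' or 'paper'")

    @property
    def params(self) -> dict:
        base = dict(DESK_SCALE if self.scale == "desk" else PAPER_SCALE)
        base.update(self.overrides)
        return base

    def sim_config(self) -> SimulationConfig:
        p = self.params
        return SimulationConfig(n_e=int(p["n_e"]), n_i=int(p["n_i"]),
                                t_sim=float(p["t_sim"]),
                                t_transient=float(p["t_transient"]),
                                record_spikes=False)

    def config_hash(self) -> str:
        doc = {"seed": self.master_seed, "scale": self.scale,
               "model": self.model, "signal": self.signal,
               "params": self.params,
               "bounds": {k: list(v) for k, v in self.domain.bounds.items()}}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        domain = ParameterDomain()
        if "domain_file" in doc:
            domain = ParameterDomain.from_yaml(doc["domain_file"])
        return cls(out_root=doc.get("out_root", "study"),
                   master_seed=int(doc.get("master_seed", 0)),
                   scale=doc.get("scale", "desk"),
                   domain=domain,
                   model=doc.get("model", "dgpr"),
                   signal=doc.get("signal", "spikes"),
                   overrides=doc.get("overrides", {}))


class DependencyError(RuntimeError):
    """An upstream stage artifact is missing."""


def _manifest_path(config: StudyConfig, stage: str) -> Path:
    return config.out_root / f"{stage}.manifest.json"


def _stage_current(config: StudyConfig, stage: str, outputs) -> bool:
    mpath = _manifest_path(config, stage)
    if not mpath.exists():
        return False
    if not all(Path(p).exists() for p in outputs):
        return False
    with open(mpath) as fh:
        manifest = json.load(fh)
    return manifest.get("config_hash") == config.config_hash()


def _write_manifest(config: StudyConfig, stage: str, outputs, t0, extra=None):
    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "outputs": [str(p) for p in outputs],
        "wall_time_s": round(time.time() - t0, 2),
        "extra": extra or {},
    }
    with open(_manifest_path(config, stage), "w") as fh:
        json.dump(manifest, fh, indent=1)


def _require(config: StudyConfig, stage_needed: str, path: Path):
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path}; run stage '{stage_needed}' first")


def run_stage(config: StudyConfig, stage: str, verbose: bool = True) -> dict:
    """Execute one pipeline stage idempotently; returns the stage manifest."""
    if stage == "all":
        out = {}
        for s in STAGES:
            out[s] = run_stage(config, s, verbose=verbose)
        return out
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    config.out_root.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    p = config.params
    root = config.out_root
    fn = {
        "sample": _stage_sample, "simulate": _stage_simulate,
        "lfp": _stage_lfp, "spectra": _stage_spectra,
        "train": _stage_train, "infer": _stage_infer,
        "evaluate": _stage_evaluate,
    }[stage]
    outputs, extra, skipped = fn(config, p, root, verbose)
    if not skipped:
        _write_manifest(config, stage, outputs, t0, extra)
    with open(_manifest_path(config, stage)) as fh:
        return json.load(fh)


def _stage_sample(config, p, root, verbose):
    out = [root / "design.h5", root / "design.csv"]
    if _stage_current(config, "sample", out):
        return out, {}, True
    n = int(p["n_simulations"])
    theta = latin_hypercube_sample(config.domain, n,
                                   derive_seed(config.master_seed, "design"))
    with h5py.File(out[0], "w") as fh:
        fh.create_dataset("theta", data=theta)
    np.savetxt(out[1], theta, delimiter=",", comments="",
               header=",".join(config.domain.names))
    return out, {"n": n}, False


def _stage_simulate(config, p, root, verbose):
    out = [root / "activity.h5"]
    if _stage_current(config, "simulate", out):
        return out, {}, True
    _require(config, "sample", root / "design.h5")
    with h5py.File(root / "design.h5", "r") as fh:
        theta = fh["theta"][()]
    sim_config = config.sim_config()
    n = len(theta)
    n_excluded = 0
    with h5py.File(out[0], "w") as fh:
        fh.attrs["bin_width"] = sim_config.bin_width
        fh.attrs["n_e"] = sim_config.n_e
        fh.attrs["n_i"] = sim_config.n_i
        counts_e = fh.create_dataset(
            "counts_e", (n, sim_config.n_bins), dtype="i8")
        counts_i = fh.create_dataset(
            "counts_i", (n, sim_config.n_bins), dtype="i8")
        flags = fh.create_dataset("excluded", (n,), dtype=bool)
        for i, row in enumerate(theta):
            point = config.domain.point(row)
            conn = build_connectivity(
                sim_config, derive_seed(config.master_seed, "connectivity", i))
            result = simulate(point, sim_config, conn,
                              derive_seed(config.master_seed, "simulate", i))
            act = result.activity
            excluded, _, _ = synchrony_flags(act)
            counts_e[i] = act.counts_e
            counts_i[i] = act.counts_i
            flags[i] = excluded
            n_excluded += int(excluded)
            if verbose and (i + 1) % 10 == 0:
                click.echo(f"  simulate: {i + 1}/{n}")
    return out, {"n_excluded": n_excluded}, False


def _load_activities(root, n=None):
    with h5py.File(root / "activity.h5", "r") as fh:
        ce = fh["counts_e"][()]
        ci = fh["counts_i"][()]
        flags = fh["excluded"][()]
        bw = float(fh.attrs["bin_width"])
        n_e, n_i = int(fh.attrs["n_e"]), int(fh.attrs["n_i"])
    acts = [PopulationActivity(counts_e=ce[i], counts_i=ci[i], bin_width=bw,
                               n_e=n_e, n_i=n_i) for i in range(len(ce))]
    return acts, flags


def _stage_lfp(config, p, root, verbose):
    out = [root / "lfp.h5"]
    if _stage_current(config, "lfp", out):
        return out, {}, True
    _require(config, "simulate", root / "activity.h5")
    with h5py.File(root / "design.h5", "r") as fh:
        theta = fh["theta"][()]
    acts, _ = _load_activities(root)
    bank = synthetic_kernel_bank(derive_seed(config.master_seed, "kernel-bank"))
    sim_dt = 0.1
    with h5py.File(out[0], "w") as fh:
        data = None
        for i, row in enumerate(theta):
            point = config.domain.point(row)
            cmq = np.clip(cm_scale_query(point.c_m), bank.cm_grid[0],
                          bank.cm_grid[-1])
            psc_e = alpha_psc_waveform(point.j, point.tau_syn, sim_dt,
                                       max(10 * point.tau_syn, 80.0))
            psc_i = -point.g * psc_e
            h_e = compose_population_kernel(
                interpolate_kernel(bank, cmq, point.tau_m, "E"), psc_e,
                point.t_d, sim_dt)
            h_i = compose_population_kernel(
                interpolate_kernel(bank, cmq, point.tau_m, "I"), psc_i,
                point.t_d, sim_dt)
            sig = compute_lfp(acts[i], h_e, h_i)
            if data is None:
                data = fh.create_dataset(
                    "lfp", (len(theta),) + sig.data.shape, dtype="f8")
            data[i] = sig.data
    return out, {}, False


def _stage_spectra(config, p, root, verbose):
    out = [root / "spectra.h5", root / "theta_train.csv"]
    if _stage_current(config, "spectra", out):
        return out, {}, True
    _require(config, "simulate", root / "activity.h5")
    _require(config, "lfp", root / "lfp.h5")
    with h5py.File(root / "design.h5", "r") as fh:
        theta = fh["theta"][()]
    acts, flags = _load_activities(root)
    from .lfp import LFPSignal
    with h5py.File(root / "lfp.h5", "r") as fh:
        lfp_arr = fh["lfp"][()]
    lfps = [LFPSignal(data=lfp_arr[i]) for i in range(len(lfp_arr))]

    ds_spikes = assemble_dataset(list(theta), activities=acts, flags=flags,
                                 kind="spikes")
    ds_lfp = assemble_dataset(list(theta), lfps=lfps, flags=flags, kind="lfp")
    rng = np.random.default_rng(derive_seed(config.master_seed, "split"))
    n = ds_spikes.n
    n_test = max(1, int(round(config.test_fraction * n)))
    split = np.array(["train"] * n)
    split[rng.permutation(n)[:n_test]] = "test"
    ds_spikes.split = split
    ds_lfp.split = split
    ds_spikes.to_hdf5(out[0], group="spikes")
    ds_lfp.to_hdf5(out[0], group="lfp")
    ds_spikes.subset(split == "train").theta_to_csv(out[1])
    return out, {"n_rows": n, "n_test": n_test,
                 "n_excluded": int(flags.sum())}, False


def _load_dataset(config, root):
    group = "spikes" if config.signal == "spikes" else "lfp"
    return SpectraDataset.from_hdf5(root / "spectra.h5", group=group)


def _stage_train(config, p, root, verbose):
    out = [root / f"model_{config.model}_{config.signal}.npz",
           root / f"train_log_{config.model}_{config.signal}.csv"]
    if _stage_current(config, "train", out):
        return out, {}, True
    _require(config, "spectra", root / "spectra.h5")
    ds = _load_dataset(config, root)
    train = ds.subset(ds.split == "train")
    seed = derive_seed(config.master_seed, "model-init")
    if config.model == "dgpr":
        cfg = dgpr_mod.DGPRConfig(
            epochs=int(p["dgpr_epochs"]), seed=seed,
            n_inducing=min(int(p["n_inducing"]), train.n),
            n_latent=int(p["n_latent"]))
        model = dgpr_mod.train_dgpr(train, cfg, domain=config.domain)
        trace = model.elbo_trace
        colname = "elbo"
    elif config.model == "maf":
        cfg = maf_mod.MAFConfig(epochs=int(p["maf_epochs"]), seed=seed)
        model = maf_mod.train_maf(train, cfg)
        trace = [-v for v in model.loss_trace]
        colname = "log_likelihood"
    else:
        raise ValueError("model must be 'dgpr' or 'maf'")
    model.save(out[0])
    np.savetxt(out[1], np.column_stack([np.arange(len(trace)), trace]),
               delimiter=",", comments="", header=f"step,{colname}")
    return out, {"n_train": train.n}, False


def load_model(config: StudyConfig, root=None):
    root = Path(root or config.out_root)
    path = root / f"model_{config.model}_{config.signal}.npz"
    _require(config, "train", path)
    cls = dgpr_mod.DGPRModel if config.model == "dgpr" else maf_mod.MAFModel
    return cls.load(path)


def _stage_infer(config, p, root, verbose):
    out = [root / f"posterior_{config.model}_{config.signal}.h5"]
    if _stage_current(config, "infer", out):
        return out, {}, True
    ds = _load_dataset(config, root)
    model = load_model(config, root)
    test = ds.subset(ds.split == "test")
    n_post = min(int(p["n_posteriors"]), test.n)
    mcmc = MCMCConfig(n_chains=int(p["mcmc_chains"]),
                      n_proposals=int(p["mcmc_proposals"]),
                      n_burn_in=int(p["mcmc_burn_in"]),
                      seed=derive_seed(config.master_seed, "mcmc"))
    domain = config.domain
    with h5py.File(out[0], "w") as fh:
        for i in range(n_post):
            x0 = test.x[i]
            rng = np.random.default_rng(
                derive_seed(config.master_seed, "mcmc-init", i))
            init = rng.uniform(domain.lower, domain.upper,
                               size=(mcmc.n_chains, len(domain.lower)))
            samples = adaptive_metropolis(
                lambda th: log_posterior(model, x0, th, domain),
                mcmc, init, init_proposal_sd=0.05 * (domain.upper - domain.lower),
                x0=x0)
            g = fh.create_group(f"posterior_{i}")
            g.create_dataset("draws", data=samples.draws)
            g.create_dataset("acceptance", data=samples.acceptance)
            g.create_dataset("r_hat", data=samples.r_hat)
            g.create_dataset("x0", data=x0)
            g.create_dataset("theta_true", data=test.theta[i])
            if verbose:
                click.echo(f"  infer: posterior {i + 1}/{n_post} "
                           f"acc={samples.acceptance.mean():.2f}")
    return out, {"n_posteriors": n_post}, False


def _stage_evaluate(config, p, root, verbose):
    out = [root / "evaluation.json", root / "posterior_summary.csv"]
    if _stage_current(config, "evaluate", out):
        return out, {}, True
    post_path = root / f"posterior_{config.model}_{config.signal}.h5"
    _require(config, "infer", post_path)
    ds = _load_dataset(config, root)
    model = load_model(config, root)
    test = ds.subset(ds.split == "test")

    from .inference import PosteriorSamples
    archives, truths = [], []
    with h5py.File(post_path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            archives.append(PosteriorSamples(
                draws=g["draws"][()], acceptance=g["acceptance"][()],
                proposal_cov=np.zeros(0), proposal_scale=np.zeros(0),
                r_hat=g["r_hat"][()]))
            truths.append(g["theta_true"][()])
    report = posterior_summaries(archives, truths)
    if hasattr(model, "predict"):
        pred = model.predict(test.theta)
        report.max_abs_errors = np.max(np.abs(pred.mean - test.x), axis=1)
        report.mean_predictive_sd = np.mean(np.sqrt(pred.variance), axis=1)
    report.to_json(out[0])
    report.posterior_table().to_csv(out[1], index=False)
    return out, {}, False


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

EXIT_CONFIG = 2
EXIT_DEPENDENCY = 3
EXIT_NUMERICAL = 4


def _build_config(config_path, seed, out, scale, model, signal):
    if config_path:
        cfg = StudyConfig.from_yaml(config_path)
    else:
        cfg = StudyConfig(out_root=out or "study")
    if seed is not None:
        cfg.master_seed = seed
    if out:
        cfg.out_root = Path(out)
    if scale:
        cfg.scale = scale
    if model:
        cfg.model = model
    if signal:
        cfg.signal = signal
    return cfg


@click.group()
def cli():
    """Staged pipeline for the spiking-network metamodelling study."""


def _stage_command(stage):
    @cli.command(name=stage)
    @click.option("--config", "config_path", type=click.Path(exists=True),
                  default=None, help="study YAML config")
    @click.option("--seed", type=int, default=None, help="master seed")
    @click.option("--out", type=click.Path(), default=None, help="output root")
    @click.option("--scale", type=click.Choice(["desk", "paper"]), default=None)
    @click.option("--model", type=click.Choice(["dgpr", "maf"]), default=None)
    @click.option("--signal", type=click.Choice(["spikes", "lfp"]), default=None)
    def command(config_path, seed, out, scale, model, signal):
        try:
            cfg = _build_config(config_path, seed, out, scale, model, signal)
        except (ValueError, KeyError) as exc:
            raise SystemExit(EXIT_CONFIG) from exc
        try:
            run_stage(cfg, stage)
        except DependencyError as exc:
            click.echo(str(exc), err=True)
            raise SystemExit(EXIT_DEPENDENCY) from exc
        except FloatingPointError as exc:
            click.echo(str(exc), err=True)
            raise SystemExit(EXIT_NUMERICAL) from exc
    command.__name__ = f"cmd_{stage}"
    return command


for _stage in STAGES + ("all",):
    _stage_command(_stage)
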