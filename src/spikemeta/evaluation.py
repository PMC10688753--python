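"""Evaluation analyses: forward-prediction errors, learning curves,
posterior summaries and signal comparisons.

Because log-spectra have many output channels, forward accuracy is summarized
by the maximum absolute error over frequencies per example (the mean washes
out isolated large deviations).  Posterior quality is summarized by marginal
standard deviations, standardized distances |theta_true - E[theta]| / SD and
mean pairwise Pearson correlation matrices of the draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import PARAMETER_NAMES

__all__ = [
    "EvaluationReport", "max_abs_error", "learning_curve",
    "posterior_summaries", "signal_comparison",
]


@dataclass
class EvaluationReport:
    """Container for the summary quantities of one evaluation run."""

    max_abs_errors: Optional[np.ndarray] = None        # per test example
    mean_predictive_sd: Optional[np.ndarray] = None    # per test example
    posterior_sd: Optional[np.ndarray] = None          # per parameter
    standardized_distance: Optional[np.ndarray] = None  # per parameter
    correlation: Optional[np.ndarray] = None           # (d, d)
    curve_sizes: Optional[np.ndarray] = None
    curve_train_error: Optional[np.ndarray] = None
    curve_test_error: Optional[np.ndarray] = None
    parameter_names: tuple = PARAMETER_NAMES

    def to_json(self, path):
        doc = {}
        for k, v in asdict(self).items():
            if isinstance(v, np.ndarray):
                doc[k] = v.tolist()
            else:
                doc[k] = v
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def posterior_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(self.parameter_names),
            "mean_marginal_sd": self.posterior_sd,
            "mean_standardized_distance": self.standardized_distance,
        })


def render_report(report: EvaluationReport, outdir) -> list:
    """Render the report's figures (error histogram, learning curve,
    posterior-width bars, correlation heatmap) as PNG files; returns the
    written paths.  Sections without data are skipped."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if report.max_abs_errors is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(report.max_abs_errors, bins=20, color="C0")
        ax.set_xlabel("max |error| over frequencies (log10 power)")
        ax.set_ylabel("test examples")
        path = outdir / "max_abs_errors.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if report.curve_sizes is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(report.curve_sizes, report.curve_train_error, "o-",
                label="train")
        ax.plot(report.curve_sizes, report.curve_test_error, "s-",
                label="test")
        ax.set_xscale("log")
        ax.set_xlabel("training-set size")
        ax.set_ylabel("mean max |error|")
        ax.legend()
        path = outdir / "learning_curve.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if report.posterior_sd is not None:
        fig, ax = plt.subplots(figsize=(5, 3))
        idx = np.arange(len(report.posterior_sd))
        ax.bar(idx - 0.2, report.posterior_sd, width=0.4,
               label="marginal SD")
        if report.standardized_distance is not None:
            ax.bar(idx + 0.2, report.standardized_distance, width=0.4,
                   label="|truth - mean| / SD")
        ax.set_xticks(idx)
        ax.set_xticklabels(report.parameter_names, rotation=60)
        ax.legend()
        path = outdir / "posterior_widths.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if report.correlation is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(report.correlation, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(report.parameter_names)))
        ax.set_yticks(range(len(report.parameter_names)))
        ax.set_xticklabels(report.parameter_names, rotation=90)
        ax.set_yticklabels(report.parameter_names)
        fig.colorbar(im, ax=ax, label="mean Pearson correlation")
        path = outdir / "posterior_correlations.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def max_abs_error(prediction_mean: np.ndarray,
                  simulated_spectrum: np.ndarray) -> float:
    """Maximum over output dimensions of |prediction - simulation| (log10 units)."""
    a = np.asarray(prediction_mean, float)
    b = np.asarray(simulated_spectrum, float)
    if a.shape != b.shape:
        raise ValueError("prediction and simulation dimensions differ")
    return float(np.max(np.abs(a - b)))


def learning_curve(sizes: Sequence[int], train_dataset, test_dataset,
                   train_fn: Callable, seed: int = 0):
    """Train fresh metamodels on nested subsets and measure mean max-abs-error.

    ``train_fn(dataset) -> model`` must return an object with a
    ``predict(theta)`` method whose result has a ``mean`` attribute (batch
    prediction).  Subsets are nested (each smaller training set is contained
    in every larger one) so the curve reflects data volume rather than
    sampling noise.  Returns (sizes, train errors, test errors).
    """
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > train_dataset.n:
        raise ValueError("requested size exceeds the available training rows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(train_dataset.n)
    train_err, test_err = [], []
    for size in sizes:
        sub = train_dataset.subset(order[:size])
        model = train_fn(sub)
        train_err.append(_mean_max_abs_error(model, sub))
        test_err.append(_mean_max_abs_error(model, test_dataset))
    return np.asarray(sizes), np.asarray(train_err), np.asarray(test_err)


def _mean_max_abs_error(model, dataset) -> float:
    pred = model.predict(dataset.theta)
    return float(np.mean(np.max(np.abs(pred.mean - dataset.x), axis=1)))


def posterior_summaries(archives: Sequence, true_thetas: Sequence[np.ndarray],
                        parameter_names=PARAMETER_NAMES) -> EvaluationReport:
    """Summaries across a list of posterior archives.

    Per parameter: the mean (over archives) marginal SD, the mean
    standardized distance |theta_true - E[theta]| / SD, and the mean pairwise
    Pearson correlation matrix of the draws.  All archives enter the means
    regardless of their convergence diagnostics.
    """
    if len(archives) == 0:
        raise ValueError("no posterior archives supplied")
    if len(archives) != len(true_thetas):
        raise ValueError("need one true parameter vector per archive")
    sds, dists, corrs = [], [], []
    for arch, truth in zip(archives, true_thetas):
        pooled = arch.pooled()
        sd = pooled.std(axis=0, ddof=1)
        mean = pooled.mean(axis=0)
        sds.append(sd)
        dists.append(np.abs(np.asarray(truth, float) - mean) / sd)
        corrs.append(np.corrcoef(pooled.T))
    corr = np.mean(corrs, axis=0)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return EvaluationReport(
        posterior_sd=np.mean(sds, axis=0),
        standardized_distance=np.mean(dists, axis=0),
        correlation=corr,
        parameter_names=tuple(parameter_names))


def signal_comparison(report_spikes: EvaluationReport,
                      report_lfp: EvaluationReport,
                      sd_spikes: Optional[np.ndarray] = None,
                      sd_lfp: Optional[np.ndarray] = None,
                      n_bootstrap: int = 1000, seed: int = 0):
    """Per-parameter posterior-width ratios (spikes / LFP).

    When per-archive SD matrices (n_archives, d) are supplied, bootstrap
    percentile intervals over archives are attached; the archives must be
    paired (identical conditioning examples in the same order).
    Returns (ratios, lower, upper) arrays.
    """
    r_s = report_spikes.posterior_sd
    r_l = report_lfp.posterior_sd
    if r_s is None or r_l is None:
        raise ValueError("reports must contain posterior SDs")
    ratios = r_s / r_l
    if sd_spikes is None or sd_lfp is None:
        return ratios, None, None
    sd_spikes = np.asarray(sd_spikes)
    sd_lfp = np.asarray(sd_lfp)
    if sd_spikes.shape != sd_lfp.shape:
        raise ValueError("paired SD arrays must share shape "
                         "(same conditioning examples)")
    rng = np.random.default_rng(seed)
    n = len(sd_spikes)
    boot = np.empty((n_bootstrap, sd_spikes.shape[1]))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boot[b] = sd_spikes[idx].mean(0) / sd_lfp[idx].mean(0)
    lower, upper = np.percentile(boot, [2.5, 97.5], axis=0)
    return ratios, lower, upper
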