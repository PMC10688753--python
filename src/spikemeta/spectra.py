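"""Welch power spectra of population activities and LFPs, and dataset assembly.

Signals are uniformly sampled at 1 kHz (the 1 ms activity resolution).  The
PSD is the Welch average of modified periodograms with a Hann window of
length 256 and overlap 128, one-sided, density scaling, no detrending (the
DC bin absorbs the mean and is dropped from metamodel targets).  Metamodels
are trained on the base-10 logarithm of the spectra, with a small power floor
guarding exactly silent channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.signal import welch

from .parameters import PARAMETER_NAMES

__all__ = [
    "FS", "NPERSEG", "NOVERLAP", "POWER_FLOOR",
    "PSDVector", "SpectraDataset",
    "welch_psd", "log10_spectrum", "assemble_dataset",
]

FS = 1000.0      # Hz
NPERSEG = 256
NOVERLAP = 128
POWER_FLOOR = 1e-20


@dataclass
class PSDVector:
    """One-sided PSD on the Welch frequency grid (bin spacing 1000/256 Hz)."""

    frequencies: np.ndarray
    power: np.ndarray
    channel: str = ""
    log10: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("power must be finite")


def welch_psd(signal: np.ndarray, channel: str = "",
              fs: float = FS) -> PSDVector:
    """Welch PSD of a uniformly sampled series (Hann 256, overlap 128)."""
    signal = np.asarray(signal, float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(signal) < NPERSEG:
        raise ValueError(f"signal must contain at least {NPERSEG} samples")
    f, pxx = welch(signal, fs=fs, window="hann", nperseg=NPERSEG,
                   noverlap=NOVERLAP, detrend=False, scaling="density")
    return PSDVector(frequencies=f, power=pxx, channel=channel)


def log10_spectrum(psd: PSDVector, floor: float = POWER_FLOOR) -> PSDVector:
    """Elementwise log10 of the power, with a positive floor applied first."""
    power = np.log10(np.maximum(psd.power, floor))
    return PSDVector(frequencies=psd.frequencies, power=power,
                     channel=psd.channel, log10=True)


@dataclass
class SpectraDataset:
    """Design matrix paired with concatenated log10 PSD vectors.

    ``theta`` is (n, 10) in the units of the parameter domain; ``x`` is
    (n, D) with D = channels x frequency bins.  Excluded (strongly
    synchronous) rows are dropped at assembly and recorded in ``n_excluded``.
    """

    theta: np.ndarray
    x: np.ndarray
    frequencies: np.ndarray
    channels: list
    kind: str                       # "spikes" or "lfp"
    parameter_names: tuple = PARAMETER_NAMES
    split: Optional[np.ndarray] = None   # "train"/"test" per row
    n_excluded: int = 0

    def __post_init__(self):
        if self.theta.shape[0] != self.x.shape[0]:
            raise ValueError("theta and x must have aligned rows")
        expected = len(self.channels) * len(self.frequencies)
        if self.x.shape[1] != expected:
            raise ValueError(
                f"x has {self.x.shape[1]} columns, expected {expected}")

    @property
    def n(self) -> int:
        return self.theta.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]

    def subset(self, idx) -> "SpectraDataset":
        split = None if self.split is None else self.split[idx]
        return SpectraDataset(theta=self.theta[idx], x=self.x[idx],
                              frequencies=self.frequencies,
                              channels=list(self.channels), kind=self.kind,
                              split=split, n_excluded=self.n_excluded)

    # ---- binary store ---------------------------------------------------
    def to_hdf5(self, path, group: str = "dataset"):
        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.create_dataset("theta", data=self.theta)
            g.create_dataset("x", data=self.x)
            g.create_dataset("frequencies", data=self.frequencies)
            g.attrs["channels"] = [str(c) for c in self.channels]
            g.attrs["kind"] = self.kind
            g.attrs["n_excluded"] = self.n_excluded
            if self.split is not None:
                g.create_dataset(
                    "split", data=np.asarray(self.split, dtype="S8"))

    @classmethod
    def from_hdf5(cls, path, group: str = "dataset") -> "SpectraDataset":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            split = None
            if "split" in g:
                split = g["split"][()].astype(str)
            return cls(theta=g["theta"][()], x=g["x"][()],
                       frequencies=g["frequencies"][()],
                       channels=list(g.attrs["channels"]),
                       kind=str(g.attrs["kind"]),
                       split=split, n_excluded=int(g.attrs["n_excluded"]))

    def theta_to_csv(self, path):
        pd.DataFrame(self.theta, columns=list(self.parameter_names)).to_csv(
            path, index=False)


def _psd_matrix(signals: Sequence[np.ndarray], labels: Sequence[str],
                drop_dc: bool):
    rows = []
    freqs = None
    for sig in signals:
        p = log10_spectrum(welch_psd(sig))
        if freqs is None:
            freqs = p.frequencies
        rows.append(p.power)
    rows = np.concatenate(rows)
    if drop_dc:
        keep = freqs > 0
        n_f = int(keep.sum())
        rows = rows.reshape(len(labels), -1)[:, keep].ravel()
        return rows, freqs[keep]
    return rows, freqs


def assemble_dataset(points, activities=None, lfps=None, flags=None,
                     kind: str = "spikes", drop_dc: bool = True,
                     populations=("E", "I")) -> SpectraDataset:
    """Build a SpectraDataset from simulated runs.

    ``kind="spikes"`` concatenates the PSDs of the population spike-count
    signals (both populations by default); ``kind="lfp"`` concatenates the 6
    LFP channels.  Rows whose exclusion flag is set are dropped.
    """
    if kind == "spikes":
        if activities is None:
            raise ValueError("activities required for the spike variant")
        n_runs = len(activities)
    elif kind == "lfp":
        if lfps is None:
            raise ValueError("lfps required for the LFP variant")
        n_runs = len(lfps)
    else:
        raise ValueError("kind must be 'spikes' or 'lfp'")
    if len(points) != n_runs:
        raise ValueError("points and runs must align")
    flags = np.zeros(n_runs, bool) if flags is None else np.asarray(flags, bool)

    theta_rows, x_rows = [], []
    freqs = None
    channels = None
    for i in range(n_runs):
        if flags[i]:
            continue
        if kind == "spikes":
            act = activities[i]
            sigs = [{"E": act.counts_e, "I": act.counts_i}[p].astype(float)
                    for p in populations]
            channels = [f"spikes_{p}" for p in populations]
        else:
            sig = lfps[i]
            sigs = [sig.data[c] for c in range(sig.n_channels)]
            channels = [f"lfp_ch{c + 1}" for c in range(sig.n_channels)]
        row, freqs = _psd_matrix(sigs, channels, drop_dc)
        x_rows.append(row)
        p = points[i]
        theta_rows.append(p if isinstance(p, np.ndarray) else p.as_vector())
    if not x_rows:
        raise ValueError("all runs were excluded")
    return SpectraDataset(theta=np.array(theta_rows), x=np.array(x_rows),
                          frequencies=freqs, channels=channels, kind=kind,
                          n_excluded=int(flags.sum()))
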