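"""Conditional masked autoregressive flow baseline density estimator.

A stack of autoregressive affine transforms, each parameterized by a MADE
network (one masked hidden layer, tanh activation): transform k maps the data
x to ``u = (x - mu(x, theta)) * exp(-alpha(x, theta))`` where mu_i and
alpha_i depend only on x_j with earlier autoregressive degree, and on the
conditioning vector theta, which feeds every hidden unit unmasked.  The base
distribution is standard normal; the variable order is reversed between
transforms.  Log-scales are tanh-clamped for stability.

Training maximizes the conditional log-likelihood by Adam, with early
stopping on a validation split.  Inputs and outputs are standardized; the
log-density carries the standardization Jacobian, so densities are reported
on the original data scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Adam, Parameter, Tensor

__all__ = ["MAFConfig", "MAFModel", "train_maf", "maf_log_prob", "maf_sample"]

_LOGSCALE_CAP = 7.0


@dataclass
class MAFConfig:
    n_transforms: int = 5
    n_hidden: int = 50
    lr: float = 0.005
    epochs: int = 800
    batch_size: int = 0            # 0 = full batch
    seed: int = 0
    patience: int = 50             # early-stopping patience (validation checks)
    val_fraction: float = 0.15

    def __post_init__(self):
        if self.n_transforms < 1:
            raise ValueError("need at least one transform")
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")


class _MADE:
    """One masked autoregressive block producing (mu, log-scale)."""

    def __init__(self, d, d_ctx, n_hidden, degrees, rng):
        self.d = d
        self.degrees = degrees
        max_prev = max(1, d - 1)
        self.h_degrees = rng.integers(1, max_prev + 1, size=n_hidden)
        # hidden unit k sees input i iff deg_h[k] >= deg_in[i]
        self.mask1 = (self.h_degrees[None, :] >= degrees[:, None]).astype(float)
        # output i sees hidden k iff deg_out[i] > deg_h[k]
        self.mask2 = (degrees[None, :] > self.h_degrees[:, None]).astype(float)
        s1 = 1.0 / np.sqrt(d + d_ctx + 1)
        s2 = 1.0 / np.sqrt(n_hidden + 1)
        self.w1 = Parameter(s1 * rng.standard_normal((d, n_hidden)))
        self.v1 = Parameter(s1 * rng.standard_normal((d_ctx, n_hidden)))
        self.b1 = Parameter(np.zeros(n_hidden))
        self.w_mu = Parameter(s2 * rng.standard_normal((n_hidden, d)))
        self.v_mu = Parameter(s2 * rng.standard_normal((d_ctx, d)))
        self.b_mu = Parameter(np.zeros(d))
        self.w_al = Parameter(0.01 * s2 * rng.standard_normal((n_hidden, d)))
        self.v_al = Parameter(0.01 * s2 * rng.standard_normal((d_ctx, d)))
        self.b_al = Parameter(np.zeros(d))

    def parameters(self):
        return [self.w1, self.v1, self.b1, self.w_mu, self.v_mu, self.b_mu,
                self.w_al, self.v_al, self.b_al]

    def forward(self, x, ctx):
        h = (x @ (self.w1 * self.mask1) + ctx @ self.v1 + self.b1).tanh()
        mu = h @ (self.w_mu * self.mask2) + ctx @ self.v_mu + self.b_mu
        raw = h @ (self.w_al * self.mask2) + ctx @ self.v_al + self.b_al
        alpha = _LOGSCALE_CAP * (raw * (1.0 / _LOGSCALE_CAP)).tanh()
        return mu, alpha

    def forward_np(self, x, ctx):
        h = np.tanh(x @ (self.w1.data * self.mask1) + ctx @ self.v1.data
                    + self.b1.data)
        mu = h @ (self.w_mu.data * self.mask2) + ctx @ self.v_mu.data + self.b_mu.data
        raw = h @ (self.w_al.data * self.mask2) + ctx @ self.v_al.data + self.b_al.data
        return mu, _LOGSCALE_CAP * np.tanh(raw / _LOGSCALE_CAP)


class MAFModel:
    """Trained conditional MAF exposing log_prob and sample."""

    def __init__(self, config, blocks, orders, ctx_mean, ctx_sd, out_mean,
                 out_sd):
        self.config = config
        self.blocks = blocks
        self.orders = orders          # per-transform permutation of dims
        self.ctx_mean = ctx_mean
        self.ctx_sd = ctx_sd
        self.out_mean = out_mean
        self.out_sd = out_sd
        self.loss_trace: list = []
        self.val_trace: list = []

    @property
    def d_out(self) -> int:
        return len(self.out_mean)

    def parameters(self):
        ps = []
        for b in self.blocks:
            ps += b.parameters()
        return ps

    # ---- density --------------------------------------------------------
    def _standardize(self, theta, x):
        theta = np.atleast_2d(np.asarray(theta, float))
        x = np.atleast_2d(np.asarray(x, float))
        return ((theta - self.ctx_mean) / self.ctx_sd,
                (x - self.out_mean) / self.out_sd)

    def _forward_graph(self, x: Tensor, ctx: Tensor):
        """Map data to base space; returns (u, total log|det J|) per row."""
        u = x
        logdet = None
        for block, order in zip(self.blocks, self.orders):
            up = u[:, order]
            mu, alpha = block.forward(up, ctx)
            u_raw = (up - mu) * (-alpha).exp()
            contrib = -alpha.sum(axis=1)
            logdet = contrib if logdet is None else logdet + contrib
            u = u_raw
        return u, logdet

    def _forward_np(self, x, ctx):
        u = x
        logdet = np.zeros(len(x))
        for block, order in zip(self.blocks, self.orders):
            up = u[:, order]
            mu, alpha = block.forward_np(up, ctx)
            u = (up - mu) * np.exp(-alpha)
            logdet = logdet - alpha.sum(axis=1)
        return u, logdet

    def transform_to_base(self, theta, x):
        """Standardize and push x through the flow (numpy path)."""
        ctx, xs = self._standardize(theta, x)
        return self._forward_np(xs, ctx)

    def inverse_np(self, u, ctx):
        """Invert the flow: base samples to (standardized) data space."""
        x = u
        for block, order in zip(reversed(self.blocks), reversed(self.orders)):
            d = x.shape[1]
            xp = np.zeros_like(x)
            # fill dimensions in autoregressive (degree) order
            for _ in range(d):
                mu, alpha = block.forward_np(xp, ctx)
                xp = x * np.exp(alpha) + mu
            inv = np.argsort(order)
            x = xp[:, inv]
        return x

    def log_prob(self, theta, x) -> float:
        x_arr = np.atleast_2d(np.asarray(x, float))
        if x_arr.shape[1] != self.d_out:
            raise ValueError("x dimension does not match the model output")
        u, logdet = self.transform_to_base(theta, x_arr)
        base = -0.5 * np.sum(u ** 2 + np.log(2 * np.pi), axis=1)
        jac_std = -np.sum(np.log(self.out_sd))
        lp = base + logdet + jac_std
        return float(lp[0]) if np.asarray(x).ndim == 1 else lp

    def sample(self, theta, n: int, seed: int = 0) -> np.ndarray:
        if n == 0:
            return np.zeros((0, self.d_out))
        rng = np.random.default_rng(seed)
        theta = np.asarray(theta, float)
        ctx = np.tile((theta - self.ctx_mean) / self.ctx_sd, (n, 1))
        u = rng.standard_normal((n, self.d_out))
        xs = self.inverse_np(u, ctx)
        return xs * self.out_sd + self.out_mean

    # ---- persistence ----------------------------------------------------
    def save(self, path):
        arrays = {
            "ctx_mean": self.ctx_mean, "ctx_sd": self.ctx_sd,
            "out_mean": self.out_mean, "out_sd": self.out_sd,
            "orders": np.asarray(self.orders),
            "loss_trace": np.asarray(self.loss_trace),
            "config_json": np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
        }
        for i, b in enumerate(self.blocks):
            arrays[f"b{i}_hdeg"] = b.h_degrees
            arrays[f"b{i}_deg"] = b.degrees
            for name in ("w1", "v1", "b1", "w_mu", "v_mu", "b_mu",
                         "w_al", "v_al", "b_al"):
                arrays[f"b{i}_{name}"] = getattr(b, name).data
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MAFModel":
        with np.load(path) as data:
            config = MAFConfig(**json.loads(bytes(data["config_json"]).decode()))
            orders = [np.asarray(o) for o in data["orders"]]
            d = len(data["out_mean"])
            d_ctx = len(data["ctx_mean"])
            rng = np.random.default_rng(0)
            blocks = []
            for i in range(config.n_transforms):
                blk = _MADE(d, d_ctx, config.n_hidden, data[f"b{i}_deg"], rng)
                blk.h_degrees = data[f"b{i}_hdeg"]
                blk.mask1 = (blk.h_degrees[None, :] >= blk.degrees[:, None]).astype(float)
                blk.mask2 = (blk.degrees[None, :] > blk.h_degrees[:, None]).astype(float)
                for name in ("w1", "v1", "b1", "w_mu", "v_mu", "b_mu",
                             "w_al", "v_al", "b_al"):
                    getattr(blk, name).data = data[f"b{i}_{name}"]
                blocks.append(blk)
            model = cls(config, blocks, orders, data["ctx_mean"],
                        data["ctx_sd"], data["out_mean"], data["out_sd"])
            model.loss_trace = list(data["loss_trace"])
        return model


def train_maf(dataset, config: MAFConfig) -> MAFModel:
    """Fit the conditional MAF to a SpectraDataset-like object by maximum
    likelihood with early stopping on a held-out validation split."""
    theta = np.asarray(dataset.theta, float)
    x = np.asarray(dataset.x, float)
    n, d = x.shape
    if n == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)

    ctx_mean, ctx_sd = theta.mean(0), np.maximum(theta.std(0), 1e-8)
    out_mean, out_sd = x.mean(0), np.maximum(x.std(0), 1e-8)
    ctx = (theta - ctx_mean) / ctx_sd
    xs = (x - out_mean) / out_sd

    n_val = max(1, int(round(config.val_fraction * n))) if n > 4 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    blocks, orders = [], []
    base_order = np.arange(d)
    for k in range(config.n_transforms):
        order = base_order if k % 2 == 0 else base_order[::-1].copy()
        degrees = np.arange(1, d + 1)
        blocks.append(_MADE(d, theta.shape[1], config.n_hidden, degrees, rng))
        orders.append(order)
    model = MAFModel(config, blocks, orders, ctx_mean, ctx_sd, out_mean, out_sd)

    params = model.parameters()
    opt = Adam(params, lr=config.lr)
    xt_train = Tensor(xs[train_idx])
    ct_train = Tensor(ctx[train_idx])
    best_val = np.inf
    best_state = None
    stall = 0
    for epoch in range(config.epochs):
        if config.batch_size and config.batch_size < len(train_idx):
            sel = rng.choice(len(train_idx), config.batch_size, replace=False)
            xb, cb = Tensor(xs[train_idx][sel]), Tensor(ctx[train_idx][sel])
        else:
            xb, cb = xt_train, ct_train
        opt.zero_grad()
        u, logdet = model._forward_graph(xb, cb)
        nll = (0.5 * (u * u).sum(axis=1)
               + 0.5 * d * np.log(2 * np.pi) - logdet).mean()
        if not np.isfinite(float(nll.data)):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        nll.backward()
        opt.step()
        model.loss_trace.append(float(nll.data))

        if n_val and epoch % 10 == 0:
            uv, ldv = model._forward_np(xs[val_idx], ctx[val_idx])
            val_nll = float(np.mean(0.5 * np.sum(uv ** 2, axis=1)
                                    + 0.5 * d * np.log(2 * np.pi) - ldv))
            model.val_trace.append(val_nll)
            if val_nll < best_val - 1e-6:
                best_val = val_nll
                best_state = [p.data.copy() for p in params]
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if best_state is not None:
        for p, s in zip(params, best_state):
            p.data = s
    return model


def maf_log_prob(model: MAFModel, theta, x):
    return model.log_prob(theta, x)


def maf_sample(model: MAFModel, theta, n: int, seed: int = 0) -> np.ndarray:
    return model.sample(theta, n, seed)
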