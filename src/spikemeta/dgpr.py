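"""Two-layer deep Gaussian-process conditional metamodel.

Architecture: a first layer of independent sparse variational GPs maps the
(unit-cube scaled) parameters to hidden features; a second layer maps the
hidden features to P latent functions; the D-dimensional output (a log10
power spectrum) is a learned linear mixture ``f = W g`` of the latents plus
per-dimension Gaussian noise.  All GPs use Matérn 5/2 kernels with ARD
lengthscales and zero mean; each layer shares one kernel across its GPs.

Training maximizes the doubly stochastic variational bound: the first layer's
outputs are sampled with the reparameterization trick, the second layer's
contribution to the expected log-likelihood is available in closed form
through the linear mixing.  Inducing outputs use the whitened
parameterization, so each GP's KL term is the standard normal KL.

The predictive distribution is Gaussian and treated as independent across
output dimensions; the low-rank latent structure (W, latent means/variances)
is retained and exposed for sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular

from .autodiff import Adam, Parameter, Tensor
from .gp import Matern52Kernel, exact_gp_posterior, matern52  # noqa: F401 (metamodel surface)

__all__ = [
    "DGPRConfig", "ConditionalGaussianPrediction", "DGPRModel", "train_dgpr",
    "dgpr_predict", "dgpr_log_prob", "dgpr_sample",
    "Matern52Kernel", "matern52", "exact_gp_posterior",
]

SQRT5 = np.sqrt(5.0)
_D_EPS = 1e-12      # smoothing inside the distance sqrt
_VAR_FLOOR = 1e-10


@dataclass
class DGPRConfig:
    """Architecture and optimization settings.

    ``n_layers`` is 2 for the full model; 1 gives a single sparse GP layer
    (used for the exact-posterior oracle check).  ``n_latent`` is the latent
    dimension P of the low-rank output mixing and must be smaller than the
    output dimension D unless ``fix_w_identity`` collapses the mixing.
    """

    n_layers: int = 2
    n_hidden_gps: int = 10
    n_latent: int = 16
    n_inducing: int = 128
    noise_init: float = 0.05          # observation noise variance (standardized)
    lr: float = 0.01
    epochs: int = 400
    seed: int = 0
    jitter: float = 1e-6
    lengthscale_init: float = 0.3
    variance_init: float = 1.0
    train_hyperparams: bool = True
    train_noise: bool = True
    fix_w_identity: bool = False
    n_train_samples: int = 1

    def __post_init__(self):
        if self.n_layers not in (1, 2):
            raise ValueError("n_layers must be 1 or 2")
        if self.n_inducing < 1 or self.n_latent < 1:
            raise ValueError("n_inducing and n_latent must be positive")


@dataclass
class ConditionalGaussianPrediction:
    """Predictive mean and marginal variance per output dimension."""

    mean: np.ndarray
    variance: np.ndarray
    w: Optional[np.ndarray] = None
    latent_mean: Optional[np.ndarray] = None
    latent_variance: Optional[np.ndarray] = None


class _SVGPLayer:
    """One layer of independent whitened sparse variational GPs.

    Shares a Matérn 5/2 kernel (ARD lengthscales + variance) across the
    layer's ``n_out`` GPs; each GP has its own whitened inducing mean and
    lower-triangular covariance factor.
    """

    def __init__(self, d_in, n_out, z_init, config: DGPRConfig, rng,
                 m_init=None):
        m = z_init.shape[0]
        self.m = m
        self.n_out = n_out
        self.log_ls = Parameter(np.full(d_in, np.log(config.lengthscale_init)))
        self.log_var = Parameter(np.array(np.log(config.variance_init)))
        self.z = Parameter(z_init.copy())
        if m_init is None:
            m_init = 0.01 * rng.standard_normal((m, n_out))
        self.mu = Parameter(m_init)
        ls_free = np.tile(np.eye(m) * _inv_softplus(0.1), (n_out, 1, 1))
        self.ls_free = Parameter(ls_free)
        self._strict = np.tril(np.ones((m, m)), k=-1)
        self._eye = np.eye(m)
        self.jitter = config.jitter

    def parameters(self, include_hyper=True):
        ps = [self.mu, self.ls_free]
        if include_hyper:
            ps += [self.log_ls, self.log_var, self.z]
        return ps

    def _kernel(self, a: Tensor, b: Tensor, na, da, nb) -> Tensor:
        r2 = ((a.reshape(na, 1, da) - b.reshape(1, nb, da)) ** 2.0).sum(axis=-1)
        d = (r2 + _D_EPS).sqrt()
        amp = self.log_var.exp()
        return amp * (1.0 + SQRT5 * d + (5.0 / 3.0) * d * d) * ((-SQRT5) * d).exp()

    def forward(self, x: Tensor):
        """Return (mean (n, n_out), var (n, n_out), kl scalar)."""
        n, d = x.shape
        inv_ls = (-self.log_ls).exp()
        az = self.z * inv_ls
        ax = x * inv_ls
        kzz = self._kernel(az, az, self.m, d, self.m) + self._eye * self.jitter
        lk = kzz.cholesky()
        kzx = self._kernel(az, ax, self.m, d, n)
        a = lk.tri_solve(kzx)                                 # (M, n)
        mean = a.T @ self.mu                                  # (n, n_out)

        ls = self.ls_free * self._strict + self.ls_free.softplus() * self._eye
        b = ls.swap_last() @ a                                # (n_out, M, n)
        kdiag = self.log_var.exp()
        var_gn = kdiag - (a * a).sum(axis=0) + (b * b).sum(axis=1)
        var = var_gn.T.clip_min(_VAR_FLOOR)                   # (n, n_out)

        diag = (ls * self._eye).sum(axis=-1)                  # (n_out, M)
        kl = 0.5 * ((self.mu * self.mu).sum() + (ls * ls).sum()
                    - self.n_out * self.m - 2.0 * diag.log().sum())
        return mean, var, kl

    # numpy twin of forward(), used for fast prediction
    def forward_np(self, x: np.ndarray):
        inv_ls = np.exp(-self.log_ls.data)
        az = self.z.data * inv_ls
        ax = x * inv_ls
        amp = float(np.exp(self.log_var.data))

        def k(u, v):
            d2 = ((u[:, None, :] - v[None, :, :]) ** 2).sum(-1)
            d = np.sqrt(d2 + _D_EPS)
            return amp * (1 + SQRT5 * d + 5.0 / 3.0 * d * d) * np.exp(-SQRT5 * d)

        kzz = k(az, az) + self._eye * self.jitter
        lk = np.linalg.cholesky(kzz)
        a = solve_triangular(lk, k(az, ax), lower=True)
        mean = a.T @ self.mu.data
        lf = self.ls_free.data
        ls = lf * self._strict + np.logaddexp(0.0, lf) * self._eye
        b = np.matmul(np.swapaxes(ls, -1, -2), a)
        var = (amp - (a * a).sum(0) + (b * b).sum(1)).T
        return mean, np.maximum(var, _VAR_FLOOR)


def _inv_softplus(y: float) -> float:
    return float(np.log(np.expm1(y)))


class DGPRModel:
    """Trained deep-GP conditional density model p(x | theta)."""

    def __init__(self, config: DGPRConfig, layers, w, log_noise,
                 input_lo, input_hi, out_mean, out_sd):
        self.config = config
        self.layers = layers
        self.w = w                    # Parameter (D, P)
        self.log_noise = log_noise    # Parameter (D,)  log sigma_n
        self.input_lo = input_lo
        self.input_hi = input_hi
        self.out_mean = out_mean
        self.out_sd = out_sd
        self.elbo_trace: list = []

    # ---- scaling --------------------------------------------------------
    def _scale_inputs(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, float))
        return (theta - self.input_lo) / (self.input_hi - self.input_lo)

    @property
    def d_out(self) -> int:
        return self.w.data.shape[0]

    # ---- prediction -----------------------------------------------------
    def latent_moments(self, theta: np.ndarray, n_samples: int = 0,
                       seed: int = 0):
        """Mean/variance of the latent g(theta) on the standardized scale.

        ``n_samples=0`` propagates the first layer's posterior mean
        deterministically; otherwise moments are averaged over sampled
        first-layer features.
        """
        s = self._scale_inputs(theta)
        if self.config.n_layers == 1:
            return self.layers[0].forward_np(s)
        m1, v1 = self.layers[0].forward_np(s)
        if n_samples == 0:
            return self.layers[1].forward_np(m1)
        rng = np.random.default_rng(seed)
        means, raw2 = 0.0, 0.0
        for _ in range(n_samples):
            h = m1 + np.sqrt(v1) * rng.standard_normal(m1.shape)
            m2, v2 = self.layers[1].forward_np(h)
            means = means + m2
            raw2 = raw2 + v2 + m2 ** 2
        mean = means / n_samples
        var = raw2 / n_samples - mean ** 2
        return mean, np.maximum(var, _VAR_FLOOR)

    def predict(self, theta: np.ndarray, n_samples: int = 0,
                seed: int = 0) -> ConditionalGaussianPrediction:
        g_mean, g_var = self.latent_moments(theta, n_samples, seed)
        w = self.w.data
        s2 = np.exp(2.0 * self.log_noise.data)
        mean_std = g_mean @ w.T
        var_std = g_var @ (w ** 2).T + s2
        mean = mean_std * self.out_sd + self.out_mean
        var = var_std * self.out_sd ** 2
        squeeze = np.asarray(theta).ndim == 1
        if squeeze:
            return ConditionalGaussianPrediction(
                mean=mean[0], variance=var[0], w=w,
                latent_mean=g_mean[0], latent_variance=g_var[0])
        return ConditionalGaussianPrediction(
            mean=mean, variance=var, w=w,
            latent_mean=g_mean, latent_variance=g_var)

    def log_prob(self, theta: np.ndarray, x: np.ndarray) -> float:
        """Gaussian log-density of x under the prediction at theta
        (independent marginals per output dimension)."""
        x = np.asarray(x, float)
        if x.shape[-1] != self.d_out:
            raise ValueError("x dimension does not match the model output")
        pred = self.predict(theta)
        resid = x - pred.mean
        return float(np.sum(
            -0.5 * np.log(2.0 * np.pi * pred.variance)
            - 0.5 * resid ** 2 / pred.variance))

    def sample(self, theta: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
        """Draw n spectra from the predictive distribution.

        Uses the generative path: g ~ N(latent mean, latent var),
        x = W g + noise (on the standardized scale), then unstandardizes.
        """
        if n == 0:
            return np.zeros((0, self.d_out))
        rng = np.random.default_rng(seed)
        g_mean, g_var = self.latent_moments(theta)
        g_mean, g_var = g_mean[0], g_var[0]
        w = self.w.data
        s2 = np.exp(2.0 * self.log_noise.data)
        g = g_mean + np.sqrt(g_var) * rng.standard_normal((n, len(g_mean)))
        eps = np.sqrt(s2) * rng.standard_normal((n, self.d_out))
        x_std = g @ w.T + eps
        return x_std * self.out_sd + self.out_mean

    # ---- persistence ----------------------------------------------------
    def save(self, path):
        arrays = {
            "w": self.w.data, "log_noise": self.log_noise.data,
            "input_lo": self.input_lo, "input_hi": self.input_hi,
            "out_mean": self.out_mean, "out_sd": self.out_sd,
            "elbo_trace": np.asarray(self.elbo_trace),
        }
        for i, layer in enumerate(self.layers):
            arrays[f"l{i}_log_ls"] = layer.log_ls.data
            arrays[f"l{i}_log_var"] = layer.log_var.data
            arrays[f"l{i}_z"] = layer.z.data
            arrays[f"l{i}_mu"] = layer.mu.data
            arrays[f"l{i}_ls_free"] = layer.ls_free.data
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DGPRModel":
        with np.load(path) as data:
            config = DGPRConfig(**json.loads(bytes(data["config_json"]).decode()))
            rng = np.random.default_rng(0)
            layers = []
            for i in range(config.n_layers):
                z = data[f"l{i}_z"]
                layer = _SVGPLayer(z.shape[1], data[f"l{i}_mu"].shape[1], z,
                                   config, rng)
                layer.log_ls.data = data[f"l{i}_log_ls"]
                layer.log_var.data = data[f"l{i}_log_var"]
                layer.mu.data = data[f"l{i}_mu"]
                layer.ls_free.data = data[f"l{i}_ls_free"]
                layers.append(layer)
            model = cls(config, layers, Parameter(data["w"]),
                        Parameter(data["log_noise"]), data["input_lo"],
                        data["input_hi"], data["out_mean"], data["out_sd"])
            model.elbo_trace = list(data["elbo_trace"])
        return model


def train_dgpr(dataset, config: DGPRConfig, domain=None,
               verbose: bool = False) -> DGPRModel:
    """Fit the deep-GP metamodel to a SpectraDataset (or any object with
    ``theta`` (n, d) and ``x`` (n, D) arrays).

    Inputs are min-max scaled to the unit cube (by the domain bounds when a
    ParameterDomain is given, else by the data range); outputs are
    standardized per dimension.  Training runs full-batch Adam on the
    negative ELBO; the ELBO trace is recorded on the model.
    """
    theta = np.asarray(dataset.theta, float)
    x_raw = np.asarray(dataset.x, float)
    n, d_in = theta.shape
    d_out = x_raw.shape[1]
    if n == 0:
        raise ValueError("dataset is empty")
    p = config.n_latent
    if p >= d_out and not config.fix_w_identity:
        raise ValueError("latent dimension must be smaller than the output "
                         "dimension (low-rank requirement)")
    if config.n_inducing > n:
        raise ValueError("inducing-point count exceeds the training size")

    if domain is not None:
        lo, hi = domain.lower.astype(float), domain.upper.astype(float)
    else:
        lo, hi = theta.min(axis=0), theta.max(axis=0)
        hi = np.where(hi > lo, hi, lo + 1.0)
    s = (theta - lo) / (hi - lo)
    out_mean = x_raw.mean(axis=0)
    out_sd = np.maximum(x_raw.std(axis=0), 1e-8)
    x = (x_raw - out_mean) / out_sd

    rng = np.random.default_rng(config.seed)
    m = config.n_inducing
    idx = rng.choice(n, size=m, replace=False)
    z1 = s[idx] + 1e-4 * rng.standard_normal((m, d_in))

    layers = []
    if config.n_layers == 1:
        layers.append(_SVGPLayer(d_in, p, z1, config, rng))
    else:
        g1 = config.n_hidden_gps
        # identity-like initialization of the first layer: whitened means
        # chosen so the layer's posterior mean approximates the (centered)
        # inputs, which gives the second layer informative features from the
        # first step
        layer1 = _SVGPLayer(d_in, g1, z1, config, rng)
        targets = (z1 - 0.5)[:, np.arange(g1) % d_in]
        kzz = _np_matern(z1, z1, np.exp(layer1.log_ls.data),
                         float(np.exp(layer1.log_var.data))) + np.eye(m) * config.jitter
        lk = np.linalg.cholesky(kzz)
        layer1.mu.data = solve_triangular(lk, targets, lower=True)
        layers.append(layer1)
        h0 = layer1.forward_np(s)[0]
        idx2 = rng.choice(n, size=m, replace=False)
        z2 = h0[idx2] + 1e-4 * rng.standard_normal((m, g1))
        layers.append(_SVGPLayer(g1, p, z2, config, rng))

    # output mixing initialized from the principal components of the outputs
    if config.fix_w_identity:
        w = Parameter(np.eye(d_out, p))
    else:
        u, sv, vt = np.linalg.svd(x, full_matrices=False)
        k = min(p, vt.shape[0])
        w_init = np.zeros((d_out, p))
        w_init[:, :k] = (vt[:k].T * (sv[:k] / np.sqrt(n)))
        w = Parameter(w_init)
    log_noise = Parameter(np.full(d_out, 0.5 * np.log(config.noise_init)))

    final_inputs = s if config.n_layers == 1 else layers[0].forward_np(s)[0]
    _natural_init_final_layer(layers[-1], final_inputs, x, w.data,
                              log_noise.data, config.jitter)

    params = []
    for layer in layers:
        params += layer.parameters(include_hyper=config.train_hyperparams)
    if not config.fix_w_identity:
        params.append(w)
    if config.train_noise:
        params.append(log_noise)
    opt = Adam(params, lr=config.lr)

    model = DGPRModel(config, layers, w, log_noise, lo, hi, out_mean, out_sd)
    xt = Tensor(x)
    st = Tensor(s)
    log2pi = np.log(2.0 * np.pi)
    for epoch in range(config.epochs):
        opt.zero_grad()
        kl_total = 0.0
        if config.n_layers == 1:
            g_mean, g_var, kl = layers[0].forward(st)
            kl_total = kl
        else:
            m1, v1, kl1 = layers[0].forward(st)
            eps = rng.standard_normal(m1.shape)
            h = m1 + v1.sqrt() * eps
            g_mean, g_var, kl2 = layers[1].forward(h)
            kl_total = kl1 + kl2
        mu = g_mean @ w.T
        s2 = (2.0 * log_noise).exp()
        resid2 = (xt - mu) ** 2.0
        prop_var = g_var @ (w * w).T
        ell = (-0.5 * (log2pi + (2.0 * log_noise))
               - 0.5 * (resid2 + prop_var) / s2).sum()
        elbo = ell - kl_total
        loss = -elbo
        loss.backward()
        opt.step()
        model.elbo_trace.append(float(elbo.data))
        if verbose and epoch % 50 == 0:
            print(f"epoch {epoch:5d}  elbo {float(elbo.data):.2f}")
        if not np.isfinite(float(elbo.data)):
            raise FloatingPointError(
                f"ELBO diverged at epoch {epoch}; trace: {model.elbo_trace[-5:]}")
    return model


def _natural_init_final_layer(layer: _SVGPLayer, h: np.ndarray, x: np.ndarray,
                              w: np.ndarray, log_noise: np.ndarray,
                              jitter: float):
    """Closed-form optimum of the final layer's whitened variational
    distribution given its initial kernel and the mixing matrix.

    Treats the latents as decoupled, each with pseudo-targets W^+ x and
    effective noise precision sum_d W_dp^2 / sigma_d^2; for an identity
    mixing this is the exact collapsed optimum, otherwise a strong starting
    point for Adam.
    """
    inv_ls = np.exp(-layer.log_ls.data)
    amp = float(np.exp(layer.log_var.data))
    az = layer.z.data * inv_ls
    ah = h * inv_ls
    kzz = _np_matern(az, az, 1.0, amp) + np.eye(layer.m) * jitter
    lk = np.linalg.cholesky(kzz)
    a = solve_triangular(lk, _np_matern(az, ah, 1.0, amp), lower=True)
    s2 = np.exp(2.0 * log_noise)
    lam = ((w ** 2) / s2[:, None]).sum(axis=0)        # per-latent precision
    y = x @ np.linalg.pinv(w).T                        # (n, P) pseudo-targets
    eye = np.eye(layer.m)
    mu = np.empty((layer.m, layer.n_out))
    ls_free = np.empty_like(layer.ls_free.data)
    for p_i in range(layer.n_out):
        prec = eye + lam[p_i] * (a @ a.T)
        s_opt = np.linalg.inv(prec)
        s_opt = 0.5 * (s_opt + s_opt.T) + 1e-10 * eye
        mu[:, p_i] = lam[p_i] * (s_opt @ (a @ y[:, p_i]))
        ls_opt = np.linalg.cholesky(s_opt)
        lf = np.tril(ls_opt, -1)
        lf[np.diag_indices_from(lf)] = np.log(np.expm1(np.diag(ls_opt)))
        ls_free[p_i] = lf
    layer.mu.data = mu
    layer.ls_free.data = ls_free


def _np_matern(a, b, ls, amp):
    d2 = (((a[:, None, :] - b[None, :, :]) / ls) ** 2).sum(-1)
    d = np.sqrt(d2 + _D_EPS)
    return amp * (1 + SQRT5 * d + 5.0 / 3.0 * d * d) * np.exp(-SQRT5 * d)


# functional aliases mirroring the module surface
def dgpr_predict(model: DGPRModel, theta) -> ConditionalGaussianPrediction:
    return model.predict(theta)


def dgpr_log_prob(model: DGPRModel, theta, x) -> float:
    return model.log_prob(theta, x)


def dgpr_sample(model: DGPRModel, theta, n: int, seed: int = 0) -> np.ndarray:
    return model.sample(theta, n, seed)
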