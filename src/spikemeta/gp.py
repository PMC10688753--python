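"""Matérn 5/2 kernel and the exact Gaussian-process posterior.

The closed-form posterior serves as the internal oracle against which the
variational deep-GP is checked: with Gram matrix K_nn on the training inputs,
noise variance s2 and cross-covariances K_*n,

    mean = K_*n (K_nn + s2 I)^{-1} x
    cov  = K_** - K_*n (K_nn + s2 I)^{-1} K_n*
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["Matern52Kernel", "matern52", "exact_gp_posterior"]

SQRT5 = np.sqrt(5.0)


@dataclass
class Matern52Kernel:
    """Matérn 5/2 with signal variance and per-dimension (ARD) lengthscales."""

    variance: float = 1.0
    lengthscales: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self):
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, float))
        if self.variance <= 0 or np.any(self.lengthscales <= 0):
            raise ValueError("variance and lengthscales must be positive")

    def __call__(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return matern52(a, b, self)


def matern52(a: np.ndarray, b: np.ndarray, kernel: Matern52Kernel) -> np.ndarray:
    """Covariance matrix k(a, b) under the Matérn 5/2 kernel.

    ``k = s2 * (1 + sqrt(5) d + 5 d^2 / 3) exp(-sqrt(5) d)`` with d the
    lengthscale-weighted Euclidean distance.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("input dimensionalities differ")
    ls = np.broadcast_to(kernel.lengthscales, (a.shape[1],))
    diff = (a[:, None, :] - b[None, :, :]) / ls
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    return kernel.variance * (1.0 + SQRT5 * d + 5.0 / 3.0 * d * d) * np.exp(-SQRT5 * d)


def exact_gp_posterior(train_theta: np.ndarray, train_x: np.ndarray,
                       noise_variance: float, kernel: Matern52Kernel,
                       test_theta: np.ndarray, jitter: float = 1e-10):
    """Closed-form GP predictive distribution at the test inputs.

    Returns (mean, covariance) of the latent function (noise-free) at
    ``test_theta``.  With an empty conditioning set this is the prior.
    Raises ``np.linalg.LinAlgError`` if the jittered Gram matrix is not
    positive definite.
    """
    test_theta = np.atleast_2d(test_theta)
    if len(train_theta) == 0:
        kss = matern52(test_theta, test_theta, kernel)
        return np.zeros(len(test_theta)), kss
    train_theta = np.atleast_2d(train_theta)
    train_x = np.asarray(train_x, float)
    knn = matern52(train_theta, train_theta, kernel)
    knn[np.diag_indices_from(knn)] += noise_variance + jitter
    kns = matern52(train_theta, test_theta, kernel)
    kss = matern52(test_theta, test_theta, kernel)
    c = cho_factor(knn, lower=True)
    alpha = cho_solve(c, train_x)
    v = cho_solve(c, kns)
    mean = kns.T @ alpha
    cov = kss - kns.T @ v
    return mean, cov
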