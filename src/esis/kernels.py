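"""Characteristic kernels, Nadaraya-Watson smoothing weights and the bandwidth rule.

The dependence index pairs a characteristic positive-definite kernel ``K`` on
the (transformed) outcome with a Gaussian smoothing kernel ``G`` on the
(transformed) feature.  Because the estimator normalizes the smoothing
weights row-wise, any constant factor on ``G`` cancels; it is nevertheless
computed as ``G_h(v) = h^{-q} exp(-(v/h)^2 / 2)`` to mirror its definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KernelConfig",
    "silverman_bandwidth",
    "median_heuristic",
    "kernel_matrix",
    "smoothing_kernel_matrix",
    "smoothing_weights",
]

_CHARACTERISTIC = ("gaussian", "laplacian")
_SMOOTHING = ("gaussian",)
_BANDWIDTH_RULES = ("silverman", "fixed")


class DegenerateInputError(ValueError):
    """Raised when an input has no variation where variation is required."""


@dataclass(frozen=True)
class KernelConfig:
    """Kernel and bandwidth settings for the dependence index.

    Parameters
    ----------
    characteristic_kernel : {"gaussian", "laplacian"}
        Positive-definite characteristic kernel applied to the outcome
        transform; bounded with unit diagonal on [0, 1]^2.
    sigma_k : float or None
        Scale of the characteristic kernel.  ``None`` resolves to the median
        of the nonzero pairwise absolute differences of the transformed
        outcome (median heuristic).
    smoothing_kernel : {"gaussian"}
        Kernel ``G`` used for the Nadaraya-Watson weights.
    bandwidth_rule : {"silverman", "fixed"}
        ``silverman`` resolves h per conditioning variable as
        ``1.06 * sd * n**(-1/5)``; ``fixed`` uses ``bandwidth`` as given.
    bandwidth : float or None
        The fixed bandwidth when ``bandwidth_rule == "fixed"``.
    q : int
        Dimension of the conditioning variable (always 1 here).
    """

    characteristic_kernel: str = "gaussian"
    sigma_k: float | None = None
    smoothing_kernel: str = "gaussian"
    bandwidth_rule: str = "silverman"
    bandwidth: float | None = None
    q: int = 1

    def __post_init__(self) -> None:
        if self.characteristic_kernel not in _CHARACTERISTIC:
            raise ValueError(f"unknown characteristic kernel {self.characteristic_kernel!r}")
        if self.smoothing_kernel not in _SMOOTHING:
            raise ValueError(f"unknown smoothing kernel {self.smoothing_kernel!r}")
        if self.bandwidth_rule not in _BANDWIDTH_RULES:
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")
        if self.sigma_k is not None and not self.sigma_k > 0:
            raise ValueError("sigma_k must be positive")
        if self.bandwidth_rule == "fixed":
            if self.bandwidth is None or not self.bandwidth > 0:
                raise ValueError("fixed bandwidth rule requires bandwidth > 0")
        if self.q != 1:
            raise ValueError("only scalar conditioning variables (q = 1) are supported")

    def resolve_sigma(self, u: np.ndarray) -> "KernelConfig":
        """Return a config with ``sigma_k`` fixed (median heuristic if unset)."""
        if self.sigma_k is not None:
            return self
        return replace(self, sigma_k=median_heuristic(u))

    def resolve_bandwidth(self, v: np.ndarray) -> float:
        if self.bandwidth_rule == "fixed":
            return float(self.bandwidth)
        return silverman_bandwidth(v)


def silverman_bandwidth(v) -> float:
    """Rule-of-thumb bandwidth ``1.06 * sd(v) * n**(-1/5)``.

    ``sd`` is the sample standard deviation with denominator ``n - 1``.
    Constant inputs are rejected: a zero bandwidth would make the smoothing
    weights degenerate, and constant features should have been filtered out.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-d vector with n >= 2")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("zero-variance input has no usable bandwidth")
    return 1.06 * sd * v.size ** (-1 / 5)


def median_heuristic(u) -> float:
    """Median of the nonzero pairwise absolute differences of ``u``."""
    u = np.asarray(u, dtype=float)
    diffs = np.abs(u[:, None] - u[None, :])
    nz = diffs[np.triu_indices(u.size, k=1)]
    nz = nz[nz > 0]
    if nz.size == 0:
        raise DegenerateInputError("all pairwise differences are zero (constant input)")
    return float(np.median(nz))


def kernel_matrix(u, config: KernelConfig) -> np.ndarray:
    """Characteristic-kernel Gram matrix ``K[t, s] = K(u_t, u_s)``.

    Gaussian: ``exp(-(u - u')^2 / (2 sigma^2))``; Laplacian:
    ``exp(-|u - u'| / sigma)``.  Both are unit-diagonal and symmetric
    positive semidefinite.
    """
    u = np.asarray(u, dtype=float)
    sigma = config.sigma_k
    if sigma is None:
        sigma = median_heuristic(u)
    if not sigma > 0:
        raise ValueError("sigma_k must be positive")
    d = u[:, None] - u[None, :]
    if config.characteristic_kernel == "gaussian":
        return np.exp(-(d * d) / (2.0 * sigma * sigma))
    return np.exp(-np.abs(d) / sigma)


def smoothing_kernel_matrix(v, h: float) -> np.ndarray:
    """Raw smoothing-kernel values ``G[t, s] = G_h(v_t - v_s)`` (Gaussian G)."""
    if not h > 0:
        raise ValueError("bandwidth must be positive")
    v = np.asarray(v, dtype=float)
    z = (v[:, None] - v[None, :]) / h
    return np.exp(-0.5 * z * z) / h


def smoothing_weights(v, h: float) -> np.ndarray:
    """Row-stochastic Nadaraya-Watson weight matrix ``A``.

    ``A[t, s] = G_h(v_t - v_s) / sum_l G_h(v_t - v_l)``; every row sums to 1
    and, for a Gaussian G with h > 0, every entry is strictly positive.
    """
    g = smoothing_kernel_matrix(v, h)
    rows = g.sum(axis=1, keepdims=True)
    if np.any(rows == 0):
        raise DegenerateInputError("a smoothing row collapsed to zero weight")
    return g / rows
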