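"""The ECCFIC dependence statistic and its normalized correlation.

ECCFIC (expected conditional characteristic function-based independence
criterion) measures the dependence of U on V as

    H2_K(U|V) = E_V E_{U|V, U'|V} K(U, U') - E_{U,U'} K(U, U'),

for a characteristic kernel K; it is zero iff U and V are independent.  Its
normalization rho_K(U|V) = H2_K(U|V) / H2_K(U|U) lies in [0, 1] at the
population level and equals 1 iff U is a function of V, generalizing the
coefficient of determination R^2 to arbitrary nonlinear dependence.

Two estimators of H2_K(U|V) are provided: a literal transcription of the
Nadaraya-Watson plug-in quintuple sum (`h2_cond_naive`, the correctness
oracle, O(n^5)) and an algebraically equivalent reduced form (`h2_cond`)
obtained by summing the two free indices analytically, at O(n^3) cost:

    (1/n) * sum_t [ (A K A^T)_tt - (2/n) (A R)_t + Q / n^2 ],

with A the row-stochastic smoothing weights of V, R the row sums of K and Q
its grand sum.  Each summand is the squared RKHS distance between the
smoothed conditional mean embedding at V_t and the marginal mean embedding.
Finite-sample estimates of rho are reported raw (not clamped to [0, 1]):
the only downstream use is ranking, and clamping would mask estimator bugs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import (
    KernelConfig,
    kernel_matrix,
    smoothing_kernel_matrix,
    smoothing_weights,
)

__all__ = ["EccficResult", "h2_cond", "h2_cond_naive", "h2_self", "eccfic_corr"]

_NAIVE_CAP = 12


@dataclass(frozen=True)
class EccficResult:
    """Plug-in ECCFIC estimates for one (U, V) pair."""

    h2_cond: float
    h2_self: float
    rho: float
    n: int
    config: KernelConfig


def _as_pair(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.ndim != 1 or v.ndim != 1 or u.size != v.size or u.size == 0:
        raise ValueError("u and v must be non-empty 1-d arrays of equal length")
    return u, v


def _h2_cond_from_matrices(kmat: np.ndarray, weights: np.ndarray) -> float:
    n = kmat.shape[0]
    row_sums = kmat.sum(axis=1)
    grand = row_sums.sum()
    ak = weights @ kmat
    cond_diag = np.einsum("ij,ij->i", ak, weights)
    return float(np.mean(cond_diag - (2.0 / n) * (weights @ row_sums) + grand / n**2))


def _h2_self_from_matrix(kmat: np.ndarray) -> float:
    return float(np.mean(np.diag(kmat)) - np.mean(kmat))


def h2_cond(u, v, config: KernelConfig | None = None) -> float:
    """Nadaraya-Watson plug-in estimate of ``H2_K(U|V)`` (reduced form)."""
    u, v = _as_pair(u, v)
    if u.size == 1 or np.ptp(u) == 0.0:
        return 0.0  # every K_ts is equal, so all centred terms cancel
    config = (config or KernelConfig()).resolve_sigma(u)
    kmat = kernel_matrix(u, config)
    h = config.resolve_bandwidth(v)
    return _h2_cond_from_matrices(kmat, smoothing_weights(v, h))


def h2_cond_naive(u, v, config: KernelConfig | None = None, cap: int = _NAIVE_CAP) -> float:
    """Literal nested-summation transcription of the plug-in estimator.

    The quintuple sum over t1..t5 with the per-t1 denominator
    ``(1/n^2) sum_{s1,s2} G_{t1 s1} G_{t1 s2}`` is evaluated exactly as
    printed.  This is the correctness oracle for `h2_cond`; its cost grows
    like n^5, so inputs longer than ``cap`` are refused.
    """
    u, v = _as_pair(u, v)
    n = u.size
    if n > cap:
        raise ValueError(f"naive oracle limited to n <= {cap}")
    if n == 1 or np.ptp(u) == 0.0:
        return 0.0
    config = (config or KernelConfig()).resolve_sigma(u)
    kmat = kernel_matrix(u, config)
    h = config.resolve_bandwidth(v)
    g = smoothing_kernel_matrix(v, h)

    total = 0.0
    for t1 in range(n):
        denom = 0.0
        for s1 in range(n):
            for s2 in range(n):
                denom += g[t1, s1] * g[t1, s2]
        denom /= n**2
        num = 0.0
        for t2 in range(n):
            for t3 in range(n):
                gg = g[t1, t2] * g[t1, t3]
                for t4 in range(n):
                    for t5 in range(n):
                        d = kmat[t2, t3] - kmat[t2, t4] - kmat[t3, t5] + kmat[t4, t5]
                        num += gg * d
        total += num / denom
    return total / n**5


def h2_self(u, config: KernelConfig | None = None) -> float:
    """Plug-in estimate of ``H2_K(U|U)``: mean diagonal minus mean of K."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("u must be a non-empty 1-d array")
    if np.ptp(u) == 0.0:
        return 0.0
    config = (config or KernelConfig()).resolve_sigma(u)
    return _h2_self_from_matrix(kernel_matrix(u, config))


def eccfic_corr(u, v, config: KernelConfig | None = None) -> EccficResult:
    """Estimated ECCFIC correlation ``rho = H2_K(U|V) / H2_K(U|U)``.

    Raises a degenerate-outcome error when U is constant (zero
    self-dependence leaves the ratio undefined).
    """
    u, v = _as_pair(u, v)
    if np.ptp(u) == 0.0:
        raise ValueError("H2_K(U|U) is zero: constant u has no normalizable dependence")
    config = (config or KernelConfig()).resolve_sigma(u)
    kmat = kernel_matrix(u, config)
    self_term = _h2_self_from_matrix(kmat)
    if self_term <= 0.0:
        raise ValueError("H2_K(U|U) is zero: constant u has no normalizable dependence")
    if u.size == 1:
        cond = 0.0
    else:
        h = config.resolve_bandwidth(v)
        cond = _h2_cond_from_matrices(kmat, smoothing_weights(v, h))
    return EccficResult(
        h2_cond=cond,
        h2_self=self_term,
        rho=cond / self_term,
        n=u.size,
        config=config,
    )
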