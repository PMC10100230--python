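"""CDF transforms that map raw survival and expression data onto the unit interval.

Screening operates on rank-like variables: the observed times are mapped
through the Kaplan-Meier estimate of the event-time CDF, and each gene is
mapped through its empirical CDF.  Both transforms are invariant under
strictly increasing changes of scale, which is what makes the downstream
dependence index robust to heavy tails and outliers in expression values.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = ["SurvivalSamples", "KaplanMeierCDF", "km_cdf", "ecdf_transform"]


@dataclass(frozen=True, eq=False)
class SurvivalSamples:
    """Right-censored survival observations.

    Parameters
    ----------
    y : array-like of float
        Observed times ``Y_i = min(T_i, C_i)``, strictly positive (months).
    delta : array-like of {0, 1}
        Event indicators ``delta_i = I(T_i <= C_i)``; 1 = event, 0 = censored.
    """

    y: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        delta = np.asarray(self.delta)
        if y.ndim != 1 or delta.ndim != 1 or y.shape != delta.shape:
            raise ValueError("y and delta must be 1-d arrays of equal length")
        if y.size == 0:
            raise ValueError("empty survival sample")
        if not np.all(np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("observed times must be finite and > 0")
        if not np.isin(delta, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "delta", delta.astype(np.int8))

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    def subset(self, idx) -> "SurvivalSamples":
        return SurvivalSamples(self.y[idx], self.delta[idx])


class KaplanMeierCDF:
    """Kaplan-Meier estimate of the event-time CDF, as a step function.

    The survival product uses one factor ``(1 - d_k / r_k)`` per distinct
    event time, with ``d_k`` events and ``r_k = #{Y_l >= t_k}`` at risk;
    censored observations tied with an event time count toward its risk set.
    Factors are accumulated in exact rational arithmetic so that, when every
    observation is an event, the estimate coincides bit-for-bit with the
    empirical CDF, tied times included.
    """

    def __init__(self, event_times: np.ndarray, cdf_values: np.ndarray):
        self.event_times = event_times  # distinct, ascending
        self.cdf_values = cdf_values  # F at each event time

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.event_times.size == 0:  # no events: F is identically zero
            out = np.zeros(t.shape)
        else:
            k = np.searchsorted(self.event_times, t, side="right")
            out = np.where(k > 0, self.cdf_values[np.maximum(k - 1, 0)], 0.0)
        return out if out.ndim else float(out)


def km_cdf(samples: SurvivalSamples) -> tuple[KaplanMeierCDF, np.ndarray]:
    """Kaplan-Meier CDF of the event time under right censoring.

    Returns the step function ``F_T`` and its values at each observed time
    ``Y_i`` (censored observations are evaluated exactly like events).  With
    no events at all the CDF is identically zero.
    """
    y, delta = samples.y, samples.delta
    event_mask = delta == 1
    times = np.unique(y[event_mask])
    # risk set and event count at each distinct event time
    y_sorted = np.sort(y)
    at_risk = y.size - np.searchsorted(y_sorted, times, side="left")
    d = np.array([np.count_nonzero(y[event_mask] == t) for t in times], dtype=int)

    surv = Fraction(1)
    cdf_vals = np.empty(times.size, dtype=float)
    for k in range(times.size):
        surv *= Fraction(int(at_risk[k] - d[k]), int(at_risk[k]))
        cdf_vals[k] = float(1 - surv)
    fhat = KaplanMeierCDF(times, cdf_vals)
    return fhat, np.asarray(fhat(y), dtype=float)


def ecdf_transform(x) -> np.ndarray:
    """Empirical CDF of a feature evaluated at its own observations.

    The i-th output is ``#{x_l <= x_i} / n``, so outputs lie in ``(0, 1]``
    with maximum exactly 1, and are invariant under any strictly increasing
    transform of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-d array")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    xs = np.sort(x)
    return np.searchsorted(xs, x, side="right") / x.size
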