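"""Synthetic censored survival datasets with a known active gene set.

Emulates the structure of high-throughput survival cohorts (hundreds of
samples, thousands of genes, 30-60% censoring, a handful of genes driving
the hazard linearly or nonlinearly) so that the screening -> selection ->
evaluation workflow is fully testable without external data.  The design is
the canonical screening test bed: mean-zero equicorrelated Gaussian genes,
event times from a proportional-hazards model (or a non-PH accelerated
model), and independent exponential censoring whose rate is calibrated to a
target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .screening import select_top
from .transforms import SurvivalSamples

__all__ = ["SyntheticDataset", "generate", "minimum_model_size"]

MODELS = ("cox_linear", "cox_nonlinear", "non_ph")

# defaults chosen as the study conditions; see docs/methods.md
DEFAULT_EFFECT_SIZE = 3.0
DEFAULT_CENSOR_FRAC = 0.4
DEFAULT_RHO_X = 0.0
BASELINE_HAZARD = 0.05  # events per month at zero linear predictor

# effect components standardized to mean zero / unit variance under X ~ N(0,1),
# so equal beta means equal per-gene signal regardless of the component's shape
_NONLINEAR_FUNCS = (
    ("square", lambda x: (x * x - 1.0) / np.sqrt(2.0)),
    ("sin", lambda x: np.sin(x) / np.sqrt((1.0 - np.exp(-2.0)) / 2.0)),
    ("abs", lambda x: (np.abs(x) - np.sqrt(2.0 / np.pi)) / np.sqrt(1.0 - 2.0 / np.pi)),
)


@dataclass(frozen=True, eq=False)
class SyntheticDataset:
    """Generated cohort with ground truth attached."""

    X: np.ndarray
    t: np.ndarray
    c: np.ndarray
    y: np.ndarray
    delta: np.ndarray
    active: np.ndarray
    descriptor: dict = field(compare=False)

    @property
    def samples(self) -> SurvivalSamples:
        return SurvivalSamples(self.y, self.delta)

    @property
    def gene_ids(self) -> np.ndarray:
        return np.array([f"g{j}" for j in range(self.X.shape[1])])

    @property
    def censor_fraction(self) -> float:
        return float(1.0 - self.delta.mean())


def _linear_predictor(X: np.ndarray, active: np.ndarray, beta: np.ndarray, model: str):
    """Score eta_i = sum_j beta_j f_j(X_ij) over the active set."""
    eta = np.zeros(X.shape[0])
    labels = []
    for k, j in enumerate(active):
        if model == "cox_linear":
            name, f = "identity", lambda x: x
        else:
            name, f = _NONLINEAR_FUNCS[k % len(_NONLINEAR_FUNCS)]
        eta += beta[k] * f(X[:, j])
        labels.append(name)
    return eta, labels


def _event_times(eta: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    n = eta.size
    if model in ("cox_linear", "cox_nonlinear"):
        # exponential baseline: T = E / (lambda0 * exp(eta)), E ~ Exp(1)
        return rng.exponential(1.0, n) / (BASELINE_HAZARD * np.exp(eta))
    # non-PH: log-normal accelerated model, monotone in the gene score plus noise
    s = (eta - eta.mean()) / (eta.std() + 1e-12)
    return 20.0 * np.exp(-0.7 * s + 0.5 * rng.standard_normal(n))


def _calibrate_censoring_rate(t_pilot: np.ndarray, censor_frac: float) -> float:
    """Exponential censoring rate c with P(C < T) = censor_frac, via root finding.

    For C ~ Exp(c) independent of T, P(censored) = 1 - E[exp(-c T)], which is
    continuous and increasing in c; the root is bracketed by a bounded
    doubling search before solving.
    """

    def frac(rate: float) -> float:
        return float(np.mean(-np.expm1(-rate * t_pilot)))

    lo, hi = 1e-12, 1.0
    for _ in range(60):
        if frac(hi) >= censor_frac:
            break
        hi *= 2.0
    else:
        raise RuntimeError("censoring calibration failed: target fraction unreachable")
    return brentq(lambda r: frac(r) - censor_frac, lo, hi, xtol=1e-12)


def generate(
    n: int,
    p: int,
    active_size: int = 4,
    model: str = "cox_linear",
    effect_size: float = DEFAULT_EFFECT_SIZE,
    censor_frac: float = DEFAULT_CENSOR_FRAC,
    rho_x: float = DEFAULT_RHO_X,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a censored survival cohort with ``active_size`` causal genes.

    Genes are mean-zero unit-variance Gaussian with pairwise correlation
    ``rho_x`` (equicorrelated; noise genes therefore correlate with active
    ones, stressing marginal screening).  The active set is the first
    ``active_size`` columns.  ``cox_linear`` uses hazard proportional to
    ``exp(sum beta_j X_j)``; ``cox_nonlinear`` cycles the effects through
    x^2, sin(x), |x|; ``non_ph`` draws event times from a log-normal
    accelerated model (violating proportional hazards).  Censoring is
    independent exponential, rate-calibrated on a pilot sample so the
    expected censored fraction equals ``censor_frac``.  Everything is
    reproducible from ``seed``, with sub-streams arranged so that growing
    ``p`` leaves the leading columns unchanged.
    """
    if not 0 < active_size <= p:
        raise ValueError("need 0 < active_size <= p")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    if not 0 <= rho_x < 1:
        raise ValueError("rho_x must be in [0, 1)")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")

    ss = np.random.SeedSequence(seed)
    rng_design, rng_event, rng_censor, rng_pilot = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # gene-major noise so the first columns are stable as p grows
    shared = rng_design.standard_normal(n)
    noise = rng_design.standard_normal((p, n)).T
    X = np.sqrt(rho_x) * shared[:, None] + np.sqrt(1.0 - rho_x) * noise

    active = np.arange(active_size)
    beta = np.full(active_size, float(effect_size))
    eta, effect_labels = _linear_predictor(X, active, beta, model)
    t = _event_times(eta, model, rng_event)

    if censor_frac == 0.0:
        c = np.full(n, np.inf)
        rate = 0.0
    else:
        # pilot cohort from the same model, on its own sub-stream
        m = max(4000, 4 * n)
        shared_p = rng_pilot.standard_normal(m)
        noise_p = rng_pilot.standard_normal((active_size, m)).T
        Xp = np.sqrt(rho_x) * shared_p[:, None] + np.sqrt(1.0 - rho_x) * noise_p
        eta_p, _ = _linear_predictor(Xp, active, beta, model)
        rate = _calibrate_censoring_rate(_event_times(eta_p, model, rng_pilot), censor_frac)
        c = rng_censor.exponential(1.0 / rate, n)

    y = np.minimum(t, c)
    delta = (t <= c).astype(np.int8)
    descriptor = {
        "model": model,
        "effect_size": float(effect_size),
        "effects": effect_labels,
        "censor_frac_target": float(censor_frac),
        "censoring_rate": float(rate),
        "rho_x": float(rho_x),
        "seed": int(seed),
        "n": int(n),
        "p": int(p),
    }
    return SyntheticDataset(X=X, t=t, c=c, y=y, delta=delta, active=active, descriptor=descriptor)


def minimum_model_size(scores, active) -> int:
    """Smallest screening size ``d`` whose top-``d`` set covers the active set.

    Uses the same deterministic ranking as `select_top`, so it equals the
    worst (1-based) rank among the active genes.
    """
    scores = np.asarray(scores, dtype=float)
    active = np.asarray(active, dtype=int)
    if active.size == 0:
        raise ValueError("active set must be nonempty")
    order = select_top(scores, scores.size).order
    positions = np.empty(scores.size, dtype=int)
    positions[order] = np.arange(scores.size)
    return int(positions[active].max() + 1)
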