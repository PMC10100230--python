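"""ESIS: ECCFIC-based sure independence screening for right-censored outcomes.

Each gene j is scored by the estimated ECCFIC correlation between the
Kaplan-Meier-transformed observed time, ``U_T = F_T(Y)``, and the
ECDF-transformed expression column, ``U_Xj = F_Xj(X_j)``.  Genes are ranked
by decreasing score and the top ``d`` retained; the ranking is model-free
(no proportional-hazards or linearity assumption) and invariant to strictly
monotone rescaling of any gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .eccfic import _h2_cond_from_matrices, _h2_self_from_matrix
from .kernels import KernelConfig, kernel_matrix, smoothing_weights
from .transforms import SurvivalSamples, ecdf_transform, km_cdf

__all__ = ["ScreeningResult", "esis_scores", "default_d", "select_top", "screen"]

logger = logging.getLogger(__name__)

D_RULES = ("n_over_logn", "two_n_over_logn", "three_n_over_logn", "n_minus_1")


@dataclass(frozen=True, eq=False)
class ScreeningResult:
    """Ranked screening output.

    ``order`` is the permutation of column indices by decreasing score (ties
    broken by ascending column index) and ``selected`` its first ``d``
    entries.  Columns that could not be scored (constant expression) carry a
    ``-inf`` sentinel score and are flagged in ``failed``.
    """

    gene_ids: np.ndarray
    scores: np.ndarray
    order: np.ndarray
    selected: np.ndarray
    d: int
    failed: np.ndarray

    @property
    def selected_ids(self) -> np.ndarray:
        return self.gene_ids[self.selected]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d samples x genes matrix")
    return X


def esis_scores(X, samples: SurvivalSamples, config: KernelConfig | None = None) -> np.ndarray:
    """Per-gene ECCFIC correlation scores ``w_j`` against the survival outcome.

    The outcome transform, its kernel Gram matrix and the kernel scale
    (median heuristic unless fixed) are shared across genes; per gene, only
    the ECDF transform, the Silverman bandwidth and the smoothing weights
    are recomputed.  Constant columns are flagged and scored ``-inf`` rather
    than silently dropped.
    """
    X = _as_matrix(X)
    n, p = X.shape
    if n != samples.n:
        raise ValueError("X row count does not match survival sample size")
    if samples.n_events == 0:
        raise ValueError("no events: the Kaplan-Meier transform is identically zero")
    _, u = km_cdf(samples)

    config = (config or KernelConfig()).resolve_sigma(u)
    kmat = kernel_matrix(u, config)
    self_term = _h2_self_from_matrix(kmat)
    if self_term <= 0.0:
        raise ValueError("degenerate outcome transform: H2_K(U|U) = 0")

    scores = np.full(p, -np.inf)
    n_failed = 0
    for j in range(p):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            n_failed += 1
            continue
        v = ecdf_transform(col)
        h = config.resolve_bandwidth(v)
        weights = smoothing_weights(v, h)
        scores[j] = _h2_cond_from_matrices(kmat, weights) / self_term
    if n_failed:
        logger.warning("%d constant gene column(s) scored as -inf", n_failed)
    return scores


def default_d(n: int, rule: str = "n_over_logn") -> int:
    """Common screening sizes: ``[n/log n]``, twice or thrice that, or ``n - 1``."""
    if n < 2:
        raise ValueError("need n >= 2")
    if rule == "n_minus_1":
        d = n - 1
    elif rule in D_RULES:
        mult = {"n_over_logn": 1, "two_n_over_logn": 2, "three_n_over_logn": 3}[rule]
        d = math.floor(mult * n / math.log(n))
    else:
        raise ValueError(f"unknown d rule {rule!r}")
    if d < 1:
        raise ValueError(f"rule {rule!r} yields d < 1 at n = {n}")
    return d


def select_top(scores, d: int, gene_ids=None) -> ScreeningResult:
    """Deterministic top-``d`` selection: descending score, ties by column index."""
    scores = np.asarray(scores, dtype=float)
    p = scores.size
    if not 1 <= d <= p:
        raise ValueError(f"d must be in [1, {p}], got {d}")
    if gene_ids is None:
        gene_ids = np.array([f"g{j}" for j in range(p)])
    else:
        gene_ids = np.asarray(gene_ids)
        if gene_ids.size != p:
            raise ValueError("gene_ids length does not match scores")
    # stable sort on index after primary sort on -score
    order = np.lexsort((np.arange(p), -scores))
    return ScreeningResult(
        gene_ids=gene_ids,
        scores=scores,
        order=order,
        selected=order[:d],
        d=d,
        failed=~np.isfinite(scores),
    )


def screen(
    X,
    samples: SurvivalSamples,
    config: KernelConfig | None = None,
    d: int | None = None,
    d_rule: str = "n_over_logn",
    gene_ids=None,
) -> ScreeningResult:
    """Score every gene and return the top-``d`` screened set."""
    scores = esis_scores(X, samples, config)
    if d is None:
        d = default_d(samples.n, d_rule)
    return select_top(scores, d, gene_ids)
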