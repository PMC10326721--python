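"""Bayesian false-discovery-rate control from posterior null probabilities.

Given posterior probabilities ``p_1 .. p_G`` that each gene is *not*
differentially translated, rejecting ``H0g`` whenever ``p_g < c`` has
estimated Bayesian FDR

    FDRhat(c) = sum_g p_g I(p_g < c) / sum_g I(p_g < c),

and the level-``alpha`` rule uses the supremum threshold

    c* = sup { c : FDRhat(c) < alpha }.

Operationally c* is found from the running averages of the sorted
probabilities.  The inequality ``p_g < c`` is strict, so genes tied at
the threshold are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .vi import FitResult

#: Sentinel returned by :func:`bayes_fdr` when the rejection set is empty.
NO_REJECTIONS = None


@dataclass
class FdrResult:
    """Decisions of the Bayesian FDR rule at one nominal level."""

    null_probs: np.ndarray
    alpha: float
    threshold: float  # c*; 0.0 when nothing can be rejected
    fdr_hat: float | None  # estimated FDR at c*, None when no rejections
    reject: np.ndarray  # boolean, reject H0g iff p_g < c*
    min_abs_log2_te_change: float | None = None

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


def _validate_probs(null_probs: np.ndarray) -> np.ndarray:
    p = np.asarray(null_probs, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("null_probs must be 1-D")
    if p.size and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
        raise ConfigurationError("null_probs must lie in [0, 1]")
    return p


def bayes_fdr(null_probs: np.ndarray, c: float) -> float | None:
    """Estimated Bayesian FDR of the rule "reject iff p_g < c".

    Returns the mean posterior null probability over the rejected set,
    or the ``NO_REJECTIONS`` sentinel (``None``) when no p_g falls
    strictly below ``c``.
    """
    p = _validate_probs(null_probs)
    mask = p < c
    if not mask.any():
        return NO_REJECTIONS
    return float(p[mask].mean())


def fdr_threshold(
    null_probs: np.ndarray, alpha: float
) -> tuple[float, np.ndarray]:
    """Supremum threshold c* controlling Bayesian FDR at ``alpha``.

    Returns ``(c_star, reject)`` where ``reject[g]`` is
    ``null_probs[g] < c_star``.  Since the estimated FDR of the top-k
    rejection set is the running mean of the sorted probabilities, c*
    is located by scanning those cumulative means; when no set is
    admissible the threshold is the 0.0 sentinel and nothing is
    rejected.
    """
    p = _validate_probs(null_probs)
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    cummean = np.cumsum(sorted_p) / np.arange(1, p.size + 1)
    # a rejection set {p < c} always contains every copy of a tied value,
    # so only ranks that end a tie group are candidate sets
    last_of_value = np.r_[sorted_p[1:] != sorted_p[:-1], True]
    admissible = (cummean < alpha) & last_of_value
    if not admissible.any():
        return 0.0, np.zeros(p.size, dtype=bool)
    k = int(np.max(np.nonzero(admissible)[0]))  # largest admissible rank
    v_max = sorted_p[k]
    above = sorted_p[sorted_p > v_max]
    if above.size:
        c_star = float(above[0])
    else:
        c_star = float(np.nextafter(v_max, math.inf))
    return c_star, p < c_star


def make_fdr_result(
    null_probs: np.ndarray,
    alpha: float,
    min_abs_log2_te_change: float | None = None,
) -> FdrResult:
    c_star, reject = fdr_threshold(null_probs, alpha)
    fdr_hat = bayes_fdr(null_probs, c_star) if reject.any() else None
    return FdrResult(
        null_probs=np.asarray(null_probs, dtype=float),
        alpha=alpha,
        threshold=c_star,
        fdr_hat=fdr_hat,
        reject=reject,
        min_abs_log2_te_change=min_abs_log2_te_change,
    )


def call_dtgs(
    fit: FitResult,
    alpha: float = 0.05,
    min_abs_log2_te_change: float | None = None,
) -> list[str]:
    """Genes called differentially translated at nominal FDR ``alpha``.

    Applies the Bayesian FDR threshold to the posterior null
    probabilities and, optionally, an effect-size filter retaining only
    genes whose posterior-mean translational-efficiency change exceeds
    ``min_abs_log2_te_change`` in absolute value on the log2 scale.
    The filter is applied after thresholding, without recomputing the
    FDR.  Output is sorted by null probability, most significant first.
    """
    _, reject = fdr_threshold(fit.null_prob, alpha)
    keep = reject.copy()
    if min_abs_log2_te_change is not None:
        keep &= np.abs(fit.te_change_log2) > min_abs_log2_te_change
    idx = np.nonzero(keep)[0]
    idx = idx[np.argsort(fit.null_prob[idx], kind="stable")]
    return [fit.gene_ids[i] for i in idx]
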