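"""Benchmark metrics: ROC/AUC for DTG ranking and realized-FDR calibration.

The benchmark runner simulates replicated studies with known truth,
fits the variational model to each, ranks genes by the posterior
probability of differential translation (1 - p_g), and summarizes
ranking accuracy (area under the ROC curve) and the realized false
discovery proportion of the Bayesian FDR rule at a grid of nominal
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConfigurationError, RibovbError
from .fdr import fdr_threshold
from .simulate import SimulationConfig, simulate
from .vi import FitControl, PriorHyperparameters, fit

#: FPR grid used for vertical averaging of replicate ROC curves.
FPR_GRID = np.linspace(0.0, 1.0, 101)

#: Sentinel for "no rejections" when computing a realized FDR.
NO_REJECTIONS = None


def roc_auc(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Empirical ROC curve and area (larger score = more likely DTG).

    The AUC equals the Mann-Whitney concordance statistic; ties are
    handled by trapezoidal interpolation.  Returns ``((fpr, tpr), auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ConfigurationError("scores and truth must have equal length")
    if truth.all() or not truth.any():
        raise RibovbError("ROC undefined: truth contains a single class")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(roc_auc_score(truth, scores))
    return (fpr, tpr), auc


def realized_fdr(decisions: np.ndarray, truth: np.ndarray) -> float | None:
    """False discoveries / rejections; ``NO_REJECTIONS`` if none rejected."""
    decisions = np.asarray(decisions, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if decisions.shape != truth.shape:
        raise ConfigurationError("decisions and truth must have equal length")
    n_rej = int(decisions.sum())
    if n_rej == 0:
        return NO_REJECTIONS
    return float((decisions & ~truth).sum() / n_rej)


@dataclass
class BenchmarkResult:
    """Aggregated metrics over replicated simulated studies."""

    auc: np.ndarray  # per-replicate AUC
    mean_roc: np.ndarray  # TPR averaged on FPR_GRID
    fpr_grid: np.ndarray
    nominal_levels: np.ndarray
    fdr_by_level: np.ndarray  # (replicates, levels); NaN = no rejections
    n_rejected: np.ndarray  # (replicates, levels)
    converged: np.ndarray  # per-replicate convergence flag
    seeds: np.ndarray
    zero_rejection_policy: str = "zero"

    @property
    def mean_auc(self) -> float:
        return float(self.auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.auc.std(ddof=1)) if self.auc.size > 1 else 0.0

    def mean_realized_fdr(self) -> np.ndarray:
        """Per-level mean realized FDR under the zero-rejection policy."""
        vals = self.fdr_by_level.copy()
        if self.zero_rejection_policy == "zero":
            vals = np.nan_to_num(vals, nan=0.0)
            return vals.mean(axis=0)
        return np.nanmean(vals, axis=0)

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.auc.size):
            rows.append(
                dict(replicate=r, metric="auc", level=np.nan, value=self.auc[r])
            )
            for j, lvl in enumerate(self.nominal_levels):
                rows.append(
                    dict(
                        replicate=r, metric="realized_fdr", level=lvl,
                        value=self.fdr_by_level[r, j],
                    )
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            dict(metric="auc", level=np.nan, mean=self.mean_auc, sd=self.sd_auc)
        ]
        mfdr = self.mean_realized_fdr()
        vals = np.nan_to_num(self.fdr_by_level, nan=0.0)
        for j, lvl in enumerate(self.nominal_levels):
            sd = float(vals[:, j].std(ddof=1)) if vals.shape[0] > 1 else 0.0
            rows.append(dict(metric="realized_fdr", level=lvl,
                             mean=mfdr[j], sd=sd))
        return pd.DataFrame(rows)


def run_benchmark(
    config: SimulationConfig,
    nominal_levels: np.ndarray | list[float] = (0.05, 0.10),
    replicates: int = 20,
    seed: int = 1,
    prior: PriorHyperparameters | None = None,
    control: FitControl | None = None,
    zero_rejection_policy: str = "zero",
) -> BenchmarkResult:
    """Simulate, fit and score ``replicates`` studies.

    Each replicate reseeds the simulator from a child of ``seed``,
    fits the variational model, scores genes by 1 - p_g, computes the
    AUC against the simulated truth, and applies the Bayesian FDR rule
    at each nominal level to obtain realized false discovery
    proportions.  Replicates with zero rejections contribute FDR 0 to
    the averages by default (``zero_rejection_policy="exclude"`` drops
    them instead).  Fit non-convergence is recorded, not fatal.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    if zero_rejection_policy not in ("zero", "exclude"):
        raise ConfigurationError("zero_rejection_policy must be zero|exclude")
    nominal_levels = np.asarray(nominal_levels, dtype=float)
    children = np.random.SeedSequence(seed).spawn(replicates)
    seeds = np.array(
        [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]
    )
    aucs = np.empty(replicates)
    fdrs = np.full((replicates, nominal_levels.size), np.nan)
    nrej = np.zeros((replicates, nominal_levels.size), dtype=int)
    conv = np.zeros(replicates, dtype=bool)
    curves = np.empty((replicates, FPR_GRID.size))
    for r in range(replicates):
        data = simulate(replace(config, seed=int(seeds[r])))
        result = fit(data.table, prior=prior, control=control)
        conv[r] = result.converged
        scores = 1.0 - result.null_prob
        (fpr, tpr), aucs[r] = roc_auc(scores, data.is_dtg)
        curves[r] = np.interp(FPR_GRID, fpr, tpr)
        for j, lvl in enumerate(nominal_levels):
            _, reject = fdr_threshold(result.null_prob, float(lvl))
            nrej[r, j] = int(reject.sum())
            val = realized_fdr(reject, data.is_dtg)
            fdrs[r, j] = np.nan if val is NO_REJECTIONS else val
    return BenchmarkResult(
        auc=aucs,
        mean_roc=curves.mean(axis=0),
        fpr_grid=FPR_GRID.copy(),
        nominal_levels=nominal_levels,
        fdr_by_level=fdrs,
        n_rejected=nrej,
        converged=conv,
        seeds=seeds,
        zero_rejection_policy=zero_rejection_policy,
    )
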