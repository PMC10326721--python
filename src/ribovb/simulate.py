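"""Synthetic paired Ribo-seq/RNA-seq data with known truth.

Three generating schemes of increasing distance from the fitted model:

* ``A_poisson`` — counts drawn exactly from the Poisson-log-normal
  model: gene coefficients from Gaussians, a spike at zero on the
  interaction for a ``pi0`` fraction of genes, shared per-(gene,
  sample) Gaussian random effects, Poisson emission.
* ``B_negbin`` — same mean structure, negative-binomial emission with
  gene-specific dispersions drawn from a configurable pool.
* ``C_ribodiff`` — separate negative-binomial baseline means for mRNA
  and RPF, multiplicative fold changes from a shifted gamma applied to
  randomly chosen mRNA-only / RPF-only / both subsets, a shared
  lognormal sample effect multiplying each mRNA/RPF pair, and
  negative-binomial emission with dispersion a declining function of
  the mean.

A gene is a true differentially-translated gene (DTG) exactly when the
generated RPF:mRNA ratio differs between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError
from .model import MRNA, RPF, GeneParameters, PairedCountTable

SCHEMES = ("A_poisson", "B_negbin", "C_ribodiff")

CONTROL = "control"
TREATMENT = "treatment"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    The model-based defaults (schemes A/B) are: log baseline expression
    ``beta_g0 ~ N(5, 1)``, treatment and preparation main effects
    ``beta_g1, beta_g2 ~ N(0, 0.5^2)``, slab ``W_g ~ N(0, 0.75^2)``,
    null fraction ``pi0 = 0.8``, random-effect scale ``sigma_u = 0.35``.
    Scheme B draws gene dispersions from LogNormal(ln 0.1, 0.5^2).
    Scheme C uses baseline means from a negative binomial with mean 200
    and dispersion 0.3, shifted-gamma fold changes (shape 0.6, scale
    0.5, shift 1.5), dispersion function ``phi(mu) = 0.1 + 1/mu`` and
    perturbs 10% of genes in mRNA only, 10% in RPF only and 10% in
    both, giving ~20% true DTGs under the default identical-fold-change
    convention for the "both" subset.
    """

    scheme: str = "A_poisson"
    G: int = 2000
    n: int = 2  # replicates per condition
    pi0: float = 0.8
    beta0_mean: float = 5.0
    beta0_sd: float = 1.0
    beta1_sd: float = 0.5
    beta2_sd: float = 0.5
    slab_mean: float = 0.0
    slab_sd: float = 0.75
    sigma_u: float = 0.35
    # scheme B
    dispersion_log_mean: float = math.log(0.1)
    dispersion_log_sd: float = 0.5
    dispersion_pool: tuple[float, ...] | None = None
    # scheme C
    baseline_mean: float = 200.0
    baseline_dispersion: float = 0.3
    fc_shape: float = 0.6
    fc_scale: float = 0.5
    fc_shift: float = 1.5
    frac_mrna_only: float = 0.1
    frac_rpf_only: float = 0.1
    frac_both: float = 0.1
    both_independent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if not 0 <= self.pi0 <= 1:
            raise ConfigurationError("pi0 must be in [0, 1]")
        if self.G < 1 or self.n < 1:
            raise ConfigurationError("G and n must be >= 1")
        if min(self.beta0_sd, self.beta1_sd, self.beta2_sd, self.slab_sd,
               self.sigma_u) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        total = self.frac_mrna_only + self.frac_rpf_only + self.frac_both
        if total > 1 or min(
            self.frac_mrna_only, self.frac_rpf_only, self.frac_both
        ) < 0:
            raise ConfigurationError("perturbation fractions invalid")


@dataclass
class SimulatedDataset:
    """A count table plus the generating truth per gene."""

    table: PairedCountTable
    truth: list[GeneParameters]
    is_dtg: np.ndarray  # boolean, beta_g3 != 0

    @property
    def true_beta3(self) -> np.ndarray:
        return np.array([t.beta[3] for t in self.truth])


def sample_fold_changes(
    count: int,
    shape: float = 0.6,
    scale: float = 0.5,
    shift: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draws from a shifted gamma: shift + Gamma(shape, scale).

    With the default parameters every fold change is at least 1.5, so
    an affected gene's log-scale translational-efficiency change is at
    least ln 1.5 ~ 0.405; the mean is shift + shape * scale = 1.8.
    """
    if shape <= 0 or scale <= 0:
        raise ConfigurationError("shape and scale must be > 0")
    if shift < 0:
        raise ConfigurationError("shift must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return shift + rng.gamma(shape, scale, size=count)


def _make_table(counts: np.ndarray, n: int) -> PairedCountTable:
    G = counts.shape[0]
    sample_ids = [f"ctrl_{i + 1}" for i in range(n)] + [
        f"trt_{i + 1}" for i in range(n)
    ]
    condition = {
        s: (CONTROL if s.startswith("ctrl") else TREATMENT) for s in sample_ids
    }
    col_sample = [s for s in sample_ids for _ in (MRNA, RPF)]
    col_prep = [p for _ in sample_ids for p in (MRNA, RPF)]
    return PairedCountTable(
        gene_ids=[f"gene_{g + 1}" for g in range(G)],
        counts=counts,
        sample_ids=sample_ids,
        condition=condition,
        col_sample=col_sample,
        col_prep=col_prep,
        reference=CONTROL,
    )


def _negbin(
    rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray
) -> np.ndarray:
    """NB(mean mu, dispersion phi) with Var = mu + phi mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    rate = rng.gamma(1.0 / dispersion, dispersion * mean)
    return rng.poisson(rate)


def simulate_model_based(config: SimulationConfig) -> SimulatedDataset:
    """Schemes A (Poisson) and B (negative binomial) from the model.

    Draws gene coefficients and random effects from the hierarchical
    model, zeroes the interaction for a Bernoulli(pi0) fraction of
    genes, builds per-observation means via the 2 x 2 log-linear
    predictor and emits Poisson or negative-binomial counts.
    """
    if config.scheme not in ("A_poisson", "B_negbin"):
        raise ConfigurationError(
            f"simulate_model_based requires scheme A or B, got {config.scheme!r}"
        )
    rng = np.random.default_rng(config.seed)
    G, n = config.G, config.n
    N = 2 * n
    beta = np.empty((G, 4))
    beta[:, 0] = rng.normal(config.beta0_mean, config.beta0_sd, G)
    beta[:, 1] = rng.normal(0.0, config.beta1_sd, G)
    beta[:, 2] = rng.normal(0.0, config.beta2_sd, G)
    W = rng.normal(config.slab_mean, config.slab_sd, G)
    D = rng.random(G) < config.pi0
    beta[:, 3] = np.where(D, 0.0, W)
    u = rng.normal(0.0, config.sigma_u, (G, N))

    # observation layout: sample-major, mRNA then RPF; treatment samples last
    is_trt = np.repeat(np.arange(N) >= n, 2).astype(float)
    is_rpf = np.tile([0.0, 1.0], N)
    X = np.column_stack([np.ones(2 * N), is_trt, is_rpf, is_trt * is_rpf])
    sample_of_obs = np.repeat(np.arange(N), 2)
    log_lam = beta @ X.T + u[:, sample_of_obs]
    lam = np.exp(log_lam)
    if config.scheme == "A_poisson":
        counts = rng.poisson(lam)
    else:
        if config.dispersion_pool is not None:
            disp = rng.choice(np.asarray(config.dispersion_pool, float), size=G)
        else:
            disp = rng.lognormal(
                config.dispersion_log_mean, config.dispersion_log_sd, G
            )
        counts = _negbin(rng, lam, disp[:, None])

    truth = [
        GeneParameters(beta=beta[g], W=float(W[g]), D=int(D[g]), u=u[g])
        for g in range(G)
    ]
    return SimulatedDataset(
        table=_make_table(counts, n),
        truth=truth,
        is_dtg=beta[:, 3] != 0.0,
    )


def simulate_ribodiff_style(
    config: SimulationConfig,
    mean_dispersion: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SimulatedDataset:
    """Scheme C: fold-change perturbation of separate mRNA/RPF means.

    Baseline mRNA and RPF means are drawn per gene from a negative
    binomial.  Three disjoint random gene subsets receive shifted-gamma
    fold changes on the treatment-condition means of mRNA only, RPF
    only, or both.  A gene is a true DTG exactly when the applied
    change alters the RPF:mRNA ratio between conditions; with the
    default identical fold change for the "both" subset those genes
    remain null (``both_independent=True`` draws two independent fold
    changes and labels them DTGs).  Each mRNA/RPF pair shares a
    lognormal sample effect, and counts are negative binomial with
    dispersion ``phi(mu) = 0.1 + 1/mu`` unless overridden.
    """
    if config.scheme != "C_ribodiff":
        raise ConfigurationError(
            f"simulate_ribodiff_style requires scheme C, got {config.scheme!r}"
        )
    if mean_dispersion is None:
        mean_dispersion = lambda mu: 0.1 + 1.0 / np.maximum(mu, 1e-8)
    rng = np.random.default_rng(config.seed)
    G, n = config.G, config.n
    N = 2 * n

    mu_mrna = np.maximum(
        _negbin(rng, np.full(G, config.baseline_mean),
                np.full(G, config.baseline_dispersion)).astype(float), 1.0
    )
    mu_rpf = np.maximum(
        _negbin(rng, np.full(G, config.baseline_mean),
                np.full(G, config.baseline_dispersion)).astype(float), 1.0
    )

    perm = rng.permutation(G)
    n_m = int(round(config.frac_mrna_only * G))
    n_r = int(round(config.frac_rpf_only * G))
    n_b = int(round(config.frac_both * G))
    idx_m = perm[:n_m]
    idx_r = perm[n_m:n_m + n_r]
    idx_b = perm[n_m + n_r:n_m + n_r + n_b]
    if len(set(idx_m) & set(idx_r) | set(idx_m) & set(idx_b)
           | set(idx_r) & set(idx_b)) > 0:
        raise ConfigurationError("perturbation subsets must be disjoint")

    fc_m_trt = np.ones(G)  # fold change on treatment mRNA mean
    fc_r_trt = np.ones(G)  # fold change on treatment RPF mean
    fc = lambda k: sample_fold_changes(
        k, config.fc_shape, config.fc_scale, config.fc_shift, rng
    )
    fc_m_trt[idx_m] = fc(n_m)
    fc_r_trt[idx_r] = fc(n_r)
    if config.both_independent:
        fc_m_trt[idx_b] = fc(n_b)
        fc_r_trt[idx_b] = fc(n_b)
    else:
        shared = fc(n_b)
        fc_m_trt[idx_b] = shared
        fc_r_trt[idx_b] = shared

    # implied log-linear truth: beta3 is the between-condition change of
    # the log RPF:mRNA ratio
    beta = np.empty((G, 4))
    beta[:, 0] = np.log(mu_mrna)
    beta[:, 1] = np.log(fc_m_trt)
    beta[:, 2] = np.log(mu_rpf / mu_mrna)
    beta[:, 3] = np.log(fc_r_trt / fc_m_trt)

    u = rng.normal(0.0, config.sigma_u, (G, N))
    is_trt_sample = np.arange(N) >= n
    mean_mrna = mu_mrna[:, None] * np.where(is_trt_sample, fc_m_trt[:, None], 1.0)
    mean_rpf = mu_rpf[:, None] * np.where(is_trt_sample, fc_r_trt[:, None], 1.0)
    shared = np.exp(u)
    mean_mrna = mean_mrna * shared
    mean_rpf = mean_rpf * shared

    counts = np.empty((G, 2 * N), dtype=np.int64)
    counts[:, 0::2] = _negbin(rng, mean_mrna, mean_dispersion(mean_mrna))
    counts[:, 1::2] = _negbin(rng, mean_rpf, mean_dispersion(mean_rpf))

    is_dtg = beta[:, 3] != 0.0
    truth = [
        GeneParameters(
            beta=beta[g],
            W=float(beta[g, 3]) if is_dtg[g] else 0.0,
            D=int(not is_dtg[g]),
            u=u[g],
        )
        for g in range(G)
    ]
    return SimulatedDataset(table=_make_table(counts, n), truth=truth, is_dtg=is_dtg)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Dispatch on ``config.scheme``."""
    if config.scheme == "C_ribodiff":
        return simulate_ribodiff_style(config)
    return simulate_model_based(config)
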