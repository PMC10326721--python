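"""Core data structures for the paired Ribo-seq/RNA-seq count model.

The observation model is a Poisson-log-normal generalized linear mixed
model.  For gene ``g``, sample ``i`` and preparation ``j`` (``j = 1`` for
RNA-seq, ``j = 2`` for ribosome-protected fragments, RPF),

    y_gij ~ Poisson(lambda_gij),
    log lambda_gij = x_ij' beta_g + u_gi + o_ij,

where ``x_ij = (1, I(i in treatment), I(j = RPF), I(both))`` encodes the
2 x 2 condition-by-preparation layout, ``u_gi`` is a sample-level random
effect shared by the mRNA/RPF pair from the same biological sample, and
``o_ij`` is an optional known log-scale offset (zero by default).

On this parameterization the log-scale translational-efficiency change
between conditions is the interaction coefficient ``beta_g3``, which
carries a spike-and-slab prior: ``beta_g3 = (1 - D_g) W_g`` with
``D_g ~ Bernoulli(pi0)`` (``D_g = 1`` means the gene is null) and a
Gaussian slab ``W_g``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, NumericError, PairingError

MRNA = "mRNA"
RPF = "RPF"
PREPARATIONS = (MRNA, RPF)

DESIGN_COLUMNS = ("intercept", "treatment", "preparation", "interaction")


@dataclass
class PairedCountTable:
    """A genes-by-observations count matrix with paired-column metadata.

    Columns are stored in canonical order: sample-major, mRNA before RPF
    within each sample, samples ordered with all reference-condition
    samples first (input order otherwise preserved).

    Parameters
    ----------
    gene_ids
        Length-G list of unique gene identifiers.
    counts
        G x 2N matrix of non-negative integer read counts.
    sample_ids
        Length-N list of sample identifiers.
    condition
        Maps each sample id to one of exactly two condition labels.
    col_sample
        Length-2N list mapping each count column to its sample id.
    col_prep
        Length-2N list mapping each count column to ``"mRNA"`` or ``"RPF"``.
    reference
        The condition label coded as 0 in the design; defaults to the
        condition of the first sample.
    """

    gene_ids: list[str]
    counts: np.ndarray
    sample_ids: list[str]
    condition: dict[str, str]
    col_sample: list[str]
    col_prep: list[str]
    reference: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self._validate()
        self._canonicalize()

    # -- validation -------------------------------------------------
    def _validate(self) -> None:
        G, C = self.counts.shape if self.counts.ndim == 2 else (0, 0)
        if self.counts.ndim != 2 or G < 1:
            raise FormatError("counts must be a non-empty 2-D matrix")
        if len(self.gene_ids) != G:
            raise FormatError("gene_ids length does not match counts rows")
        if len(set(self.gene_ids)) != G:
            raise FormatError("duplicate gene ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.all(np.isfinite(as_int)) or np.any(as_int != np.floor(as_int)):
                raise FormatError("counts must be integers")
            self.counts = as_int.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        N = len(self.sample_ids)
        if N < 2:
            raise ConfigurationError("need at least two samples")
        if C != 2 * N:
            raise FormatError(f"expected {2 * N} count columns, got {C}")
        if len(self.col_sample) != C or len(self.col_prep) != C:
            raise FormatError("column metadata length mismatch")
        for prep in self.col_prep:
            if prep not in PREPARATIONS:
                raise FormatError(f"unknown preparation {prep!r}")
        for s in self.sample_ids:
            preps = [p for c, p in zip(self.col_sample, self.col_prep) if c == s]
            if sorted(preps) != sorted(PREPARATIONS):
                raise PairingError(
                    f"sample {s!r} must own exactly one mRNA and one RPF column"
                )
        labels = sorted({self.condition[s] for s in self.sample_ids})
        if len(labels) != 2:
            raise ConfigurationError(
                f"exactly two condition labels required, got {labels}"
            )
        if self.reference is None:
            self.reference = self.condition[self.sample_ids[0]]
        if self.reference not in labels:
            raise ConfigurationError(
                f"reference condition {self.reference!r} not present"
            )

    def _canonicalize(self) -> None:
        ref = self.reference
        order = sorted(
            range(len(self.sample_ids)),
            key=lambda k: (self.condition[self.sample_ids[k]] != ref, k),
        )
        self.sample_ids = [self.sample_ids[k] for k in order]
        col_of = {
            (s, p): k for k, (s, p) in enumerate(zip(self.col_sample, self.col_prep))
        }
        perm = [col_of[(s, p)] for s in self.sample_ids for p in PREPARATIONS]
        self.counts = np.ascontiguousarray(self.counts[:, perm])
        self.col_sample = [s for s in self.sample_ids for _ in PREPARATIONS]
        self.col_prep = [p for _ in self.sample_ids for p in PREPARATIONS]

    # -- convenience ------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def treatment_label(self) -> str:
        labels = {self.condition[s] for s in self.sample_ids}
        (other,) = labels - {self.reference}
        return other

    def subset_genes(self, keep: Sequence[int]) -> "PairedCountTable":
        keep = list(keep)
        return PairedCountTable(
            gene_ids=[self.gene_ids[k] for k in keep],
            counts=self.counts[keep].copy(),
            sample_ids=list(self.sample_ids),
            condition=dict(self.condition),
            col_sample=list(self.col_sample),
            col_prep=list(self.col_prep),
            reference=self.reference,
        )


@dataclass
class DesignMatrix:
    """Per-observation covariates for the 2 x 2 layout.

    Each of the 2N rows is ``x = (1, I(treatment), I(RPF), product)``;
    ``sample_index`` maps each row to its sample (0..N-1) and ``offset``
    holds known per-observation log offsets.
    """

    X: np.ndarray
    sample_index: np.ndarray
    offset: np.ndarray
    column_labels: tuple[str, ...] = DESIGN_COLUMNS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.sample_index = np.asarray(self.sample_index, dtype=int)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 4:
            raise ConfigurationError("design matrix must have 4 columns")
        if not np.all(np.isin(self.X, (0.0, 1.0))):
            raise ConfigurationError("design entries must be 0/1")
        if not np.all(self.X[:, 0] == 1.0):
            raise ConfigurationError("first design column must be all ones")
        if not np.allclose(self.X[:, 3], self.X[:, 1] * self.X[:, 2]):
            raise ConfigurationError(
                "interaction column must equal treatment * preparation"
            )
        if self.offset.shape != (self.X.shape[0],):
            raise ConfigurationError("offset length mismatch")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.sample_index.max()) + 1


def build_design(
    table: PairedCountTable,
    offset: np.ndarray | str | None = None,
) -> DesignMatrix:
    """Build the 2 x 2 design matrix matching a count table's column order.

    The four distinct row patterns give the cell means on the log scale:
    (beta0) for control mRNA, (beta0 + beta1) treatment mRNA,
    (beta0 + beta2) control RPF, (beta0 + beta1 + beta2 + beta3)
    treatment RPF.

    Parameters
    ----------
    table
        Validated paired count table (canonical column order).
    offset
        Per-column log offsets.  ``None`` (default) uses zeros, i.e. the
        bare model with no library-size normalization; the string
        ``"depth"`` computes ``log(column total / geometric mean of
        column totals)``; an array is used as-is.
    """
    sample_pos = {s: k for k, s in enumerate(table.sample_ids)}
    trt = table.treatment_label
    n_obs = 2 * table.n_samples
    X = np.zeros((n_obs, 4))
    sample_index = np.zeros(n_obs, dtype=int)
    for k, (s, p) in enumerate(zip(table.col_sample, table.col_prep)):
        is_trt = 1.0 if table.condition[s] == trt else 0.0
        is_rpf = 1.0 if p == RPF else 0.0
        X[k] = (1.0, is_trt, is_rpf, is_trt * is_rpf)
        sample_index[k] = sample_pos[s]
    if offset is None:
        off = np.zeros(n_obs)
    elif isinstance(offset, str):
        if offset != "depth":
            raise ConfigurationError(f"unknown offset mode {offset!r}")
        totals = table.counts.sum(axis=0).astype(float)
        if np.any(totals <= 0):
            raise ConfigurationError("cannot compute depth offsets: empty column")
        off = np.log(totals) - np.mean(np.log(totals))
    else:
        off = np.asarray(offset, dtype=float)
        if not np.all(np.isfinite(off)):
            raise NumericError("offsets must be finite")
    return DesignMatrix(X=X, sample_index=sample_index, offset=off)


@dataclass(frozen=True)
class PriorHyperparameters:
    """Fixed constants of the conjugate hyperpriors.

    ``sigma_u^2 ~ InvGamma(alpha_u, gamma_u)`` (shape/rate),
    ``sigma_beta_p^2 ~ InvGamma(alpha_beta[p], gamma_beta[p])`` for
    p = 0..3 (p = 3 governs the slab variable W),
    ``mu_beta_p ~ Normal(0, sigma2_mu)``, and
    ``pi0 ~ Beta(*pi0_prior)``.

    Defaults are weakly informative: inverse-gamma shape 2 / rate 1
    (prior mean variance 1), a diffuse Normal(0, 100) on the
    hierarchical means, and a uniform Beta(1, 1) on the null fraction.
    """

    alpha_u: float = 2.0
    gamma_u: float = 1.0
    alpha_beta: tuple[float, float, float, float] = (2.0, 2.0, 2.0, 2.0)
    gamma_beta: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    sigma2_mu: float = 100.0
    pi0_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        vals = [self.alpha_u, self.gamma_u, self.sigma2_mu, *self.alpha_beta,
                *self.gamma_beta, *self.pi0_prior]
        if len(self.alpha_beta) != 4 or len(self.gamma_beta) != 4:
            raise ConfigurationError("alpha_beta/gamma_beta must have length 4")
        if any((not np.isfinite(v)) or v <= 0 for v in vals):
            raise ConfigurationError("all prior hyperparameters must be > 0")


@dataclass
class GeneParameters:
    """Ground-truth (in simulation) or estimand (in inference) per gene."""

    beta: np.ndarray  # (beta_g0, beta_g1, beta_g2, beta_g3)
    W: float
    D: int
    u: np.ndarray  # length-N sample effects

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.beta.shape != (4,):
            raise ConfigurationError("beta must have length 4")
        if self.D not in (0, 1):
            raise ConfigurationError("D must be 0 or 1")
        expected = (1 - self.D) * self.W
        if not math.isclose(self.beta[3], expected, rel_tol=0.0, abs_tol=1e-12):
            raise ConfigurationError("beta[3] must equal (1 - D) * W")


def cell_mean_log(
    beta: np.ndarray, x: np.ndarray, u: float = 0.0, offset: float = 0.0
) -> float:
    """Log-scale Poisson mean for one observation: x' beta + u + offset."""
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    val = float(x @ beta + u + offset)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(x)) and np.isfinite(val)):
        raise NumericError("non-finite input to cell_mean_log")
    return val


def lognormal_rate_moment(mean: float, variance: float) -> float:
    """E[exp(eta)] for Gaussian eta: exp(mean + variance / 2).

    This is the moment that turns a Gaussian variational factor on the
    log rate into an expected Poisson rate.
    """
    if not (np.isfinite(mean) and np.isfinite(variance)):
        raise NumericError("non-finite input to lognormal_rate_moment")
    if variance < 0:
        raise NumericError("variance must be non-negative")
    return float(np.exp(mean + variance / 2.0))
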