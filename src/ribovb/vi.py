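"""Mean-field variational Bayes for the paired-count mixed model.

The variational posterior factorizes over genes, the null indicators
``D_g`` and the global parameters

    q(theta) = q(phi) prod_g q(D_g) q_g(kappa_g | D_g),

where ``q(phi)`` collects conjugate factors — Normal for the
hierarchical means ``mu_beta_p``, inverse-gamma for the variances
``sigma_u^2`` and ``sigma_beta_p^2``, Beta for the null fraction
``pi0`` — and the per-gene block is *branch-conditional*: given
``D_g = 0`` (non-null) a full multivariate Gaussian over
``kappa_g = (beta_g0, beta_g1, beta_g2, W_g, u_g1..u_gN)``; given
``D_g = 1`` (null) a Gaussian over ``(beta_g0, beta_g1, beta_g2,
u_g1..u_gN)`` with the decoupled slab ``W_g`` reverting to its
(expected) prior in closed form.  Conditioning the Gaussian block on
the indicator keeps the evidence (Occam) term in the indicator update:
a single Gaussian shared by both branches makes the coordinate-ascent
fixed point for ``q(D_g)`` collapse to a hard 0/1 classification,
which ruins the calibration of the posterior null probabilities that
Bayesian FDR control relies on.

Indicator and hyperparameter factors admit closed-form conjugate
coordinate updates; ``q(D_g = 1)`` is the logistic function of the
difference of per-branch free energies plus the prior log-odds of the
null.  The Gaussian blocks are not conjugate to the Poisson likelihood
and are updated by non-conjugate variational message passing (NCVMP),
whose natural-parameter fixed-point map for a Gaussian ``N(m, S)``
simplifies to

    S_new^-1 = -2 dF/dS,        m_new = m + S_new dF/dm,

with ``F(m, S) = E_q[ln p(y, theta)]`` holding all other factors
fixed.  Every Poisson term contributes a positive-semidefinite
rank-one piece to the proposed precision and the Gaussian prior adds a
positive-definite diagonal, so proposals stay positive definite; steps
are damped on the natural-parameter scale and the outer loop
backtracks on the rare ELBO decrease, keeping the ELBO trace
non-decreasing in practice.

The natural-parameter convention for the Gaussian blocks is canonical:
``(precision times mean, -1/2 precision)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import betaln, digamma, expit, gammaln, xlogy

from .errors import ConfigurationError, NumericError
from .model import DesignMatrix, PairedCountTable, PriorHyperparameters, build_design

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# variational factor containers
# ---------------------------------------------------------------------------


@dataclass
class GeneVariationalFactor:
    """Multivariate Gaussian block for one gene, one indicator branch."""

    mean: np.ndarray  # (d,)
    cov: np.ndarray  # (d, d), symmetric positive definite

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.shape[0]
        if self.cov.shape != (d, d):
            raise ConfigurationError("covariance shape mismatch")
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise NumericError("covariance is not positive definite") from exc

    @property
    def natural_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Canonical natural parameters (precision @ mean, -1/2 precision)."""
        prec = np.linalg.inv(self.cov)
        return prec @ self.mean, -0.5 * prec

    @classmethod
    def from_natural(
        cls, eta1: np.ndarray, eta2: np.ndarray
    ) -> "GeneVariationalFactor":
        prec = -2.0 * np.asarray(eta2, dtype=float)
        cov = np.linalg.inv(prec)
        cov = 0.5 * (cov + cov.T)
        return cls(mean=cov @ np.asarray(eta1, dtype=float), cov=cov)

    def log_partition(self) -> float:
        """h(lambda) = 1/2 m' S^-1 m + 1/2 ln det S + d/2 ln 2 pi."""
        d = self.mean.shape[0]
        sign, logdet = np.linalg.slogdet(self.cov)
        if sign <= 0:
            raise NumericError("covariance is not positive definite")
        prec = np.linalg.inv(self.cov)
        return float(
            0.5 * self.mean @ prec @ self.mean + 0.5 * logdet + 0.5 * d * _LOG2PI
        )


@dataclass
class GlobalVariationalFactor:
    """Conjugate factors for hyperparameters and the null fraction."""

    mu_mean: np.ndarray  # q(mu_beta_p) means, length 4
    mu_var: np.ndarray  # q(mu_beta_p) variances, length 4
    su_shape: float  # q(sigma_u^2) = InvGamma(shape, rate)
    su_rate: float
    sb_shape: np.ndarray  # q(sigma_beta_p^2), length 4
    sb_rate: np.ndarray
    pi_a: float  # q(pi0) = Beta(pi_a, pi_b)
    pi_b: float

    def __post_init__(self) -> None:
        self.mu_mean = np.asarray(self.mu_mean, dtype=float)
        self.mu_var = np.asarray(self.mu_var, dtype=float)
        self.sb_shape = np.asarray(self.sb_shape, dtype=float)
        self.sb_rate = np.asarray(self.sb_rate, dtype=float)
        positives = np.concatenate(
            [self.mu_var, self.sb_shape, self.sb_rate,
             [self.su_shape, self.su_rate, self.pi_a, self.pi_b]]
        )
        if np.any(~np.isfinite(positives)) or np.any(positives <= 0):
            raise NumericError("global factor parameters must be positive")

    # expectations used throughout the updates
    @property
    def e_inv_su(self) -> float:
        return self.su_shape / self.su_rate

    @property
    def e_inv_sb(self) -> np.ndarray:
        return self.sb_shape / self.sb_rate

    @property
    def e_log_pi(self) -> float:
        return float(digamma(self.pi_a) - digamma(self.pi_a + self.pi_b))

    @property
    def e_log_1mpi(self) -> float:
        return float(digamma(self.pi_b) - digamma(self.pi_a + self.pi_b))


@dataclass(frozen=True)
class FitControl:
    """Knobs of the outer variational loop."""

    max_iterations: int = 100
    elbo_tolerance: float = 1e-4
    elbo_rel_tolerance: float = 1e-8
    damping: float = 0.5
    seed: int = 0
    init_jitter_sd: float = 0.0
    exp_clip: float = 30.0
    max_backtracks: int = 12

    def __post_init__(self) -> None:
        if self.elbo_tolerance <= 0:
            raise ConfigurationError("elbo_tolerance must be > 0")
        if not 0 < self.damping <= 1:
            raise ConfigurationError("damping must be in (0, 1]")


@dataclass
class VariationalState:
    """All variational factors; gene blocks stored as stacked arrays.

    ``M_alt``/``S_alt`` hold the non-null branch Gaussians over the
    (4+N)-dimensional kappa including the slab W; ``M_null``/``S_null``
    hold the null branch over the (3+N)-dimensional vector without it.
    """

    M_alt: np.ndarray  # (G, 4+N)
    S_alt: np.ndarray  # (G, 4+N, 4+N)
    M_null: np.ndarray  # (G, 3+N)
    S_null: np.ndarray  # (G, 3+N, 3+N)
    p: np.ndarray  # (G,) Bernoulli null probabilities q(D_g = 1)
    globals_: GlobalVariationalFactor
    n_samples: int

    @property
    def n_genes(self) -> int:
        return self.M_alt.shape[0]

    def gene_factor(self, g: int, branch: str = "alt") -> GeneVariationalFactor:
        if branch == "alt":
            return GeneVariationalFactor(self.M_alt[g].copy(), self.S_alt[g].copy())
        if branch == "null":
            return GeneVariationalFactor(self.M_null[g].copy(), self.S_null[g].copy())
        raise ConfigurationError("branch must be 'alt' or 'null'")

    def slab_null_moments(self) -> tuple[float, float]:
        """Mean and variance of q(W | D = 1), the prior-matched slab."""
        g = self.globals_
        return float(g.mu_mean[3]), float(g.sb_rate[3] / g.sb_shape[3])

    # mixture posterior moments over the indicator
    def beta_mean(self) -> np.ndarray:
        """(G, 4) posterior means of (beta_0, beta_1, beta_2, beta_3)."""
        out = np.empty((self.n_genes, 4))
        out[:, :3] = (
            self.p[:, None] * self.M_null[:, :3]
            + (1.0 - self.p)[:, None] * self.M_alt[:, :3]
        )
        out[:, 3] = (1.0 - self.p) * self.M_alt[:, 3]
        return out

    def copy(self) -> "VariationalState":
        return VariationalState(
            M_alt=self.M_alt.copy(),
            S_alt=self.S_alt.copy(),
            M_null=self.M_null.copy(),
            S_null=self.S_null.copy(),
            p=self.p.copy(),
            globals_=replace(
                self.globals_,
                mu_mean=self.globals_.mu_mean.copy(),
                mu_var=self.globals_.mu_var.copy(),
                sb_shape=self.globals_.sb_shape.copy(),
                sb_rate=self.globals_.sb_rate.copy(),
            ),
            n_samples=self.n_samples,
        )


@dataclass
class FitResult:
    """Output of :func:`fit`."""

    gene_ids: list[str]
    null_prob: np.ndarray  # p_g = q(D_g = 1)
    beta3_mean: np.ndarray  # E[beta_g3] = (1 - p_g) E[W_g | D_g = 0]
    slab_mean: np.ndarray  # E[W_g | D_g = 0]
    beta_mean: np.ndarray  # (G, 4) posterior means
    state: VariationalState
    elbo_trace: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def te_change_log2(self) -> np.ndarray:
        return self.beta3_mean / math.log(2.0)


# ---------------------------------------------------------------------------
# internal dense representation
# ---------------------------------------------------------------------------


def _selectors(design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Selector rows mapping each branch's kappa to the linear predictor.

    ``A_alt`` (K x (4+N)) routes the interaction through the slab
    coordinate W; ``A_null`` (K x (3+N)) has no slab coordinate.
    """
    K = design.n_obs
    N = design.n_samples
    A_alt = np.zeros((K, 4 + N))
    A_alt[:, :4] = design.X
    A_alt[np.arange(K), 4 + design.sample_index] = 1.0
    A_null = np.zeros((K, 3 + N))
    A_null[:, :3] = design.X[:, :3]
    A_null[np.arange(K), 3 + design.sample_index] = 1.0
    return A_alt, A_null


def _check_dims(table: PairedCountTable, design: DesignMatrix) -> None:
    if design.n_obs != table.counts.shape[1]:
        raise ConfigurationError("design rows do not match count columns")
    if design.n_samples != table.n_samples:
        raise ConfigurationError("design samples do not match table samples")


def _log_rate_terms(
    M: np.ndarray, S: np.ndarray, A: np.ndarray, offset: np.ndarray, clip: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(gene, obs) E[eta] and clipped log E[exp(eta)] for one branch."""
    mean = M @ A.T + offset[None, :]
    var = np.einsum("ki,gij,kj->gk", A, S, A, optimize=True)
    c = np.minimum(mean + 0.5 * var, clip)
    return mean, c


def _branch_prior(
    glob: GlobalVariationalFactor, n_samples: int, with_slab: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected prior precision diag, prior mean, and mean-uncertainty diag."""
    nb = 4 if with_slab else 3
    d = nb + n_samples
    r = np.empty(d)
    r[:nb] = glob.e_inv_sb[:nb]
    r[nb:] = glob.e_inv_su
    mu_bar = np.zeros(d)
    mu_bar[:nb] = glob.mu_mean[:nb]
    mu_unc = np.zeros(d)
    mu_unc[:nb] = glob.mu_var[:nb]
    return r, mu_bar, mu_unc


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_state(
    table: PairedCountTable,
    design: DesignMatrix,
    prior: PriorHyperparameters,
    control: FitControl,
) -> VariationalState:
    """Moment-based initialization of every variational factor.

    Gene-block means start from ``log(count + 0.5)`` cell averages
    mapped to the four coefficients (the null branch drops the
    interaction); sample effects start at zero with a generous variance
    so the random-effect scale can adapt in either direction.
    Hyperparameter factors are moment-matched to the spread of the
    initial coefficients; ``p_g`` starts at the prior mean of the null
    fraction.
    """
    _check_dims(table, design)
    G = table.n_genes
    N = table.n_samples
    Y = table.counts.astype(float)
    Z = np.log(Y + 0.5) - design.offset[None, :]
    X = design.X
    cells = {
        (0, 0): (X[:, 1] == 0) & (X[:, 2] == 0),
        (1, 0): (X[:, 1] == 1) & (X[:, 2] == 0),
        (0, 1): (X[:, 1] == 0) & (X[:, 2] == 1),
        (1, 1): (X[:, 1] == 1) & (X[:, 2] == 1),
    }
    m = {key: Z[:, mask].mean(axis=1) for key, mask in cells.items()}
    b0 = m[(0, 0)]
    b1 = m[(1, 0)] - b0
    b2 = m[(0, 1)] - b0
    w = m[(1, 1)] - m[(1, 0)] - m[(0, 1)] + b0

    M_alt = np.zeros((G, 4 + N))
    M_alt[:, 0], M_alt[:, 1], M_alt[:, 2], M_alt[:, 3] = b0, b1, b2, w
    M_null = np.zeros((G, 3 + N))
    M_null[:, 0], M_null[:, 1], M_null[:, 2] = b0, b1, b2
    if control.init_jitter_sd > 0:
        rng = np.random.default_rng(control.seed)
        M_alt = M_alt + rng.normal(0.0, control.init_jitter_sd, M_alt.shape)
        M_null = M_null + rng.normal(0.0, control.init_jitter_sd, M_null.shape)

    def diag_cov(nb: int) -> np.ndarray:
        d = nb + N
        S = np.zeros((G, d, d))
        diag = np.concatenate([np.full(nb, 0.05), np.full(N, 0.25)])
        S[:, np.arange(d), np.arange(d)] = diag
        return S

    a0, b0p = prior.pi0_prior
    p = np.full(G, a0 / (a0 + b0p))

    mu_mean = M_alt[:, :4].mean(axis=0)
    spread = ((M_alt[:, :4] - mu_mean) ** 2).sum(axis=0)
    glob = GlobalVariationalFactor(
        mu_mean=mu_mean,
        mu_var=np.full(4, 0.1),
        su_shape=prior.alpha_u,
        su_rate=prior.gamma_u,
        sb_shape=np.asarray(prior.alpha_beta) + 0.5 * G,
        sb_rate=np.asarray(prior.gamma_beta) + 0.5 * spread + 1e-8,
        pi_a=a0,
        pi_b=b0p,
    )
    return VariationalState(
        M_alt=M_alt, S_alt=diag_cov(4),
        M_null=M_null, S_null=diag_cov(3),
        p=p, globals_=glob, n_samples=N,
    )


# ---------------------------------------------------------------------------
# expected rates
# ---------------------------------------------------------------------------


def expected_rate(
    state: VariationalState,
    g: int,
    x: np.ndarray,
    sample_index: int,
    offset: float = 0.0,
    clip: float = 30.0,
) -> float:
    """E_q[exp(x' beta_g + u_gi + offset)] mixing over the null indicator.

    The rate mixes the spike-and-slab branches,
    ``p_g E[e^eta | D=1] + (1 - p_g) E[e^eta | D=0]``, each branch a
    Gaussian moment-generating-function evaluation
    ``exp(a'm + a'Sa/2)`` with the branch's selector vector ``a``; for
    a null gene the slab coordinate never enters.
    """
    x = np.asarray(x, dtype=float)
    N = state.n_samples
    a_alt = np.zeros(4 + N)
    a_alt[:4] = x
    a_alt[4 + sample_index] = 1.0
    a_null = np.zeros(3 + N)
    a_null[:3] = x[:3]
    a_null[3 + sample_index] = 1.0
    out = 0.0
    for weight, a, M, S in (
        (float(state.p[g]), a_null, state.M_null[g], state.S_null[g]),
        (1.0 - float(state.p[g]), a_alt, state.M_alt[g], state.S_alt[g]),
    ):
        c = a @ M + 0.5 * a @ S @ a + offset
        out += weight * math.exp(min(c, clip))
    return out


# ---------------------------------------------------------------------------
# vectorized update steps
# ---------------------------------------------------------------------------


def _ncvmp_step(
    M: np.ndarray,
    S: np.ndarray,
    Y: np.ndarray,
    A: np.ndarray,
    offset: np.ndarray,
    r: np.ndarray,
    mu_bar: np.ndarray,
    rho: float | np.ndarray,
    clip: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One damped NCVMP step for every gene's Gaussian block, one branch.

    ``r`` and ``mu_bar`` are the expected prior precision diagonal and
    prior mean of the branch's kappa.  ``rho`` may be a scalar or
    per-gene damping factor applied on the natural-parameter scale.
    """
    G, d = M.shape
    _, c = _log_rate_terms(M, S, A, offset, clip)
    w = np.exp(c)  # (G, K) expected rates

    prec_new = np.einsum("gk,ki,kj->gij", w, A, A, optimize=True)
    prec_new[:, np.arange(d), np.arange(d)] += r[None, :]
    grad = (Y - w) @ A - (M - mu_bar[None, :]) * r[None, :]
    S_prop = np.linalg.inv(prec_new)
    m_prop = M + np.einsum("gij,gj->gi", S_prop, grad)

    # damp on the natural-parameter scale; a convex combination of
    # positive-definite precisions stays positive definite
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (G,))
    prec_old = np.linalg.inv(S)
    h_old = np.einsum("gij,gj->gi", prec_old, M)
    h_prop = np.einsum("gij,gj->gi", prec_new, m_prop)
    lam = rho_arr[:, None, None]
    prec_d = (1.0 - lam) * prec_old + lam * prec_new
    h_d = (1.0 - rho_arr[:, None]) * h_old + rho_arr[:, None] * h_prop
    S_new = np.linalg.inv(prec_d)
    S_new = 0.5 * (S_new + np.swapaxes(S_new, 1, 2))
    M_new = np.einsum("gij,gj->gi", S_new, h_d)
    return M_new, S_new


def _branch_free_energy(
    M: np.ndarray,
    S: np.ndarray,
    Y: np.ndarray,
    A: np.ndarray,
    offset: np.ndarray,
    r: np.ndarray,
    mu_bar: np.ndarray,
    mu_unc: np.ndarray,
    e_log_inv: np.ndarray,
    clip: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (E_q[ln p(y, kappa | phi)], entropy) for one branch.

    ``e_log_inv`` holds E[ln(1/prior variance)] per kappa coordinate.
    """
    G, d = M.shape
    mean, c = _log_rate_terms(M, S, A, offset, clip)
    lik = (Y * mean - np.exp(c) - gammaln(Y + 1.0)).sum(axis=1)
    idx = np.arange(d)
    e_dev2 = (
        (M - mu_bar[None, :]) ** 2 + S[:, idx, idx] + mu_unc[None, :]
    )
    prior = (
        0.5 * (e_log_inv - _LOG2PI)[None, :] - 0.5 * r[None, :] * e_dev2
    ).sum(axis=1)
    sign, logdet = np.linalg.slogdet(S)
    if np.any(sign <= 0):
        raise NumericError("gene covariance lost positive definiteness")
    entropy = 0.5 * (logdet + d * (1.0 + _LOG2PI))
    return lik + prior, entropy


def _slab_null_terms(glob: GlobalVariationalFactor) -> float:
    """E[ln p(W | phi)] + H of the prior-matched q(W | D = 1).

    With q(W | D=1) = N(m_mu3, 1 / E[1/sigma_b3^2]) this is the same
    for every gene:  1/2 (E[ln 1/s2] - ln 2 pi) - 1/2 (1 + r3 var(mu3))
    + 1/2 ln(2 pi e / r3).
    """
    r3 = float(glob.e_inv_sb[3])
    e_log_inv = float(digamma(glob.sb_shape[3]) - math.log(glob.sb_rate[3]))
    f = 0.5 * (e_log_inv - _LOG2PI) - 0.5 * (1.0 + r3 * float(glob.mu_var[3]))
    h = 0.5 * (1.0 + _LOG2PI - math.log(r3))
    return f + h


def _e_log_inv_diag(
    glob: GlobalVariationalFactor, n_samples: int, with_slab: bool
) -> np.ndarray:
    nb = 4 if with_slab else 3
    out = np.empty(nb + n_samples)
    out[:nb] = (digamma(glob.sb_shape) - np.log(glob.sb_rate))[:nb]
    out[nb:] = digamma(glob.su_shape) - math.log(glob.su_rate)
    return out


def _indicator_step(
    state: VariationalState,
    Y: np.ndarray,
    A_alt: np.ndarray,
    A_null: np.ndarray,
    offset: np.ndarray,
    clip: float,
) -> np.ndarray:
    """Conjugate update of every q(D_g).

    p_g is the logistic function of the prior log-odds of the null plus
    the difference of branch free energies (expected log-joint plus
    entropy), the structured-factor analogue of the ell_1 - ell_0
    contrast; the free-energy form keeps the evidence (Occam) penalty
    for the extra slab dimension.
    """
    glob = state.globals_
    N = state.n_samples
    r0, mu0, unc0 = _branch_prior(glob, N, with_slab=True)
    r1, mu1, unc1 = _branch_prior(glob, N, with_slab=False)
    f_alt, h_alt = _branch_free_energy(
        state.M_alt, state.S_alt, Y, A_alt, offset,
        r0, mu0, unc0, _e_log_inv_diag(glob, N, True), clip,
    )
    f_null, h_null = _branch_free_energy(
        state.M_null, state.S_null, Y, A_null, offset,
        r1, mu1, unc1, _e_log_inv_diag(glob, N, False), clip,
    )
    slab_const = _slab_null_terms(glob)
    logit = (
        glob.e_log_pi - glob.e_log_1mpi
        + (f_null + h_null + slab_const) - (f_alt + h_alt)
    )
    return expit(logit)


def _mixture_moments(
    state: VariationalState,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Indicator-averaged moments needed by the conjugate global updates.

    Returns (E[beta_p], E[beta_p^2], E[W], E[W^2], E[u_i^2]) where the
    beta arrays are (G, 3) over p = 0..2 and u is (G, N).
    """
    p = state.p[:, None]
    N = state.n_samples
    i3 = np.arange(3)
    v_alt = state.S_alt[:, i3, i3]
    v_null = state.S_null[:, i3, i3]
    e_b = p * state.M_null[:, :3] + (1.0 - p) * state.M_alt[:, :3]
    e_b2 = (
        p * (state.M_null[:, :3] ** 2 + v_null)
        + (1.0 - p) * (state.M_alt[:, :3] ** 2 + v_alt)
    )
    m_w1, v_w1 = state.slab_null_moments()
    e_w = p[:, 0] * m_w1 + (1.0 - p[:, 0]) * state.M_alt[:, 3]
    e_w2 = (
        p[:, 0] * (m_w1**2 + v_w1)
        + (1.0 - p[:, 0]) * (state.M_alt[:, 3] ** 2 + state.S_alt[:, 3, 3])
    )
    iu_alt = np.arange(4, 4 + N)
    iu_null = np.arange(3, 3 + N)
    e_u2 = (
        p * (state.M_null[:, 3:] ** 2 + state.S_null[:, iu_null, iu_null])
        + (1.0 - p) * (state.M_alt[:, 4:] ** 2 + state.S_alt[:, iu_alt, iu_alt])
    )
    return e_b, e_b2, e_w, e_w2, e_u2


def _global_step(
    state: VariationalState, prior: PriorHyperparameters
) -> GlobalVariationalFactor:
    """Closed-form conjugate updates of all hyperparameter factors.

    q(sigma_u^2): shape alpha_u + GN/2, rate gamma_u + sum E[u^2]/2;
    q(sigma_beta_p^2): shape alpha_p + G/2, rate gamma_p +
    sum E[(beta_p - mu_p)^2]/2 (the slab W for p = 3);
    q(mu_p): precision 1/sigma_mu^2 + G E[1/sigma_p^2], matched mean;
    q(pi0): Beta(a0 + sum p_g, b0 + sum (1 - p_g)).
    """
    glob = state.globals_
    G = state.n_genes
    N = state.n_samples
    e_b, e_b2, e_w, e_w2, e_u2 = _mixture_moments(state)
    su_shape = prior.alpha_u + 0.5 * G * N
    su_rate = prior.gamma_u + 0.5 * e_u2.sum()

    e_all = np.column_stack([e_b, e_w])
    e_all2 = np.column_stack([e_b2, e_w2])
    e_dev2 = (
        e_all2 - 2.0 * e_all * glob.mu_mean[None, :]
        + (glob.mu_mean**2 + glob.mu_var)[None, :]
    )
    sb_shape = np.asarray(prior.alpha_beta) + 0.5 * G
    sb_rate = np.asarray(prior.gamma_beta) + 0.5 * e_dev2.sum(axis=0)

    r_b = sb_shape / sb_rate
    mu_prec = 1.0 / prior.sigma2_mu + G * r_b
    mu_var = 1.0 / mu_prec
    mu_mean = r_b * e_all.sum(axis=0) * mu_var

    a0, b0 = prior.pi0_prior
    return GlobalVariationalFactor(
        mu_mean=mu_mean,
        mu_var=mu_var,
        su_shape=su_shape,
        su_rate=su_rate,
        sb_shape=sb_shape,
        sb_rate=sb_rate,
        pi_a=a0 + state.p.sum(),
        pi_b=b0 + (1.0 - state.p).sum(),
    )


# ---------------------------------------------------------------------------
# spec-level single-gene wrappers
# ---------------------------------------------------------------------------


def update_gene_factor(
    g: int,
    state: VariationalState,
    table: PairedCountTable,
    design: DesignMatrix,
    prior: PriorHyperparameters,
    damping: float = 0.5,
    branch: str = "alt",
    clip: float = 30.0,
) -> GeneVariationalFactor:
    """One damped NCVMP update of gene ``g``'s Gaussian block."""
    A_alt, A_null = _selectors(design)
    sl = slice(g, g + 1)
    Y = table.counts[sl].astype(float)
    if branch == "alt":
        r, mu_bar, _ = _branch_prior(state.globals_, state.n_samples, True)
        M, S = _ncvmp_step(
            state.M_alt[sl], state.S_alt[sl], Y, A_alt, design.offset,
            r, mu_bar, damping, clip,
        )
    elif branch == "null":
        r, mu_bar, _ = _branch_prior(state.globals_, state.n_samples, False)
        M, S = _ncvmp_step(
            state.M_null[sl], state.S_null[sl], Y, A_null, design.offset,
            r, mu_bar, damping, clip,
        )
    else:
        raise ConfigurationError("branch must be 'alt' or 'null'")
    return GeneVariationalFactor(mean=M[0], cov=S[0])


def update_indicator(
    g: int,
    state: VariationalState,
    table: PairedCountTable,
    design: DesignMatrix,
    clip: float = 30.0,
) -> float:
    """Conjugate update of q(D_g); returns the new null probability."""
    A_alt, A_null = _selectors(design)
    sub = VariationalState(
        M_alt=state.M_alt[g:g + 1], S_alt=state.S_alt[g:g + 1],
        M_null=state.M_null[g:g + 1], S_null=state.S_null[g:g + 1],
        p=state.p[g:g + 1], globals_=state.globals_,
        n_samples=state.n_samples,
    )
    p = _indicator_step(
        sub, table.counts[g:g + 1].astype(float), A_alt, A_null,
        design.offset, clip,
    )
    return float(p[0])


def update_global_factors(
    state: VariationalState, prior: PriorHyperparameters
) -> GlobalVariationalFactor:
    """Conjugate updates of q(sigma_u^2), q(sigma_beta_p^2), q(mu), q(pi0).

    With no genes every factor reverts to its prior.
    """
    if state.n_genes == 0:
        a0, b0 = prior.pi0_prior
        return GlobalVariationalFactor(
            mu_mean=np.zeros(4),
            mu_var=np.full(4, prior.sigma2_mu),
            su_shape=prior.alpha_u,
            su_rate=prior.gamma_u,
            sb_shape=np.asarray(prior.alpha_beta, dtype=float),
            sb_rate=np.asarray(prior.gamma_beta, dtype=float),
            pi_a=a0,
            pi_b=b0,
        )
    return _global_step(state, prior)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


def _invgamma_entropy(shape: np.ndarray, rate: np.ndarray) -> np.ndarray:
    return shape + np.log(rate) + gammaln(shape) - (1.0 + shape) * digamma(shape)


def _beta_entropy(a: float, b: float) -> float:
    return float(
        betaln(a, b)
        - (a - 1.0) * digamma(a)
        - (b - 1.0) * digamma(b)
        + (a + b - 2.0) * digamma(a + b)
    )


def compute_elbo(
    state: VariationalState,
    table: PairedCountTable,
    design: DesignMatrix,
    prior: PriorHyperparameters,
    clip: float = 30.0,
) -> float:
    """Evidence lower bound E_q[ln p(y, theta)] - E_q[ln q(theta)].

    All expectations are closed-form for the chosen factor families;
    the Poisson rate expectation reuses the same clipped
    moment-generating-function evaluation as the updates.
    """
    glob = state.globals_
    G = state.n_genes
    N = state.n_samples
    Y = table.counts.astype(float)
    A_alt, A_null = _selectors(design)
    p = state.p

    r0, mu0, unc0 = _branch_prior(glob, N, with_slab=True)
    r1, mu1, unc1 = _branch_prior(glob, N, with_slab=False)
    f_alt, h_alt = _branch_free_energy(
        state.M_alt, state.S_alt, Y, A_alt, design.offset,
        r0, mu0, unc0, _e_log_inv_diag(glob, N, True), clip,
    )
    f_null, h_null = _branch_free_energy(
        state.M_null, state.S_null, Y, A_null, design.offset,
        r1, mu1, unc1, _e_log_inv_diag(glob, N, False), clip,
    )
    slab_const = _slab_null_terms(glob)
    gene_terms = float(
        (p * (f_null + h_null + slab_const) + (1.0 - p) * (f_alt + h_alt)).sum()
    )
    prior_d = float((p * glob.e_log_pi + (1.0 - p) * glob.e_log_1mpi).sum())
    ent_d = float(-(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)).sum())

    def ig_cross(alpha: float, gamma: float, shape: float, rate: float) -> float:
        e_log_s2 = math.log(rate) - digamma(shape)
        return (
            alpha * math.log(gamma)
            - gammaln(alpha)
            - (alpha + 1.0) * e_log_s2
            - gamma * shape / rate
        )

    hyper = ig_cross(prior.alpha_u, prior.gamma_u, glob.su_shape, glob.su_rate)
    for pp in range(4):
        hyper += ig_cross(
            prior.alpha_beta[pp], prior.gamma_beta[pp],
            float(glob.sb_shape[pp]), float(glob.sb_rate[pp]),
        )
    hyper += float(
        (-0.5 * (_LOG2PI + math.log(prior.sigma2_mu))
         - (glob.mu_mean**2 + glob.mu_var) / (2.0 * prior.sigma2_mu)).sum()
    )
    a0, b0 = prior.pi0_prior
    hyper += float(
        -betaln(a0, b0)
        + (a0 - 1.0) * glob.e_log_pi
        + (b0 - 1.0) * glob.e_log_1mpi
    )

    ent_ig = float(
        _invgamma_entropy(
            np.asarray([glob.su_shape]), np.asarray([glob.su_rate])
        ).sum()
        + _invgamma_entropy(glob.sb_shape, glob.sb_rate).sum()
    )
    ent_mu = float((0.5 * (1.0 + _LOG2PI + np.log(glob.mu_var))).sum())
    ent_pi = _beta_entropy(glob.pi_a, glob.pi_b)

    elbo = gene_terms + prior_d + ent_d + hyper + ent_ig + ent_mu + ent_pi
    if not np.isfinite(elbo):
        terms = dict(
            gene_terms=gene_terms, prior_d=prior_d, ent_d=ent_d,
            hyper=hyper, ent_ig=ent_ig, ent_mu=ent_mu, ent_pi=ent_pi,
        )
        bad = [k for k, v in terms.items() if not np.isfinite(v)]
        raise NumericError(f"non-finite ELBO; offending terms: {bad}")
    return float(elbo)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------


def _one_iteration(
    state: VariationalState,
    Y: np.ndarray,
    A_alt: np.ndarray,
    A_null: np.ndarray,
    offset: np.ndarray,
    prior: PriorHyperparameters,
    rho: float,
    clip: float,
) -> VariationalState:
    """Gene blocks (both branches), then indicators, then global factors."""
    glob = state.globals_
    N = state.n_samples
    r0, mu0, _ = _branch_prior(glob, N, with_slab=True)
    r1, mu1, _ = _branch_prior(glob, N, with_slab=False)
    M_alt, S_alt = _ncvmp_step(
        state.M_alt, state.S_alt, Y, A_alt, offset, r0, mu0, rho, clip
    )
    M_null, S_null = _ncvmp_step(
        state.M_null, state.S_null, Y, A_null, offset, r1, mu1, rho, clip
    )
    interim = VariationalState(
        M_alt=M_alt, S_alt=S_alt, M_null=M_null, S_null=S_null,
        p=state.p, globals_=glob, n_samples=N,
    )
    interim.p = _indicator_step(interim, Y, A_alt, A_null, offset, clip)
    interim.globals_ = _global_step(interim, prior)
    return interim


def fit(
    table: PairedCountTable,
    design: DesignMatrix | None = None,
    prior: PriorHyperparameters | None = None,
    control: FitControl | None = None,
) -> FitResult:
    """Fit the model by mean-field variational Bayes.

    Iterates NCVMP updates of every gene's branch Gaussians, conjugate
    updates of the null indicators and of the global factors, then
    evaluates the ELBO, until the ELBO change falls below
    ``control.elbo_tolerance`` or ``control.max_iterations`` is
    reached.  If an iteration would decrease the ELBO, the iteration is
    re-run from the previous state with halved damping.

    Returns a :class:`FitResult` with per-gene posterior null
    probabilities, effect estimates
    ``E[beta_g3] = (1 - p_g) E[W_g | D_g = 0]``, the full variational
    state and the ELBO trace.  Non-convergence is flagged on the
    result, not raised.
    """
    prior = prior or PriorHyperparameters()
    control = control or FitControl()
    if design is None:
        design = build_design(table)
    _check_dims(table, design)
    A_alt, A_null = _selectors(design)
    Y = table.counts.astype(float)
    clip = control.exp_clip

    state = initialize_state(table, design, prior, control)
    elbo = compute_elbo(state, table, design, prior, clip)
    trace = [elbo]
    converged = False
    clip_warned = False
    for it in range(control.max_iterations):
        rho = control.damping
        accepted = None
        for _ in range(control.max_backtracks):
            cand = _one_iteration(
                state, Y, A_alt, A_null, design.offset, prior, rho, clip
            )
            try:
                cand_elbo = compute_elbo(cand, table, design, prior, clip)
            except NumericError:
                rho *= 0.5
                continue
            if cand_elbo >= elbo - 1e-8 * max(1.0, abs(elbo)):
                accepted = (cand, cand_elbo)
                break
            rho *= 0.5
        if accepted is None:
            logger.warning(
                "iteration %d: ELBO decrease persisted after %d dampings; "
                "accepting last step", it, control.max_backtracks,
            )
            accepted = (cand, cand_elbo)
        state, new_elbo = accepted
        trace.append(new_elbo)
        if not clip_warned:
            _, c_a = _log_rate_terms(
                state.M_alt, state.S_alt, A_alt, design.offset, np.inf
            )
            if np.any(c_a > clip):
                logger.warning("exp() arguments clipped at %.1f", clip)
                clip_warned = True
        delta = abs(new_elbo - elbo)
        elbo = new_elbo
        if delta < control.elbo_tolerance + control.elbo_rel_tolerance * abs(elbo):
            converged = True
            break
    if not converged:
        logger.warning(
            "variational loop did not converge in %d iterations",
            control.max_iterations,
        )
    beta_mean = state.beta_mean()
    return FitResult(
        gene_ids=list(table.gene_ids),
        null_prob=state.p.copy(),
        beta3_mean=beta_mean[:, 3].copy(),
        slab_mean=state.M_alt[:, 3].copy(),
        beta_mean=beta_mean,
        state=state,
        elbo_trace=np.asarray(trace),
        converged=converged,
        n_iterations=len(trace) - 1,
    )
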