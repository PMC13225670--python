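"""Probit-liability sum-of-single-effects fine-mapping engine.

The model for a binary trait y over one genomic region is the liability
threshold representation of a probit regression:

    y_i = 1{z_i > 0},
    z_i = mu + Ghat_i' beta + X_i' alpha + C_i' xi + eps_i,   eps_i ~ N(0, 1),

where Ghat (n x p) is the standardized predicted-expression matrix over the
region's gene-tissue pairs, X (n x s) the standardized region genotypes
carrying horizontal pleiotropy under a ridge prior alpha ~ N(0, sigma2_alpha I)
with sigma2_alpha ~ IG(1, 1), C covariates and mu the intercept (both under
flat priors).  The pair effects take the sum-of-single-effects form

    beta = sum_{l=1..L} beta_l gamma_l,   beta_l ~ N(0, sigma2_beta),
    gamma_l ~ Multinomial(1, pi),

with a hierarchical gene -> tissue selection prior pi_j = pi_g(j) * pi_t(j)|g(j)
and uninformative Dirichlet(1, ..., 1) priors on the gene vector and each
per-gene tissue vector.

Inference is mean-field coordinate-ascent variational Bayes.  Each factor
update is the exact conjugate optimum (truncated-normal liabilities, Gaussian
single-effect regressions weighted by digamma prior expectations, a
multivariate-normal ridge solve for alpha, flat-prior Gaussian updates for
mu and xi, Dirichlet pseudo-count updates), and the hyperparameters
(sigma2_beta, sigma2_alpha) are refreshed each sweep at their
ELBO-maximizing values, so the evidence lower bound is non-decreasing across
sweeps up to floating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, log_ndtr, ndtri

from ._ser import ACTIVE_V_TOL
from .io import CovariateMatrix, FineMapResult, GReXMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparameters",
    "FitConfig",
    "RegionData",
    "ModelState",
    "truncated_normal_moments",
    "init_state",
    "update_latent_liabilities",
    "update_single_effect",
    "update_pleiotropy",
    "update_covariates_intercept",
    "update_dirichlet",
    "update_hyperparameters",
    "compute_elbo",
    "fit",
]

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# truncated normal moments
# ---------------------------------------------------------------------------


def truncated_normal_moments(m: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moments of N(m, 1) truncated to (0, inf) where y = 1, (-inf, 0] where y = 0.

    Returns (mean, variance, log normalizing constant).  Uses log-space Mills
    ratios (``log_ndtr``), numerically stable for |m| far beyond 6.
    """
    m = np.asarray(m, dtype=np.float64)
    y = np.asarray(y)
    sign = np.where(y == 1, 1.0, -1.0)
    a = sign * m  # work on the y=1 orientation
    log_phi = -0.5 * a**2 - 0.5 * _LOG2PI
    logZ = log_ndtr(a)
    lam = np.exp(log_phi - logZ)  # phi(a) / Phi(a)
    mean = a + lam
    var = 1.0 - lam * (lam + a)
    var = np.clip(var, 1e-10, 1.0)
    return sign * mean, var, logZ


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------


@dataclass
class Hyperparameters:
    """Variance hyperparameters of the probit-SuSiE model.

    The intercept and covariate prior variances are flat (treated as +inf);
    only ``sigma2_beta`` (shared across the L single effects) and
    ``sigma2_alpha`` (ridge pleiotropy) are finite and estimated by empirical
    Bayes.
    """

    sigma2_beta: float = 1.0
    sigma2_alpha: float = 1.0
    L: int = 10

    def __post_init__(self) -> None:
        if self.sigma2_beta <= 0 or self.sigma2_alpha <= 0:
            raise ValueError("variance hyperparameters must be strictly positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")


@dataclass
class FitConfig:
    """Fitting options.

    ``sigma2_beta_mode`` selects how the single-effect prior variance is
    handled: "shared" (default) estimates one variance pooled across the L
    effects by empirical Bayes; "per_effect" estimates one variance per
    effect from its own posterior second moment, letting unused effects
    shrink toward zero (collapsed effects are excluded from PIPs); "fixed"
    keeps ``sigma2_beta_init``.
    """

    L: int = 10
    elbo_tol: float = 1e-4
    max_iter: int = 300
    seed: int | None = None
    update_hyperparameters: bool = True
    sigma2_beta_mode: str = "shared"  # "shared" | "per_effect" | "fixed"
    estimate_sigma2_alpha: bool = True
    sigma2_beta_init: float = 1.0
    sigma2_alpha_init: float = 1.0
    prior_expectation: str = "digamma"  # "digamma" (E[log pi]) or "mean" (log E[pi])
    include_intercept: bool = True
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if self.elbo_tol <= 0:
            raise ValueError("elbo_tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.prior_expectation not in ("digamma", "mean"):
            raise ValueError("prior_expectation must be 'digamma' or 'mean'")
        if self.sigma2_beta_mode not in ("per_effect", "shared", "fixed"):
            raise ValueError("sigma2_beta_mode must be 'per_effect', 'shared' or 'fixed'")


@dataclass
class RegionData:
    """Per-region model inputs: phenotype, GReX, optional genotypes/covariates.

    Matrices are standardized on construction.  ``genotypes`` may be None or
    have zero columns (s = 0: no pleiotropy term); likewise ``covariates``.
    """

    grex: GReXMatrix
    phenotype: PhenotypeVector
    genotypes: np.ndarray | None = None
    covariates: CovariateMatrix | None = None

    def __post_init__(self) -> None:
        self.grex = self.grex.standardize()
        if self.grex.n != self.phenotype.n:
            raise ValueError("GReX and phenotype sample sizes differ")
        if self.genotypes is not None:
            from .io import standardize_columns

            X = np.asarray(self.genotypes, dtype=np.float64)
            if X.size == 0:
                self.genotypes = None
            else:
                if X.shape[0] != self.phenotype.n:
                    raise ValueError("genotype and phenotype sample sizes differ")
                self.genotypes, _ = standardize_columns(X)
        if self.covariates is not None:
            if self.covariates.c == 0:
                self.covariates = None
            else:
                self.covariates = self.covariates.standardize()
                if self.covariates.values.shape[0] != self.phenotype.n:
                    raise ValueError("covariate and phenotype sample sizes differ")

    @property
    def n(self) -> int:
        return self.phenotype.n

    @property
    def p(self) -> int:
        return self.grex.p

    @property
    def s(self) -> int:
        return 0 if self.genotypes is None else self.genotypes.shape[1]

    @property
    def c(self) -> int:
        return 0 if self.covariates is None else self.covariates.c


@dataclass
class ModelState:
    """All variational posterior moments and hyperparameters of a fit.

    ``gamma_prob[l, j]`` is the posterior probability that single effect l
    selects pair j (rows sum to 1); ``mu_post`` / ``s2_post`` hold the
    conditional effect moments given selection; ``beta_mean`` / ``beta_var``
    the mixture moments of each scalar effect beta_l.  ``delta_gene`` and
    ``delta_tissue`` are the Dirichlet parameters of the gene and per-gene
    tissue selection posteriors (prior value 1).
    """

    z_mean: np.ndarray
    z_var: np.ndarray
    z_logZ: np.ndarray
    z_m: np.ndarray  # predictor at the time of the liability update
    mu_mean: float
    mu_var: float
    alpha_mean: np.ndarray
    xi_mean: np.ndarray
    gamma_prob: np.ndarray  # (L, p)
    mu_post: np.ndarray  # (L, p)
    s2_post: np.ndarray  # (L, p)
    sigma2_beta_l: np.ndarray  # (L,) per-effect prior variances (0 = collapsed)
    effect_evidence: np.ndarray  # (L,) log SER evidence vs the null, per effect
    beta_mean: np.ndarray  # (L,)
    beta_var: np.ndarray  # (L,)
    delta_gene: np.ndarray  # (M,)
    delta_tissue: np.ndarray  # (M, K), entries for absent pairs stay at 1
    hyper: Hyperparameters
    elbo: float = -np.inf
    iteration: int = 0
    # cached design quantities
    _xtx_eigvals: np.ndarray | None = field(default=None, repr=False)
    _xtx_eigvecs: np.ndarray | None = field(default=None, repr=False)
    _ctc_inv: np.ndarray | None = field(default=None, repr=False)

    def effect_contributions(self) -> np.ndarray:
        """E[beta_l gamma_l] as an (L, p) matrix."""
        return self.gamma_prob * self.mu_post

    def pair_coef_mean(self) -> np.ndarray:
        """Posterior-mean pair coefficient vector E[beta] (p,)."""
        return self.effect_contributions().sum(axis=0)

    @property
    def active_effects(self) -> np.ndarray:
        """Effects whose prior variance has not collapsed to zero."""
        return self.sigma2_beta_l > ACTIVE_V_TOL


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_state(region: RegionData, config: FitConfig) -> ModelState:
    """Neutral initialization: uniform selection, zero effects, intercept at
    the probit-transformed case fraction (clipped to [-5, 5])."""
    if region.p == 0:
        raise ValueError("no gene-tissue pairs to fine-map (p = 0)")
    region.phenotype.require_both_classes()
    n, p = region.n, region.p
    L = config.L
    y = region.phenotype.values
    if config.include_intercept:
        mu0 = float(np.clip(ndtri(y.mean()), -5.0, 5.0))
    else:
        mu0 = 0.0
    m0 = np.full(n, mu0)
    z_mean, z_var, z_logZ = truncated_normal_moments(m0, y)
    M, K = region.grex.M, region.grex.K
    state = ModelState(
        z_mean=z_mean,
        z_var=z_var,
        z_logZ=z_logZ,
        z_m=m0,
        mu_mean=mu0,
        mu_var=1.0 / n if config.include_intercept else 0.0,
        alpha_mean=np.zeros(region.s),
        xi_mean=np.zeros(region.c),
        gamma_prob=np.full((L, p), 1.0 / p),
        mu_post=np.zeros((L, p)),
        s2_post=np.full((L, p), config.sigma2_beta_init),
        sigma2_beta_l=np.full(L, config.sigma2_beta_init),
        effect_evidence=np.zeros(L),
        beta_mean=np.zeros(L),
        beta_var=np.full(L, config.sigma2_beta_init),
        delta_gene=np.ones(M),
        delta_tissue=np.ones((M, K)),
        hyper=Hyperparameters(
            sigma2_beta=config.sigma2_beta_init,
            sigma2_alpha=config.sigma2_alpha_init,
            L=L,
        ),
    )
    if region.s > 0:
        xtx = region.genotypes.T @ region.genotypes
        vals, vecs = np.linalg.eigh(xtx)
        state._xtx_eigvals = np.clip(vals, 0.0, None)
        state._xtx_eigvecs = vecs
    if region.c > 0:
        C = region.covariates.values
        ctc = C.T @ C
        try:
            state._ctc_inv = np.linalg.inv(ctc)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "covariate matrix C'C is singular; remove collinear covariates"
            ) from exc
    return state


# ---------------------------------------------------------------------------
# predictor bookkeeping
# ---------------------------------------------------------------------------


def _linear_predictor(state: ModelState, region: RegionData) -> np.ndarray:
    pred = np.full(region.n, state.mu_mean)
    pred += region.grex.values @ state.pair_coef_mean()
    if region.s > 0:
        pred += region.genotypes @ state.alpha_mean
    if region.c > 0:
        pred += region.covariates.values @ state.xi_mean
    return pred


# ---------------------------------------------------------------------------
# CAVI updates
# ---------------------------------------------------------------------------


def update_latent_liabilities(state: ModelState, region: RegionData) -> ModelState:
    """q(z_i): N(m_i, 1) truncated to the side dictated by y_i."""
    m = _linear_predictor(state, region)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("non-finite linear predictor in liability update")
    state.z_mean, state.z_var, state.z_logZ = truncated_normal_moments(
        m, region.phenotype.values
    )
    state.z_m = m
    return state


def _expected_log_prior(state: ModelState, region: RegionData, mode: str) -> np.ndarray:
    """E_q[log pi_j] (or log E_q[pi_j] for the sensitivity variant) per column."""
    g = region.grex.gene_index
    t = region.grex.tissue_index
    dg = state.delta_gene
    dt = state.delta_tissue
    # per-gene tissue normalizer uses only tissues actually present for the gene
    present = np.zeros_like(dt, dtype=bool)
    present[g, t] = True
    dt_sum = np.where(present, dt, 0.0).sum(axis=1)
    if mode == "digamma":
        e_gene = digamma(dg) - digamma(dg.sum())
        e_tis = digamma(dt[g, t]) - digamma(dt_sum[g])
        return e_gene[g] + e_tis
    # mean variant: log E[pi_g] + log E[pi_t|g]
    e_gene = np.log(dg / dg.sum())
    e_tis = np.log(dt[g, t] / dt_sum[g])
    return e_gene[g] + e_tis


def update_single_effect(
    state: ModelState,
    region: RegionData,
    l: int,
    prior_expectation: str = "digamma",
    estimate_prior_variance: bool = False,
) -> ModelState:
    """Bayesian single-effect regression of the residual on each GReX column.

    The residual removes every model component except effect l.  Selection
    probabilities combine the per-column Gaussian log Bayes factor with the
    hierarchical prior expectation and are normalized by log-sum-exp.
    Constant (zero-variance) columns are excluded from selection.  When
    ``estimate_prior_variance`` is set, the effect's prior variance is
    refreshed after the update at its per-effect ELBO-maximizing value (the
    posterior second moment of beta_l), so effects that carry signal keep a
    matching prior scale while unused effects shrink toward zero instead of
    accumulating diffuse copies of the same evidence.  The effect's
    single-effect log evidence against the null is recorded for scoring.
    """
    G = region.grex.values
    d = np.sum(G**2, axis=0)
    valid = d > 0
    B = state.effect_contributions()
    others = B.sum(axis=0) - B[l]
    r = state.z_mean - state.mu_mean - G @ others
    if region.s > 0:
        r -= region.genotypes @ state.alpha_mean
    if region.c > 0:
        r -= region.covariates.values @ state.xi_mean
    xtr = G.T @ r
    elogpi = _expected_log_prior(state, region, prior_expectation)
    log_prior = np.where(valid, elogpi, -np.inf) if valid.any() else elogpi
    sigma2_beta = state.sigma2_beta_l[l]

    if sigma2_beta <= ACTIVE_V_TOL:
        # fully collapsed effect: no signal; selection follows the prior
        log_w = log_prior - log_prior.max()
        pi = np.exp(log_w)
        pi /= pi.sum()
        state.gamma_prob[l] = pi
        state.mu_post[l] = 0.0
        state.s2_post[l] = 0.0
        state.effect_evidence[l] = 0.0
        state.beta_mean[l] = 0.0
        state.beta_var[l] = _VAR_FLOOR
        return state

    d_safe = np.where(valid, d, 1.0)
    s2 = 1.0 / (d_safe + 1.0 / sigma2_beta)  # unit residual variance
    mu = s2 * xtr
    log_bf = 0.5 * np.log(s2 / sigma2_beta) + 0.5 * mu**2 / s2
    log_w = log_bf + log_prior
    if valid.any():
        log_w = np.where(valid, log_w, -np.inf)
        mu = np.where(valid, mu, 0.0)
    shift = log_w.max()
    log_norm = shift + np.log(np.sum(np.exp(log_w - shift)))
    pi = np.exp(log_w - log_norm)
    state.gamma_prob[l] = pi
    state.mu_post[l] = mu
    state.s2_post[l] = s2
    # log evidence of this effect vs beta_l = 0, under the current prior
    lp_shift = log_prior.max()
    state.effect_evidence[l] = float(
        log_norm - (lp_shift + np.log(np.sum(np.exp(log_prior - lp_shift))))
    )
    state.beta_mean[l] = float(np.sum(pi * mu))
    second = float(np.sum(pi * (mu**2 + s2)))
    state.beta_var[l] = max(second - state.beta_mean[l] ** 2, _VAR_FLOOR)
    if estimate_prior_variance:
        state.sigma2_beta_l[l] = max(second, 0.0)
    return state


def update_pleiotropy(state: ModelState, region: RegionData) -> ModelState:
    """q(alpha) = N((X'X + I/sigma2_alpha)^-1 X'r, same covariance).

    Implemented through the cached eigendecomposition of X'X, which matches
    the direct solve to machine precision.  s = 0 is a no-op.
    """
    if region.s == 0:
        return state
    G = region.grex.values
    r = state.z_mean - state.mu_mean - G @ state.pair_coef_mean()
    if region.c > 0:
        r -= region.covariates.values @ state.xi_mean
    xtr = region.genotypes.T @ r
    lam = state._xtx_eigvals
    V = state._xtx_eigvecs
    inv_diag = 1.0 / (lam + 1.0 / state.hyper.sigma2_alpha)
    state.alpha_mean = V @ (inv_diag * (V.T @ xtr))
    if not np.all(np.isfinite(state.alpha_mean)):
        raise FloatingPointError("non-finite pleiotropy solve")
    return state


def update_covariates_intercept(
    state: ModelState, region: RegionData, include_intercept: bool = True
) -> ModelState:
    """Flat-prior Gaussian updates for the intercept and covariate effects."""
    G = region.grex.values
    base = state.z_mean - G @ state.pair_coef_mean()
    if region.s > 0:
        base = base - region.genotypes @ state.alpha_mean
    if include_intercept:
        r = base.copy()
        if region.c > 0:
            r -= region.covariates.values @ state.xi_mean
        state.mu_mean = float(r.mean())
        state.mu_var = 1.0 / region.n
    if region.c > 0:
        r = base - state.mu_mean
        C = region.covariates.values
        state.xi_mean = state._ctc_inv @ (C.T @ r)
    return state


def update_dirichlet(state: ModelState, region: RegionData) -> ModelState:
    """Conjugate pseudo-count updates of the gene and per-gene tissue Dirichlets.

    Only effects whose prior variance has not collapsed contribute
    pseudo-counts; collapsed effects are pruned from the model and carry no
    selection evidence.
    """
    g = region.grex.gene_index
    t = region.grex.tissue_index
    active = state.active_effects
    col_mass = state.gamma_prob[active].sum(axis=0)  # sum over active effects
    if not active.any():
        col_mass = np.zeros(region.p)
    M, K = region.grex.M, region.grex.K
    state.delta_gene = 1.0 + np.bincount(g, weights=col_mass, minlength=M)
    dt = np.ones((M, K))
    np.add.at(dt, (g, t), col_mass)
    state.delta_tissue = dt
    return state


def update_hyperparameters(state: ModelState, region: RegionData, config: FitConfig) -> Hyperparameters:
    """Empirical-Bayes refresh of sigma2_beta and sigma2_alpha.

    sigma2_beta is set to the mean second moment of the L scalar effects, the
    ELBO-maximizing value; degenerate updates are floored at 1e-8 with a
    warning.  sigma2_alpha maximizes its ELBO terms including the IG(1, 1)
    log-prior: (1 + E[a'a]/2) / (s/2 + 2).
    """
    if config.sigma2_beta_mode == "shared":
        second = np.sum(state.gamma_prob * (state.mu_post**2 + state.s2_post), axis=1)
        new = float(second.mean())
        if new < _VAR_FLOOR:
            logger.warning("sigma2_beta update degenerate; flooring at %g", _VAR_FLOOR)
            new = _VAR_FLOOR
        state.hyper.sigma2_beta = new
        state.sigma2_beta_l[:] = new
    if config.estimate_sigma2_alpha and region.s > 0:
        lam = state._xtx_eigvals
        tr_cov = float(np.sum(1.0 / (lam + 1.0 / state.hyper.sigma2_alpha)))
        e_aa = float(state.alpha_mean @ state.alpha_mean) + tr_cov
        state.hyper.sigma2_alpha = max((1.0 + 0.5 * e_aa) / (0.5 * region.s + 2.0), _VAR_FLOOR)
    return state.hyper


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


def _dirichlet_kl_vs_flat(a: np.ndarray) -> float:
    """KL( Dirichlet(a) || Dirichlet(1,...,1) )."""
    a = np.asarray(a, dtype=np.float64)
    a0 = a.sum()
    k = a.size
    return float(
        gammaln(a0)
        - gammaln(a).sum()
        - gammaln(float(k))
        + np.sum((a - 1.0) * (digamma(a) - digamma(a0)))
    )


def compute_elbo(state: ModelState, region: RegionData, config: FitConfig) -> float:
    """Evidence lower bound of the liability-augmented model at the current q.

    Flat (improper) priors on the intercept and covariates contribute only
    their constant entropies; the IG(1, 1) prior on sigma2_alpha enters as a
    point-estimate log-density term.
    """
    n, p = region.n, region.p
    G = region.grex.values
    d = np.sum(G**2, axis=0)
    y = region.phenotype.values

    m = _linear_predictor(state, region)
    resid = state.z_mean - m
    ssr = float(resid @ resid) + float(state.z_var.sum())
    if config.include_intercept:
        ssr += n * state.mu_var
    B = state.effect_contributions()
    e2 = state.gamma_prob * (state.mu_post**2 + state.s2_post)
    ssr += float(np.sum(d[None, :] * e2) - np.sum((G @ B.T) ** 2))
    if region.s > 0:
        lam = state._xtx_eigvals
        inv_prec = 1.0 / (lam + 1.0 / state.hyper.sigma2_alpha)
        ssr += float(np.sum(lam * inv_prec))  # tr(X'X Cov(alpha))
    if region.c > 0:
        ssr += region.c  # tr(C'C (C'C)^-1)
    terms = {"likelihood": -0.5 * n * _LOG2PI - 0.5 * ssr}

    # entropy of truncated-normal liabilities (against the variational mean
    # z_m in force when the liabilities were last updated)
    ent_resid = state.z_mean - state.z_m
    terms["z_entropy"] = float(
        np.sum(0.5 * _LOG2PI + 0.5 * (state.z_var + ent_resid**2) + state.z_logZ)
    )
    del y

    # single effects: prior cross term, selection entropy, Gaussian KL.
    # Collapsed effects (prior variance 0) are pruned and contribute nothing.
    elogpi = _expected_log_prior(state, region, config.prior_expectation)
    t3 = 0.0
    for l in np.flatnonzero(state.active_effects):
        pi_l = state.gamma_prob[l]
        with np.errstate(divide="ignore", invalid="ignore"):
            log_pi = np.where(pi_l > 0, np.log(np.clip(pi_l, 1e-300, None)), 0.0)
        kl_gauss = np.zeros_like(pi_l)
        pos = state.s2_post[l] > 0
        kl_gauss[pos] = 0.5 * (
            np.log(state.sigma2_beta_l[l] / state.s2_post[l, pos])
            + (state.s2_post[l, pos] + state.mu_post[l, pos] ** 2) / state.sigma2_beta_l[l]
            - 1.0
        )
        t3 += float(np.sum(pi_l * (elogpi - log_pi - kl_gauss)))
    terms["single_effects"] = t3

    # Dirichlet prior/entropy terms
    t4 = -_dirichlet_kl_vs_flat(state.delta_gene)
    g = region.grex.gene_index
    t = region.grex.tissue_index
    present = np.zeros_like(state.delta_tissue, dtype=bool)
    present[g, t] = True
    for mgene in range(region.grex.M):
        mask = present[mgene]
        if mask.sum() > 1:
            t4 -= _dirichlet_kl_vs_flat(state.delta_tissue[mgene, mask])
    terms["dirichlet"] = t4

    if region.s > 0:
        lam = state._xtx_eigvals
        prec = lam + 1.0 / state.hyper.sigma2_alpha
        logdet_cov = -float(np.sum(np.log(prec)))
        tr_cov = float(np.sum(1.0 / prec))
        s = region.s
        sa2 = state.hyper.sigma2_alpha
        kl_alpha = 0.5 * (
            (tr_cov + float(state.alpha_mean @ state.alpha_mean)) / sa2
            - s
            + s * np.log(sa2)
            - logdet_cov
        )
        terms["alpha"] = -kl_alpha
        terms["sigma2_alpha_prior"] = -2.0 * np.log(sa2) - 1.0 / sa2

    if config.include_intercept:
        terms["mu_entropy"] = 0.5 * (np.log(2 * np.pi * np.e) + np.log(state.mu_var))
    if region.c > 0:
        sign, logdet = np.linalg.slogdet(state._ctc_inv)
        terms["xi_entropy"] = 0.5 * (region.c * np.log(2 * np.pi * np.e) + logdet)

    elbo = float(sum(terms.values()))
    if not np.isfinite(elbo):
        bad = {k: v for k, v in terms.items() if not np.isfinite(v)}
        raise FloatingPointError(f"non-finite ELBO; offending terms: {bad}")
    return elbo


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------


def fit(
    region: RegionData, config: FitConfig | None = None
) -> tuple[ModelState, FineMapResult]:
    """Run CAVI to convergence and score the fitted state.

    One sweep updates, in order: latent liabilities, each single effect
    l = 1..L, pleiotropy, covariates/intercept, the Dirichlet selection
    posteriors, and (optionally) the hyperparameters, then evaluates the
    ELBO.  Convergence is a relative ELBO change below ``config.elbo_tol``.
    """
    from . import scoring

    config = config or FitConfig()
    state = init_state(region, config)
    trace: list[float] = []
    converged = False
    for it in range(config.max_iter):
        update_latent_liabilities(state, region)
        estimate_v = config.sigma2_beta_mode == "per_effect"
        for l in range(config.L):
            update_single_effect(
                state, region, l, config.prior_expectation, estimate_prior_variance=estimate_v
            )
        update_pleiotropy(state, region)
        update_covariates_intercept(state, region, config.include_intercept)
        update_dirichlet(state, region)
        if config.update_hyperparameters:
            update_hyperparameters(state, region, config)
        state.elbo = compute_elbo(state, region, config)
        state.iteration = it + 1
        trace.append(state.elbo)
        if it > 0 and abs(trace[-1] - trace[-2]) < config.elbo_tol * (
            abs(trace[-2]) + 1e-8
        ):
            converged = True
            break
    if not converged:
        logger.warning(
            "fit did not converge in %d iterations (last rel. change %.3g)",
            config.max_iter,
            abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-8) if len(trace) > 1 else np.nan,
        )
    result = scoring.score_state(state, region, level=config.fdr_level)
    result.elbo_trace = np.asarray(trace)
    result.converged = converged
    return state, result
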