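"""Construction of predicted GReX and linear sum-of-single-effects eQTL weights.

``build_grex`` turns per-gene-tissue SNP weight tables into the n x p predicted
expression matrix analyzed by the fine-mapping engine.  ``fit_linear_susie``
fits a standard Gaussian-outcome sum-of-single-effects (SuSiE) regression by
coordinate-ascent variational inference on an eQTL panel; its posterior-mean
weight vector (selection probability times posterior effect, summed over the
L single-effect components) is the prediction model exported for a pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, GReXMatrix, RegionSpec, WeightSet

logger = logging.getLogger(__name__)

__all__ = ["LinearSusieFit", "build_grex", "fit_linear_susie"]


def build_grex(
    genotypes: GenotypeMatrix,
    weights: WeightSet,
    region: RegionSpec | None = None,
) -> GReXMatrix:
    """Impute GReX for every gene-tissue pair with resolvable weights.

    Column j is the weighted dosage sum for pair j; columns are then
    standardized (constant columns — e.g. all-zero weights — are zeroed and
    flagged).  Pairs whose SNPs all fail to resolve are dropped with a warning.
    """
    geno = genotypes.standardize()
    if region is not None and geno.positions is not None:
        geno = geno.subset_region(region)
    resolved = weights.resolve(geno.snp_ids)
    if resolved.n_pairs == 0:
        raise ValueError("no gene-tissue pairs in region after weight resolution")
    col = {s: i for i, s in enumerate(geno.snp_ids)}
    pairs = sorted(resolved.entries)
    values = np.zeros((geno.n_individuals, len(pairs)))
    for j, key in enumerate(pairs):
        for snp, w in resolved.entries[key]:
            values[:, j] += w * geno.values[:, col[snp]]
    return GReXMatrix(values, pairs).standardize()


# ---------------------------------------------------------------------------
# Gaussian-outcome SuSiE for eQTL prediction weights
# ---------------------------------------------------------------------------


@dataclass
class LinearSusieFit:
    """Variational fit of y = X b + e with b a sum of L single effects.

    ``alpha[l, j]`` is the probability that effect l selects SNP j (each row
    sums to 1); ``mu[l, j]`` the posterior mean of the effect conditional on
    selection.  ``weights`` is the aggregated posterior-mean SNP weight
    vector sum_l alpha[l] * mu[l].  ``sigma2_0`` holds the per-effect prior
    variances; effects whose prior variance collapsed to zero carry no signal
    and are excluded from the aggregate ``pip``.
    """

    alpha: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    sigma2: float
    sigma2_0: np.ndarray
    elbo_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    @property
    def pip(self) -> np.ndarray:
        """Per-SNP aggregate selection probability 1 - prod_l (1 - alpha_lj),
        over effects with non-degenerate prior variance."""
        active = self.sigma2_0 > 1e-9
        if not active.any():
            return np.zeros(self.alpha.shape[1])
        return 1.0 - np.prod(1.0 - self.alpha[active], axis=0)


def _susie_elbo(
    y: np.ndarray,
    X: np.ndarray,
    d: np.ndarray,
    alpha: np.ndarray,
    mu: np.ndarray,
    s2: np.ndarray,
    sigma2: float,
    sigma2_0: np.ndarray,
) -> float:
    n, p = X.shape
    B = alpha * mu
    fitted = X @ B.sum(axis=0)
    ssr = float(np.sum((y - fitted) ** 2))
    # per-effect variance of X b_l around its mean
    e2 = alpha * (mu**2 + s2)  # E[b_lj^2 | selected] weighted
    var_term = float(np.sum(d[None, :] * e2) - np.sum((X @ B.T) ** 2))
    ll = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * (ssr + var_term) / sigma2
    # KL of each (beta_l, gamma_l) pair against N(0, sigma2_0l) x uniform(1/p);
    # effects with collapsed prior variance contribute nothing
    kl = 0.0
    for l in range(alpha.shape[0]):
        if sigma2_0[l] <= 0:
            continue
        a = alpha[l]
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ratio = np.where(a > 0, np.log(np.clip(a * p, 1e-300, None)), 0.0)
        kl_gauss = 0.5 * (
            np.log(sigma2_0[l] / s2[l]) + (s2[l] + mu[l] ** 2) / sigma2_0[l] - 1.0
        )
        kl += float(np.sum(a * (log_ratio + kl_gauss)))
    return ll - kl


from ._ser import optimize_prior_variance as _optimize_prior_variance  # noqa: E402


def fit_linear_susie(
    genotypes: GenotypeMatrix | np.ndarray,
    expression: np.ndarray,
    L: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    sigma2: float | None = None,
    sigma2_0: float | None = None,
) -> LinearSusieFit:
    """Fit a Gaussian sum-of-single-effects regression by CAVI.

    ``L`` defaults to 5, matching the simulated number of causal cis-SNPs per
    heritable gene-tissue pair.  The residual variance ``sigma2`` and prior
    effect variance ``sigma2_0`` are re-estimated each sweep at their
    ELBO-maximizing values unless fixed by the caller.  Deterministic given
    inputs; the ELBO is non-decreasing across sweeps.
    """
    if isinstance(genotypes, GenotypeMatrix):
        X = genotypes.standardize().values
    else:
        from .io import standardize_columns

        X, _ = standardize_columns(np.asarray(genotypes, dtype=np.float64))
    y = np.asarray(expression, dtype=np.float64)
    n, p = X.shape
    if n < 10:
        raise ValueError("fit_linear_susie requires n >= 10")
    if L < 1:
        raise ValueError("L must be >= 1")
    if float(np.var(y)) <= 1e-12:
        raise ValueError("expression has zero variance")
    y = y - y.mean()

    d = np.sum(X**2, axis=0)  # column squared norms (n for non-constant cols)
    d_safe = np.where(d > 0, d, 1.0)
    est_sigma2 = sigma2 is None
    est_sigma2_0 = sigma2_0 is None
    sig2 = float(np.var(y)) if est_sigma2 else float(sigma2)
    var_y = float(np.var(y))
    v = np.full(L, float(sigma2_0) if not est_sigma2_0 else 0.2 * var_y)

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    s2 = np.zeros((L, p))
    elbos: list[float] = []
    converged = False
    for _ in range(max_iter):
        B = alpha * mu
        fitted = X @ B.sum(axis=0)
        for l in range(L):
            fitted -= X @ B[l]
            r = y - fitted
            xtr = X.T @ r
            score = np.where(d > 0, xtr / sig2, 0.0)
            prec = d / sig2
            if est_sigma2_0:
                v[l] = _optimize_prior_variance(score, prec, v_max=100 * var_y, log_w=None)
            if v[l] <= 0:
                alpha[l] = 1.0 / p
                mu[l] = 0.0
                s2[l] = 0.0
            else:
                s2_l = 1.0 / (d_safe / sig2 + 1.0 / v[l])
                mu_l = s2_l * xtr / sig2
                log_bf = 0.5 * np.log(s2_l / v[l]) + 0.5 * mu_l**2 / s2_l
                log_bf = np.where(d > 0, log_bf, -np.inf if (d > 0).any() else 0.0)
                w = log_bf - log_bf.max()
                a = np.exp(w)
                a /= a.sum()
                alpha[l], mu[l], s2[l] = a, mu_l, s2_l
            B[l] = alpha[l] * mu[l]
            fitted += X @ B[l]
        if est_sigma2:
            ssr = float(np.sum((y - X @ (alpha * mu).sum(axis=0)) ** 2))
            var_term = float(
                np.sum(d[None, :] * alpha * (mu**2 + s2)) - np.sum((X @ (alpha * mu).T) ** 2)
            )
            sig2 = max((ssr + var_term) / n, 1e-9)
        elbos.append(_susie_elbo(y, X, d, alpha, mu, s2, sig2, v))
        if len(elbos) > 1 and abs(elbos[-1] - elbos[-2]) < tol * (abs(elbos[-2]) + 1e-8):
            converged = True
            break
    return LinearSusieFit(
        alpha=alpha,
        mu=mu,
        weights=(alpha * mu).sum(axis=0),
        sigma2=sig2,
        sigma2_0=v.copy(),
        elbo_trace=np.asarray(elbos),
        converged=converged,
    )
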