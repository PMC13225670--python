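import numpy as np
import pytest
from scipy.special import ndtr

from grexfine.engine import FitConfig, RegionData
from grexfine.io import GReXMatrix, PhenotypeVector


def make_region(
    n: int = 60,
    M: int = 2,
    K: int = 3,
    seed: int = 0,
    causal_col: int | None = None,
    effect: float = 0.0,
    s: int = 0,
    c: int = 0,
    grex_corr: float = 0.0,
) -> RegionData:
    """Random region fixture: p = M*K GReX columns, probit-generated phenotype.

    ``causal_col``/``effect`` inject a single causal pair on the liability
    scale; ``grex_corr`` adds a shared factor to correlate GReX columns.
    """
    rng = np.random.default_rng(seed)
    p = M * K
    base = rng.standard_normal((n, p))
    if grex_corr > 0:
        shared = rng.standard_normal((n, 1))
        base = np.sqrt(1 - grex_corr) * base + np.sqrt(grex_corr) * shared
    pairs = [(f"g{m}", f"t{k}") for m in range(M) for k in range(K)]
    grex = GReXMatrix(base, pairs)
    liability = rng.standard_normal(n)
    if causal_col is not None and effect != 0.0:
        col = base[:, causal_col]
        liability = liability + effect * (col - col.mean()) / col.std()
    y = (liability > 0).astype(int)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    X = rng.standard_normal((n, s)) if s else None
    cov = None
    if c:
        from grexfine.io import CovariateMatrix

        cov = CovariateMatrix(rng.standard_normal((n, c)), names=[f"c{i}" for i in range(c)])
    return RegionData(grex=grex, phenotype=PhenotypeVector(y), genotypes=X, covariates=cov)


@pytest.fixture
def small_region() -> RegionData:
    return make_region(n=80, M=2, K=3, seed=42)


@pytest.fixture
def fast_config() -> FitConfig:
    return FitConfig(L=3, max_iter=50)
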