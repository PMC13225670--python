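"""Posterior inclusion probabilities, local FDR and estimated-FDR calls.

Pair-level PIPs follow the sum-of-single-effects convention
``PIP_j = 1 - prod_l (1 - pi_lj)``.  Gene-level PIPs are the posterior mean of
the gene selection probabilities under the hierarchical Dirichlet posterior,
``delta_m / sum(delta)``; they are normalized selection probabilities over the
region's genes and sum to 1 (which differs semantically from per-gene
non-zero-effect probabilities).

Significance calls use the local-FDR rule: local FDR = 1 - PIP; sorting
ascending, the estimated FDR at rank r is the mean of the first r local FDRs,
and everything up to the largest rank with estimated FDR <= the target level
is called significant.  Ties in local FDR are broken by stable original-index
order (affects only boundary calls).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FineMapResult

__all__ = [
    "pair_pip",
    "gene_pip",
    "combine_gene_pip_independent",
    "estimated_fdr_calls",
    "score_state",
]


def pair_pip(gamma_prob: np.ndarray) -> np.ndarray:
    """PIP_j = 1 - prod_l (1 - pi_lj) from the (L, p) selection matrix."""
    g = np.asarray(gamma_prob, dtype=np.float64)
    if ((g < -1e-12) | (g > 1 + 1e-12)).any():
        raise ValueError("selection probabilities must lie in [0, 1]")
    return 1.0 - np.prod(1.0 - np.clip(g, 0.0, 1.0), axis=0)


def gene_pip(delta_gene: np.ndarray) -> np.ndarray:
    """Posterior-mean gene selection probabilities delta_m / sum(delta)."""
    d = np.asarray(delta_gene, dtype=np.float64)
    if (d < 1.0 - 1e-9).any():
        raise ValueError("Dirichlet parameters must be >= the prior value 1")
    return d / d.sum()


def combine_gene_pip_independent(pair_pips: np.ndarray) -> float:
    """1 - prod(1 - PIP) over a gene's tissues, assuming independence.

    Used only to build gene-level statistics from pair-level PIPs (e.g. when
    evaluating methods without a native gene-level posterior); the engine's
    own gene PIPs come from :func:`gene_pip`.
    """
    p = np.asarray(pair_pips, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("PIPs must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def estimated_fdr_calls(pips: np.ndarray, target: float = 0.05) -> pd.DataFrame:
    """Local-FDR significance calls at an estimated FDR target.

    Returns a DataFrame aligned with the input order, with columns ``pip``,
    ``local_fdr``, ``estimated_fdr`` (cumulative mean of sorted local FDRs,
    mapped back to input positions) and ``significant``.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target level must be in (0, 1)")
    p = np.asarray(pips, dtype=np.float64)
    out = pd.DataFrame({"pip": p})
    out["local_fdr"] = 1.0 - p
    if len(p) == 0:
        out["estimated_fdr"] = np.empty(0)
        out["significant"] = np.empty(0, dtype=bool)
        return out
    order = np.argsort(out["local_fdr"].to_numpy(), kind="stable")
    sorted_lfdr = out["local_fdr"].to_numpy()[order]
    cum = np.cumsum(sorted_lfdr) / np.arange(1, len(p) + 1)
    passing = np.flatnonzero(cum <= target)
    cutoff_rank = passing.max() + 1 if passing.size else 0
    est = np.empty(len(p))
    est[order] = cum
    sig = np.zeros(len(p), dtype=bool)
    sig[order[:cutoff_rank]] = True
    out["estimated_fdr"] = est
    out["significant"] = sig
    return out


def score_state(state, region, level: float = 0.05) -> FineMapResult:
    """Convert a fitted engine state into pair- and gene-level result tables.

    Effects whose prior variance collapsed to zero represent "no additional
    effect": their selection distribution reverts to the prior and they are
    excluded from the PIP product.  A fit where every effect collapsed yields
    all-zero pair PIPs.
    """
    active = getattr(state, "active_effects", None)
    if active is not None and not active.all():
        if active.any():
            pips = pair_pip(state.gamma_prob[active])
        else:
            pips = np.zeros(state.gamma_prob.shape[1])
    else:
        pips = pair_pip(state.gamma_prob)
    pair = estimated_fdr_calls(pips, target=level)
    pair.insert(0, "tissue", [t for _, t in region.grex.pairs])
    pair.insert(0, "gene", [g for g, _ in region.grex.pairs])

    gpips = gene_pip(state.delta_gene)
    gene = estimated_fdr_calls(gpips, target=level)
    gene = gene.rename(columns={"pip": "gene_pip"})
    gene.insert(0, "gene", region.grex.genes)

    result = FineMapResult(
        pair_table=pair,
        gene_table=gene,
        elbo_trace=np.asarray([state.elbo]),
        converged=True,
    )
    result.validate()
    return result
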