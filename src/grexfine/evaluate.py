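"""Replicate-level benchmarking: true-FDR power, estimated-FDR power and
null false-signal counts at the gene-tissue-pair and gene levels.

Replicate results are plain DataFrames with one row per scored unit:
columns ``replicate``, ``id``, ``pip`` (the test statistic) and ``causal``
(ground-truth flag); gene-level frames additionally carry ``gene``.

Following the grouped-replicate design, replicates are split into contiguous
groups (default 5), statistics are pooled within each group before
thresholding, and the mean across groups is reported.  The true-FDR scan
considers every distinct statistic value as a candidate cutoff and takes the
largest set whose realized FDR stays at or below the level (stable sort,
original-index tie-break).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import FitConfig, RegionData, fit
from .grex import build_grex
from .io import GenotypeMatrix, RegionSpec, WeightSet
from .scoring import combine_gene_pip_independent, estimated_fdr_calls
from .simulate import SimScenario, Study, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "GroupedPower",
    "power_at_true_fdr",
    "power_at_estimated_fdr",
    "null_false_signals",
    "gene_level_from_pairs",
    "fit_study",
    "run_replicates",
    "subset_weights_by_region",
]


@dataclass
class GroupedPower:
    per_group: np.ndarray
    mean: float
    realized_fdr: np.ndarray | None = None

    @property
    def mean_realized_fdr(self) -> float:
        return float(np.mean(self.realized_fdr)) if self.realized_fdr is not None else np.nan


def _group_replicates(results: pd.DataFrame, n_groups: int) -> list[pd.DataFrame]:
    reps = sorted(results["replicate"].unique())
    if len(reps) < n_groups:
        raise ValueError(f"cannot form {n_groups} groups from {len(reps)} replicates")
    if len(reps) % n_groups:
        logger.info(
            "replicate count %d not divisible by %d groups; group sizes differ by one",
            len(reps),
            n_groups,
        )
    if len(reps) != 100 or n_groups != 5:
        logger.info("grouping %d replicates into %d groups", len(reps), n_groups)
    chunks = np.array_split(np.asarray(reps), n_groups)
    return [results[results["replicate"].isin(chunk)] for chunk in chunks]


def power_at_true_fdr(
    results: pd.DataFrame, level: float = 0.05, n_groups: int = 5
) -> GroupedPower:
    """Power at the largest threshold whose realized (true) FDR <= level.

    Statistics are pooled per group and scanned most-to-least significant;
    power is true positives in the selected set over all causal units in the
    group.  Requires at least one causal unit per group.
    """
    powers = []
    for grp in _group_replicates(results, n_groups):
        stat = grp["pip"].to_numpy(dtype=float)
        causal = grp["causal"].to_numpy(dtype=bool)
        n_causal = int(causal.sum())
        if n_causal == 0:
            raise ValueError("power undefined: no causal units in group")
        order = np.argsort(-stat, kind="stable")
        c_sorted = causal[order]
        fp = np.cumsum(~c_sorted)
        called = np.arange(1, len(stat) + 1)
        fdr = fp / called
        ok = np.flatnonzero(fdr <= level)
        if ok.size == 0:
            powers.append(0.0)
            continue
        cut = ok.max()
        tp = int(c_sorted[: cut + 1].sum())
        powers.append(tp / n_causal)
    per_group = np.asarray(powers)
    return GroupedPower(per_group=per_group, mean=float(per_group.mean()))


def power_at_estimated_fdr(
    results: pd.DataFrame, level: float = 0.05, n_groups: int = 5
) -> GroupedPower:
    """Power and realized FDR of the estimated-FDR call set per pooled group."""
    powers, realized = [], []
    for grp in _group_replicates(results, n_groups):
        stat = grp["pip"].to_numpy(dtype=float)
        causal = grp["causal"].to_numpy(dtype=bool)
        n_causal = int(causal.sum())
        if n_causal == 0:
            raise ValueError("power undefined: no causal units in group")
        calls = estimated_fdr_calls(stat, target=level)
        sig = calls["significant"].to_numpy()
        n_sig = int(sig.sum())
        tp = int((sig & causal).sum())
        powers.append(tp / n_causal)
        realized.append((n_sig - tp) / n_sig if n_sig else 0.0)
    per_group = np.asarray(powers)
    return GroupedPower(
        per_group=per_group,
        mean=float(per_group.mean()),
        realized_fdr=np.asarray(realized),
    )


def null_false_signals(results: pd.DataFrame, level: float = 0.05) -> float:
    """Mean number of estimated-FDR-significant units per replicate.

    Intended for truly null scenarios (no causal units); counts are taken per
    replicate and averaged.
    """
    counts = []
    for _, grp in results.groupby("replicate"):
        calls = estimated_fdr_calls(grp["pip"].to_numpy(dtype=float), target=level)
        counts.append(int(calls["significant"].sum()))
    return float(np.mean(counts)) if counts else 0.0


def gene_level_from_pairs(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse pair-level results to gene level by the independence rule.

    Gene statistic = 1 - prod(1 - PIP) over the gene's tissues; gene truth =
    causal in at least one tissue.  (The engine's own hierarchical gene PIPs
    should be preferred when available; this rule serves statistics that only
    exist at the pair level.)
    """
    rows = []
    for (rep, gene), grp in results.groupby(["replicate", "gene"], sort=False):
        rows.append(
            {
                "replicate": rep,
                "id": gene,
                "gene": gene,
                "pip": combine_gene_pip_independent(grp["pip"].to_numpy(dtype=float)),
                "causal": bool(grp["causal"].any()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation-to-results pipeline
# ---------------------------------------------------------------------------


def subset_weights_by_region(
    weights: WeightSet, genotypes: GenotypeMatrix, region: RegionSpec
) -> WeightSet:
    """Keep only weight entries whose SNPs fall inside the region (silent:
    out-of-region entries belong to other regions, not to data problems)."""
    if genotypes.positions is None:
        return weights
    keep = (genotypes.positions >= region.start) & (genotypes.positions < region.end)
    region_snps = {s for s, k in zip(genotypes.snp_ids, keep) if k}
    entries = {
        key: wlist
        for key, wlist in weights.entries.items()
        if any(s in region_snps for s, _ in wlist)
    }
    return WeightSet(entries)


def fit_study(
    study: Study,
    config: FitConfig | None = None,
    include_pleiotropy_term: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every region of a study; return pair- and gene-level result frames.

    Regions are independent and fitted sequentially.  The pair frame has one
    row per gene-tissue pair with its PIP and truth flag; the gene frame one
    row per gene with the hierarchical gene PIP (region-normalized) and truth.
    """
    config = config or FitConfig()
    geno_std = study.gwas_genotypes.standardize()
    causal_pairs = set(study.truth.causal_pairs)
    pair_rows, gene_rows = [], []
    for region in study.regions:
        wsub = subset_weights_by_region(study.weights, geno_std, region)
        if wsub.n_pairs == 0:
            continue
        region_geno = geno_std.subset_region(region)
        grex = build_grex(region_geno, wsub, region=None)
        data = RegionData(
            grex=grex,
            phenotype=study.phenotype,
            genotypes=region_geno.values if include_pleiotropy_term else None,
        )
        _, result = fit(data, config)
        for _, row in result.pair_table.iterrows():
            pair_rows.append(
                {
                    "region": region.region_id,
                    "gene": row["gene"],
                    "tissue": row["tissue"],
                    "id": f"{row['gene']}::{row['tissue']}",
                    "pip": float(row["pip"]),
                    "causal": (row["gene"], row["tissue"]) in causal_pairs,
                }
            )
        for _, row in result.gene_table.iterrows():
            gene_rows.append(
                {
                    "region": region.region_id,
                    "gene": row["gene"],
                    "id": row["gene"],
                    "pip": float(row["gene_pip"]),
                    "causal": row["gene"] in study.truth.causal_genes,
                }
            )
    return pd.DataFrame(pair_rows), pd.DataFrame(gene_rows)


def run_replicates(
    scenario: SimScenario,
    n_replicates: int,
    base_seed: int = 0,
    config: FitConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and fit ``n_replicates`` independent studies.

    Per-replicate seeds are derived deterministically from ``base_seed`` and
    kept below 2^31.  Returns pooled pair- and gene-level frames with a
    ``replicate`` column.
    """
    import dataclasses as _dc

    pair_frames, gene_frames = [], []
    for rep in range(n_replicates):
        seed = (base_seed * 100_003 + 7_919 * rep + 1) % (2**31)
        scen = _dc.replace(scenario, seed=seed)
        study = simulate_study(scen)
        pair_df, gene_df = fit_study(study, config)
        pair_df["replicate"] = rep
        gene_df["replicate"] = rep
        pair_frames.append(pair_df)
        gene_frames.append(gene_df)
    return (
        pd.concat(pair_frames, ignore_index=True),
        pd.concat(gene_frames, ignore_index=True),
    )
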