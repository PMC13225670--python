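"""End-to-end synthetic study generator for benchmarking the fine-mapper.

The generator emulates a multi-tissue TWAS study design on synthetic
LD-blocked genotypes:

* biallelic dosages built from two latent-Gaussian haplotypes with AR(1)
  within-block correlation ``ld_rho ** |j - j'|`` thresholded at a per-SNP
  MAF drawn Uniform(0.05, 0.5); blocks are mutually independent, and the GWAS
  and eQTL panels are disjoint draws sharing the same MAFs and LD;
* tissue-specific gene expression in which a designated fraction of
  gene-tissue pairs is cis-heritable with cis-PVE ``pve1`` spread equally over
  ``n_causal_cis`` causal SNPs (3 shared across tissues, 2 tissue-specific in
  the default 5-SNP architecture), residual N(0, 1 - pve1); non-heritable
  pairs are pure N(0, 1) noise;
* a binary trait from a logistic model on the *true* (noiseless) genetic
  component of expression — deliberately a logistic link while the fitted
  model is probit, preserving the model-misspecification stress of the study
  design.  Per causal pair the trait variance contribution is ``w_k * pve2``
  (tissue weights act on the variance scale so the total genetic variance is
  ``ng * pve2`` for any weight vector summing to 1, matching the residual
  variance 1 - ng*pve2); the intercept ``u`` equals the expected
  log(case/control) ratio.  Optional SNP horizontal pleiotropy assigns an
  extra 6% of trait variance to i.i.d. Gaussian effects over all block SNPs
  (total genetic budget 10%: 4% GReX + 6% SNPs).

Prediction weights for fitting are obtained by running the Gaussian
sum-of-single-effects regression per pair on the eQTL panel.  With a fixed
seed the entire emitted study is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, ndtri

from .grex import fit_linear_susie
from .io import (
    GenotypeMatrix,
    PhenotypeVector,
    RegionSpec,
    WeightSet,
    write_phenotype,
    write_plink,
    write_regions,
    write_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimScenario",
    "SimTruth",
    "ExpressionSim",
    "Study",
    "causal_effect_size",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_trait",
    "fit_prediction_weights",
    "simulate_study",
    "emit_study",
]

_SNP_SPACING = 1_000  # bp between adjacent synthetic SNPs


@dataclass
class SimScenario:
    """Study-design configuration; defaults are the baseline conditions.

    ``w`` are per-tissue contribution weights (non-negative, summing to 1);
    ``ng`` causal gene-tissue pairs are drawn per tissue with positive weight.
    ``pve1`` is cis-heritability of expression for heritable pairs, ``pve2``
    the trait-variance share of each causal pair, ``u`` the logistic intercept
    (expected log case:control ratio).
    """

    n_gwas: int = 50_000
    n_eqtl: int = 500
    n_blocks: int = 50
    genes_per_block: int = 16  # mean block size of the source design
    snps_per_gene: int = 10
    n_tissues: int = 3
    heritable_fraction: float = 0.5
    pve1: float = 0.10
    n_causal_cis: int = 5
    random_cis_count: bool = False  # draw 3..7 causal cis-SNPs per heritable gene
    n_shared_cis: int = 3
    pve2: float = 0.004
    ng: int = 10
    w: tuple[float, ...] = (0.5, 0.5, 0.0)
    u: float = 0.0
    pleiotropy: bool = False
    pleiotropy_total_h2: float = 0.10
    pleiotropy_snp_h2: float = 0.06
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape[0] != self.n_tissues:
            raise ValueError("w must have one weight per tissue")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("tissue weights must be non-negative and sum to 1")
        if not 0.0 < self.pve1 < 1.0:
            raise ValueError("pve1 must lie in (0, 1)")
        if not 0.0 <= self.ng * self.pve2 < 1.0:
            raise ValueError("ng * pve2 must lie in [0, 1)")
        if not 0.0 <= self.heritable_fraction <= 1.0:
            raise ValueError("heritable_fraction must lie in [0, 1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")

    @property
    def n_genes(self) -> int:
        return self.n_blocks * self.genes_per_block

    @property
    def snps_per_block(self) -> int:
        return self.genes_per_block * self.snps_per_gene

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(self.n_genes)]

    def tissue_ids(self) -> list[str]:
        return [f"tissue{k + 1}" for k in range(self.n_tissues)]

    def snp_ids(self) -> list[str]:
        return [f"snp{j:05d}" for j in range(self.n_snps)]

    def cis_snps(self, gene_idx: int) -> np.ndarray:
        """Global SNP indices of the gene's cis window."""
        start = gene_idx * self.snps_per_gene
        return np.arange(start, start + self.snps_per_gene)

    def block_of_gene(self, gene_idx: int) -> int:
        return gene_idx // self.genes_per_block

    def regions(self) -> list[RegionSpec]:
        span = self.snps_per_block * _SNP_SPACING
        return [
            RegionSpec("1", b * span, (b + 1) * span, f"block{b:03d}")
            for b in range(self.n_blocks)
        ]

    def snp_positions(self) -> np.ndarray:
        return np.arange(self.n_snps, dtype=np.int64) * _SNP_SPACING + _SNP_SPACING // 2


@dataclass
class ExpressionSim:
    """Simulated eQTL-panel expression plus the generative cis-architecture.

    ``expression[k]`` is the n_eqtl x n_genes matrix for tissue k.
    ``effects[(gene_idx, tissue_idx)] = (snp_indices, effect_sizes)`` gives
    the causal cis model of each heritable pair (effects act on standardized
    dosages and are scaled so the genetic variance equals pve1 in the eQTL
    panel).  ``heritable[m, k]`` flags heritable pairs.
    """

    expression: list[np.ndarray]
    effects: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    heritable: np.ndarray


@dataclass
class SimTruth:
    """Ground-truth causal structure of a simulated trait."""

    causal_pairs: list[tuple[str, str]]
    causal_pair_idx: list[tuple[int, int]]
    effect_size: float  # v = sqrt(pve2 / pve1), identical across pairs
    causal_genes: set[str]
    causal_cis: dict[tuple[str, str], list[str]]
    pleiotropy_effects: np.ndarray | None = None


@dataclass
class Study:
    """A complete in-memory study: inputs for fitting plus ground truth."""

    scenario: SimScenario
    gwas_genotypes: GenotypeMatrix
    eqtl_genotypes: GenotypeMatrix
    regions: list[RegionSpec]
    expression: ExpressionSim
    phenotype: PhenotypeVector
    truth: SimTruth
    weights: WeightSet


def causal_effect_size(pve1: float, pve2: float) -> float:
    """Causal effect v = sqrt(pve2 / pve1) of a pair's true GReX on liability.

    Applied to the genetic expression component (variance pve1), each causal
    pair contributes pve2 of trait variance before tissue weighting.
    """
    if pve1 <= 0:
        raise ValueError("pve1 must be > 0")
    return float(np.sqrt(pve2 / pve1))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _haplotypes(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """Latent AR(1) Gaussians: u_1 = e_1, u_j = rho u_{j-1} + sqrt(1-rho^2) e_j."""
    e = rng.standard_normal((n, m))
    if rho == 0.0:
        return e
    u = np.empty_like(e)
    u[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        u[:, j] = rho * u[:, j - 1] + c * e[:, j]
    return u


def _panel(rng: np.random.Generator, n: int, scenario: SimScenario, taus: np.ndarray) -> np.ndarray:
    m = scenario.snps_per_block
    out = np.empty((n, scenario.n_snps), dtype=np.float64)
    for b in range(scenario.n_blocks):
        sl = slice(b * m, (b + 1) * m)
        h1 = _haplotypes(rng, n, m, scenario.ld_rho) < taus[None, sl]
        h2 = _haplotypes(rng, n, m, scenario.ld_rho) < taus[None, sl]
        out[:, sl] = h1.astype(np.float64) + h2
    return out


def simulate_genotypes(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, GenotypeMatrix, list[RegionSpec]]:
    """Draw disjoint GWAS and eQTL dosage panels sharing MAFs and LD structure."""
    rng = rng or np.random.default_rng(scenario.seed)
    mafs = rng.uniform(*scenario.maf_range, size=scenario.n_snps)
    taus = ndtri(mafs)
    snp_ids = scenario.snp_ids()
    pos = scenario.snp_positions()
    gwas = GenotypeMatrix(
        _panel(rng, scenario.n_gwas, scenario, taus), snp_ids, chrom="1", positions=pos
    )
    eqtl = GenotypeMatrix(
        _panel(rng, scenario.n_eqtl, scenario, taus), snp_ids, chrom="1", positions=pos.copy()
    )
    return gwas, eqtl, scenario.regions()


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    eqtl_genotypes: GenotypeMatrix,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> ExpressionSim:
    """Simulate tissue-specific expression with the stated cis-architecture."""
    if scenario.pve1 >= 1.0:
        raise ValueError("pve1 must be < 1")
    G, K = scenario.n_genes, scenario.n_tissues
    spg = scenario.snps_per_gene
    Z = eqtl_genotypes.standardize().values
    n = Z.shape[0]

    # exactly heritable_fraction of pairs, chosen uniformly
    n_her = int(round(scenario.heritable_fraction * G * K))
    flat = rng.permutation(G * K)[:n_her]
    heritable = np.zeros((G, K), dtype=bool)
    heritable[flat // K, flat % K] = True

    expression = [np.empty((n, G)) for _ in range(K)]
    effects: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for m in range(G):
        cis = scenario.cis_snps(m)
        her_tissues = np.flatnonzero(heritable[m])
        if her_tissues.size:
            if scenario.random_cis_count:
                n_causal = int(rng.integers(3, 8))
            else:
                n_causal = scenario.n_causal_cis
            n_shared = min(scenario.n_shared_cis, n_causal)
            n_spec = n_causal - n_shared
            if n_shared + n_spec * her_tissues.size > spg:
                raise ValueError(
                    f"gene {m}: needs {n_shared + n_spec * her_tissues.size} distinct "
                    f"causal cis-SNPs but has only {spg}"
                )
            perm = rng.permutation(cis)
            shared = perm[:n_shared]
            rest = perm[n_shared:]
            for pos_k, k in enumerate(her_tissues):
                specific = rest[pos_k * n_spec : (pos_k + 1) * n_spec]
                idx = np.concatenate([shared, specific])
                b = rng.choice([-1.0, 1.0], size=idx.size) * np.sqrt(
                    scenario.pve1 / n_causal
                )
                genetic = Z[:, idx] @ b
                sd = genetic.std()
                if sd > 0:
                    b = b * np.sqrt(scenario.pve1) / sd
                    genetic = genetic * np.sqrt(scenario.pve1) / sd
                effects[(m, int(k))] = (idx, b)
                expression[int(k)][:, m] = genetic + rng.normal(
                    0.0, np.sqrt(1.0 - scenario.pve1), size=n
                )
        for k in range(K):
            if not heritable[m, k]:
                expression[k][:, m] = rng.standard_normal(n)
    return ExpressionSim(expression=expression, effects=effects, heritable=heritable)


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------


def simulate_trait(
    gwas_genotypes: GenotypeMatrix,
    expr: ExpressionSim,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> tuple[PhenotypeVector, SimTruth]:
    """Draw the binary trait from the logistic liability model on true GReX."""
    Z = gwas_genotypes.standardize().values
    n = Z.shape[0]
    w = np.asarray(scenario.w, dtype=float)
    genes = scenario.gene_ids()
    tissues = scenario.tissue_ids()

    eta = np.full(n, scenario.u)
    causal_pairs: list[tuple[str, str]] = []
    causal_idx: list[tuple[int, int]] = []
    causal_cis: dict[tuple[str, str], list[str]] = {}
    snp_ids = scenario.snp_ids()
    for k in range(scenario.n_tissues):
        if w[k] == 0:
            continue
        pool = [m for m in range(scenario.n_genes) if expr.heritable[m, k]]
        if len(pool) < scenario.ng:
            raise ValueError(
                f"tissue {tissues[k]}: ng={scenario.ng} exceeds its "
                f"{len(pool)} heritable pairs"
            )
        chosen = rng.choice(len(pool), size=scenario.ng, replace=False)
        for ci in chosen:
            m = pool[ci]
            idx, b = expr.effects[(m, k)]
            g = Z[:, idx] @ b  # true genetic expression component, var ~ pve1
            sd = g.std()
            g_std = (g - g.mean()) / sd if sd > 0 else g
            eta += np.sqrt(w[k] * scenario.pve2) * g_std
            causal_pairs.append((genes[m], tissues[k]))
            causal_idx.append((m, k))
            causal_cis[(genes[m], tissues[k])] = [snp_ids[j] for j in idx]

    pleio = None
    if scenario.pleiotropy:
        a = rng.standard_normal(scenario.n_snps)
        v = Z @ a
        sd_v = v.std()
        eta += np.sqrt(scenario.pleiotropy_snp_h2) * (v - v.mean()) / sd_v
        pleio = a * np.sqrt(scenario.pleiotropy_snp_h2) / sd_v
        resid_var = 1.0 - scenario.pleiotropy_total_h2
    else:
        resid_var = 1.0 - scenario.ng * scenario.pve2
    eta += rng.normal(0.0, np.sqrt(resid_var), size=n)
    y = rng.binomial(1, expit(eta)).astype(np.int8)
    truth = SimTruth(
        causal_pairs=causal_pairs,
        causal_pair_idx=causal_idx,
        effect_size=causal_effect_size(scenario.pve1, scenario.pve2),
        causal_genes={g for g, _ in causal_pairs},
        causal_cis=causal_cis,
        pleiotropy_effects=pleio,
    )
    return PhenotypeVector(y), truth


# ---------------------------------------------------------------------------
# prediction weights and full studies
# ---------------------------------------------------------------------------


def fit_prediction_weights(
    eqtl_genotypes: GenotypeMatrix,
    expr: ExpressionSim,
    scenario: SimScenario,
    L: int = 5,
) -> WeightSet:
    """Fit per-pair SNP prediction weights on the eQTL panel.

    Every expressed gene-tissue pair gets a model over the gene's cis-SNPs
    (heritable or not), mirroring a real weight panel where heritability is
    unknown at fitting time.
    """
    Zstd = eqtl_genotypes.standardize()
    genes = scenario.gene_ids()
    tissues = scenario.tissue_ids()
    snp_ids = scenario.snp_ids()
    entries: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for m in range(scenario.n_genes):
        cis = scenario.cis_snps(m)
        Xc = Zstd.values[:, cis]
        for k in range(scenario.n_tissues):
            fitres = fit_linear_susie(Xc, expr.expression[k][:, m], L=L)
            entries[(genes[m], tissues[k])] = [
                (snp_ids[j], float(wj)) for j, wj in zip(cis, fitres.weights)
            ]
    return WeightSet(entries)


def simulate_study(scenario: SimScenario, fit_weights: bool = True) -> Study:
    """Generate a full study (genotypes, expression, trait, weights) in memory."""
    rng = np.random.default_rng(scenario.seed)
    gwas, eqtl, regions = simulate_genotypes(scenario, rng)
    expr = simulate_expression(eqtl, scenario, rng)
    pheno, truth = simulate_trait(gwas, expr, scenario, rng)
    weights = (
        fit_prediction_weights(eqtl, expr, scenario)
        if fit_weights
        else WeightSet({})
    )
    return Study(
        scenario=scenario,
        gwas_genotypes=gwas,
        eqtl_genotypes=eqtl,
        regions=regions,
        expression=expr,
        phenotype=pheno,
        truth=truth,
        weights=weights,
    )


def emit_study(scenario: SimScenario, out_dir: str | Path) -> Study:
    """Write a complete file-level study: genotypes (PLINK1), phenotype,
    fitted weight TSV, region BED, truth tables, and a scenario manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(scenario)
    write_plink(
        out / "gwas",
        study.gwas_genotypes.values.astype(int),
        study.gwas_genotypes.snp_ids,
        positions=study.gwas_genotypes.positions,
        chrom="1",
    )
    write_phenotype(study.phenotype, out / "phenotype.tsv")
    write_weights(study.weights, out / "weights.tsv")
    write_regions(study.regions, out / "regions.bed")
    with open(out / "truth_pairs.tsv", "w") as fh:
        fh.write("gene\ttissue\teffect_size\tcausal_cis_snps\n")
        for g, t in study.truth.causal_pairs:
            snps = ",".join(study.truth.causal_cis[(g, t)])
            fh.write(f"{g}\t{t}\t{study.truth.effect_size:.6g}\t{snps}\n")
    with open(out / "truth_genes.tsv", "w") as fh:
        fh.write("gene\n")
        for g in sorted(study.truth.causal_genes):
            fh.write(f"{g}\n")
    manifest = dataclasses.asdict(scenario)
    manifest["w"] = list(scenario.w)
    manifest["maf_range"] = list(scenario.maf_range)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return study
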