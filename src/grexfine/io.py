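"""Domain types and file I/O for genotypes, weights, phenotypes, regions and results.

All tabular interchange formats are UTF-8, tab-delimited text with a header
row.  Genotypes are additionally supported in the PLINK1 binary triple
(``.bed``/``.bim``/``.fam``); a minimal codec for that format is implemented
here since no pre-installed library reads it.

Coordinate convention: BED-style 0-based, half-open intervals.  A SNP belongs
to a region when its position lies in ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "CovariateMatrix",
    "WeightSet",
    "GReXMatrix",
    "RegionSpec",
    "FineMapResult",
    "standardize_columns",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_plink",
    "read_phenotype",
    "write_phenotype",
    "read_covariates",
    "read_weights",
    "write_weights",
    "read_regions",
    "write_regions",
    "write_result",
    "read_result",
]


# ---------------------------------------------------------------------------
# column standardization
# ---------------------------------------------------------------------------

_CONST_TOL = 1e-12


def standardize_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale each column to mean 0, sd 1 (population sd, denominator n).

    Constant (zero-variance) columns cannot be scaled; they are set to all
    zeros and flagged in the returned boolean mask so downstream selection can
    exclude them.

    Returns
    -------
    (standardized, constant_mask)
        ``standardized`` is a new float64 array; ``constant_mask[j]`` is True
        where column ``j`` had zero variance.
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("standardize_columns expects a 2-d matrix with >= 1 row")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # ddof=0
    constant = sd <= _CONST_TOL
    out = x - mean
    safe_sd = np.where(constant, 1.0, sd)
    out /= safe_sd
    out[:, constant] = 0.0
    return out, constant


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix for one genomic region: individuals x SNPs.

    ``values`` holds dosages (0/1/2 or imputed fractional values) or, when
    ``standardized`` is True, column-standardized dosages.  ``positions`` (bp,
    aligned with ``snp_ids``) are optional and only needed for region
    subsetting.
    """

    values: np.ndarray
    snp_ids: list[str]
    standardized: bool = False
    chrom: str | None = None
    positions: np.ndarray | None = None
    constant_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-dimensional")
        if self.values.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length does not match number of columns")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape[0] != len(self.snp_ids):
                raise ValueError("positions length does not match snp_ids")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def standardize(self) -> "GenotypeMatrix":
        """Return a standardized copy (idempotent)."""
        if self.standardized:
            return self
        vals, const = standardize_columns(self.values)
        return GenotypeMatrix(
            vals,
            list(self.snp_ids),
            standardized=True,
            chrom=self.chrom,
            positions=None if self.positions is None else self.positions.copy(),
            constant_mask=const,
        )

    def subset_region(self, region: "RegionSpec") -> "GenotypeMatrix":
        """Restrict to SNPs with position in [region.start, region.end)."""
        if self.positions is None:
            raise ValueError("genotype panel has no SNP positions; cannot subset by region")
        keep = (self.positions >= region.start) & (self.positions < region.end)
        if region.chrom is not None and self.chrom is not None and region.chrom != self.chrom:
            keep = np.zeros_like(keep)
        idx = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.values[:, idx],
            [self.snp_ids[i] for i in idx],
            standardized=self.standardized,
            chrom=self.chrom,
            positions=self.positions[idx],
            constant_mask=None if self.constant_mask is None else self.constant_mask[idx],
        )


@dataclass
class PhenotypeVector:
    """Binary case/control labels for n individuals (1 = case)."""

    values: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("phenotype values must be binary 0/1")
        self.values = vals.astype(np.int8)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def case_count(self) -> int:
        return int(self.values.sum())

    @property
    def control_count(self) -> int:
        return int(self.n - self.values.sum())

    def require_both_classes(self) -> None:
        if self.case_count == 0 or self.control_count == 0:
            raise ValueError(
                "phenotype must contain at least one case and one control "
                f"(got {self.case_count} cases, {self.control_count} controls)"
            )


@dataclass
class CovariateMatrix:
    """n x c covariate design (possibly empty, c = 0); columns standardized as genotypes."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[1] != len(self.names):
            raise ValueError("covariate names length does not match columns")

    @property
    def c(self) -> int:
        return self.values.shape[1]

    def standardize(self) -> "CovariateMatrix":
        if self.standardized or self.c == 0:
            return CovariateMatrix(self.values, list(self.names), standardized=True)
        vals, _ = standardize_columns(self.values)
        return CovariateMatrix(vals, list(self.names), standardized=True)


@dataclass
class WeightSet:
    """SNP -> expression prediction weights keyed by (gene_id, tissue_id).

    Each entry is a list of ``(snp_id, weight)`` pairs with at least one SNP.
    """

    entries: dict[tuple[str, str], list[tuple[str, float]]]

    @property
    def n_pairs(self) -> int:
        return len(self.entries)

    def resolve(self, snp_ids: Sequence[str]) -> "WeightSet":
        """Drop weights whose SNP is absent from the genotype panel.

        Entries left without any resolvable SNP are dropped entirely; both
        kinds of removal are logged as warnings.
        """
        known = set(snp_ids)
        out: dict[tuple[str, str], list[tuple[str, float]]] = {}
        for key, wlist in self.entries.items():
            kept = [(s, w) for s, w in wlist if s in known]
            n_dropped = len(wlist) - len(kept)
            if n_dropped:
                logger.warning(
                    "weight entry %s: dropped %d SNP(s) not present in the genotype panel",
                    key,
                    n_dropped,
                )
            if kept:
                out[key] = kept
            else:
                logger.warning("weight entry %s dropped: no resolvable SNPs", key)
        return WeightSet(out)


@dataclass
class GReXMatrix:
    """Predicted genetically regulated expression for p gene-tissue pairs.

    ``pairs[j] = (gene_id, tissue_id)`` labels column j.  ``gene_index`` /
    ``tissue_index`` map columns to indices into the unique ``genes`` /
    ``tissues`` lists; every gene appears in at least one column.
    """

    values: np.ndarray
    pairs: list[tuple[str, str]]
    standardized: bool = False
    constant_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[1] != len(self.pairs):
            raise ValueError("pairs length does not match number of columns")
        self.genes = sorted({g for g, _ in self.pairs})
        self.tissues = sorted({t for _, t in self.pairs})
        g_lookup = {g: i for i, g in enumerate(self.genes)}
        t_lookup = {t: i for i, t in enumerate(self.tissues)}
        self.gene_index = np.array([g_lookup[g] for g, _ in self.pairs], dtype=np.int64)
        self.tissue_index = np.array([t_lookup[t] for _, t in self.pairs], dtype=np.int64)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def M(self) -> int:
        return len(self.genes)

    @property
    def K(self) -> int:
        return len(self.tissues)

    def standardize(self) -> "GReXMatrix":
        if self.standardized:
            return self
        vals, const = standardize_columns(self.values)
        out = GReXMatrix(vals, list(self.pairs), standardized=True, constant_mask=const)
        return out


@dataclass(frozen=True)
class RegionSpec:
    """A genomic region analyzed as one unit (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")


@dataclass
class FineMapResult:
    """Scored fine-mapping output for one region (or a pooled set of regions).

    ``pair_table`` columns: gene, tissue, pip, local_fdr, estimated_fdr,
    significant.  ``gene_table`` columns: gene, gene_pip, local_fdr,
    estimated_fdr, significant.  Gene PIPs are normalized selection
    probabilities over the region's genes and sum to 1.
    """

    pair_table: pd.DataFrame
    gene_table: pd.DataFrame
    elbo_trace: np.ndarray
    converged: bool

    def validate(self) -> None:
        for col, tab in (("pip", self.pair_table), ("gene_pip", self.gene_table)):
            vals = tab[col].to_numpy()
            if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
                raise ValueError(f"{col} outside [0, 1]")
        s = float(self.gene_table["gene_pip"].sum())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"gene PIPs must sum to 1 (got {s})")


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Load a dosage matrix from a whitespace TSV or a PLINK1 triple.

    TSV layout: header row of SNP ids, one row per individual, dosages as
    numbers, missing entries as empty/NA.  For ``format='plink'``, ``path`` is
    the prefix of a ``.bed``/``.bim``/``.fam`` triple.  Missing dosages are
    imputed to the column mean; an all-missing column is an error.
    """
    if format == "tsv":
        return _read_genotypes_tsv(Path(path))
    if format == "plink":
        return _read_genotypes_plink(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _impute_column_means(values: np.ndarray, snp_ids: Sequence[str]) -> np.ndarray:
    missing = np.isnan(values)
    if missing.any():
        n_obs = (~missing).sum(axis=0)
        all_missing = np.flatnonzero(n_obs == 0)
        if all_missing.size:
            raise ValueError(f"column {snp_ids[all_missing[0]]!r} is entirely missing")
        col_mean = np.nanmean(values, axis=0)
        values = np.where(missing, col_mean[None, :], values)
    return values


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    snp_ids = [str(c) for c in df.columns]
    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"malformed genotype TSV {path}: non-numeric dosage ({exc})") from exc
    values = _impute_column_means(values, snp_ids)
    return GenotypeMatrix(values, snp_ids)


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(geno.values, columns=geno.snp_ids).to_csv(path, sep="\t", index=False)


# PLINK1 .bed 2-bit codes (SNP-major): 00 hom A1 (dosage 2), 01 missing,
# 10 het (dosage 1), 11 hom A2 (dosage 0).
_PLINK_MAGIC = b"\x6c\x1b\x01"
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _read_genotypes_plink(prefix: Path) -> GenotypeMatrix:
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"PLINK triple incomplete: missing {f}")
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str, "snp": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    n, s = len(fam_df), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ValueError(f"{bed} is not a SNP-major PLINK1 .bed file (bad magic bytes)")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * s:
        raise ValueError(f"{bed}: size inconsistent with {n} individuals x {s} SNPs")
    codes = body.reshape(s, bytes_per_snp)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11  # (s, bytes, 4)
    expanded = expanded.reshape(s, bytes_per_snp * 4)[:, :n]
    values = _CODE_TO_DOSAGE[expanded].T  # (n, s)
    values = _impute_column_means(values, bim_df["snp"].tolist())
    chroms = bim_df["chrom"].unique()
    return GenotypeMatrix(
        values,
        bim_df["snp"].tolist(),
        chrom=str(chroms[0]) if len(chroms) == 1 else None,
        positions=bim_df["pos"].to_numpy(np.int64),
    )


def write_plink(
    prefix: str | Path,
    dosages: np.ndarray,
    snp_ids: Sequence[str],
    positions: Sequence[int] | None = None,
    chrom: str = "1",
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Write integer dosages (0/1/2) as a PLINK1 bed/bim/fam triple."""
    prefix = Path(prefix)
    d = np.asarray(dosages)
    if not np.isin(d, [0, 1, 2]).all():
        raise ValueError("PLINK writer requires integer dosages in {0,1,2}")
    n, s = d.shape
    if sample_ids is None:
        sample_ids = [f"iid{i}" for i in range(n)]
    if positions is None:
        positions = list(range(1, s + 1))
    dosage_to_code = {2: 0b00, 1: 0b10, 0: 0b11}
    code = np.vectorize(dosage_to_code.get)(d.astype(int)).astype(np.uint8)  # (n, s)
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((s, bytes_per_snp * 4), dtype=np.uint8)
    # pad positions with code 11 (dosage 0) — ignored on read
    padded[:, :] = 0b11
    padded[:, :n] = code.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, snp in enumerate(snp_ids):
            fh.write(f"{chrom}\t{snp}\t0\t{positions[j]}\tA\tG\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# phenotype / covariates
# ---------------------------------------------------------------------------


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Read a TSV with columns ``sample_id`` and ``phenotype`` (0/1)."""
    df = pd.read_csv(path, sep="\t")
    if "phenotype" not in df.columns:
        raise ValueError(f"{path}: expected a 'phenotype' column")
    ids = df["sample_id"].astype(str).tolist() if "sample_id" in df.columns else None
    return PhenotypeVector(df["phenotype"].to_numpy(), sample_ids=ids)


def write_phenotype(pheno: PhenotypeVector, path: str | Path) -> None:
    ids = pheno.sample_ids or [f"iid{i}" for i in range(pheno.n)]
    pd.DataFrame({"sample_id": ids, "phenotype": pheno.values}).to_csv(
        path, sep="\t", index=False
    )


def read_covariates(path: str | Path) -> CovariateMatrix:
    """Read a TSV keyed by ``sample_id``; all remaining columns are covariates."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c != "sample_id"]
    return CovariateMatrix(df[cols].to_numpy(np.float64), names=cols)


# ---------------------------------------------------------------------------
# prediction weights
# ---------------------------------------------------------------------------


def read_weights(path: str | Path) -> WeightSet:
    """Read a weight TSV with columns gene, tissue, snp, weight."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "tissue": str, "snp": str})
    required = {"gene", "tissue", "snp", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: weight table must have columns {sorted(required)}")
    dup = df.duplicated(subset=["gene", "tissue", "snp"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate weight row for ({row['gene']}, {row['tissue']}, {row['snp']})"
        )
    weights = pd.to_numeric(df["weight"], errors="coerce")
    if weights.isna().any():
        bad = df.loc[weights.isna()].iloc[0]
        raise ValueError(
            f"{path}: non-numeric weight for ({bad['gene']}, {bad['tissue']}, {bad['snp']})"
        )
    entries: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for (gene, tissue), grp in df.assign(weight=weights).groupby(
        ["gene", "tissue"], sort=False
    ):
        entries[(gene, tissue)] = list(zip(grp["snp"], grp["weight"].astype(float)))
    return WeightSet(entries)


def write_weights(weights: WeightSet, path: str | Path) -> None:
    rows = [
        {"gene": g, "tissue": t, "snp": s, "weight": w}
        for (g, t), wlist in weights.entries.items()
        for s, w in wlist
    ]
    pd.DataFrame(rows, columns=["gene", "tissue", "snp", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


def read_regions(path: str | Path) -> list[RegionSpec]:
    """Read regions from a BED file (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    regions = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"region{i}"
        regions.append(RegionSpec(str(row[0]), int(row[1]), int(row[2]), name))
    return regions


def write_regions(regions: Iterable[RegionSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

_PAIR_COLS = ["gene", "tissue", "pip", "local_fdr", "estimated_fdr", "significant"]
_GENE_COLS = ["gene", "gene_pip", "local_fdr", "estimated_fdr", "significant"]


def write_result(result: FineMapResult, prefix: str | Path) -> None:
    """Write a FineMapResult as ``<prefix>.pairs.tsv``, ``<prefix>.genes.tsv``
    and a small ``<prefix>.meta.json`` holding convergence info."""
    prefix = Path(prefix)
    result.pair_table[_PAIR_COLS].to_csv(f"{prefix}.pairs.tsv", sep="\t", index=False)
    result.gene_table[_GENE_COLS].to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
    meta = {"converged": bool(result.converged), "elbo_trace": list(map(float, result.elbo_trace))}
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh)


def read_result(prefix: str | Path) -> FineMapResult:
    prefix = Path(prefix)
    pair = pd.read_csv(f"{prefix}.pairs.tsv", sep="\t", dtype={"gene": str, "tissue": str})
    gene = pd.read_csv(f"{prefix}.genes.tsv", sep="\t", dtype={"gene": str})
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    return FineMapResult(
        pair_table=pair,
        gene_table=gene,
        elbo_trace=np.asarray(meta["elbo_trace"], dtype=float),
        converged=bool(meta["converged"]),
    )
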