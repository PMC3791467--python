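"""Tabular IO, median normalization, prevalence filtering and line means.

CSV dialects (UTF-8, header row mandatory):

* map:        ``marker,chrom,cm``
* genotypes:  ``line,cytoplasm,<marker...>`` with alleles coded ``K``/``T``
* phenotypes: long format ``line,experiment,block,metabolite,value``
  (empty value = missing)
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import (
    ALLELE_CODES,
    ALLELE_LETTERS,
    CYTOPLASM,
    DataError,
    GeneticMap,
    GenotypeMatrix,
    LineMeans,
    validate_phenotypes,
)

log = logging.getLogger(__name__)

SAMPLE_KEY = ["line", "experiment", "block"]


# ---------------------------------------------------------------------------
# writers

def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    out = genotypes.alleles.replace(ALLELE_LETTERS)
    out.insert(0, CYTOPLASM, genotypes.cytoplasm.replace(ALLELE_LETTERS))
    out.to_csv(path, index=True, index_label="line")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers with validation

def read_map(path) -> GeneticMap:
    df = pd.read_csv(path)
    df["chrom"] = df["chrom"].astype(int)
    df["cm"] = df["cm"].astype(float)
    return GeneticMap(df)


def read_genotypes(path, gmap: GeneticMap | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="line")
    if CYTOPLASM not in df.columns:
        raise DataError("genotype file has no 'cytoplasm' column")
    markers = [c for c in df.columns if c != CYTOPLASM]
    if gmap is not None:
        missing = set(gmap.markers) - set(markers)
        if missing:
            raise DataError(f"genotype file lacks mapped markers {sorted(missing)[:5]}")
        markers = gmap.markers.to_list()
    for col in [CYTOPLASM] + markers:
        bad = ~df[col].isin(ALLELE_CODES)
        if bad.any():
            line = df.index[bad][0]
            raise DataError(
                f"non-biallelic code {df.loc[line, col]!r} at marker {col!r}, "
                f"line {line!r}"
            )
    alleles = df[markers].map(ALLELE_CODES.get).astype(np.int8)
    cyto = df[CYTOPLASM].map(ALLELE_CODES.get).astype(np.int8)
    return GenotypeMatrix(alleles, cyto)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["experiment"] = df["experiment"].astype(int)
    df["block"] = df["block"].astype(int)
    return validate_phenotypes(df)


def load_dataset(map_path, geno_path, pheno_path):
    """Read and cross-validate the three input tables.

    Every phenotype line id must exist in the genotype matrix.
    """
    gmap = read_map(map_path)
    genotypes = read_genotypes(geno_path, gmap)
    pheno = read_phenotypes(pheno_path)
    unknown = set(pheno["line"]) - set(genotypes.lines)
    if unknown:
        raise DataError(
            f"phenotype table references unknown line {sorted(unknown)[0]!r}"
        )
    return gmap, genotypes, pheno


# ---------------------------------------------------------------------------
# normalization and summaries

def median_normalize(pheno: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample so its metabolite median equals the grand median.

    A sample is one extraction (line x experiment x block).  Each sample's
    values are multiplied by a single factor bringing its within-sample
    median over metabolites to the grand median of all sample medians,
    removing per-sample technical scale while preserving relative
    abundances.  Samples with no detected metabolites are left unscaled.
    """
    pheno = validate_phenotypes(pheno)
    med = pheno.groupby(SAMPLE_KEY, sort=False)["value"].transform("median")
    sample_medians = pheno.groupby(SAMPLE_KEY, sort=False)["value"].median()
    grand = float(np.nanmedian(sample_medians.to_numpy()))
    n_empty = int(sample_medians.isna().sum())
    if n_empty:
        log.warning("%d samples have no detected metabolites; left unscaled", n_empty)
    out = pheno.copy()
    factor = grand / med
    factor = factor.where(med.notna(), 1.0)
    out["value"] = out["value"] * factor
    return out


def prevalence_filter(
    pheno: pd.DataFrame, min_fraction: float = 0.25, n_lines: int | None = None
) -> pd.DataFrame:
    """Drop metabolites detected in no more than ``min_fraction`` of lines.

    Detection means at least one non-missing observation for a line.
    """
    if n_lines is None:
        n_lines = pheno["line"].nunique()
    detected = (
        pheno[pheno["value"].notna()].groupby("metabolite", observed=True)["line"].nunique()
    )
    frac = detected.reindex(pheno["metabolite"].unique(), fill_value=0) / n_lines
    keep = frac[frac > min_fraction].index
    dropped = frac.index.difference(keep)
    if len(dropped):
        log.info(
            "prevalence filter dropped %d of %d metabolites (<= %.0f%% of lines)",
            len(dropped),
            len(frac),
            100 * min_fraction,
        )
    return pheno[pheno["metabolite"].isin(keep)].reset_index(drop=True)


def line_means(
    pheno: pd.DataFrame, genotypes: GenotypeMatrix | None = None
) -> LineMeans:
    """Arithmetic mean over available replicates per (line, metabolite)."""
    wide = pheno.pivot_table(
        index="line", columns="metabolite", values="value", aggfunc="mean"
    )
    wide.columns.name = None
    cyto = None
    if genotypes is not None:
        wide = wide.reindex(genotypes.lines)
        cyto = genotypes.cytoplasm
    return LineMeans(values=wide, cytoplasm=cyto)
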