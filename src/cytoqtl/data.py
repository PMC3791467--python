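"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Alleles are coded numerically with Kas = +1 and Tsu = -1, for nuclear
  markers and for the cytoplasm alike.  Letter codes ``K``/``T`` are used
  on disk.
* The cytoplasm is addressed everywhere by the reserved locus name
  ``"cytoplasm"``.
* Genetic map positions are in centimorgans (cM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KAS = 1
TSU = -1
CYTOPLASM = "cytoplasm"

ALLELE_LETTERS = {KAS: "K", TSU: "T"}
ALLELE_CODES = {"K": KAS, "T": TSU}

#: required columns of a long-format phenotype table
PHENO_COLUMNS = ("line", "experiment", "block", "metabolite", "value")


class DataError(ValueError):
    """Raised when an input table violates the documented dialect."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered genetic map: one row per marker with chromosome and cM position.

    ``table`` has columns ``marker`` (unique str), ``chrom`` (int, 1-based)
    and ``cm`` (float, non-decreasing within chromosome).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = {"marker", "chrom", "cm"} - set(t.columns)
        if missing:
            raise DataError(f"genetic map is missing columns {sorted(missing)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise DataError(f"duplicate marker name {dup!r} in genetic map")
        for chrom, grp in t.groupby("chrom", sort=False):
            d = np.diff(grp["cm"].to_numpy())
            if (d < 0).any():
                bad = grp["marker"].iloc[int(np.argmax(d < 0)) + 1]
                raise DataError(
                    f"map positions decrease on chromosome {chrom} at marker {bad!r}"
                )

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[int]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_table(self, chrom: int) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def chrom_length(self, chrom: int) -> float:
        return float(self.chrom_table(chrom)["cm"].max())

    @property
    def total_length(self) -> float:
        return float(sum(self.chrom_length(c) for c in self.chromosomes))

    def position_of(self, marker: str) -> tuple[int, float]:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in map")
        return int(row["chrom"].iloc[0]), float(row["cm"].iloc[0])

    def nearest_marker(self, chrom: int, cm: float) -> str:
        grp = self.chrom_table(chrom)
        if grp.empty:
            raise KeyError(f"no markers on chromosome {chrom}")
        i = (grp["cm"] - cm).abs().to_numpy().argmin()
        return str(grp["marker"].iloc[i])

    def median_spacing(self) -> float:
        gaps = []
        for chrom in self.chromosomes:
            gaps.append(np.diff(self.chrom_table(chrom)["cm"].to_numpy()))
        return float(np.median(np.concatenate(gaps)))


@dataclass
class GenotypeMatrix:
    """Lines x markers allele matrix plus the cytoplasm label per line.

    ``alleles``: DataFrame indexed by line id, one int8 column per marker
    holding +1 (Kas) or -1 (Tsu).  ``cytoplasm``: Series (same index) of
    +1/-1.  RILs are fully inbred, so no heterozygous codes exist.
    """

    alleles: pd.DataFrame
    cytoplasm: pd.Series

    def __post_init__(self):
        if not self.alleles.index.equals(self.cytoplasm.index):
            raise DataError("genotype alleles and cytoplasm have different line ids")
        vals = self.alleles.to_numpy()
        if not np.isin(vals, (KAS, TSU)).all():
            raise DataError("genotype matrix contains codes other than +1/-1")
        if not np.isin(self.cytoplasm.to_numpy(), (KAS, TSU)).all():
            raise DataError("cytoplasm column contains codes other than +1/-1")

    @property
    def lines(self) -> pd.Index:
        return self.alleles.index

    @property
    def n_lines(self) -> int:
        return len(self.alleles)

    def locus_values(self, locus: str) -> pd.Series:
        """±1-coded values at a nuclear marker or at the cytoplasm."""
        if locus == CYTOPLASM:
            return self.cytoplasm
        if locus not in self.alleles.columns:
            raise KeyError(f"unknown locus {locus!r}")
        return self.alleles[locus]

    def cyto_counts(self) -> tuple[int, int]:
        c = self.cytoplasm.to_numpy()
        return int((c == KAS).sum()), int((c == TSU).sum())


@dataclass
class LineMeans:
    """Per-line mean metabolite abundances (lines x metabolites).

    Derived from the replicated phenotype table; carries the cytoplasm
    label so downstream models need not join back to the genotypes.
    """

    values: pd.DataFrame
    cytoplasm: pd.Series | None = None

    @property
    def lines(self) -> pd.Index:
        return self.values.index

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and return it unchanged."""
    missing = set(PHENO_COLUMNS) - set(pheno.columns)
    if missing:
        raise DataError(f"phenotype table is missing columns {sorted(missing)}")
    vals = pheno["value"]
    bad = vals.notna() & (vals <= 0)
    if bad.any():
        row = pheno[bad].iloc[0]
        raise DataError(
            f"non-positive abundance for line {row['line']!r}, "
            f"metabolite {row['metabolite']!r}"
        )
    key = ["line", "experiment", "block", "metabolite"]
    if pheno.duplicated(subset=key).any():
        row = pheno[pheno.duplicated(subset=key)].iloc[0]
        raise DataError(
            f"duplicate observation for line {row['line']!r}, experiment "
            f"{row['experiment']}, block {row['block']}, metabolite {row['metabolite']!r}"
        )
    return pheno
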