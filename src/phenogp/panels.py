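"""Core data containers: genotype matrix, phenomic (ChlF) panel, trait panel.

Genotypes are biallelic SNPs in additive 0/1/2 coding stored as floats with
``numpy.nan`` marking missing calls.  Phenomic and trait panels are tidy
tables with one record per sample x condition x variable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The fixed roster of chlorophyll-a-fluorescence (OJIP transient) parameters.
CHLF_PARAMS: tuple[str, ...] = (
    "IBR",
    "PI total",
    "phi(Ro)",
    "phi(Eo)",
    "psi(Eo)",
    "phi(Po)",
    "phi(Po)/(1-phi(Po))",
    "dRo/(1-dRo)",
    "psi(Eo)/(1-psi(Eo))",
    "RC/ABS",
    "REo/RC",
    "DIo/RC",
    "ETo/RC",
    "TRo/RC",
    "ABS/RC",
    "Fo",
    "Fm",
    "Fv/Fm",
)

#: Growth traits: leaf count, tree height, trunk diameter.
TRAITS: tuple[str, ...] = ("LC", "TH", "TD")


def col_label(variable: str, condition: int) -> str:
    """Column label for a variable measured under a treatment condition."""
    return f"{variable}_{condition}"


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x markers additive SNP codes with a missingness mask.

    ``codes`` holds values in {0, 1, 2} (possibly fractional after mean
    imputation) with ``nan`` for missing calls.
    """

    sample_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        for name, ids in (("sample", self.sample_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("genotype codes must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.sample_ids, columns=self.marker_ids)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        s = slice(None) if sample_idx is None else np.asarray(sample_idx)
        m = slice(None) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(self.sample_ids[s], self.marker_ids[m], self.codes[np.ix_(
            np.arange(self.n_samples)[s], np.arange(self.n_markers)[m])])

    # ---------------------------------------------------------------- I/O

    def write_tsv(self, path: str | Path) -> None:
        """Tab-delimited text: rows = samples, header = marker ids, missing = NA."""
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object),
                   df.to_numpy(float))

    def write_vcf(self, path: str | Path, contig: str = "1") -> None:
        """Minimal single-contig VCF with GT-only records (unphased diploid)."""
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(str(s) for s in self.sample_ids) + "\n")
            for j, mid in enumerate(self.marker_ids):
                gts = [gt_map.get(v, "./.") if not np.isnan(v) else "./."
                       for v in self.codes[:, j]]
                fh.write(f"{contig}\t{j + 1}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")

    @classmethod
    def read_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read a diploid VCF into additive coding (alt-allele dosage)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = np.asarray(vcf.samples, dtype=object)
        marker_ids, cols = [], []
        for var in vcf:
            marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
            g = np.asarray(var.gt_types, dtype=float)  # 0,1,2; 3 = unknown
            g[g == 3] = np.nan
            cols.append(g)
        codes = np.column_stack(cols) if cols else np.empty((len(samples), 0))
        return cls(samples, np.asarray(marker_ids, dtype=object), codes)


class _TidyPanel:
    """Tidy sample x condition x variable table with wide-format helpers."""

    #: override in subclasses: fixed variable roster or None
    ROSTER: tuple[str, ...] | None = None

    def __init__(self, data: pd.DataFrame):
        required = {"sample_id", "condition", "variable", "value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"panel is missing columns {sorted(missing)}")
        data = data.loc[:, ["sample_id", "condition", "variable", "value"]].copy()
        data["condition"] = data["condition"].astype(int)
        if data.duplicated(["sample_id", "condition", "variable"]).any():
            raise ValueError("panel has duplicate sample x condition x variable records")
        if self.ROSTER is not None:
            extra = set(data["variable"]) - set(self.ROSTER)
            if extra:
                raise ValueError(f"unknown variables {sorted(extra)}")
        self.data = data

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].unique()

    @property
    def conditions(self) -> list[int]:
        return sorted(self.data["condition"].unique())

    @property
    def variables(self) -> list[str]:
        present = set(self.data["variable"])
        if self.ROSTER is not None:
            return [v for v in self.ROSTER if v in present]
        return sorted(present)

    def wide(self, conditions: Sequence[int] | None = None,
             suffix: bool = True) -> pd.DataFrame:
        """Samples x (variable x condition) wide table.

        Column order: conditions outer, roster order inner.  With
        ``suffix=False`` a single condition is required and bare variable
        names are used (needed when train/test columns must match across
        conditions).
        """
        conds = list(conditions) if conditions is not None else self.conditions
        if not suffix and len(conds) != 1:
            raise ValueError("bare column names require exactly one condition")
        sub = self.data[self.data["condition"].isin(conds)]
        wide = sub.pivot(index="sample_id", columns=["condition", "variable"],
                         values="value")
        cols = [(c, v) for c in conds for v in self.variables
                if (c, v) in wide.columns]
        wide = wide.loc[:, cols]
        wide.columns = [v if not suffix else col_label(v, c) for c, v in cols]
        return wide.loc[self.sample_ids[np.isin(self.sample_ids, wide.index)]]

    def restrict(self, sample_ids: Iterable) -> "_TidyPanel":
        keep = set(sample_ids)
        return type(self)(self.data[self.data["sample_id"].isin(keep)].reset_index(drop=True))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path):
        return cls(pd.read_csv(path))

    @classmethod
    def from_wide(cls, arrays: dict[tuple[str, int], np.ndarray],
                  sample_ids: Sequence) -> "_TidyPanel":
        """Build from {(variable, condition): values-aligned-to-sample_ids}."""
        rows = []
        for (var, cond), vals in arrays.items():
            rows.append(pd.DataFrame({
                "sample_id": list(sample_ids), "condition": cond,
                "variable": var, "value": np.asarray(vals, dtype=float)}))
        return cls(pd.concat(rows, ignore_index=True))


class PhenomicPanel(_TidyPanel):
    """Chlorophyll-fluorescence endophenotypes: 18 parameters per sample x condition."""

    ROSTER = CHLF_PARAMS


class TraitPanel(_TidyPanel):
    """Growth traits (LC, TH, TD) per sample x condition."""

    ROSTER = TRAITS
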