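"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are 0-based half-open; conversion (if any) happens
only at file boundaries.  PIR values are percentages in [0, 100]; missing
values are NaN and are skipped pairwise by all downstream arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRACTIONS = ("nucleus", "cytoplasm")
GENOTYPES = ("control", "mutant")


class ValidationError(ValueError):
    """An input violated a container invariant."""


@dataclass
class SampleSheet:
    """Design of a fractionated differentiation time course.

    One row per RNA-seq sample: which compartment it came from
    (nucleus/cytoplasm), the differentiation day (DIV), the genotype and
    the clone/patient it derives from.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "fraction", "div_day", "genotype", "clone_id", "patient_id")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad_frac = set(df["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValidationError(f"unknown fractions: {sorted(bad_frac)}")
        bad_gt = set(df["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValidationError(f"unknown genotypes: {sorted(bad_gt)}")
        if (df["div_day"].astype(int) < 0).any():
            raise ValidationError("div_day must be >= 0")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def div_days(self) -> list[int]:
        return sorted(self.table["div_day"].unique().tolist())

    def condition_key(self) -> pd.Series:
        """Condition label per sample: fraction / DIV / genotype."""
        t = self.table
        key = (
            t["fraction"].astype(str)
            + ":div"
            + t["div_day"].astype(int).astype(str)
            + ":"
            + t["genotype"].astype(str)
        )
        key.index = t["sample_id"]
        return key

    def subset(self, **criteria) -> "SampleSheet":
        mask = pd.Series(True, index=self.table.index)
        for col, value in criteria.items():
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= self.table[col].isin(list(value))
            else:
                mask &= self.table[col] == value
        return SampleSheet(self.table.loc[mask].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PIRMatrix:
    """Percent-intron-retention values, introns x samples, with the design attached."""

    values: pd.DataFrame  # index: intron ids, columns: sample ids, NaN = missing
    samples: SampleSheet

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate intron ids in PIR matrix")
        if list(v.columns) != self.samples.sample_ids:
            raise ValidationError(
                "PIR matrix columns do not match the sample sheet "
                f"({list(v.columns)[:3]}... vs {self.samples.sample_ids[:3]}...)"
            )
        arr = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 100)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"PIR value out of [0,100] at intron {v.index[i]!r}, "
                f"sample {v.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def intron_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_samples(self, **criteria) -> "PIRMatrix":
        sub = self.samples.subset(**criteria)
        return PIRMatrix(self.values[sub.sample_ids], sub)

    def condition_means(self) -> pd.DataFrame:
        """Mean PIR per intron per condition (fraction:divD:genotype), NaN-skipping."""
        key = self.samples.condition_key()
        return self.values.T.groupby(key.values).mean(numeric_only=True).T


@dataclass(frozen=True)
class IntronRecord:
    """One intron with its flanking-exon extents.

    ``upstream_exon_start`` / ``downstream_exon_end`` are the OUTER genomic
    boundaries of the exons immediately left/right of the intron (genomic
    orientation); the inner boundaries are the intron's own start/end.
    """

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    upstream_exon_start: int
    downstream_exon_end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"intron {self.intron_id}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"intron {self.intron_id}: bad strand {self.strand!r}")
        if self.upstream_exon_start > self.start:
            raise ValidationError(f"intron {self.intron_id}: upstream exon inconsistent")
        if self.downstream_exon_end < self.end:
            raise ValidationError(f"intron {self.intron_id}: downstream exon inconsistent")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def left_exon_length(self) -> int:
        return self.start - self.upstream_exon_start

    @property
    def right_exon_length(self) -> int:
        return self.downstream_exon_end - self.end


@dataclass
class CrosslinkTrack:
    """Single-nucleotide protein-RNA cross-link events for one RBP."""

    rbp_name: str
    positions: set  # of (chrom, pos0, strand)

    def __post_init__(self) -> None:
        for p in self.positions:
            if len(p) != 3 or p[2] not in ("+", "-"):
                raise ValidationError(f"bad cross-link event {p!r} in {self.rbp_name}")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class DETable:
    """Differential-expression results for one contrast: gene, log2FC, p."""

    table: pd.DataFrame  # columns gene_id, log2fc, p_value
    contrast_label: str

    def __post_init__(self) -> None:
        df = self.table
        for c in ("gene_id", "log2fc", "p_value"):
            if c not in df.columns:
                raise ValidationError(f"DE table missing column {c!r}")
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in DE table")
        p = df["p_value"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValidationError("p_value outside (0,1]")
        self.table = df.reset_index(drop=True)

    def log2fc_of(self, genes) -> pd.Series:
        s = self.table.set_index("gene_id")["log2fc"]
        return s.loc[[g for g in genes if g in s.index]]


@dataclass(frozen=True)
class TargetSet:
    """Predicted target genes of one miRNA (or any named gene set)."""

    set_name: str
    gene_ids: frozenset
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError(f"target set {self.set_name!r} is empty")

    def restricted_to(self, universe) -> "TargetSet":
        kept = frozenset(self.gene_ids) & frozenset(universe)
        if not kept:
            raise ValidationError(
                f"target set {self.set_name!r} has no genes in the declared universe"
            )
        return TargetSet(self.set_name, kept, self.is_control)
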