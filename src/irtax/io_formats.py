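"""Readers and writers for every on-disk format the pipeline touches.

TSV for PIR / sample-sheet / DE / feature tables, BED for introns and
cross-link events, GMT for miRNA target sets, FASTA for sequences and
bedGraph for per-base conservation.  All writers emit a deterministic
column order and a leading ``#`` comment with the tool version (and seed
where one applies); all readers skip ``#`` comment lines.

Missing PIR cells are the literal token ``NA`` on disk and NaN in memory —
never imputed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .types import (
    CrosslinkTrack,
    DETable,
    IntronRecord,
    PIRMatrix,
    SampleSheet,
    TargetSet,
    ValidationError,
)

NA_TOKEN = "NA"


class FormatError(ValueError):
    """A file did not conform to its declared format."""


def _header_comment(seed=None) -> str:
    tail = f" seed={seed}" if seed is not None else ""
    return f"# irtax {__version__}{tail}\n"


# ---------------------------------------------------------------------------
# sample sheet


def write_sample_sheet(sheet: SampleSheet, path, seed=None) -> None:
    cols = list(SampleSheet.REQUIRED)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        sheet.table[cols].to_csv(fh, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "clone_id": str, "patient_id": str})
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# PIR matrix


def write_pir_table(pir: PIRMatrix, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        out = pir.values.round(6)
        out.index.name = "intron_id"
        out.to_csv(fh, sep="\t", na_rep=NA_TOKEN, float_format="%.6f")


def read_pir_table(path, samples: SampleSheet) -> PIRMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in set(samples.sample_ids)]
    if unknown:
        raise FormatError(f"PIR table has sample ids not in the sample sheet: {unknown}")
    missing = [s for s in samples.sample_ids if s not in set(df.columns)]
    if missing:
        raise FormatError(f"PIR table lacks samples declared in the sheet: {missing}")
    df = df[samples.sample_ids]
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric PIR cell at intron {bad.index[0]!r}, sample {col!r}: {bad.iloc[0]!r}"
            )
    arr = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 100)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"PIR value out of [0,100] at intron {df.index[i]!r}, sample {df.columns[j]!r}: {arr[i, j]}"
        )
    return PIRMatrix(df.astype(float), samples)


# ---------------------------------------------------------------------------
# BED: cross-link events and introns


def read_crosslink_bed(path, rbp_name: str) -> CrosslinkTrack:
    """Each BED interval contributes its start position as one 1-nt event.

    Duplicated (chrom, start, strand) triples collapse to a single event.
    """
    positions = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: BED line with <3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(f"{path}:{ln}: interval end <= start ({start},{end})")
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: bad strand {strand!r}")
            positions.add((chrom, start, strand))
    return CrosslinkTrack(rbp_name, positions)


def write_crosslink_bed(track: CrosslinkTrack, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for chrom, pos, strand in sorted(track.positions):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{track.rbp_name}\t0\t{strand}\n")


def write_intron_bed(introns, path, seed=None) -> None:
    """BED6 + gene_id, upstream_exon_start, downstream_exon_end."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for iv in introns:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.intron_id}\t0\t{iv.strand}"
                f"\t{iv.gene_id}\t{iv.upstream_exon_start}\t{iv.downstream_exon_end}\n"
            )


def read_intron_bed(path) -> list:
    introns = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{ln}: intron BED needs 9 fields, got {len(f)}")
            try:
                rec = IntronRecord(
                    intron_id=f[3],
                    gene_id=f[6],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    upstream_exon_start=int(f[7]),
                    downstream_exon_end=int(f[8]),
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            introns.append(rec)
    return introns


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> list:
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{ln}: GMT line with <3 fields")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{ln}: empty gene set {name!r}")
            sets.append(TargetSet(name, genes, is_control=desc.strip().lower() == "control"))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for ts in sets:
            desc = "control" if ts.is_control else "."
            genes = "\t".join(sorted(ts.gene_ids))
            fh.write(f"{ts.set_name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# DE tables


def write_de_table(de: DETable, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        out = de.table[["gene_id", "log2fc", "p_value"]].copy()
        out["contrast"] = de.contrast_label
        out.to_csv(fh, sep="\t", index=False)


def read_de_table(path) -> DETable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if "contrast" not in df.columns:
        raise FormatError("DE table lacks a 'contrast' column")
    labels = df["contrast"].unique()
    if len(labels) != 1:
        raise FormatError(f"DE table mixes contrasts: {labels.tolist()}")
    return DETable(df[["gene_id", "log2fc", "p_value"]], str(labels[0]))


# ---------------------------------------------------------------------------
# FASTA and bedGraph


def write_fasta(sequences: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    sequences = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_bedgraph(intervals, path, seed=None) -> None:
    """intervals: iterable of (chrom, start, end, score)."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for chrom, start, end, score in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{score:.6g}\n")


def read_bedgraph(path) -> list:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{ln}: bedGraph line with <4 fields")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise FormatError(f"{path}:{ln}: interval end <= start")
            out.append((f[0], start, end, float(f[3])))
    return out
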