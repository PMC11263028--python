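"""Readers and writers for the plain-text formats shared across the pipeline.

Conventions
-----------
* FASTA via Biopython ``SeqIO``.
* GFF3 is 1-based inclusive on disk and converted to 0-based half-open
  coordinates on read (and back on write).
* BED-like junction tables are 0-based half-open:
  ``chrom  start  end  circ_id  strand``.
* Count matrices are TSV with the feature id in the first column and one
  integer column per sample.
* Mixed RNA/DNA alphabets are normalized once at ingestion (``U`` <-> ``T``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("circsponge")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


# ---------------------------------------------------------------------------
# sequence alphabet helpers


def normalize_dna(seq: str) -> str:
    """Uppercase and coerce to the DNA alphabet (U -> T)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def normalize_rna(seq: str) -> str:
    """Uppercase and coerce to the RNA alphabet (T -> U)."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def revcomp_dna(seq: str) -> str:
    return normalize_dna(seq).translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return normalize_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3 (genes only)


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse gene records from a GFF3 file.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand``
    where ``start``/``end`` are 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            start_i, end_i = int(start), int(end)
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{path}:{lineno}: bad coordinates {start}..{end}")
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene record without ID attribute")
            rows.append((gene_id, chrom, start_i - 1, end_i, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_gff3(path: str | Path, genes: pd.DataFrame) -> None:
    """Write gene records (internal 0-based half-open) as 1-based inclusive GFF3."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tcircsponge\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED-like circRNA junction table


BED_COLUMNS = ["chrom", "start", "end", "circ_id", "strand"]


def read_bedlike(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, dtype={"chrom": str})
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end at data line {bad[0] + 1}")
    return df


def write_bedlike(path: str | Path, df: pd.DataFrame) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# matrices and maps


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample integer count TSV; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not pd.api.types.is_integer_dtype(df[col]):
            frac = df[col] % 1 != 0
            if frac.any():
                raise ValueError(
                    f"{path}: non-integer count for feature "
                    f"{df.index[frac.argmax()]!r} in column {col!r}"
                )
            df[col] = df[col].astype(int)
        neg = df[col] < 0
        if neg.any():
            raise ValueError(
                f"{path}: negative count for feature {df.index[neg.argmax()]!r} in column {col!r}"
            )
    return df


def write_matrix(path: str | Path, df: pd.DataFrame, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>group`` TSV (with header) into an ordered dict."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns 'sample' and 'group'")
    sample_col, group_col = df.columns[:2]
    dup = df[sample_col].duplicated()
    if dup.any():
        raise ValueError(f"{path}: sample {df[sample_col][dup.argmax()]!r} mapped twice")
    return dict(zip(df[sample_col].astype(str), df[group_col].astype(str)))


def write_group_map(path: str | Path, groups: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"sample": list(groups.keys()), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene -> term annotation TSV with columns gene_id, term_id[, term_name]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "term_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation table needs columns {sorted(required)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df[["gene_id", "term_id", "term_name"]]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table with at least id, log2fc, status columns."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "id"})
    required = {"id", "log2fc", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    return df
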