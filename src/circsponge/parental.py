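"""Parental-gene assignment for circRNAs by the both-ends rule.

A gene is the parental gene of a circRNA when both ends of the back-splice
junction fall within that single gene.  Two modes are provided:

* ``coordinate`` — both junction coordinates lie inside the gene span and
  strands match (unless relaxed).
* ``anchor`` — the two anchor_len-mers flanking the junction (upstream of the
  donor, downstream of the acceptor) are located by sequence search, exact or
  with at most one mismatch, inside the same gene's genomic span.

Ties between overlapping candidate genes are broken by largest base-pair
overlap, then lexicographic gene id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .quantify import CircRecord


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    utr3_seq: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")


@dataclass(frozen=True)
class ParentalAssignment:
    circ_id: str
    gene_id: str | None
    mode: str
    overlap_bp: int


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    return [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def _overlap(circ: CircRecord, gene: GeneModel) -> int:
    return max(0, min(circ.end, gene.end) - max(circ.start, gene.start))


def _find_with_mismatches(haystack: str, needle: str, max_mismatches: int) -> bool:
    if needle in haystack:
        return True
    if max_mismatches <= 0:
        return False
    n, m = len(haystack), len(needle)
    for o in range(n - m + 1):
        mism = 0
        for a, b in zip(haystack[o : o + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        if mism <= max_mismatches:
            return True
    return False


def _coordinate_hit(circ: CircRecord, gene: GeneModel, require_strand: bool) -> bool:
    if circ.chrom != gene.chrom:
        return False
    if require_strand and circ.strand != gene.strand:
        return False
    return gene.start <= circ.start < gene.end and gene.start <= circ.end - 1 < gene.end


def _anchor_hit(
    circ: CircRecord,
    gene: GeneModel,
    genome: Mapping[str, str],
    anchor_len: int,
    max_mismatches: int,
    require_strand: bool,
) -> bool:
    if circ.chrom != gene.chrom:
        return False
    if require_strand and circ.strand != gene.strand:
        return False
    chrom_seq = genome[circ.chrom]
    donor_anchor = chrom_seq[circ.end - anchor_len : circ.end]
    acceptor_anchor = chrom_seq[circ.start : circ.start + anchor_len]
    if len(donor_anchor) < anchor_len or len(acceptor_anchor) < anchor_len:
        return False
    gene_seq = chrom_seq[gene.start : gene.end]
    return _find_with_mismatches(gene_seq, donor_anchor, max_mismatches) and _find_with_mismatches(
        gene_seq, acceptor_anchor, max_mismatches
    )


def assign_parental(
    circs: Sequence[CircRecord],
    genes: Sequence[GeneModel],
    mode: str = "coordinate",
    anchor_len: int = 20,
    genome: Mapping[str, str] | None = None,
    max_mismatches: int = 1,
    require_strand: bool = True,
) -> list[ParentalAssignment]:
    """Assign each circRNA to its parental gene, or to none.

    A circRNA whose two junction ends fall in different genes (or outside any
    gene) is left unassigned: the both-ends rule requires a single gene.
    """
    if mode not in {"coordinate", "anchor"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "anchor":
        if genome is None:
            raise ValueError("anchor mode requires the genome sequences")
        if anchor_len < 15:
            raise ValueError("anchor_len must be >= 15 in anchor mode")
    known_chroms = {g.chrom for g in genes}
    if genome is not None:
        known_chroms |= set(genome)
    out = []
    for circ in circs:
        if circ.chrom not in known_chroms:
            raise KeyError(f"{circ.circ_id}: unknown chromosome {circ.chrom!r}")
        candidates = []
        for gene in genes:
            if mode == "coordinate":
                hit = _coordinate_hit(circ, gene, require_strand)
            else:
                hit = _anchor_hit(circ, gene, genome, anchor_len, max_mismatches, require_strand)
            if hit:
                candidates.append((-_overlap(circ, gene), gene.gene_id))
        if candidates:
            candidates.sort()
            neg_overlap, gene_id = candidates[0]
            out.append(ParentalAssignment(circ.circ_id, gene_id, mode, -neg_overlap))
        else:
            out.append(ParentalAssignment(circ.circ_id, None, mode, 0))
    return out


def assignments_frame(assignments: Sequence[ParentalAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.circ_id, a.gene_id if a.gene_id is not None else "", a.mode, a.overlap_bp) for a in assignments],
        columns=["circ_id", "gene_id", "mode", "overlap_bp"],
    )


def parental_term_table(
    assignments: Sequence[ParentalAssignment], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Join assigned parental genes against a gene -> term annotation table.

    Genes without terms pass through with an empty term_id/term_name.
    """
    rows = []
    by_gene = annotation.groupby("gene_id") if len(annotation) else None
    for a in assignments:
        if a.gene_id is None:
            continue
        if by_gene is not None and a.gene_id in by_gene.groups:
            for r in by_gene.get_group(a.gene_id).itertuples(index=False):
                rows.append((a.circ_id, a.gene_id, r.term_id, r.term_name))
        else:
            rows.append((a.circ_id, a.gene_id, "", ""))
    return pd.DataFrame(rows, columns=["circ_id", "gene_id", "term_id", "term_name"])
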