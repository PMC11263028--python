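"""Tripartite ceRNA (circRNA - miRNA - mRNA) network assembly and sub-networks.

Nodes are restricted to differentially expressed features; edges are
restricted to target hits that passed all three predictors.  The graph is a
directed ``networkx`` graph with ``kind`` in {circRNA, miRNA, mRNA} on every
node, circRNA -> miRNA and miRNA -> mRNA edges only, and optional pathway
labels on mRNA nodes for pathway-restricted sub-network extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

NODE_KINDS = ("circRNA", "miRNA", "mRNA")


@dataclass(frozen=True)
class Axis:
    """One circRNA / miRNA / mRNA regulatory axis (both edges in the graph)."""

    circ_id: str
    mirna_id: str
    mrna_id: str


def _de_map(de_table: pd.DataFrame) -> dict[str, float]:
    """id -> log2fc for rows called differential (status != ns)."""
    de = de_table[de_table["status"] != "ns"]
    return dict(zip(de["id"].astype(str), de["log2fc"].astype(float)))


def build_cerna(
    circ_hits: pd.DataFrame,
    mrna_hits: pd.DataFrame,
    de_circ: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    require_anticorrelation: bool = False,
    pathway_labels: Mapping[str, Sequence[str]] | None = None,
) -> nx.DiGraph:
    """Assemble the DEcircRNA -> DEmiRNA -> DEmRNA graph from pass_all hits.

    ``de_*`` tables need columns ``id, log2fc, status``.  With
    ``require_anticorrelation`` an edge is kept only when its endpoints have
    opposite log2FC signs (the ceRNA expectation).  miRNAs left without any
    partner are dropped.
    """
    circ_lfc = _de_map(de_circ)
    mirna_lfc = _de_map(de_mirna)
    mrna_lfc = _de_map(de_mrna)
    collisions = (set(circ_lfc) & set(mirna_lfc)) | (set(mirna_lfc) & set(mrna_lfc)) | (
        set(circ_lfc) & set(mrna_lfc)
    )
    if collisions:
        raise ValueError(f"id collision across node types: {sorted(collisions)[:5]}")

    g = nx.DiGraph()

    def _edges(hits: pd.DataFrame, src_lfc: dict, dst_lfc: dict, circ_side: bool):
        if hits.empty:
            return
        passed = hits[hits["pass_all"]]
        for r in passed.itertuples(index=False):
            if circ_side:
                src, dst = str(r.target_id), str(r.mirna_id)  # circRNA sponges the miRNA
            else:
                src, dst = str(r.mirna_id), str(r.target_id)
            src_l = src_lfc.get(src)
            dst_l = dst_lfc.get(dst)
            if src_l is None or dst_l is None:
                continue
            if require_anticorrelation and src_l * dst_l >= 0:
                continue
            kinds = ("circRNA", "miRNA") if circ_side else ("miRNA", "mRNA")
            g.add_node(src, kind=kinds[0], log2fc=src_l)
            g.add_node(dst, kind=kinds[1], log2fc=dst_l)
            g.add_edge(
                src,
                dst,
                align_score=float(r.align_score),
                duplex_dg=float(r.duplex_dg),
                allen_score=float(r.allen_score),
            )

    _edges(circ_hits, circ_lfc, mirna_lfc, circ_side=True)
    _edges(mrna_hits, mirna_lfc, mrna_lfc, circ_side=False)

    # drop miRNAs with no surviving partner on either side
    for n in [n for n, d in g.nodes(data=True) if d["kind"] == "miRNA" and g.degree(n) == 0]:
        g.remove_node(n)

    if pathway_labels:
        for node, data in g.nodes(data=True):
            if data["kind"] == "mRNA":
                g.nodes[node]["terms"] = tuple(pathway_labels.get(node, ()))
    validate_graph(g)
    return g


def validate_graph(g: nx.DiGraph) -> None:
    """Assert strict tripartiteness: circRNA->miRNA and miRNA->mRNA edges only."""
    for n, d in g.nodes(data=True):
        if d.get("kind") not in NODE_KINDS:
            raise ValueError(f"node {n!r} has no valid kind")
    for u, v in g.edges():
        ku, kv = g.nodes[u]["kind"], g.nodes[v]["kind"]
        if (ku, kv) not in {("circRNA", "miRNA"), ("miRNA", "mRNA")}:
            raise ValueError(f"forbidden edge {u!r}({ku}) -> {v!r}({kv})")


def mirna_centric_subnetwork(g: nx.DiGraph, mirna_id: str) -> nx.DiGraph:
    """Induced subgraph of one miRNA, its circRNA sponges and its mRNA targets."""
    if mirna_id not in g:
        raise KeyError(f"unknown miRNA {mirna_id!r}")
    if g.nodes[mirna_id]["kind"] != "miRNA":
        raise KeyError(f"{mirna_id!r} is not a miRNA node")
    nodes = {mirna_id} | set(g.predecessors(mirna_id)) | set(g.successors(mirna_id))
    return g.subgraph(nodes).copy()


def pathway_subnetwork(g: nx.DiGraph, terms: Sequence[str]) -> nx.DiGraph:
    """Restrict to mRNAs annotated to any listed term, then prune upstream.

    Keeps annotated mRNAs, then miRNAs with >= 1 surviving mRNA edge, then
    circRNAs with >= 1 surviving miRNA edge.
    """
    term_set = set(terms)
    mrnas = {
        n
        for n, d in g.nodes(data=True)
        if d["kind"] == "mRNA" and term_set & set(d.get("terms", ()))
    }
    mirnas = {n for n in g for s in g.successors(n) if g.nodes[n]["kind"] == "miRNA" and s in mrnas}
    circs = {n for n in g for s in g.successors(n) if g.nodes[n]["kind"] == "circRNA" and s in mirnas}
    sub = g.subgraph(mrnas | mirnas | circs).copy()
    # remove edges into non-kept mRNAs / miRNAs are gone with subgraph already
    return sub


def enumerate_axes(g: nx.DiGraph) -> list[Axis]:
    """All (circRNA, miRNA, mRNA) triples with both edges present."""
    axes = []
    for mi, d in g.nodes(data=True):
        if d["kind"] != "miRNA":
            continue
        circs = sorted(p for p in g.predecessors(mi) if g.nodes[p]["kind"] == "circRNA")
        mrnas = sorted(s for s in g.successors(mi) if g.nodes[s]["kind"] == "mRNA")
        for c in circs:
            for m in mrnas:
                axes.append(Axis(c, mi, m))
    return axes


# ---------------------------------------------------------------------------
# export


def edge_list(g: nx.DiGraph) -> pd.DataFrame:
    rows = [
        (
            u,
            g.nodes[u]["kind"],
            v,
            g.nodes[v]["kind"],
            d.get("align_score", float("nan")),
            d.get("duplex_dg", float("nan")),
            d.get("allen_score", float("nan")),
        )
        for u, v, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(
        rows,
        columns=["source", "source_type", "sink", "sink_type", "align_score", "duplex_dg", "allen_score"],
    )


def write_edge_list(path, g: nx.DiGraph) -> None:
    edge_list(g).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edge_list(path, de_lfc: Mapping[str, float] | None = None) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for r in df.itertuples(index=False):
        g.add_node(r.source, kind=r.source_type)
        g.add_node(r.sink, kind=r.sink_type)
        g.add_edge(
            r.source,
            r.sink,
            align_score=float(r.align_score),
            duplex_dg=float(r.duplex_dg),
            allen_score=float(r.allen_score),
        )
    if de_lfc:
        for n in g:
            if n in de_lfc:
                g.nodes[n]["log2fc"] = de_lfc[n]
    return g


def write_graphml(path, g: nx.DiGraph) -> None:
    h = g.copy()
    for _n, d in h.nodes(data=True):
        if "terms" in d:
            d["terms"] = ",".join(d["terms"])
    nx.write_graphml(h, path)


def axes_frame(axes: Iterable[Axis]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.circ_id, a.mirna_id, a.mrna_id) for a in axes],
        columns=["circ_id", "mirna_id", "mrna_id"],
    )
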