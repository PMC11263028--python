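"""Synthetic data generator with known ground truth.

Emulates the data structure of a three-timepoint larval-gut development
study: three groups x three biological replicates of back-splice junction
counts (negative-binomial, low mean, overdispersed), a single synthetic
chromosome carrying non-overlapping genes, circRNAs nested inside genes,
miRNAs, 3'UTRs, a planted fraction of differential circRNAs (including
presence/absence dropouts that produce extreme |log2FC| under a pseudocount
policy), planted miRNA response elements (MREs) creating true
circRNA-miRNA-mRNA axes, a hub miRNA sponged by many circRNAs, pathway
labels over genes, and qPCR / luciferase validation tables.

Everything is driven by one integer seed; the same configuration and seed
produce a byte-identical file bundle.  Unplanned occurrences of any miRNA
seed complement are deterministically scrubbed from the genome (and across
back-splice seams) so that planted MRE counts are exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .quantify import CircRecord

_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic dataset (defaults = the
    conditions the generator is meant to emulate; see docs/methods.md)."""

    seed: int = 1
    n_genes: int = 100
    n_circ: int = 150
    n_mirna: int = 12
    n_groups: int = 3
    reps_per_group: int = 3
    mean_count: float = 10.0  # mean junction reads per circRNA per sample
    dispersion: float = 20.0  # negative-binomial size parameter
    frac_de: float = 0.2
    planted_log2fc: float = 3.0
    frac_dropout: float = 0.1  # fraction of DE circRNAs absent in one group
    n_true_axes: int = 10
    hub_mirna_fanin: int = 15  # circRNAs carrying the hub miRNA's MRE
    hub_mirna_fanout: int = 20  # mRNA 3'UTRs carrying the hub miRNA's MRE
    mre_mismatches: int = 0
    utr_len: int = 250
    pathway_sizes: tuple[int, ...] = (15, 15, 10, 10, 8, 8)
    mirna_len: int = 22
    junction_half: int = 30  # k: junction-spanning sequence is 2k nt
    gene_len: int = 1200
    intergenic: int = 150
    minus_strand_genes: bool = False

    def __post_init__(self) -> None:
        positive = [
            "n_genes", "n_circ", "n_mirna", "reps_per_group", "mean_count",
            "dispersion", "utr_len", "mirna_len", "junction_half", "gene_len",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ["frac_de", "frac_dropout"]:
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.mre_mismatches >= 8:
            raise ValueError("mre_mismatches must be < 8")
        n_special_circ = self.hub_mirna_fanin + self.n_true_axes
        if n_special_circ > self.n_circ:
            raise ValueError("hub_mirna_fanin + n_true_axes exceeds n_circ")
        if self.n_true_axes > 0 and self.n_mirna < 2:
            raise ValueError("planting axes requires n_mirna >= 2 (hub + axis miRNAs)")
        if n_special_circ + self.n_true_axes + self.hub_mirna_fanout > self.n_genes:
            raise ValueError("not enough genes to host planted circRNAs and MRE-bearing UTRs")
        if self.gene_len < self.utr_len + 320:
            raise ValueError("gene_len too short to host a circRNA outside the 3'UTR")

    @property
    def group_names(self) -> list[str]:
        if self.n_groups == 3:
            return ["Ac4", "Ac5", "Ac6"]
        return [f"g{i + 1}" for i in range(self.n_groups)]


@dataclass
class GroundTruth:
    """Planted truth of one generated dataset."""

    comparisons: list[str]
    de_circ_ids: dict  # comparison -> {circ_id: "up"|"down"}
    dropout_circ_ids: dict  # comparison -> [circ_id]
    true_axes: list  # [(circ_id, mirna_id, gene_id)]
    hub_mirna_id: str
    hub_circ_ids: list
    hub_mrna_ids: list
    pathway_assignment: dict  # gene_id -> [term_id]
    parental_gene: dict  # circ_id -> host gene_id
    mre_sites: list  # [(target_kind, target_id, mirna_id, offset, length)]
    group_of: dict  # sample -> group

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)


@dataclass
class SynthData:
    """In-memory bundle returned by :func:`build`."""

    config: SynthConfig
    genome: dict  # chrom -> sequence (DNA)
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand (0-based half-open)
    circs: list  # CircRecord (junction_seq in DNA alphabet)
    mirnas: list  # (mirna_id, RNA sequence)
    utrs: list  # (gene_id, DNA sequence)
    counts: pd.DataFrame
    group_of: dict
    annotation: pd.DataFrame  # gene_id, term_id, term_name
    mirna_de: pd.DataFrame  # id, log2fc, status
    mrna_de: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# MRE planting


def _site_string(mirna_rna: str, mismatches: int, rng: np.random.Generator, dna: bool) -> str:
    """Reverse complement of the miRNA with ``mismatches`` mutations outside
    the seed-pairing region (site positions pairing miRNA bases 2-8)."""
    site = list(io.revcomp_rna(mirna_rna))
    L = len(site)
    protected = set(range(L - 8, L - 1))  # pairs miRNA bases 2..8
    eligible = [i for i in range(L) if i not in protected]
    if mismatches > len(eligible):
        raise ValueError("too many mismatches requested")
    if mismatches:
        pos = rng.choice(len(eligible), size=mismatches, replace=False)
        for p in sorted(int(i) for i in pos):
            i = eligible[p]
            alternatives = [b for b in "ACGU" if b != site[i]]
            site[i] = alternatives[int(rng.integers(len(alternatives)))]
    s = "".join(site)
    return io.normalize_dna(s) if dna else s


def plant_mre(
    sequence: str, mirna: str, position: int, mismatches: int = 0, seed: int = 0
) -> str:
    """Plant a miRNA response element into ``sequence`` at ``position``.

    The planted window is the reverse complement of the miRNA (in the
    sequence's own alphabet); the positions pairing miRNA bases 2-8 are kept
    exactly complementary and any requested mismatches fall outside that
    seed-pairing region.  Deterministic for a fixed ``seed``.
    """
    mirna_rna = io.normalize_rna(mirna)
    if position < 0 or position + len(mirna_rna) > len(sequence):
        raise ValueError("planting window out of range")
    dna = "U" not in sequence.upper()
    rng = np.random.default_rng(seed)
    site = _site_string(mirna_rna, mismatches, rng, dna)
    return sequence[:position] + site + sequence[position + len(site) :]


# ---------------------------------------------------------------------------
# internals


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _DNA[rng.integers(0, 4, size=n)]


def _seed_pattern_dna(mirna_rna: str) -> str:
    """DNA reverse complement of the miRNA seed (positions 2-8)."""
    return io.revcomp_dna(io.normalize_dna(mirna_rna[1:8]))


def _generate_mirnas(cfg: SynthConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Random miRNAs whose seed patterns are mutually non-interfering: no
    miRNA's seed complement occurs inside any planted site of another."""
    accepted: list[str] = []
    guard = 0
    while len(accepted) < cfg.n_mirna:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("could not generate non-interfering miRNAs")
        cand = "".join(_random_seq(rng, cfg.mirna_len)).replace("T", "U")
        pool = accepted + [cand]
        sites = [io.revcomp_dna(io.normalize_dna(m)) for m in pool]
        patterns = [_seed_pattern_dna(m) for m in pool]
        ok = len(set(patterns)) == len(pool)
        if ok:
            for i, pat in enumerate(patterns):
                for j, site in enumerate(sites):
                    n_occ = site.count(pat)
                    expected = 1 if i == j else 0
                    if n_occ != expected:
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            accepted.append(cand)
    return [(f"mir_{i + 1:03d}", seq) for i, seq in enumerate(accepted)]


def _scrub_genome(
    genome: np.ndarray,
    patterns: list[str],
    protected: list[tuple[int, int]],
    circ_coords: list[tuple[int, int]],
    k: int,
) -> None:
    """Deterministically mutate unplanned seed-complement occurrences, both in
    the linear genome and across every back-splice seam."""

    def is_protected(a: int, b: int) -> bool:
        return any(a < pe and b > ps for ps, pe in protected)

    def break_occurrence(genomic_positions: list[int]) -> bool:
        for gp in genomic_positions:
            if not is_protected(gp, gp + 1):
                base = genome[gp]
                genome[gp] = {"A": "C", "C": "G", "G": "T", "T": "A"}[str(base)]
                return True
        return False

    for _round in range(25):
        dirty = False
        text = "".join(genome)
        for pat in patterns:
            start = 0
            while True:
                s = text.find(pat, start)
                if s < 0:
                    break
                start = s + 1
                if is_protected(s, s + len(pat)):
                    continue
                if break_occurrence([s + 3, s + 2, s + 4, s + 1, s + 5, s, s + 6]):
                    dirty = True
                    text = "".join(genome)
        # seam-spanning occurrences in junction sequences
        for cs, ce in circ_coords:
            junction = text[ce - k : ce] + text[cs : cs + k]
            for pat in patterns:
                start = 0
                while True:
                    q = junction.find(pat, start)
                    if q < 0:
                        break
                    start = q + 1
                    if not (q < k < q + len(pat)):
                        continue  # fully within one half: the linear scan owns it
                    genomic = [
                        (ce - k + qq) if qq < k else (cs + qq - k)
                        for qq in range(q, q + len(pat))
                    ]
                    mid = len(genomic) // 2
                    order = sorted(range(len(genomic)), key=lambda t: abs(t - mid))
                    if break_occurrence([genomic[t] for t in order]):
                        dirty = True
                        text = "".join(genome)
                        junction = text[ce - k : ce] + text[cs : cs + k]
        if not dirty:
            return
    raise RuntimeError("seed-complement scrubbing did not converge")


# ---------------------------------------------------------------------------
# main builder


def build(config: SynthConfig) -> SynthData:
    """Generate the full in-memory dataset with ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    k = cfg.junction_half
    L = cfg.mirna_len

    # genes on one synthetic chromosome
    stride = cfg.gene_len + cfg.intergenic
    genome = _random_seq(rng, cfg.n_genes * stride + cfg.intergenic)
    n_special_circ = cfg.hub_mirna_fanin + cfg.n_true_axes
    gene_rows = []
    for i in range(cfg.n_genes):
        start = cfg.intergenic + i * stride
        strand = "+"
        if cfg.minus_strand_genes and i >= n_special_circ and i % 2 == 1:
            strand = "-"
        gene_rows.append((f"gene_{i + 1:04d}", chrom, start, start + cfg.gene_len, strand))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    # circRNAs nested inside genes, clear of the 3'UTR
    host = np.empty(cfg.n_circ, dtype=int)
    host[:n_special_circ] = np.arange(n_special_circ)
    host[n_special_circ:] = rng.integers(0, cfg.n_genes, size=cfg.n_circ - n_special_circ)
    circ_coords = []
    for i in range(cfg.n_circ):
        g = genes.iloc[int(host[i])]
        lo, hi = int(g.start), int(g.end) - cfg.utr_len
        length = int(rng.integers(300, min(800, hi - lo - 10)))
        cstart = int(rng.integers(lo, hi - length))
        circ_coords.append((cstart, cstart + length))

    # miRNAs (hub first) and MRE planting plan
    mirnas = _generate_mirnas(cfg, rng)
    hub_id = mirnas[0][0]
    axis_mirna_ids = []
    if cfg.n_true_axes:
        others = mirnas[1:]
        axis_mirna_ids = [others[i % len(others)][0] for i in range(cfg.n_true_axes)]
    mirna_seq = dict(mirnas)

    hub_circ_idx = list(range(cfg.hub_mirna_fanin))
    axis_circ_idx = list(range(cfg.hub_mirna_fanin, n_special_circ))
    axis_gene_idx = list(range(n_special_circ, n_special_circ + cfg.n_true_axes))
    hub_gene_idx = list(
        range(n_special_circ + cfg.n_true_axes, n_special_circ + cfg.n_true_axes + cfg.hub_mirna_fanout)
    )

    circ_ids = [f"circ_{i + 1:04d}" for i in range(cfg.n_circ)]
    gene_ids = list(genes["gene_id"])

    protected: list[tuple[int, int]] = []
    mre_sites: list[tuple[str, str, str, int, int]] = []

    def plant_junction(circ_i: int, mirna_id: str) -> None:
        cstart, cend = circ_coords[circ_i]
        site = _site_string(mirna_seq[mirna_id], cfg.mre_mismatches, rng, dna=True)
        p = k - L // 2  # site spans the back-splice seam
        for q, base in enumerate(site, start=p):
            gp = (cend - k + q) if q < k else (cstart + q - k)
            genome[gp] = base
            protected.append((gp, gp + 1))
        mre_sites.append(("circRNA", circ_ids[circ_i], mirna_id, p, L))

    def plant_utr(gene_i: int, mirna_id: str) -> None:
        g = genes.iloc[gene_i]
        site = _site_string(mirna_seq[mirna_id], cfg.mre_mismatches, rng, dna=True)
        utr_start = int(g.end) - cfg.utr_len
        p = (cfg.utr_len - L) // 2
        genome[utr_start + p : utr_start + p + L] = list(site)
        protected.append((utr_start + p, utr_start + p + L))
        mre_sites.append(("mRNA", gene_ids[gene_i], mirna_id, p, L))

    for ci in hub_circ_idx:
        plant_junction(ci, hub_id)
    true_axes = []
    for a in range(cfg.n_true_axes):
        plant_junction(axis_circ_idx[a], axis_mirna_ids[a])
        plant_utr(axis_gene_idx[a], axis_mirna_ids[a])
        true_axes.append((circ_ids[axis_circ_idx[a]], axis_mirna_ids[a], gene_ids[axis_gene_idx[a]]))
    for gi in hub_gene_idx:
        plant_utr(gi, hub_id)

    # remove unplanned seed complements so planted MRE counts are exact
    patterns = [_seed_pattern_dna(seq) for _mid, seq in mirnas]
    _scrub_genome(genome, patterns, protected, circ_coords, k)
    genome_str = "".join(genome)

    circs = []
    for i, (cstart, cend) in enumerate(circ_coords):
        g = genes.iloc[int(host[i])]
        junction = genome_str[cend - k : cend] + genome_str[cstart : cstart + k]
        if g.strand == "-":
            junction = io.revcomp_dna(junction)
        circs.append(CircRecord(circ_ids[i], chrom, cstart, cend, str(g.strand), junction))
    utrs = [
        (gene_ids[i], genome_str[int(genes.iloc[i].end) - cfg.utr_len : int(genes.iloc[i].end)])
        for i in range(cfg.n_genes)
    ]

    # planted differential expression over consecutive comparisons
    group_names = cfg.group_names
    comparisons = [f"{group_names[c]}_vs_{group_names[c + 1]}" for c in range(cfg.n_groups - 1)]
    n_de = int(round(cfg.frac_de * cfg.n_circ))
    de_circ_ids: dict[str, dict[str, str]] = {}
    dropout_ids: dict[str, list[str]] = {}
    mult = np.ones((cfg.n_circ, cfg.n_groups))
    chosen_per_comp: list[list[int]] = []
    for c, comp in enumerate(comparisons):
        if n_de == 0:
            chosen: list[int] = []
        elif c == 0:
            special = list(range(min(n_special_circ, n_de)))
            pool = [i for i in range(cfg.n_circ) if i not in set(special)]
            fill = rng.choice(len(pool), size=n_de - len(special), replace=False)
            chosen = special + sorted(pool[int(f)] for f in fill)
        else:
            chosen = sorted(int(i) for i in rng.choice(cfg.n_circ, size=n_de, replace=False))
        chosen_per_comp.append(chosen)
        # balanced up/down so per-group library sizes stay depth-matched:
        # "up" boosts the later groups, "down" boosts the earlier groups
        half = len(chosen) // 2
        directions = np.array(["up"] * (len(chosen) - half) + ["down"] * half)
        directions = directions[rng.permutation(len(directions))]
        de_circ_ids[comp] = {circ_ids[i]: str(d) for i, d in zip(chosen, directions)}
        boost = 2.0 ** cfg.planted_log2fc
        for i, d in zip(chosen, directions):
            if d == "up":
                mult[i, c + 1 :] *= boost
            else:
                mult[i, : c + 1] *= boost
    for c, comp in enumerate(comparisons):
        others = set().union(*(set(chosen_per_comp[cc]) for cc in range(len(comparisons)) if cc != c)) if len(
            comparisons
        ) > 1 else set()
        candidates = [i for i in chosen_per_comp[c] if i not in others]
        n_drop = int(round(cfg.frac_dropout * len(chosen_per_comp[c])))
        n_drop = min(n_drop, len(candidates))
        picked = sorted(
            candidates[int(t)] for t in rng.choice(len(candidates), size=n_drop, replace=False)
        ) if n_drop else []
        dropout_ids[comp] = [circ_ids[i] for i in picked]
        for i in picked:
            if de_circ_ids[comp][circ_ids[i]] == "up":
                mult[i, : c + 1] = 0.0  # absent before the step up
            else:
                mult[i, c + 1 :] = 0.0  # absent after the step down

    samples = [f"{g}-{r + 1}" for g in group_names for r in range(cfg.reps_per_group)]
    group_of = {s: s.rsplit("-", 1)[0] for s in samples}
    mu = np.repeat(mult * cfg.mean_count, cfg.reps_per_group, axis=1)
    p_nb = cfg.dispersion / (cfg.dispersion + mu)
    counts = rng.negative_binomial(cfg.dispersion, p_nb)
    counts_df = pd.DataFrame(counts, index=pd.Index(circ_ids, name="circ_id"), columns=samples)

    # pathway labels over genes; MRE-bearing mRNA genes are annotated first
    special_genes = [gene_ids[i] for i in axis_gene_idx + hub_gene_idx]
    ann_rows = []
    pathway_assignment: dict[str, list[str]] = {}
    for t, size in enumerate(cfg.pathway_sizes):
        term_id = f"term_{t + 1:03d}"
        term_name = f"pathway_{t + 1}"
        firsts = [gid for gi, gid in enumerate(special_genes) if gi % len(cfg.pathway_sizes) == t]
        remaining = [gid for gid in gene_ids if gid not in set(firsts)]
        n_fill = max(0, size - len(firsts))
        fill_idx = rng.choice(len(remaining), size=min(n_fill, len(remaining)), replace=False)
        members = firsts + sorted(remaining[int(i)] for i in fill_idx)
        for gid in members:
            ann_rows.append((gid, term_id, term_name))
            pathway_assignment.setdefault(gid, []).append(term_id)
    annotation = pd.DataFrame(ann_rows, columns=["gene_id", "term_id", "term_name"])

    # planted DE tables for the miRNA and mRNA layers (companion-study stand-ins)
    de_mirna_ids = {hub_id} | set(axis_mirna_ids)
    mirna_rows = []
    for mid, _seq in mirnas:
        if mid in de_mirna_ids:
            lfc = 2.0 if mid == hub_id else float(rng.choice([-1, 1]) * (1.5 + rng.random()))
            mirna_rows.append((mid, lfc, 0.001, "up" if lfc > 0 else "down"))
        else:
            mirna_rows.append((mid, 0.0, 0.9, "ns"))
    mirna_de = pd.DataFrame(mirna_rows, columns=["id", "log2fc", "q", "status"])
    de_gene_ids = set(special_genes)
    mrna_rows = []
    for gid in gene_ids:
        if gid in de_gene_ids:
            lfc = float(rng.choice([-1, 1]) * (1.5 + rng.random()))
            mrna_rows.append((gid, lfc, 0.001, "up" if lfc > 0 else "down"))
        else:
            mrna_rows.append((gid, 0.0, 0.9, "ns"))
    mrna_de = pd.DataFrame(mrna_rows, columns=["id", "log2fc", "q", "status"])

    truth = GroundTruth(
        comparisons=comparisons,
        de_circ_ids=de_circ_ids,
        dropout_circ_ids=dropout_ids,
        true_axes=true_axes,
        hub_mirna_id=hub_id,
        hub_circ_ids=[circ_ids[i] for i in hub_circ_idx],
        hub_mrna_ids=[gene_ids[i] for i in hub_gene_idx],
        pathway_assignment=pathway_assignment,
        parental_gene={circ_ids[i]: gene_ids[int(host[i])] for i in range(cfg.n_circ)},
        mre_sites=mre_sites,
        group_of=group_of,
    )
    return SynthData(
        config=cfg,
        genome={chrom: genome_str},
        genes=genes,
        circs=circs,
        mirnas=mirnas,
        utrs=utrs,
        counts=counts_df,
        group_of=group_of,
        annotation=annotation,
        mirna_de=mirna_de,
        mrna_de=mrna_de,
        truth=truth,
    )


def generate_dataset(config: SynthConfig, out_dir: str | Path) -> tuple[dict, GroundTruth]:
    """Generate and write the full file bundle; returns (paths, GroundTruth).

    The bundle: genome FASTA, gene GFF3, circRNA junction BED-like TSV,
    junction-spanning sequence FASTA, miRNA FASTA, 3'UTR FASTA, junction
    count TSV, sample-group map TSV, gene-term annotation TSV, planted
    miRNA/mRNA DE tables, and the ground truth as JSON.  Identical seed and
    configuration give a byte-identical bundle.
    """
    data = build(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("genome", "genome.fa"),
        ("gff3", "genes.gff3"),
        ("circ_bed", "circ.bed"),
        ("junction_fasta", "circ_junctions.fa"),
        ("mirna_fasta", "mirna.fa"),
        ("utr_fasta", "utr3.fa"),
        ("counts", "counts.tsv"),
        ("groups", "groups.tsv"),
        ("annotation", "gene_terms.tsv"),
        ("mirna_de", "mirna_de.tsv"),
        ("mrna_de", "mrna_de.tsv"),
        ("truth", "truth.json"),
    ]}
    io.write_fasta(paths["genome"], sorted(data.genome.items()))
    io.write_gff3(paths["gff3"], data.genes)
    bed = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.circ_id, c.strand) for c in data.circs],
        columns=io.BED_COLUMNS,
    )
    io.write_bedlike(paths["circ_bed"], bed)
    io.write_fasta(paths["junction_fasta"], [(c.circ_id, c.junction_seq) for c in data.circs])
    io.write_fasta(paths["mirna_fasta"], data.mirnas)
    io.write_fasta(paths["utr_fasta"], data.utrs)
    io.write_matrix(paths["counts"], data.counts, index_label="circ_id")
    io.write_group_map(paths["groups"], data.group_of)
    data.annotation.to_csv(paths["annotation"], sep="\t", index=False, lineterminator="\n")
    data.mirna_de.to_csv(paths["mirna_de"], sep="\t", index=False, lineterminator="\n")
    data.mrna_de.to_csv(paths["mrna_de"], sep="\t", index=False, lineterminator="\n")
    with open(paths["truth"], "w", newline="\n") as fh:
        fh.write(data.truth.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}, data.truth


# ---------------------------------------------------------------------------
# validation-assay tables


def generate_qpcr_table(
    true_fold: float,
    noise_sd: float = 0.1,
    n_per_group: int = 9,
    seed: int = 0,
    target_gene: str = "circ_target",
    reference_gene: str = "actin",
    control_group: str = "control",
    test_group: str = "test",
) -> pd.DataFrame:
    """Ct table in which the target is shifted by -log2(true_fold) in the
    test group while the reference gene stays flat; Gaussian Ct noise."""
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, shift in [(control_group, 0.0), (test_group, -np.log2(true_fold))]:
        for i in range(n_per_group):
            sample = f"{group}-{i + 1}"
            rows.append((sample, group, reference_gene, 20.0 + rng.normal(0.0, noise_sd)))
            rows.append((sample, group, target_gene, 25.0 + shift + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


def generate_luciferase_table(
    knockdown: float = 0.5,
    noise_sd: float = 0.05,
    n_wells: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-well firefly/Renilla readouts for wt and mut reporter constructs.

    In the wt construct the mimic group's firefly signal is multiplied by
    ``knockdown`` (< 1 means repression); the mut construct does not respond.
    """
    if not 0 < knockdown:
        raise ValueError("knockdown must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for construct in ["wt", "mut"]:
        for group in ["mimic", "NC"]:
            effect = knockdown if (construct == "wt" and group == "mimic") else 1.0
            for _i in range(n_wells):
                well += 1
                renilla = 1000.0 * (1.0 + rng.normal(0.0, noise_sd))
                firefly = renilla * effect * (1.0 + rng.normal(0.0, noise_sd))
                rows.append((f"w{well:02d}", group, construct, firefly, renilla))
    return pd.DataFrame(rows, columns=["well", "group", "construct", "firefly", "renilla"])
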