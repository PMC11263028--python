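"""miRNA-target prediction by the intersection of three scoring schemes.

Candidate sites are generated by a seed scan (perfect Watson-Crick
complementarity to miRNA positions 2-8 on the target sense strand; one G:U
optionally allowed).  Each candidate window is then scored three ways:

1. ``miranda_score`` — a local complementarity alignment (match +5, G:U
   wobble +1, mismatch -3, affine gaps -9/-4) with pair scores doubled at
   miRNA seed positions 2-8, in the spirit of miRanda.
2. ``duplex_mfe`` — the intermolecular duplex minimum free energy over
   Watson-Crick and wobble pairs with bulges/internal loops, computed by
   dynamic programming over a bundled nearest-neighbor parameter table
   (37 degC), in the spirit of RNAhybrid's duplex model.
3. ``allen_score`` — a position-weighted penalty (mismatch 1, G:U 0.5,
   gap 2; penalties doubled at miRNA positions 2-13), lower is better.

Only sites passing all three thresholds (``pass_all``) feed the ceRNA
network.  Thresholds ship in :class:`TargetThresholds` and are configurable;
the alignment cutoff is expressed for a 22-nt miRNA and rescaled to each
miRNA's maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .io import normalize_rna

SEED_START, SEED_END = 1, 8  # 0-based slice of miRNA positions 2-8
_PAIR = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class MirnaRecord:
    mirna_id: str
    seq: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if not 18 <= len(self.seq) <= 26:
            raise ValueError(f"{self.mirna_id}: miRNA length must be in [18, 26]")

    @property
    def seed(self) -> str:
        return self.seq[SEED_START:SEED_END]


@dataclass(frozen=True)
class MirandaParams:
    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_weight: float = 2.0
    max_window: int = 80


@dataclass(frozen=True)
class TargetThresholds:
    """Pass cutoffs and window geometry for :func:`predict_targets`."""

    align_min: float = 140.0  # on the 22-nt scale (max attainable 145)
    energy_max: float = -14.0  # kcal/mol
    allen_max: float = 4.0
    flank: int = 30  # nt of target upstream of the seed site in the scored window
    allow_gu_in_seed: bool = False


# ---------------------------------------------------------------------------
# parameter table


@dataclass(frozen=True)
class DuplexParams:
    init: float
    asym: float
    stacks: dict  # (x1, x2, y1, y2) -> dG
    loops: dict  # total unpaired length -> dG
    max_loop: int = 6  # max unpaired bases on either side between two pairs

    def loop_penalty(self, a: int, b: int) -> float:
        """Penalty for a bulge/internal loop with a and b unpaired bases."""
        total = a + b
        biggest = max(self.loops)
        base = self.loops.get(total, self.loops[biggest] + 0.3 * (total - biggest))
        return base + min(self.asym * abs(a - b), 3.0)


@lru_cache(maxsize=1)
def load_duplex_params() -> DuplexParams:
    """Load the bundled nearest-neighbor duplex free-energy table."""
    text = resources.files("circsponge.data").joinpath("rna_duplex_params.tsv").read_text()
    init = asym = None
    stacks: dict = {}
    loops: dict = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "INIT":
            init = float(parts[1])
        elif parts[0] == "ASYM":
            asym = float(parts[1])
        elif parts[0] == "STACK":
            stacks[tuple(parts[1:5])] = float(parts[5])
        elif parts[0] == "LOOP":
            loops[int(parts[1])] = float(parts[2])
    if init is None or asym is None or not stacks or not loops:
        raise ValueError("malformed duplex parameter table")
    return DuplexParams(init=init, asym=asym, stacks=stacks, loops=loops)


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _PAIR or (a, b) in _WOBBLE


# ---------------------------------------------------------------------------
# seed scan


def seed_scan(target_seq: str, mirna: MirnaRecord, allow_gu_in_seed: bool = False) -> list[int]:
    """Offsets where the target contains the reverse complement of the seed.

    The seed is miRNA positions 2-8 (7 nt).  Matching is Watson-Crick unless
    ``allow_gu_in_seed``, in which case a single G:U pair is tolerated.
    Offsets are deduplicated and ascending.
    """
    target = normalize_rna(target_seq)
    if len(target) < 7:
        raise ValueError("target too short for a seed scan")
    seed = mirna.seed
    # target 5'->3' window t[o..o+7) pairs the seed antiparallel:
    # t[o + i] pairs seed[6 - i]
    hits = []
    for o in range(len(target) - 6):
        gu = 0
        ok = True
        for i in range(7):
            pair = (target[o + i], seed[6 - i])
            if pair in _PAIR:
                continue
            if allow_gu_in_seed and pair in _WOBBLE and gu == 0:
                gu += 1
                continue
            ok = False
            break
        if ok:
            hits.append(o)
    return hits


# ---------------------------------------------------------------------------
# miRanda-style local alignment


def _miranda_pair_score(t: str, m: str, mirna_pos: int, params: MirandaParams) -> float:
    pair = (t, m)
    if pair in _PAIR:
        s = params.match
    elif pair in _WOBBLE:
        s = params.wobble
    else:
        s = params.mismatch
    if SEED_START + 1 <= mirna_pos <= SEED_END:  # 1-based positions 2..8
        s *= params.seed_weight
    return s


def miranda_score(
    target_window: str, mirna: MirnaRecord, params: MirandaParams = MirandaParams()
) -> tuple[float, str]:
    """Best local complementarity alignment score and its traceback string.

    The target window (5'->3') is aligned against the miRNA read 3'->5'
    (antiparallel), Smith-Waterman style with affine gaps: a gap of length L
    costs gap_open + (L-1) * gap_extend.  Traceback prefers diagonal, then a
    gap in the target (up), then a gap in the miRNA (left).  The trace string
    is over {'|' pair, ':' wobble, '.' mismatch, '-' gap}.
    """
    x = normalize_rna(target_window)
    if len(x) > params.max_window:
        raise ValueError(f"window longer than {params.max_window} nt")
    y = mirna.seq[::-1]  # 3'->5'
    L = len(mirna.seq)
    n, m = len(x), len(y)
    NEG = -1e18
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in miRNA (x aligned to '-')
    Iy = np.full((n + 1, m + 1), NEG)  # gap in target
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            mirna_pos = L - (j - 1)  # 1-based miRNA position of y[j-1]
            s = _miranda_pair_score(x[i - 1], y[j - 1], mirna_pos, params)
            M[i, j] = max(0.0, max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s)
            Ix[i, j] = max(M[i - 1, j] + params.gap_open, Ix[i - 1, j] + params.gap_extend)
            Iy[i, j] = max(M[i, j - 1] + params.gap_open, Iy[i, j - 1] + params.gap_extend)
            if M[i, j] > best:
                best, best_ij = M[i, j], (i, j)
    # traceback from the best M cell
    trace = []
    i, j = best_ij
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0.0:
                break
            mirna_pos = L - (j - 1)
            s = _miranda_pair_score(x[i - 1], y[j - 1], mirna_pos, params)
            pair = (x[i - 1], y[j - 1])
            trace.append("|" if pair in _PAIR else (":" if pair in _WOBBLE else "."))
            prev = M[i, j] - s
            # prefer diagonal, then up (Ix), then left (Iy)
            if abs(M[i - 1, j - 1] - prev) < 1e-9:
                state = "M"
            elif abs(Ix[i - 1, j - 1] - prev) < 1e-9:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
        elif state == "Ix":
            trace.append("-")
            if abs(Ix[i, j] - (M[i - 1, j] + params.gap_open)) < 1e-9:
                state = "M"
            i -= 1
        else:
            trace.append("-")
            if abs(Iy[i, j] - (M[i, j - 1] + params.gap_open)) < 1e-9:
                state = "M"
            j -= 1
    return float(best), "".join(reversed(trace))


def max_miranda_score(mirna: MirnaRecord, params: MirandaParams = MirandaParams()) -> float:
    """Score of a perfect Watson-Crick duplex over the full miRNA length."""
    L = len(mirna.seq)
    n_seed = SEED_END - SEED_START
    return params.match * (L - n_seed) + params.match * params.seed_weight * n_seed


# ---------------------------------------------------------------------------
# duplex minimum free energy


def duplex_mfe(
    target_window: str,
    mirna: MirnaRecord,
    params: DuplexParams | None = None,
) -> float:
    """Minimum free energy (kcal/mol) of the intermolecular duplex.

    Dynamic programming over chains of base pairs (Watson-Crick + G:U)
    separated by stacks or bulges/internal loops of at most ``max_loop``
    unpaired bases per strand; no intramolecular structure.  Returns the
    energy of the best structure with at least one pair, or +inf when the
    two sequences cannot pair at all.
    """
    if params is None:
        params = load_duplex_params()
    x = normalize_rna(target_window)
    if len(x) > 80:
        raise ValueError("window longer than 80 nt")
    y = mirna.seq[::-1]  # both indices ascending along the duplex
    n, m = len(x), len(y)
    INF = float("inf")
    e = np.full((n, m), INF)
    for i in range(n):
        for j in range(m):
            if not _pairable(x[i], y[j]):
                continue
            best = params.init  # open the duplex at this pair
            for a in range(0, params.max_loop + 1):
                pi = i - 1 - a
                if pi < 0:
                    break
                for b in range(0, params.max_loop + 1):
                    pj = j - 1 - b
                    if pj < 0:
                        break
                    prev = e[pi, pj]
                    if prev == INF:
                        continue
                    if a == 0 and b == 0:
                        link = params.stacks[(x[pi], x[i], y[pj], y[j])]
                    else:
                        link = params.loop_penalty(a, b)
                    cand = prev + link
                    if cand < best:
                        best = cand
            e[i, j] = best
    mfe = e.min()
    return float(mfe)


# ---------------------------------------------------------------------------
# Allen-style penalty score


def allen_score(target_window: str, mirna: MirnaRecord) -> float:
    """Position-weighted penalty of the best global alignment, lower is better.

    Pairing penalties: Watson-Crick 0, G:U 0.5, mismatch 1, gap 2; all
    doubled at miRNA positions 2-13.  The target window is aligned 5'->3'
    against the miRNA 3'->5' over its full length; gaps in the target strand
    take the weight of the next miRNA position.
    """
    x = normalize_rna(target_window)
    y = mirna.seq[::-1]
    L = len(mirna.seq)
    n, m = len(x), len(y)

    def weight(mirna_pos: int) -> float:
        return 2.0 if 2 <= mirna_pos <= 13 else 1.0

    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for j in range(1, m + 1):  # unpaired miRNA bases
        D[0, j] = D[0, j - 1] + 2.0 * weight(L - (j - 1))
    for i in range(1, n + 1):  # unpaired target bases cost nothing at the ends
        D[i, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            mirna_pos = L - (j - 1)
            pair = (x[i - 1], y[j - 1])
            if pair in _PAIR:
                sub = 0.0
            elif pair in _WOBBLE:
                sub = 0.5 * weight(mirna_pos)
            else:
                sub = 1.0 * weight(mirna_pos)
            gap_y = 2.0 * weight(mirna_pos)  # miRNA base unpaired
            gap_x = 2.0 * weight(mirna_pos)  # extra target base inside the duplex
            D[i, j] = min(D[i - 1, j - 1] + sub, D[i - 1, j] + gap_x, D[i, j - 1] + gap_y)
    # trailing unpaired target bases are free
    return float(D[:, m].min())


# ---------------------------------------------------------------------------
# intersection predictor


def site_window(target: str, offset: int, mirna_len: int, flank: int) -> tuple[int, int] | None:
    """Window [start, end) on the target for a seed hit at ``offset``.

    The miRNA pairs antiparallel, so positions beyond the seed extend
    upstream (5') on the target; the window spans the full putative site
    plus ``flank`` extra upstream bases.  None when the full site would run
    off the target.
    """
    site_start = offset + 8 - mirna_len
    if site_start < 0 or offset + 8 > len(target):
        return None
    return max(0, min(site_start, offset - flank)), offset + 8


def predict_targets(
    target_records: Iterable[tuple[str, str]],
    mirna_records: Iterable[MirnaRecord],
    target_kind: str = "mRNA",
    thresholds: TargetThresholds = TargetThresholds(),
    miranda_params: MirandaParams = MirandaParams(),
    duplex_params: DuplexParams | None = None,
) -> pd.DataFrame:
    """Score every seed-scan candidate with the three predictors.

    Returns one row per (miRNA, target, site) with all scores, the per-
    predictor pass flags and ``pass_all`` (their conjunction).  Only
    ``pass_all`` rows should form ceRNA edges downstream.
    """
    if duplex_params is None:
        duplex_params = load_duplex_params()
    targets = [(tid, normalize_rna(seq)) for tid, seq in target_records]
    mirnas = list(mirna_records)
    if not targets or not mirnas:
        raise ValueError("non-empty target and miRNA inputs are required")
    rows = []
    for mirna in mirnas:
        L = len(mirna.seq)
        align_cut = thresholds.align_min / 145.0 * max_miranda_score(mirna, miranda_params)
        for tid, tseq in targets:
            for offset in seed_scan(tseq, mirna, thresholds.allow_gu_in_seed):
                win = site_window(tseq, offset, L, thresholds.flank)
                if win is None:
                    continue
                wstart, wend = win
                window = tseq[wstart:wend]
                a_score, _ = miranda_score(window, mirna, miranda_params)
                dg = duplex_mfe(window, mirna, duplex_params)
                site = tseq[offset + 8 - L : offset + 8]
                pen = allen_score(site, mirna)
                pa = a_score >= align_cut
                pe = dg <= thresholds.energy_max
                pl = pen <= thresholds.allen_max
                rows.append(
                    (
                        mirna.mirna_id,
                        tid,
                        target_kind,
                        offset + 8 - L,
                        offset + 8,
                        a_score,
                        dg,
                        pen,
                        pa,
                        pe,
                        pl,
                        pa and pe and pl,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "target_id",
            "target_kind",
            "site_start",
            "site_end",
            "align_score",
            "duplex_dg",
            "allen_score",
            "pass_align",
            "pass_energy",
            "pass_allen",
            "pass_all",
        ],
    )


def mirnas_from_fasta(records: Iterable[tuple[str, str]]) -> list[MirnaRecord]:
    return [MirnaRecord(name, seq) for name, seq in records]
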