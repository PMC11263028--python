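"""Term enrichment and wet-lab validation statistics.

* Hypergeometric over-representation of annotation terms in a gene set.
* Livak 2^-ddCt relative quantification from qPCR Ct tables with a
  two-sided t-test on per-sample dCt values.
* Dual-luciferase firefly/Renilla ratio comparison (mimic vs negative
  control) per reporter construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass(frozen=True)
class QpcrResult:
    gene_id: str
    group_pair: tuple[str, str]  # (control, test)
    ddct: float
    rel_expr: float  # 2 ** -ddct
    mean_control: float
    sd_control: float
    mean_test: float
    sd_test: float
    p: float  # nan when a group has a single sample


def hypergeom_enrich(
    gene_set: Sequence[str],
    annotation: pd.DataFrame,
    background: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in ``gene_set``.

    p = P[X >= k] for X ~ Hypergeometric(N, K, n) with N the background
    size, K the term size in the background, n the gene-set size and k the
    overlap.  q is BH-adjusted across terms; rows sorted by p then term_id.
    The background defaults to all genes in the annotation table.
    """
    ann = annotation.drop_duplicates(["gene_id", "term_id"])
    if background is None:
        bg = set(ann["gene_id"])
    else:
        bg = set(background)
    genes = set(gene_set)
    if not genes <= bg:
        raise ValueError("gene_set must be a subset of the background")
    ann = ann[ann["gene_id"].isin(bg)]
    N, n = len(bg), len(genes)
    rows = []
    for term_id, sub in ann.groupby("term_id", sort=True):
        term_genes = set(sub["gene_id"])
        K = len(term_genes)
        k = len(term_genes & genes)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, sub["term_name"].iloc[0], k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = []
    return df


def _ttest(a: np.ndarray, b: np.ndarray, var_equal: bool = False) -> float:
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        # degenerate noise-free case: identical constants are indistinguishable,
        # different constants are trivially separated
        return 1.0 if float(np.mean(a)) == float(np.mean(b)) else 0.0
    res = stats.ttest_ind(a, b, equal_var=var_equal)
    return float(res.pvalue)


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
    test_group: str,
    var_equal: bool = False,
) -> QpcrResult:
    """Livak 2^-ddCt relative expression of ``target_gene`` in test vs control.

    ``ct_table`` needs columns ``sample, group, gene, ct``.  dCt is computed
    per sample (Ct_target - Ct_reference), ddCt as mean dCt(test) - mean
    dCt(control), and the p-value is a two-sided t-test on the per-sample
    dCt values (Welch by default; ``var_equal=True`` for pooled Student's).
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")

    def _dct(group: str) -> np.ndarray:
        sub = ct_table[ct_table["group"] == group]
        tgt = sub[sub["gene"] == target_gene].set_index("sample")["ct"]
        ref = sub[sub["gene"] == reference_gene].set_index("sample")["ct"]
        common = tgt.index.intersection(ref.index)
        if len(common) == 0:
            raise ValueError(
                f"group {group!r} lacks paired measurements of "
                f"{target_gene!r} and {reference_gene!r}"
            )
        return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)

    dct_control = _dct(control_group)
    dct_test = _dct(test_group)
    delta = float(dct_test.mean() - dct_control.mean())
    return QpcrResult(
        gene_id=target_gene,
        group_pair=(control_group, test_group),
        ddct=delta,
        rel_expr=float(2.0 ** (-delta)),
        mean_control=float(dct_control.mean()),
        sd_control=float(dct_control.std(ddof=1)) if len(dct_control) > 1 else float("nan"),
        mean_test=float(dct_test.mean()),
        sd_test=float(dct_test.std(ddof=1)) if len(dct_test) > 1 else float("nan"),
        p=_ttest(dct_test, dct_control, var_equal=var_equal),
    )


def luciferase_compare(
    readouts: pd.DataFrame,
    mimic_group: str = "mimic",
    control_group: str = "NC",
    var_equal: bool = False,
) -> pd.DataFrame:
    """Firefly/Renilla ratio comparison per construct, mimic vs control.

    ``readouts`` needs columns ``well, group, construct, firefly, renilla``.
    Returns one row per construct with group means +- SD and a two-sided
    t-test p-value on the per-well normalized ratios.
    """
    required = {"well", "group", "construct", "firefly", "renilla"}
    if not required.issubset(readouts.columns):
        raise ValueError(f"luciferase table needs columns {sorted(required)}")
    if (readouts["renilla"] <= 0).any():
        raise ValueError("Renilla readouts must be strictly positive")
    df = readouts.copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    rows = []
    for construct, sub in df.groupby("construct", sort=True):
        mimic = sub[sub["group"] == mimic_group]["ratio"].to_numpy(dtype=float)
        nc = sub[sub["group"] == control_group]["ratio"].to_numpy(dtype=float)
        if len(mimic) < 2 or len(nc) < 2:
            raise ValueError(f"construct {construct!r}: need >= 2 wells per group")
        rows.append(
            (
                construct,
                float(mimic.mean()),
                float(mimic.std(ddof=1)),
                float(nc.mean()),
                float(nc.std(ddof=1)),
                _ttest(mimic, nc, var_equal=var_equal),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["construct", "mean_mimic", "sd_mimic", "mean_control", "sd_control", "p"],
    )
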