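"""Differential circRNA expression between consecutive groups.

Fold change is computed on group-mean RPM with a symmetric pseudocount, the
per-circRNA p-value comes from either a pooled exact conditional binomial
test with a library-size offset (default; suited to sparse junction counts)
or a Welch t-test on log2(RPM + pseudo), and significance is assessed on
Benjamini-Hochberg adjusted q-values.  A circRNA is called up when
q < alpha and log2FC > lfc_threshold, down when q < alpha and
log2FC < -lfc_threshold, and ns otherwise.

CircRNAs that are entirely absent in one group ("dropout") obtain large but
finite |log2FC| through the pseudocount policy (default: half the smallest
nonzero RPM in the dataset), mirroring the extreme fold changes that
presence/absence junction counts produce.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import group_mean_rpm, group_sum_counts

log = logging.getLogger("circsponge")

TREND_LABELS = (
    "continuous_increase",
    "continuous_decrease",
    "increase_decrease",
    "decrease_increase",
)


# ---------------------------------------------------------------------------
# fold change


def default_pseudocount(rpm_matrix: pd.DataFrame) -> float:
    """Half the smallest nonzero RPM in the dataset (1.0 if the matrix is all zero)."""
    vals = rpm_matrix.to_numpy()
    nz = vals[vals > 0]
    return float(nz.min()) / 2.0 if nz.size else 1.0


def fold_change(ref_rpm: float, test_rpm: float, pseudo: float) -> tuple[float, float]:
    """FC = (test + pseudo) / (ref + pseudo); returns (fc, log2fc), finite for zeros."""
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    if ref_rpm < 0 or test_rpm < 0:
        raise ValueError("RPM values must be non-negative")
    fc = (test_rpm + pseudo) / (ref_rpm + pseudo)
    return fc, float(np.log2(fc))


# ---------------------------------------------------------------------------
# p-values


@lru_cache(maxsize=200_000)
def _binom_p(k: int, m: int, p0: float) -> float:
    return stats.binomtest(k, m, p0, alternative="two-sided").pvalue


def de_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    ref: str,
    test: str,
    method: str = "pooled_binomial",
    pseudo: float | None = None,
) -> pd.Series:
    """Two-sided per-circRNA p-values for ref vs test.

    pooled_binomial: conditional on m = C_ref + C_test (replicates pooled),
    test C_test ~ Binomial(m, N_test / (N_ref + N_test)); p = 1 when m = 0.
    welch_log: Welch t-test on log2(RPM + pseudo) across replicates.
    """
    if method == "pooled_binomial":
        c_ref = group_sum_counts(counts, groups, ref)
        c_test = group_sum_counts(counts, groups, test)
        n_ref, n_test = int(c_ref.sum()), int(c_test.sum())
        if n_ref == 0 or n_test == 0:
            log.warning("group %s or %s has zero total counts; p set to 1", ref, test)
            return pd.Series(1.0, index=counts.index)
        p0 = round(n_test / (n_ref + n_test), 12)
        p = np.ones(len(counts))
        for i, (kr, kt) in enumerate(zip(c_ref.to_numpy(), c_test.to_numpy())):
            m = int(kr + kt)
            if m > 0:
                # floor guards against exact-zero underflow in extreme tails
                p[i] = max(_binom_p(int(kt), m, p0), 1e-300)
        return pd.Series(p, index=counts.index)
    if method == "welch_log":
        from .quantify import rpm as _rpm

        rpm_matrix = _rpm(counts)
        if pseudo is None:
            pseudo = default_pseudocount(rpm_matrix)
        ref_cols = [s for s in counts.columns if groups.get(s) == ref]
        test_cols = [s for s in counts.columns if groups.get(s) == test]
        if not ref_cols or not test_cols:
            raise KeyError("both groups must have at least one sample")
        a = np.log2(rpm_matrix[ref_cols].to_numpy() + pseudo)
        b = np.log2(rpm_matrix[test_cols].to_numpy() + pseudo)
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        return pd.Series(p, index=counts.index)
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# calling


def classify(log2fc: float, q: float, alpha: float = 0.05, lfc_threshold: float = 1.0) -> str:
    """up / down / ns by strict thresholds on q and log2FC."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be > 0")
    if q < alpha and log2fc > lfc_threshold:
        return "up"
    if q < alpha and log2fc < -lfc_threshold:
        return "down"
    return "ns"


def run_comparison(
    counts: pd.DataFrame,
    rpm_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    ref: str,
    test: str,
    method: str = "pooled_binomial",
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Full DE table for one consecutive-group comparison.

    Returns columns ``circ_id, fc, log2fc, p, q, status`` (circ_id as index).
    """
    if pseudo is None:
        pseudo = default_pseudocount(rpm_matrix)
    ref_mean = group_mean_rpm(rpm_matrix, groups, ref)
    test_mean = group_mean_rpm(rpm_matrix, groups, test)
    fcs, lfcs = zip(*(fold_change(r, t, pseudo) for r, t in zip(ref_mean, test_mean)))
    p = de_test(counts, groups, ref, test, method=method, pseudo=pseudo)
    q = bh_adjust(p.to_numpy())
    status = [classify(l, qq, alpha, lfc_threshold) for l, qq in zip(lfcs, q)]
    return pd.DataFrame(
        {
            "fc": fcs,
            "log2fc": lfcs,
            "p": p.to_numpy(),
            "q": q,
            "status": status,
        },
        index=counts.index.rename("circ_id"),
    )


def de_ids(result: pd.DataFrame) -> list[str]:
    """Ids called differential (up or down), in table order."""
    return list(result.index[result["status"] != "ns"])


def shared_de(set_a: Sequence[str], set_b: Sequence[str]) -> list[str]:
    """Intersection of two DE id sets, order-stable by ``set_a``."""
    b = set(set_b)
    return [x for x in set_a if x in b]


# ---------------------------------------------------------------------------
# trend clustering over three timepoints


def zscore3(values: Sequence[float]) -> np.ndarray:
    """Z-score a 3-vector of group means using the population SD (n denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size != 3:
        raise ValueError("exactly three group means are required")
    sd = x.std()  # population SD
    if sd == 0:
        raise ValueError("all-equal profile has no trend")
    return (x - x.mean()) / sd


def trend_classify(group_means: Sequence[float]) -> tuple[np.ndarray, str]:
    """Assign one of the four developmental trend classes to a 3-point profile.

    continuous_increase z1<z2<z3; continuous_decrease z1>z2>z3;
    increase_decrease z2 above both ends; decrease_increase z2 below both.
    Exact ties are degenerate and raise.
    """
    z = zscore3(group_means)
    z1, z2, z3 = z
    if z1 < z2 < z3:
        return z, "continuous_increase"
    if z1 > z2 > z3:
        return z, "continuous_decrease"
    if z2 > max(z1, z3):
        return z, "increase_decrease"
    if z2 < min(z1, z3):
        return z, "decrease_increase"
    raise ValueError("tied profile cannot be assigned a trend")


def trend_table(
    rpm_matrix: pd.DataFrame,
    groups: Mapping[str, str],
    group_order: Sequence[str],
    circ_ids: Sequence[str],
) -> pd.DataFrame:
    """Trend classes for the given circRNAs over three ordered groups."""
    if len(group_order) != 3:
        raise ValueError("trend clustering is defined over exactly three groups")
    means = {g: group_mean_rpm(rpm_matrix, groups, g) for g in group_order}
    rows = []
    for cid in circ_ids:
        profile = [float(means[g].loc[cid]) for g in group_order]
        z, trend = trend_classify(profile)
        rows.append((cid, *z, trend))
    return pd.DataFrame(
        rows, columns=["circ_id", "z1", "z2", "z3", "trend"]
    ).set_index("circ_id")
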