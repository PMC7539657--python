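"""Two-sample Mann–Whitney U statistics and group reporting.

The U statistic is computed from midranks.  For tie-free samples with
n_a·n_b <= 400 the two-tailed p-value is exact, from the full null
distribution of U (the count of rank arrangements per U value, built by
the standard recursion — identical to exhaustive enumeration); otherwise
a normal approximation with tie correction and a 0.5 continuity
correction is used.  Group summaries report mean ± sample SD (n−1
denominator; SD of a single-member group is reported as 0 with a note).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .model import (
    GroupComparison,
    Lifestyle,
    MitoClass,
    RcdError,
    SpeciesRecord,
)

EXACT_MAX_PRODUCT = 400  # switch to the normal approximation above this


def _u_null_counts(n: int, m: int) -> np.ndarray:
    """counts[u] = number of rank arrangements of n-vs-m samples with
    U statistic u, via f(n,m,u) = f(n-1,m,u-m) + f(n,m-1,u)."""
    umax = n * m
    C = np.zeros((n + 1, m + 1, umax + 1))
    C[0, :, 0] = 1.0
    C[:, 0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            row = C[i, j - 1].copy()
            row[j:] += C[i - 1, j][: umax + 1 - j]
            C[i, j] = row
    return C[n, m]


def exact_p_two_tailed(u: float, n: int, m: int) -> float:
    """Exact two-tailed p for integer U under the tie-free null."""
    counts = _u_null_counts(n, m)
    total = counts.sum()
    cdf = counts.cumsum() / total
    ui = int(round(u))
    p_le = cdf[ui]
    p_ge = 1.0 - (cdf[ui - 1] if ui > 0 else 0.0)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def approx_p_two_tailed(u: float, x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n, m = len(x), len(y)
    N = n + m
    mu = n * m / 2.0
    pooled = np.concatenate([x, y])
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0  # all observations identical
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-tailed Mann–Whitney U comparison of two count vectors."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise RcdError("mann_whitney_u needs non-empty groups")
    n, m = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0

    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and n * m <= EXACT_MAX_PRODUCT:
        p = exact_p_two_tailed(u_x, n, m)
        method = "exact"
    else:
        p = approx_p_two_tailed(u_x, x, y)
        method = "normal_approx"

    notes = []
    sd_a = float(np.std(x, ddof=1)) if n > 1 else 0.0
    sd_b = float(np.std(y, ddof=1)) if m > 1 else 0.0
    if n == 1:
        notes.append(f"sd_a undefined (n=1), reported as 0")
    if m == 1:
        notes.append(f"sd_b undefined (n=1), reported as 0")
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=n,
        n_b=m,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        sd_a=sd_a,
        sd_b=sd_b,
        U=float(u_x),
        p_two_tailed=p,
        method=method,
        notes="; ".join(notes),
    )


# ---------------------------------------------------------------------------
# group reporting

Grouping = Union[str, Mapping[str, str]]


def _labels_for(
    records: Sequence[SpeciesRecord], grouping: Grouping
) -> dict[str, str]:
    if isinstance(grouping, str):
        if grouping == "mito_class":
            return {r.species_id: r.mito_class.value for r in records}
        if grouping == "lifestyle":
            return {r.species_id: r.lifestyle.value for r in records}
        raise RcdError(f"unknown grouping {grouping!r}")
    return dict(grouping)


def group_summary(
    counts: Mapping[str, int], labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group n, mean and sample SD of the count vector."""
    rows = []
    for label in sorted(set(labels.values())):
        vals = np.array(
            [counts[sp] for sp in counts if labels.get(sp) == label], dtype=float
        )
        if len(vals) == 0:
            warnings.warn(f"group {label!r} has no species; excluded")
            continue
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "sd_defined": len(vals) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _vals(counts, labels, pred) -> list[float]:
    return [counts[sp] for sp in counts if pred(labels.get(sp))]


def group_report(
    counts: Mapping[str, int],
    records: Sequence[SpeciesRecord],
    grouping: Grouping,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-group mean ± SD table and the standard pairwise comparisons.

    grouping="mito_class": summary by phenotype class plus the
    diverged-vs-aerobic contrast (diverged = every non-aerobic class).
    grouping="lifestyle": summary by lifestyle plus parasitic vs
    non-parasitic and transiently-multicellular vs free-living.
    A mapping species_id -> label yields all pairwise label comparisons.
    """
    labels = _labels_for(records, grouping)
    missing = set(counts) - set(labels)
    if missing:
        raise RcdError(f"no group label for species {sorted(missing)[:5]}")
    summary = group_summary(counts, labels)
    comparisons: list[GroupComparison] = []

    def compare(a_vals, b_vals, la, lb):
        if a_vals and b_vals:
            comparisons.append(mann_whitney_u(a_vals, b_vals, la, lb))
        else:
            warnings.warn(f"comparison {la} vs {lb} skipped: empty group")

    if grouping == "mito_class":
        div = _vals(counts, labels, lambda v: v is not None and v != MitoClass.AEROBIC.value)
        aer = _vals(counts, labels, lambda v: v == MitoClass.AEROBIC.value)
        compare(div, aer, "diverged", "aerobic")
    elif grouping == "lifestyle":
        par = _vals(counts, labels, lambda v: v == Lifestyle.P.value)
        nonpar = _vals(counts, labels, lambda v: v is not None and v != Lifestyle.P.value)
        compare(par, nonpar, "parasitic", "non_parasitic")
        multi = _vals(counts, labels, lambda v: v == Lifestyle.M.value)
        free = _vals(counts, labels, lambda v: v == Lifestyle.F.value)
        compare(multi, free, "multicellular", "free_living")
    else:
        groups = sorted(set(labels.values()))
        for i, la in enumerate(groups):
            for lb in groups[i + 1:]:
                compare(
                    _vals(counts, labels, lambda v, la=la: v == la),
                    _vals(counts, labels, lambda v, lb=lb: v == lb),
                    la,
                    lb,
                )
    return summary, comparisons


def comparisons_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    """Tabular view of comparisons for TSV export."""
    return pd.DataFrame(
        [
            {
                "group_a": c.label_a, "group_b": c.label_b,
                "n_a": c.n_a, "n_b": c.n_b,
                "mean_a": c.mean_a, "mean_b": c.mean_b,
                "sd_a": c.sd_a, "sd_b": c.sd_b,
                "U": c.U, "p_two_tailed": c.p_two_tailed,
                "method": c.method, "notes": c.notes,
            }
            for c in comparisons
        ]
    )
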