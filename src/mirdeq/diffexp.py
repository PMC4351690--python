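"""Per-miRNA two-group testing, Holm adjustment and selection rules.

Tests are pooled-variance (equal-variance) two-tailed Student t tests on
log10-normalized values; Welch's correction is available behind a flag.
Multiplicity is controlled with the Holm step-down procedure against a
configurable family size. Fold changes are direction-oriented ratios of the
linear-scale group means (always >= 1, undefined when the smaller mean is 0).

Two selection rules are provided: the significance signature (adjusted
p < alpha) and the clustering set (defined fold change > fc_min and absolute
mean difference > diff_min, both strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mirdeq.counts_io import SampleTable
from mirdeq.normalization import NormalizedMatrix

__all__ = [
    "DERecord",
    "two_group_ttest",
    "ttest_table",
    "holm_adjust",
    "fold_change",
    "make_de_records",
    "select_signature",
    "select_clustering_set",
]


@dataclass
class DERecord:
    """Per-miRNA differential expression statistics.

    ``mean_tumor`` / ``mean_normal`` are linear-scale normalized reads; the
    test statistic and p-values come from the log10-scale comparison.
    ``fold_change`` is ``None`` when the smaller group mean is zero
    (serialized as ``N/A``).
    """

    mirna_id: str
    mean_tumor: float
    mean_normal: float
    t: float
    p_raw: float
    p_adj: float
    direction: str  # "up" | "down"
    fold_change: float | None
    mean_diff: float


def two_group_ttest(
    values_a: np.ndarray, values_b: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-tailed two-sample t test; pooled variance unless ``welch``.

    Returns ``(t, p)``. Degenerate inputs follow fixed conventions: both
    groups constant with equal means gives ``(0.0, 1.0)``; zero pooled
    variance with unequal means is an error; groups of size < 2 are an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 values (got {na} and {nb})")
    mean_a, mean_b = a.mean(), b.mean()
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if welch:
        se2 = var_a / na + var_b / nb
        if se2 == 0.0:
            if mean_a == mean_b:
                return 0.0, 1.0
            raise ValueError("zero variance, unequal means")
        t = (mean_a - mean_b) / math.sqrt(se2)
        df = se2**2 / (
            (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
        )
    else:
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        if pooled == 0.0:
            if mean_a == mean_b:
                return 0.0, 1.0
            raise ValueError("zero variance, unequal means")
        t = (mean_a - mean_b) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def ttest_table(
    values: np.ndarray, mask_a: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized row-wise pooled t test of columns in ``mask_a`` vs the rest.

    Rows with zero pooled variance get t=0, p=1 when the means are equal and
    +/-inf, p=0 otherwise (the scalar path raises instead; at matrix scale a
    sentinel is more useful than aborting the whole table).
    """
    values = np.asarray(values, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    a = values[:, mask_a]
    b = values[:, ~mask_a]
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 samples")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = mean_a - mean_b
    if welch:
        se2 = var_a / na + var_b / nb
        df = np.full(len(values), na + nb - 2, dtype=float)
        nz = se2 > 0
        df[nz] = se2[nz] ** 2 / (
            (var_a[nz] / na) ** 2 / (na - 1) + (var_b[nz] / nb) ** 2 / (nb - 1)
        )
    else:
        se2 = (
            ((na - 1) * var_a + (nb - 1) * var_b)
            / (na + nb - 2)
            * (1.0 / na + 1.0 / nb)
        )
        df = np.full(len(values), na + nb - 2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t[(se2 == 0) & (diff == 0)] = 0.0
    p = np.minimum(2.0 * stats.t.sf(np.abs(t), df), 1.0)
    p[(se2 == 0) & (diff == 0)] = 1.0
    p[(se2 == 0) & (diff != 0)] = 0.0
    return t, p


def holm_adjust(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Holm step-down adjusted p-values, aligned to the input order.

    With ascending ranks k = 1..K, ``adj(k) = min(1, max_{i<=k} (m-i+1) p(i))``
    — the running maximum enforces monotonicity. ``m`` is the family size and
    defaults to the number of p-values supplied; it may exceed it (the family
    can be larger than the subset being adjusted) but never be smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be 1-D")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than {k} p-values")
    if k == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    multipliers = m - np.arange(k)  # m, m-1, ..., m-k+1
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(multipliers * p[order]))
    out = np.empty(k)
    out[order] = adj_sorted
    return out


def fold_change(
    mean_tumor: float, mean_normal: float
) -> tuple[str, float | None]:
    """Direction-oriented fold change between two non-negative group means.

    Returns ``(direction, fold)`` with fold = larger mean / smaller mean
    (>= 1). Direction is "up" when the tumor mean is larger, with ties going
    "up" by convention. Fold is ``None`` (undefined) when the smaller mean is
    zero.
    """
    if mean_tumor < 0 or mean_normal < 0:
        raise ValueError("group means must be non-negative")
    direction = "up" if mean_tumor >= mean_normal else "down"
    smaller = min(mean_tumor, mean_normal)
    larger = max(mean_tumor, mean_normal)
    if smaller == 0:
        return direction, None
    return direction, larger / smaller


def make_de_records(
    linear: NormalizedMatrix,
    logged: NormalizedMatrix,
    samples: SampleTable,
    family_size: int | None = None,
    welch: bool = False,
) -> list[DERecord]:
    """Build one :class:`DERecord` per miRNA.

    Group means come from the linear-scale matrix, test statistics from the
    log10-scale matrix; Holm adjustment uses ``family_size`` (default: number
    of miRNAs tested).
    """
    if linear.scale != "linear" or logged.scale != "log10":
        raise ValueError("expected a linear and a log10 matrix")
    if linear.mirna_ids != logged.mirna_ids or linear.sample_ids != logged.sample_ids:
        raise ValueError("linear and log10 matrices are not aligned")
    tumor_ids = set(samples.ids_in_group("tumor"))
    normal_ids = set(samples.ids_in_group("normal"))
    missing = [s for s in linear.sample_ids if s not in tumor_ids | normal_ids]
    if missing:
        raise ValueError(f"sample {missing[0]!r} missing from the sample table")
    mask = np.array([s in tumor_ids for s in linear.sample_ids])
    t_stats, p_raw = ttest_table(logged.values, mask, welch=welch)
    p_adj = holm_adjust(p_raw, m=family_size)
    mean_t = linear.values[:, mask].mean(axis=1)
    mean_n = linear.values[:, ~mask].mean(axis=1)
    records = []
    for i, mid in enumerate(linear.mirna_ids):
        direction, fold = fold_change(float(mean_t[i]), float(mean_n[i]))
        records.append(
            DERecord(
                mirna_id=mid,
                mean_tumor=float(mean_t[i]),
                mean_normal=float(mean_n[i]),
                t=float(t_stats[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                direction=direction,
                fold_change=fold,
                mean_diff=abs(float(mean_t[i]) - float(mean_n[i])),
            )
        )
    return records


def select_signature(records: list[DERecord], alpha: float = 0.05) -> list[DERecord]:
    """Records with adjusted p strictly below ``alpha``.

    Sorted by raw p ascending, ties broken by miRNA id.
    """
    hits = [r for r in records if r.p_adj < alpha]
    return sorted(hits, key=lambda r: (r.p_raw, r.mirna_id))


def select_clustering_set(
    records: list[DERecord], fc_min: float = 2.0, diff_min: float = 100.0
) -> list[DERecord]:
    """Records with defined fold change > ``fc_min`` and mean difference
    > ``diff_min`` (both strict); undefined fold change never passes."""
    return [
        r
        for r in records
        if r.fold_change is not None
        and r.fold_change > fc_min
        and r.mean_diff > diff_min
    ]
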