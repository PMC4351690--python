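"""Low-expression filtering and quantile-quantile scaling normalization.

Raw counts are filtered on the per-miRNA mean across all samples, then each
sample is rescaled to a reference distribution built from the per-miRNA mean
of the raw counts. Two scaling behaviours are provided:

* :func:`qq_scale` (default): rank-based quantile matching — the k-th
  smallest value of each sample is replaced by the k-th smallest reference
  value; ties within a sample receive the mean of the reference values they
  would jointly occupy.
* :func:`total_scale`: a single linear factor per sample matching the
  reference total.

Values are analysed downstream on a log10 scale after adding a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mirdeq.counts_io import CountMatrix


@dataclass
class NormalizedMatrix:
    """Normalized expression values with an explicit scale flag."""

    mirna_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str  # "linear" | "log10"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with identifiers")
        if self.scale == "linear" and self.values.size and self.values.min() < 0:
            raise ValueError("linear-scale values must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.mirna_ids, columns=self.sample_ids
        )


def filter_low_expression(cm: CountMatrix, min_mean: float = 5.0) -> CountMatrix:
    """Drop miRNAs whose mean raw count across all samples is < ``min_mean``.

    The boundary is kept: a mean exactly equal to ``min_mean`` survives.
    Row order is preserved, so the operation is idempotent.
    """
    if cm.n_samples == 0:
        raise ValueError("count matrix has zero samples")
    means = cm.counts.mean(axis=1)
    return cm.subset_rows(means >= min_mean)


def build_reference(cm: CountMatrix) -> np.ndarray:
    """Per-miRNA arithmetic mean of raw counts over all samples."""
    if cm.n_samples == 0:
        raise ValueError("count matrix has zero samples")
    return cm.counts.mean(axis=1)


def _qq_scale_column(values: np.ndarray, sorted_ref: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    # group indices of runs of equal input values
    if len(values) == 0:
        return values.astype(float)
    new_run = np.r_[True, sorted_vals[1:] != sorted_vals[:-1]]
    grp = np.cumsum(new_run) - 1
    sums = np.bincount(grp, weights=sorted_ref)
    sizes = np.bincount(grp)
    averaged = sums / sizes
    out = np.empty(len(values), dtype=float)
    out[order] = averaged[grp]
    return out


def qq_scale(cm: CountMatrix, ref: np.ndarray) -> NormalizedMatrix:
    """Quantile-match every sample against the sorted reference distribution.

    For each sample independently the k-th smallest count is replaced by the
    k-th smallest reference value; tied counts share the mean of the
    reference values spanning their ranks. Within-sample rank order is
    preserved, and for tie-free samples the output multiset equals the
    reference multiset exactly.
    """
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (cm.n_mirnas,):
        raise ValueError(
            f"reference length {ref.shape} does not match {cm.n_mirnas} miRNAs"
        )
    sorted_ref = np.sort(ref)
    out = np.empty(cm.counts.shape, dtype=float)
    for j in range(cm.n_samples):
        out[:, j] = _qq_scale_column(cm.counts[:, j].astype(float), sorted_ref)
    return NormalizedMatrix(list(cm.mirna_ids), list(cm.sample_ids), out, "linear")


def total_scale(cm: CountMatrix, ref: np.ndarray) -> NormalizedMatrix:
    """Alternative normalization: one global linear factor per sample.

    Each sample is multiplied by ``sum(ref) / sample_total`` so all samples
    share the reference total. Kept behind the same interface so it can be
    swapped for :func:`qq_scale`.
    """
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (cm.n_mirnas,):
        raise ValueError("reference does not match matrix rows")
    totals = cm.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"sample {cm.sample_ids[j]!r} has zero total count")
    factors = ref.sum() / totals
    out = cm.counts.astype(float) * factors[np.newaxis, :]
    return NormalizedMatrix(list(cm.mirna_ids), list(cm.sample_ids), out, "linear")


NORMALIZERS = {"quantile": qq_scale, "scale": total_scale}


def normalize_counts(
    cm: CountMatrix, method: str = "quantile"
) -> NormalizedMatrix:
    """Filtered-matrix normalization against the per-miRNA mean reference."""
    try:
        fn = NORMALIZERS[method]
    except KeyError:
        raise ValueError(f"unknown normalization method {method!r}") from None
    return fn(cm, build_reference(cm))


def log10_transform(
    nm: NormalizedMatrix, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Elementwise ``log10(value + pseudocount)``.

    Refuses to transform a matrix already on the log10 scale.
    """
    if nm.scale == "log10":
        raise ValueError("matrix is already log10-scaled")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return NormalizedMatrix(
        list(nm.mirna_ids),
        list(nm.sample_ids),
        np.log10(nm.values + pseudocount),
        "log10",
    )
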