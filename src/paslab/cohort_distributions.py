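"""Per-cohort expression distributions, Ward.D2 clustering, high-expressor flag.

Used for pan-cancer single-gene analyses: bin one gene's expression within
each cohort (cancer type) on a log2 scale, cluster the cohort histograms so
cohorts with similar expression patterns group together, and flag cohorts in
which more than 5% of samples exceed a reference cohort's mean expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

DEFAULT_N_BINS = 64
HIGH_FRACTION_CUTOFF = 0.05


@dataclass
class CohortDistribution:
    """Normalized histogram of one gene's expression within one cohort."""

    cohort: str
    bin_edges: np.ndarray
    freqs: np.ndarray
    n: int
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.freqs) != len(self.bin_edges) - 1:
            raise ValueError("freqs length must be len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if self.n < 1:
            raise ValueError("cohort must contain at least one sample")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("freqs must sum to 1")


def analysis_scale(values) -> np.ndarray:
    """log2(intensity + 1), the scale on which distributions are built."""
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def pooled_bin_edges(values, n_bins: int = DEFAULT_N_BINS,
                     lo_pct: float = 0.5, hi_pct: float = 99.5) -> np.ndarray:
    """Equal-width edges spanning the pooled 0.5th-99.5th percentile range."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.percentile(v, [lo_pct, hi_pct])
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def build_distribution(values, bin_edges, cohort: str = "") -> CohortDistribution:
    """Histogram one cohort's values over shared edges; out-of-range values
    are clipped into the terminal bins and counted."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError(f"empty cohort {cohort!r}")
    edges = np.asarray(bin_edges, dtype=float)
    n_clipped = int(((v < edges[0]) | (v > edges[-1])).sum())
    clipped = np.clip(v, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return CohortDistribution(
        cohort=cohort,
        bin_edges=edges,
        freqs=counts / v.size,
        n=int(v.size),
        n_clipped=n_clipped,
    )


def cluster_distributions(dists: list[CohortDistribution]) -> dict:
    """Ward.D2 agglomerative clustering of cohort histograms.

    Cohorts are sorted by label before linkage so the output is invariant to
    input order (ties broken by label). Returns the scipy linkage matrix, the
    leaf order (cohort labels), and the two-cluster bipartition.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 cohorts to cluster")
    edges0 = dists[0].bin_edges
    for d in dists[1:]:
        if not np.array_equal(d.bin_edges, edges0):
            raise ValueError("mismatched bin_edges across cohorts")
    ordered = sorted(dists, key=lambda d: d.cohort)
    labels = [d.cohort for d in ordered]
    X = np.vstack([d.freqs for d in ordered])
    # scipy 'ward' on raw observations == R hclust ward.D2 on Euclidean dist
    Z = linkage(X, method="ward")
    order = [labels[i] for i in leaves_list(Z)]
    top2 = fcluster(Z, t=2, criterion="maxclust")
    return {
        "linkage": Z,
        "labels": labels,
        "leaf_order": order,
        "bipartition": dict(zip(labels, (int(c) for c in top2))),
    }


def high_fraction(cohort_values, reference_values) -> dict:
    """Fraction of cohort samples above the reference cohort's mean.

    The threshold is the arithmetic mean of ``reference_values`` on whatever
    scale both vectors share. A cohort is flagged high when strictly more
    than 5% of its samples exceed the threshold.
    """
    cv = np.asarray(cohort_values, dtype=float)
    rv = np.asarray(reference_values, dtype=float)
    if cv.size == 0 or rv.size == 0:
        raise ValueError("cohort and reference must be non-empty")
    threshold = float(rv.mean())
    fraction = float((cv > threshold).mean())
    return {
        "fraction": fraction,
        "threshold": threshold,
        "is_high_cohort": fraction > HIGH_FRACTION_CUTOFF,
    }


def cohort_distribution_table(expr_values: pd.Series, cohorts: pd.Series,
                              n_bins: int = DEFAULT_N_BINS) -> list[CohortDistribution]:
    """Build one distribution per cohort for a single gene's sample values.

    Values are moved to the log2(x+1) analysis scale and binned over shared
    pooled-percentile edges.
    """
    scaled = pd.Series(analysis_scale(expr_values), index=expr_values.index)
    edges = pooled_bin_edges(scaled, n_bins=n_bins)
    out = []
    for cohort, idx in scaled.groupby(cohorts.reindex(scaled.index)).groups.items():
        out.append(build_distribution(scaled.loc[idx], edges, cohort=str(cohort)))
    return out
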