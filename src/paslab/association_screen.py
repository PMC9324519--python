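"""Signature scoring and Pearson correlation screens under two-stage FDR.

Two screens share this machinery: a driver gene's expression against
per-sample immune-signature scores (within each cohort), and a driver gene
against per-sample pathway activation levels. Significance calling uses the
Benjamini-Krieger-Yekutieli two-stage adaptive step-up (their definition 6:
stage 1 is BH at alpha' = alpha/(1+alpha); the rejection count estimates the
number of true nulls m0 = m - r1; stage 2 reruns BH at alpha' * m / m0),
optionally combined with an effect-size floor |r| > r_min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedCorrelation
from .expression_io import ExpressionMatrix

MIN_PAIRS = 3


@dataclass(frozen=True)
class CorrelationRecord:
    """One feature-vs-driver association within one cohort."""

    feature: str
    cohort: str
    r: float
    p: float
    q: float
    significant: bool
    n: int


def signature_score(
    expr: ExpressionMatrix | pd.DataFrame,
    signature: list[str],
    name: str = "",
    mode: str = "mean_square",
) -> pd.Series:
    """Per-sample signature score: mean of squared expression over the
    signature's measured genes (``mode="rms"`` takes the square root).

    Missing signature genes are dropped; if none is measured the signature is
    rejected by name.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    measured = [g for g in signature if g in values.index]
    if not measured:
        raise ValueError(f"no gene of signature {name or signature!r} is measured")
    score = (values.loc[measured] ** 2).mean(axis=0)
    if mode == "rms":
        score = np.sqrt(score)
    elif mode != "mean_square":
        raise ValueError(f"unknown mode {mode!r}")
    score.name = name or None
    return score


def read_gmt(path) -> dict[str, list[str]]:
    """Plain GMT: ``name<TAB>description<TAB>gene...`` per line."""
    sigs: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = [t for t in line.split("\t") if t]
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: GMT line needs >= 1 gene")
            if parts[0] in sigs:
                raise ValueError(f"line {lineno}: duplicate signature {parts[0]!r}")
            sigs[parts[0]] = parts[2:]
    return sigs


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value (t transform, n-2 df).

    Pairs with a missing entry on either side are dropped first
    (pairwise-complete). Constant input or fewer than 3 complete pairs raises
    :class:`UndefinedCorrelation`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < MIN_PAIRS:
        raise UndefinedCorrelation(f"only {x.size} complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation("constant input vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fdr_twostage(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Krieger-Yekutieli two-stage step-up: (q values, reject flags)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_tsbky")
    return q, reject


def correlation_screen(
    driver: pd.Series,
    scores: pd.DataFrame,
    alpha: float = 0.05,
    r_min: float = 0.2,
    cohorts: pd.Series | None = None,
) -> tuple[list[CorrelationRecord], pd.DataFrame]:
    """Correlate every feature (row of ``scores``) with the driver.

    FDR correction is applied within each cohort across features (the
    correction family); with no cohort annotation all samples form one cohort
    named ``"all"``. A record is significant when q < alpha and |r| > r_min.
    Features with undefined correlation are dropped with a log entry in the
    counts table (column ``n_undefined``).

    Returns the records plus per-cohort counts of significant positive /
    negative correlations.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if r_min < 0:
        raise ValueError("r_min must be >= 0")
    shared = driver.index.intersection(scores.columns)
    if len(shared) < MIN_PAIRS:
        raise ValueError("driver and scores share fewer than 3 samples")
    driver = driver.loc[shared]
    scores = scores[shared]
    if cohorts is None:
        cohorts = pd.Series("all", index=shared)
    else:
        cohorts = cohorts.reindex(shared)

    records: list[CorrelationRecord] = []
    count_rows = []
    for cohort, idx in sorted(cohorts.groupby(cohorts).groups.items()):
        d = driver.loc[idx]
        partial = []
        n_undef = 0
        for feature, row in scores[idx].iterrows():
            try:
                r, p = pearson(d.to_numpy(), row.to_numpy())
            except UndefinedCorrelation:
                n_undef += 1
                continue
            partial.append((str(feature), r, p, int(min(d.notna().sum(), row.notna().sum()))))
        if partial:
            q, _ = fdr_twostage([p for _, _, p, _ in partial], alpha=alpha)
        else:
            q = []
        n_pos = n_neg = 0
        for (feature, r, p, n), qv in zip(partial, q):
            sig = bool(qv < alpha and abs(r) > r_min)
            if sig:
                if r > 0:
                    n_pos += 1
                else:
                    n_neg += 1
            records.append(CorrelationRecord(feature, str(cohort), r, p, float(qv), sig, n))
        count_rows.append((str(cohort), n_pos, n_neg, n_undef))
    counts = pd.DataFrame(
        count_rows, columns=["cohort", "n_pos_sig", "n_neg_sig", "n_undefined"]
    ).set_index("cohort")
    return records, counts


def pas_association(
    pas: pd.DataFrame,
    driver: pd.Series,
    alpha: float = 0.05,
    r_min: float = 0.0,
) -> tuple[list[CorrelationRecord], int]:
    """Correlate per-sample PAL of every pathway with a driver gene.

    ``pas`` is sample-by-pathway (as produced by per_sample_pas). Following
    the screen's published form, significance requires only q < alpha; no
    effect-size floor is applied unless ``r_min`` is set.
    """
    shared = pas.index.intersection(driver.index)
    if len(shared) < MIN_PAIRS:
        raise ValueError("fewer than 3 shared samples")
    d = driver.loc[shared]
    if np.ptp(d.to_numpy(dtype=float)) == 0:
        raise UndefinedCorrelation("driver is constant")
    records, _ = correlation_screen(
        d, pas.loc[shared].T, alpha=alpha, r_min=r_min
    )
    n_significant = sum(rec.q < alpha and abs(rec.r) > r_min for rec in records)
    return records, n_significant


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature, r.cohort, r.r, r.p, r.q, r.significant, r.n)
            for r in records
        ],
        columns=["feature", "cohort", "r", "p", "q", "significant", "n"],
    )
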