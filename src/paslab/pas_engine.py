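"""Case-to-normal ratios and pathway activation level (PAL / PAS) scoring.

The pathway activation level of pathway *p* for a case-vs-norm comparison is
the role-weighted mean of log case-to-normal ratios over the pathway's
measured members:

    PAL(p) = sum_n ARR(n,p) * log(CNR_n) / sum_n |ARR(n,p)|

where CNR_n is the gene's mean expression in the case samples divided by its
mean in the control ("norm") samples, and ARR is the signed
activator/repressor role. Membership outside the pathway contributes nothing
(the membership indicator is folded into the sums); neutral members (ARR = 0)
drop out of both numerator and denominator. Positive PAL means the pathway's
output is up in the case condition; a repressor going down pushes PAL up.

Genes not measured in the expression matrix are excluded from numerator and
denominator rather than imputed to CNR = 1, so an unmeasured gene never
dilutes the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import PathwayUnmeasured, PathwayUnscorable
from .expression_io import DEFAULT_EPS, ExpressionMatrix
from .pathway_model import Pathway, PathwayCollection, restrict_to_measured

NORM_MODES = ("control_arith_mean", "control_geom_mean", "cohort_mean")


@dataclass
class CNRVector:
    """Per-gene case-to-normal ratios (all > 0 after eps flooring)."""

    cnr: pd.Series
    norm_mode: str
    floored_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.norm_mode not in NORM_MODES:
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")
        if (self.cnr <= 0).any():
            raise ValueError("CNR values must be positive")
        extra = self.floored_genes - set(self.cnr.index)
        if extra:
            raise ValueError(f"floored genes not in index: {sorted(extra)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.cnr.index


@dataclass
class PASResult:
    """PAL per scorable pathway, with skip reasons for the rest."""

    table: pd.DataFrame  # index pathway id; columns klass, pal, n_members_used
    skipped: pd.DataFrame  # index pathway id; column reason
    context: dict = field(default_factory=dict)

    @property
    def pal(self) -> pd.Series:
        return self.table["pal"]


def _group_mean(df: pd.DataFrame, mode: str, eps: float) -> np.ndarray:
    vals = df.to_numpy(dtype=float)
    if mode == "control_geom_mean":
        return gmean(np.maximum(vals, eps), axis=1)
    return vals.mean(axis=1)


def compute_cnr(
    case: pd.DataFrame | ExpressionMatrix,
    control: pd.DataFrame | ExpressionMatrix,
    eps: float = DEFAULT_EPS,
    norm_mode: str = "control_arith_mean",
) -> CNRVector:
    """Per-gene ratio of mean case expression to mean control expression.

    Both inputs are gene-by-sample tables sharing a gene index (extra genes on
    either side are dropped to the intersection). Means are arithmetic by
    default (`control_arith_mean`), geometric under `control_geom_mean` —
    the mode applies to both the case and the control mean. Numerator and
    denominator are floored at ``eps``; floored genes are recorded.
    """
    case_df = case.values if isinstance(case, ExpressionMatrix) else case
    ctrl_df = control.values if isinstance(control, ExpressionMatrix) else control
    if case_df.shape[1] == 0 or ctrl_df.shape[1] == 0:
        raise ValueError("case and control must each contain at least one sample")
    shared = case_df.index.intersection(ctrl_df.index)
    if shared.empty:
        raise ValueError("case and control share no genes")
    if norm_mode not in NORM_MODES:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    mean_mode = "control_geom_mean" if norm_mode == "control_geom_mean" else "control_arith_mean"
    num = _group_mean(case_df.loc[shared], mean_mode, eps)
    den = _group_mean(ctrl_df.loc[shared], mean_mode, eps)
    floored = (num < eps) | (den < eps)
    cnr = np.maximum(num, eps) / np.maximum(den, eps)
    return CNRVector(
        cnr=pd.Series(cnr, index=shared, name="cnr"),
        norm_mode=norm_mode,
        floored_genes=frozenset(shared[floored]),
    )


def compute_pal(cnr: CNRVector, p: Pathway, log_base: float = 10.0) -> float:
    """Role-weighted mean log CNR over the pathway's measured members."""
    if log_base <= 1:
        raise ValueError("log_base must be > 1")
    measured = restrict_to_measured(p, cnr.genes)
    genes = list(measured.members)
    arr = np.array([measured.members[g] for g in genes])
    logs = np.log(cnr.cnr.loc[genes].to_numpy()) / math.log(log_base)
    denom = np.abs(arr).sum()
    if denom == 0:
        raise PathwayUnscorable(p.id)
    return float((arr * logs).sum() / denom)


def _split_design(expr: ExpressionMatrix, design) -> tuple[list, list]:
    """Accept a dict/Series sample->{case,control} or a 2-column DataFrame."""
    if isinstance(design, pd.DataFrame):
        design = design.set_index(design.columns[0])[design.columns[1]]
    design = pd.Series(design)
    case = [s for s, g in design.items() if g == "case"]
    control = [s for s, g in design.items() if g == "control"]
    missing = set(case + control) - set(expr.samples)
    if missing:
        raise ValueError(f"design names samples absent from matrix: {sorted(missing)[:5]}")
    if not case or not control:
        raise ValueError("design must name at least one case and one control sample")
    return case, control


def _score_collection(
    cnr: CNRVector, coll: PathwayCollection, log_base: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, skipped = [], []
    for p in coll:
        try:
            measured = restrict_to_measured(p, cnr.genes)
            pal = compute_pal(cnr, measured, log_base=log_base)
        except PathwayUnmeasured:
            skipped.append((p.id, "unmeasured"))
            continue
        except PathwayUnscorable:
            skipped.append((p.id, "unscorable"))
            continue
        n_used = sum(1 for r in measured.members.values() if r != 0)
        rows.append((p.id, p.klass, pal, n_used))
    table = pd.DataFrame(rows, columns=["pathway", "klass", "pal", "n_members_used"])
    table = table.set_index("pathway")
    skip = pd.DataFrame(skipped, columns=["pathway", "reason"]).set_index("pathway")
    return table, skip


def pas_table(
    expr: ExpressionMatrix,
    design,
    coll: PathwayCollection,
    log_base: float = 10.0,
    eps: float = DEFAULT_EPS,
    norm_mode: str = "control_arith_mean",
) -> PASResult:
    """One PAL per scorable pathway for a case/control design."""
    case, control = _split_design(expr, design)
    cnr = compute_cnr(expr.values[case], expr.values[control], eps=eps, norm_mode=norm_mode)
    table, skipped = _score_collection(cnr, coll, log_base)
    return PASResult(
        table=table,
        skipped=skipped,
        context={
            "case": case,
            "control": control,
            "norm_mode": norm_mode,
            "log_base": log_base,
            "eps": eps,
            "n_floored_genes": len(cnr.floored_genes),
        },
    )


def per_sample_pas(
    expr: ExpressionMatrix,
    coll: PathwayCollection,
    norm: str | list = "cohort_mean",
    log_base: float = 10.0,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Sample-by-pathway PAL table, each sample scored alone against a norm.

    ``norm`` is either ``"cohort_mean"`` (the per-gene arithmetic mean over
    all samples serves as the control profile) or an explicit list of control
    sample ids. Pathways unmeasured/unscorable for the matrix are dropped.
    """
    if isinstance(norm, str):
        if norm != "cohort_mean":
            raise ValueError(f"unknown norm {norm!r}")
        if expr.shape[1] < 2:
            raise ValueError("cohort_mean norm needs at least 2 samples")
        control_df = expr.values.mean(axis=1).to_frame("__cohort_mean__")
        norm_mode = "cohort_mean"
    else:
        control_df = expr.values[list(norm)]
        norm_mode = "control_arith_mean"

    rows = {}
    for sample in expr.samples:
        cnr_vals = compute_cnr(
            expr.values[[sample]], control_df, eps=eps, norm_mode="control_arith_mean"
        )
        cnr = CNRVector(cnr_vals.cnr, norm_mode="cohort_mean" if norm_mode == "cohort_mean" else norm_mode,
                        floored_genes=cnr_vals.floored_genes)
        table, _ = _score_collection(cnr, coll, log_base)
        rows[sample] = table["pal"]
    out = pd.DataFrame(rows).T
    return out.loc[list(expr.samples)]


def count_regulated(pal, threshold: float) -> dict:
    """Counts of up-/down-regulated pathways at a strict |PAL| threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if isinstance(pal, PASResult):
        pal = pal.pal
    vals = np.asarray(pd.Series(pal), dtype=float)
    n_total = len(vals)
    n_up = int((vals > threshold).sum())
    n_down = int((vals < -threshold).sum())
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_total": n_total,
        "frac_up": n_up / n_total if n_total else 0.0,
        "frac_down": n_down / n_total if n_total else 0.0,
    }
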