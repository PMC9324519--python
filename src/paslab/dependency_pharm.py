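"""Cell-line dependency vs drug-sensitivity analysis.

Dependency panels hold one screen channel each (RNAi / CRISPR) of
cell-line-by-gene dependency scores; more negative means the line depends on
the gene. Drug panels hold drug-by-cell-line dose-response AUCs (lower =
more sensitive) plus a drug-to-target map. For each drug-target pair the
Pearson correlation between AUC and the target's dependency score is computed
per channel over the shared cell lines and the channel correlations are
averaged; a target whose dependency tracks sensitivity across a drug family
stands out by its mean correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .association_screen import pearson
from .errors import UndefinedCorrelation

CHANNELS = ("RNAi", "CRISPR")
MIN_SHARED_LINES = 3


@dataclass
class DependencyPanel:
    """One screen channel of cell-line x gene dependency scores."""

    channel: str
    scores: pd.DataFrame  # index cell_line, columns gene; NaN = not screened
    tumor_types: pd.Series | None = None  # cell_line -> tumor type

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate cell-line ids")


@dataclass
class DrugPanel:
    """Drug x cell-line AUCs plus the drug -> target-gene map."""

    auc: pd.DataFrame  # index drug, columns cell_line
    targets: dict[str, list[str]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for drug, tg in self.targets.items():
            if not tg:
                raise ValueError(f"drug {drug!r} has no target")


def read_dependency_csv(path) -> dict[str, DependencyPanel]:
    """Long-format CSV (cell_line, tumor_type, gene, score, channel) -> panels."""
    df = pd.read_csv(path)
    panels = {}
    for channel, sub in df.groupby("channel"):
        mat = sub.pivot_table(index="cell_line", columns="gene", values="score")
        types = sub.drop_duplicates("cell_line").set_index("cell_line")["tumor_type"]
        panels[channel] = DependencyPanel(channel, mat, types.reindex(mat.index))
    return panels


def read_drug_csv(auc_path, targets_path, provenance: str = "") -> DrugPanel:
    """AUC CSV (drug, cell_line, auc) + target map CSV (drug, target)."""
    auc = pd.read_csv(auc_path).pivot_table(index="drug", columns="cell_line", values="auc")
    tmap = pd.read_csv(targets_path)
    targets = {d: sorted(g["target"]) for d, g in tmap.groupby("drug")}
    return DrugPanel(auc, targets, provenance)


def group_dependency(dep: DependencyPanel, gene: str, min_lines: int = 5) -> pd.DataFrame:
    """Per-tumor-type dependency summary for one gene.

    Only tumor types represented by strictly more than ``min_lines`` cell
    lines (with a non-missing score for the gene) are kept. Returns a frame
    indexed by tumor type with n, median and quartiles.
    """
    if gene not in dep.scores.columns:
        raise KeyError(f"gene {gene!r} absent from {dep.channel} panel")
    if dep.tumor_types is None:
        raise ValueError("panel carries no tumor-type annotation")
    s = dep.scores[gene].dropna()
    rows = []
    for ttype, vals in s.groupby(dep.tumor_types.reindex(s.index)):
        if len(vals) > min_lines:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((str(ttype), len(vals), med, q1, q3))
    out = pd.DataFrame(rows, columns=["tumor_type", "n", "median", "q1", "q3"])
    out = out.set_index("tumor_type").sort_values("median")
    if out.empty:
        import logging

        logging.getLogger(__name__).warning(
            "no tumor type has more than %d lines for %s", min_lines, gene
        )
    return out


def _channel_r(drugs: DrugPanel, dep: DependencyPanel, drug: str, target: str):
    if target not in dep.scores.columns or drug not in drugs.auc.index:
        return None
    auc = drugs.auc.loc[drug].dropna()
    score = dep.scores[target].dropna()
    shared = auc.index.intersection(score.index)
    if len(shared) < MIN_SHARED_LINES:
        return None
    try:
        r, _ = pearson(auc.loc[shared].to_numpy(), score.loc[shared].to_numpy())
    except UndefinedCorrelation:
        return None
    return r


def drug_target_correlation(
    drugs: DrugPanel,
    rnai: DependencyPanel | None,
    crispr: DependencyPanel | None,
) -> pd.DataFrame:
    """Drug x target table of channel-averaged AUC-dependency correlations.

    Per channel, r is the Pearson correlation of (AUC, dependency score) over
    the cell lines shared by both panels (>= 3 required, else that channel is
    missing for the pair). The cell value is the mean over available
    channels; a pair present in one channel yields that channel's r, a pair
    present in none is NaN.
    """
    all_targets = sorted({t for tg in drugs.targets.values() for t in tg})
    table = pd.DataFrame(
        np.nan, index=sorted(drugs.targets), columns=all_targets, dtype=float
    )
    for drug, tg in drugs.targets.items():
        for target in tg:
            rs = []
            for panel in (rnai, crispr):
                if panel is None:
                    continue
                r = _channel_r(drugs, panel, drug, target)
                if r is not None:
                    rs.append(r)
            if rs:
                table.loc[drug, target] = float(np.mean(rs))
    return table


def rank_targets(table: pd.DataFrame) -> dict:
    """Rank targets by mean correlation; cluster drugs by Ward.D2.

    Targets are sorted by the mean of their available cells (descending).
    For the drug clustering only, missing cells are imputed with the target's
    column mean (all-missing columns with 0); imputed positions are flagged.
    """
    if table.empty:
        raise ValueError("empty correlation table")
    target_mean = table.mean(axis=0, skipna=True).sort_values(
        ascending=False, kind="stable"
    )
    target_order = list(target_mean.index)

    imputed_mask = table.isna()
    filled = table.fillna(table.mean(axis=0)).fillna(0.0)
    if len(table.index) >= 2:
        Z = linkage(filled.to_numpy(), method="ward")
        drug_order = [table.index[i] for i in leaves_list(Z)]
    else:
        Z = None
        drug_order = list(table.index)
    return {
        "target_order": target_order,
        "target_mean_r": target_mean,
        "drug_linkage": Z,
        "drug_order": drug_order,
        "n_imputed_cells": int(imputed_mask.to_numpy().sum()),
    }
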