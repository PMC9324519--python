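"""Seeded synthetic-data generators with planted, closed-form effects.

Every generator emulates the statistical structure one pipeline stage
assumes, so the whole chain is testable without downloads:

* multi-cohort log-normal expression of a driver gene with an optional
  "high-expressor" mixture component (pan-cancer distribution analyses);
* case/control designs in which one pathway's members shift coherently with
  their signed roles, making the planted activation level exact in the
  noise-free case;
* signature genes whose mean-square score tracks a driver gene at a set
  correlation (Gaussian latent shared between driver and signature);
* cell-line panels in which one true target's dependency score linearly
  predicts drug AUC, with decoy targets uncorrelated.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
arguments and seed give bit-identical output.

Expression is generated log-normally: microarray intensities are positive
and roughly normal on a log scale. Pathway effects are planted on the log10
scale so the expected pathway activation level equals the planted shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .pathway_model import PathwayCollection


@dataclass
class CohortSpec:
    """One cohort of a pan-cancer driver-gene simulation.

    ``baseline_log_mean``/``baseline_log_sd`` parameterize the log2-scale
    base component; a fraction ``pi`` of samples is drawn from a component
    shifted up by ``shift`` log2-SD units (the "high expressors").
    """

    name: str
    n_samples: int
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    pi: float = 0.0
    shift: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.pi <= 1:
            raise ValueError("pi must lie in [0, 1]")
        if self.baseline_log_sd <= 0:
            raise ValueError("baseline_log_sd must be > 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SyntheticSpec:
    """Bundle of generator settings for the end-to-end synthetic workflow."""

    seed: int = 0
    n_genes: int = 300
    cohorts: list[CohortSpec] = field(default_factory=list)
    pathway_delta: float = 1.0
    pathway_sigma: float = 0.2
    n_case: int = 3
    n_ctrl: int = 3
    signature_rho: float = 0.7
    n_samples: int = 100
    n_cell_lines: int = 60
    pharm_slope: float = 1.0
    pharm_noise_ratio: float = 0.5


def gen_cohort_expression(
    cohorts: list[CohortSpec],
    n_genes: int = 50,
    driver: str = "KIT",
    seed: int = 0,
) -> ExpressionMatrix:
    """Multi-cohort expression with a mixture-distributed driver gene.

    The driver gene follows each cohort's two-component log-normal mixture;
    the remaining ``n_genes - 1`` genes are i.i.d. log-normal with the
    cohort's base parameters. Output is linear scale (2**log-value), with
    cohort annotations attached.
    """
    rng = np.random.default_rng(seed)
    cols, sample_ids, cohort_labels = [], [], []
    for spec in cohorts:
        base = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                          size=(n_genes, spec.n_samples))
        is_high = rng.random(spec.n_samples) < spec.pi
        base[0, is_high] += spec.shift * spec.baseline_log_sd
        cols.append(base)
        sample_ids.extend(f"{spec.name}_s{i}" for i in range(spec.n_samples))
        cohort_labels.extend([spec.name] * spec.n_samples)
    logvals = np.concatenate(cols, axis=1)
    genes = [driver] + [f"G{i:04d}" for i in range(1, n_genes)]
    values = pd.DataFrame(2.0 ** logvals, index=genes, columns=sample_ids)
    ann = pd.DataFrame({"cohort": cohort_labels, "group": "none"}, index=sample_ids)
    return ExpressionMatrix(values, ann)


def gen_pathway_dataset(
    coll: PathwayCollection,
    activated: str,
    delta: float = 1.0,
    n_case: int = 3,
    n_ctrl: int = 3,
    sigma: float = 0.2,
    seed: int = 0,
    n_extra_genes: int = 0,
    baseline_log_mean: float = 2.0,
    baseline_log_sd: float = 0.5,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Case/control matrix with one pathway activated by ``delta`` log10 units.

    Case samples shift the activated pathway's activator members by +delta
    and repressor members by -delta on the log10 scale (neutral members are
    untouched); every gene gets i.i.d. N(0, sigma) log10 noise per sample.
    With sigma = 0 the planted pathway's activation level is exactly delta
    under the role-weighted log-ratio score, and every other pathway scores 0.
    """
    if activated not in coll:
        raise KeyError(f"pathway {activated!r} not in collection")
    rng = np.random.default_rng(seed)
    genes = sorted({g for p in coll for g in p.members})
    genes += [f"X{i:04d}" for i in range(n_extra_genes)]
    mu = pd.Series(rng.normal(baseline_log_mean, baseline_log_sd, len(genes)), index=genes)

    shift = pd.Series(0.0, index=genes)
    for g, role in coll[activated].members.items():
        if role > 0:
            shift.loc[g] = delta
        elif role < 0:
            shift.loc[g] = -delta

    n_total = n_case + n_ctrl
    noise = rng.normal(0.0, sigma, size=(len(genes), n_total)) if sigma > 0 else 0.0
    logv = np.tile(mu.to_numpy()[:, None], (1, n_total)) + noise
    logv[:, :n_case] += shift.to_numpy()[:, None]
    samples = [f"case_{i}" for i in range(n_case)] + [f"ctrl_{i}" for i in range(n_ctrl)]
    values = pd.DataFrame(10.0 ** logv, index=genes, columns=samples)
    design = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples, name="group")
    ann = pd.DataFrame({"cohort": "synthetic", "group": design}, index=samples)
    return ExpressionMatrix(values, ann), design


def gen_signature_dataset(
    signatures: dict[str, list[str]],
    rho: float | dict[str, float],
    n_samples: int = 100,
    driver: str = "KIT",
    n_extra_genes: int = 20,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression in which each signature's mean-square score tracks the driver.

    A standard-normal latent z drives the driver gene
    (driver = 100 * 10**(0.1 z), nearly linear in z). Per signature, a latent
    u = rho*z + sqrt(1-rho^2)*noise is shared by its genes, whose values are
    constructed so the signature's mean-square score is linear in u up to
    per-gene noise — the population score-vs-driver correlation is ~rho.
    Non-signature genes are independent log-normals.
    """
    rhos = {name: (rho[name] if isinstance(rho, dict) else rho) for name in signatures}
    for name, r in rhos.items():
        if not -1 < r < 1:
            raise ValueError(f"signature {name!r}: |rho| must be < 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    samples = [f"s{i:04d}" for i in range(n_samples)]
    rows: dict[str, np.ndarray] = {driver: 100.0 * 10.0 ** (0.1 * z)}

    base, gain = 25.0, 4.0
    for name, genes in sorted(signatures.items()):
        r = rhos[name]
        u = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n_samples)
        level = np.clip(base + gain * u, 0.01, None)
        for g in genes:
            eta = rng.standard_normal(n_samples)
            rows[g] = np.sqrt(level) * np.exp(0.05 * eta)
    for i in range(n_extra_genes):
        rows[f"N{i:04d}"] = 10.0 ** rng.normal(1.0, 0.3, n_samples)
    values = pd.DataFrame(rows, index=samples).T
    return ExpressionMatrix(values)


def gen_pharm_panel(
    n_lines: int = 60,
    drug_targets: dict[str, list[str]] | None = None,
    true_target: dict[str, str] | str = "KIT",
    slope: float = 1.0,
    noise_ratio: float = 0.5,
    n_tumor_types: int = 4,
    seed: int = 0,
):
    """Cell-line panels in which one target's dependency predicts drug AUC.

    Per true-target gene, a latent per-line dependency t ~ N(-0.5, 0.4) is
    shared by both screen channels (it is the planted ground truth); all
    other genes are independent N(-0.1, 0.3) noise per channel. Per drug,
    AUC = slope * t + eps with SD(eps) = noise_ratio * |slope| * SD(t).
    Lines are assigned to ``n_tumor_types`` tumor types cyclically.

    Returns (DrugPanel, rnai DependencyPanel, crispr DependencyPanel).
    """
    from .dependency_pharm import DependencyPanel, DrugPanel

    if drug_targets is None:
        drug_targets = {"drugA": ["KIT", "RET", "FLT3"]}
    rng = np.random.default_rng(seed)
    lines = [f"CL{i:03d}" for i in range(n_lines)]
    genes = sorted({t for tg in drug_targets.values() for t in tg})
    truth = ({d: true_target for d in drug_targets}
             if isinstance(true_target, str) else dict(true_target))
    true_genes = sorted(set(truth.values()))

    latent = {g: rng.normal(-0.5, 0.4, n_lines) for g in true_genes}
    channels = {}
    for channel in ("RNAi", "CRISPR"):
        mat = pd.DataFrame(
            rng.normal(-0.1, 0.3, size=(n_lines, len(genes))),
            index=lines, columns=genes,
        )
        for g in true_genes:
            mat[g] = latent[g]
        types = pd.Series(
            [f"type{i % n_tumor_types}" for i in range(n_lines)], index=lines
        )
        channels[channel] = DependencyPanel(channel, mat, types)

    auc_rows = {}
    for drug in sorted(drug_targets):
        t = latent[truth[drug]]
        eps_sd = noise_ratio * abs(slope) * t.std(ddof=0)
        eps = rng.normal(0.0, eps_sd, n_lines) if eps_sd > 0 else 0.0
        auc_rows[drug] = slope * t + eps
    auc = pd.DataFrame(auc_rows, index=lines).T
    drugs = DrugPanel(auc, {d: list(tg) for d, tg in drug_targets.items()},
                      provenance=f"synthetic seed={seed}")
    return drugs, channels["RNAi"], channels["CRISPR"]
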