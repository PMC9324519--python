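"""Shared fixtures and independent oracles for the paslab test suite."""

import numpy as np
import pandas as pd
import pytest

from paslab import ExpressionMatrix, Pathway, PathwayCollection


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)

def naive_pal(cnr: dict, members: dict, log_base: float = 10.0) -> float:
    """Literal per-gene-loop evaluation of the role-weighted log-ratio score."""
    num = 0.0
    den = 0.0
    for gene, role in members.items():
        if gene not in cnr:
            continue
        num += role * (np.log(cnr[gene]) / np.log(log_base))
        den += abs(role)
    if den == 0:
        raise ZeroDivisionError("no weighted member measured")
    return num / den


def bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up, literal definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    below = np.nonzero(ps <= alpha * np.arange(1, m + 1) / m)[0]
    k = below[-1] + 1 if len(below) else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def bky_brute(p, alpha: float = 0.05) -> np.ndarray:
    """Brute-force two-stage adaptive step-up (BKY 2006, definition 6)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    a_prime = alpha / (1.0 + alpha)
    r1 = int(bh_reject(p, a_prime).sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return bh_reject(p, a_prime * m / m0)


def exact_corr_vector(x: np.ndarray, r: float, rng) -> np.ndarray:
    """A vector whose sample Pearson correlation with x is exactly r.

    Built from the standardized x and a standardized residual orthogonal to
    it, so corr(y, x) = r up to floating rounding.
    """
    n = len(x)
    xc = (x - x.mean()) / x.std()
    e = rng.standard_normal(n)
    e -= e.mean()
    e -= xc * (e @ xc) / (xc @ xc)
    e /= e.std()
    return r * xc + np.sqrt(1.0 - r * r) * e


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[10.0, 12.0, 5.0, 5.0], [4.0, 6.0, 1.0, 3.0], [7.0, 7.0, 7.0, 7.0]],
        index=["KIT", "MYC", "GAPDH"],
        columns=["case_0", "case_1", "ctrl_0", "ctrl_1"],
    )
    ann = pd.DataFrame(
        {"cohort": "c1", "group": ["case", "case", "control", "control"]},
        index=values.columns,
    )
    return ExpressionMatrix(values, ann)


@pytest.fixture
def toy_collection() -> PathwayCollection:
    return PathwayCollection(
        [
            Pathway("act", "signaling", {"KIT": 1.0, "MYC": 0.5}),
            Pathway("mixed", "signaling", {"KIT": 1.0, "MYC": -1.0, "GAPDH": 0.0}),
            Pathway("rep_only", "metabolic", {"MYC": -1.0, "GAPDH": -0.5}),
            Pathway("unmeasured", "metabolic", {"ZZZ1": 1.0, "ZZZ2": -1.0}),
            Pathway("neutral", "signaling", {"KIT": 0.0, "GAPDH": 0.0}),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
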