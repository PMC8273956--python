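"""Conditional independence testing on categorical data.

The workhorse is the G² (likelihood-ratio) test of Ind(X; Y | Z):

    G² = 2 · Σ_{x,y,z}  O_xyz · ln( O_xyz · N_z / (N_xz · N_yz) )

with the convention 0·ln(·) = 0, referred to a chi-square distribution with
df = (|X|−1)(|Y|−1)·Π|Z_i|.  Pearson's chi-square on the same cube is
available as an option.  Association strength for ranking inside the
constraint-based learners is the negative natural log of the p-value,
computed through the chi-square log-survival function so that extreme
dependence never underflows to a tie at p = 0.

A test is flagged unreliable when the average cell support n/df falls below
5 (the classic adequacy heuristic); learners treat unreliable tests as
providing no evidence of dependence.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy.stats import chi2

from .core import Dataset

__all__ = ["CITestResult", "g2_test", "assoc", "RELIABILITY_RATIO", "DEFAULT_ALPHA"]

#: minimum n/df for a test to count as reliable
RELIABILITY_RATIO = 5.0

#: conventional significance threshold used by every CI decision
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    df: int
    p_value: float
    reliable: bool
    #: natural -log(p), computed stably; large = strong dependence
    neg_log_p: float = 0.0

    @property
    def effective_p(self) -> float:
        """p-value as the learners consume it: unreliable tests report 1."""
        return self.p_value if self.reliable else 1.0


def _contingency_cube(
    data: Dataset, x: str, y: str, z: Sequence[str]
) -> tuple[np.ndarray, int, int, int]:
    """Observed counts as an array of shape (qz, rx, ry)."""
    cx = data.column(x)
    cy = data.column(y)
    rx = data.cardinality(x)
    ry = data.cardinality(y)
    qz = 1
    flat = np.zeros(data.n, dtype=np.int64)
    for name in z:
        flat = flat * data.cardinality(name) + data.column(name)
        qz *= data.cardinality(name)
    flat = (flat * rx + cx) * ry + cy
    cube = np.bincount(flat, minlength=qz * rx * ry).reshape(qz, rx, ry)
    return cube, qz, rx, ry


def g2_test(
    data: Dataset,
    x: str,
    y: str,
    z: Sequence[str] = (),
    statistic: str = "g2",
) -> CITestResult:
    """Test Ind(X; Y | Z) on a categorical dataset.

    Parameters
    ----------
    statistic
        "g2" (default, likelihood ratio) or "x2" (Pearson).

    Degenerate inputs (X or Y observed at a single level) return independence
    (statistic 0, p = 1) flagged unreliable rather than raising, so that
    learners degrade gracefully.
    """
    z = tuple(z)
    if x == y or x in z or y in z:
        raise ValueError("x, y and z must name distinct variables")
    cube, qz, rx, ry = _contingency_cube(data, x, y, z)
    df = (rx - 1) * (ry - 1) * qz
    if len(np.unique(data.column(x))) < 2 or len(np.unique(data.column(y))) < 2:
        return CITestResult(0.0, max(df, 1), 1.0, False, 0.0)

    n_z = cube.sum(axis=(1, 2), keepdims=True).astype(float)
    n_xz = cube.sum(axis=2, keepdims=True).astype(float)
    n_yz = cube.sum(axis=1, keepdims=True).astype(float)
    obs = cube.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "g2":
            ratio = obs * n_z / (n_xz * n_yz)
            terms = np.where(obs > 0, obs * np.log(np.where(obs > 0, ratio, 1.0)), 0.0)
            stat = 2.0 * float(terms.sum())
        elif statistic == "x2":
            expected = n_xz * n_yz / n_z
            terms = np.where(expected > 0, (obs - expected) ** 2 / np.where(expected > 0, expected, 1.0), 0.0)
            stat = float(terms.sum())
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df))
    neg_log_p = float(-chi2.logsf(stat, df))
    reliable = data.n / df >= RELIABILITY_RATIO
    return CITestResult(stat, df, p, reliable, neg_log_p)


def assoc(
    data: Dataset,
    x: str,
    t: str,
    cond: Sequence[str] = (),
    statistic: str = "g2",
) -> float:
    """Dependence strength of X and T given ``cond``: −ln p of the G² test.

    Monotone in evidence against independence; 0 for a perfectly independent
    table.  Stable for extreme dependence (computed on the log scale, never
    a hard 0/inf tie).
    """
    return g2_test(data, x, t, cond, statistic=statistic).neg_log_p
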