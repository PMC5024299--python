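"""Cross-platform validation: score pairing, correlations and the
free-energy-to-probability transform.

SELEX-derived 8-mer scores are compared to protein-binding-microarray (PBM)
8-mer intensities by Pearson correlation after collapsing both tables to
reverse-complement classes. Published binding free-energy differences
(ddG, kcal/mol relative to the consensus site) are mapped to binding
probabilities with a logistic transform, and two correlations sharing a
variable are compared with the Hotelling-Williams test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import canonical_kmer


@dataclass
class ScorePairing:
    """Two score vectors joined on common reverse-complement k-mer classes."""

    keys: list[str]
    x: np.ndarray
    y: np.ndarray
    unmatched_x: int = 0
    unmatched_y: int = 0

    @property
    def n(self) -> int:
        return len(self.keys)

    def pearson(self) -> float:
        return pearson(self.x, self.y)


def pearson(x, y) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a vector with zero variance has no defined correlation")
    return float(stats.pearsonr(x, y).statistic)


def ddg_to_probability(ddg, scale: float = 0.592, mode: str = "multiply"):
    """Binding probability from a free-energy difference.

    p = 1 / (1 + exp(ddG * scale)) with ``scale`` = 0.592 kcal/mol (RT at
    298 K). ddG = 0 (the consensus site) maps to 0.5 and the transform is
    strictly decreasing. ``mode='divide'`` uses exp(ddG / scale), the form
    with ddG expressed in units of RT.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    ddg = np.asarray(ddg, dtype=np.float64)
    z = ddg * scale if mode == "multiply" else ddg / scale
    out = 1.0 / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


class WilliamsResult(NamedTuple):
    statistic: float
    pvalue: float
    df: int


def compare_dependent_correlations(
    r_xy: float, r_xz: float, r_yz: float, n: int
) -> WilliamsResult:
    """Hotelling-Williams t-test for two overlapping correlations.

    Tests H0: rho(x,y) = rho(x,z) given the correlation r_yz between the two
    competing predictors, with t distributed on n - 3 degrees of freedom:

        t = (r_xy - r_xz) * sqrt( (n-1)(1 + r_yz) /
              ( 2 |R| (n-1)/(n-3) + rbar^2 (1 - r_yz)^3 ) )

    where |R| is the determinant of the 3x3 correlation matrix and
    rbar = (r_xy + r_xz) / 2. Returns the two-sided p-value.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie in (-1, 1), got {r}")
    det = 1 - r_xy**2 - r_xz**2 - r_yz**2 + 2 * r_xy * r_xz * r_yz
    if det <= 0:
        raise ValueError(
            f"correlation matrix is not positive definite (determinant {det:.3g})"
        )
    rbar = (r_xy + r_xz) / 2
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_yz) ** 3
    t = (r_xy - r_xz) * math.sqrt((n - 1) * (1 + r_yz) / denom)
    df = n - 3
    p = 2 * float(stats.t.sf(abs(t), df))
    return WilliamsResult(t, min(p, 1.0), df)


def _collapse(table: Mapping[str, float]) -> dict[str, float]:
    """Average scores over reverse-complement classes."""
    acc: dict[str, list[float]] = {}
    for kmer, score in table.items():
        acc.setdefault(canonical_kmer(kmer), []).append(float(score))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def pair_scores(
    table_x: Mapping[str, float],
    table_y: Mapping[str, float],
    collapse: bool = True,
) -> ScorePairing:
    """Join two k-mer score tables on shared reverse-complement classes.

    Both tables must be keyed by equal-length k-mers. With ``collapse`` (the
    default) an 8-mer in one table pairs with its reverse complement in the
    other, and a table listing both orientations contributes their mean.
    """
    if not table_x or not table_y:
        raise ValueError("both score tables must be non-empty")
    kx = {len(k) for k in table_x}
    ky = {len(k) for k in table_y}
    if len(kx) != 1 or kx != ky:
        raise ValueError(f"tables must be keyed by k-mers of one equal length, got {kx} vs {ky}")
    if collapse:
        table_x = _collapse(table_x)
        table_y = _collapse(table_y)
    common = sorted(set(table_x) & set(table_y))
    if not common:
        raise ValueError("tables share no k-mer classes; nothing to pair")
    x = np.array([table_x[k] for k in common])
    y = np.array([table_y[k] for k in common])
    return ScorePairing(
        common, x, y, unmatched_x=len(table_x) - len(common), unmatched_y=len(table_y) - len(common)
    )


def read_score_table(path) -> dict[str, float]:
    """Read a two-column (k-mer, score) table; tab/whitespace separated, '#' comments."""
    df = pd.read_csv(Path(path), sep=r"\s+", comment="#", header=None, names=["kmer", "score"])
    return dict(zip(df["kmer"].str.upper(), df["score"].astype(float)))
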