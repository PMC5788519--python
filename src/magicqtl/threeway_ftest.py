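"""Nested-model F-test confirming candidate three-way interactions.

Collinearity among three-way product pseudomarkers makes shrinkage estimates
alone unreliable, so each candidate trio (M1, M2, M3) is confirmed by
ordinary least squares: the reduced model

    y ~ 1 + M1 + M2 + M3 + M1:M2 + M1:M3 + M2:M3        (7 columns)

is compared against the full model adding the M1:M2:M3 product (8 columns),

    F = (RSS_reduced - RSS_full) / (RSS_full / (n - 8)),

with p from F(1, n-8).  A rank-deficient full design (e.g. a pairwise
product coinciding with a marker in the sample) is reported as non-testable
with the collinear columns named rather than fabricating a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_qc import GenotypeMatrix

__all__ = ["FTestResult", "trio_ftest", "trio_design"]

_COLUMN_NAMES = ("1", "M1", "M2", "M3", "M1:M2", "M1:M3", "M2:M3", "M1:M2:M3")


@dataclass(frozen=True)
class FTestResult:
    trio: tuple[int, int, int]
    f_stat: float | None
    df1: int
    df2: int
    p_value: float | None
    significant: bool
    alpha: float
    testable: bool = True
    collinear_columns: tuple[str, ...] = field(default=())


def trio_design(G: GenotypeMatrix, trio: tuple[int, int, int]) -> np.ndarray:
    """Full 8-column design [1, M1, M2, M3, M1M2, M1M3, M2M3, M1M2M3]."""
    m1, m2, m3 = (G.column(j) for j in trio)
    return np.column_stack(
        [np.ones(G.n), m1, m2, m3, m1 * m2, m1 * m3, m2 * m3, m1 * m2 * m3]
    )


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _collinear_columns(X: np.ndarray) -> tuple[str, ...]:
    """Columns that add nothing to the rank of the design built so far."""
    bad: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            bad.append(_COLUMN_NAMES[j])
        rank = new_rank
    return tuple(bad)


def trio_ftest(
    y: np.ndarray,
    G: GenotypeMatrix,
    trio: tuple[int, int, int],
    alpha: float = 1e-5,
) -> FTestResult:
    """F-test of the three-way term for one marker trio against the response."""
    trio = tuple(int(j) for j in trio)
    if len(set(trio)) != 3:
        raise ValueError("trio indices must be distinct")
    if any(b <= a for a, b in zip(trio, trio[1:])):
        raise ValueError("trio indices must be ascending")
    y = np.asarray(y, dtype=np.float64)
    n = G.n
    if y.size != n:
        raise ValueError("response length must equal line count")
    if n <= 8:
        raise ValueError("need n > 8 observations for the F-test")

    full = trio_design(G, trio)
    df2 = n - 8
    if np.linalg.matrix_rank(full) < 8:
        return FTestResult(
            trio=trio, f_stat=None, df1=1, df2=df2, p_value=None,
            significant=False, alpha=alpha, testable=False,
            collinear_columns=_collinear_columns(full),
        )

    rss_full = _rss(full, y)
    rss_reduced = _rss(full[:, :7], y)
    num = max(rss_reduced - rss_full, 0.0)  # nesting: never negative up to rounding
    f_stat = num / (rss_full / df2)
    p_value = float(stats.f.sf(f_stat, 1, df2))
    return FTestResult(
        trio=trio, f_stat=float(f_stat), df1=1, df2=df2, p_value=p_value,
        significant=bool(p_value <= alpha), alpha=alpha,
    )
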