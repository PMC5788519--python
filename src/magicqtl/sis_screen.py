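"""Memory-bounded sure independence screening (SIS) over product pseudomarkers.

A pseudomarker is the elementwise product of two or three ±1-coded marker
columns and represents a two- or three-way interaction term.  The screen
enumerates every ascending index tuple exactly once, scores it by the
absolute Pearson correlation of its pseudo-column with the response, and
keeps only the top ``keep`` hits in a bounded buffer — working memory is
O(keep + n) regardless of how many tuples exist, which is what makes the
three-way search (billions of combinations at genome scale) feasible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_qc import GenotypeMatrix

__all__ = [
    "PseudoMarkerIndex",
    "ScreenHit",
    "ScreenResult",
    "pseudo_column",
    "screen_interactions",
    "search_space_size",
    "write_screen_result",
]


@dataclass(frozen=True, order=True)
class PseudoMarkerIndex:
    """Strictly ascending marker indices defining an interaction term."""

    order: int
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")
        if len(self.indices) != self.order:
            raise ValueError("indices length must equal order")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("indices must be strictly ascending")


@dataclass(frozen=True)
class ScreenHit:
    index: PseudoMarkerIndex
    score: float  # |Pearson r| with the response, in [0, 1]


@dataclass(frozen=True)
class ScreenResult:
    """Top hits sorted by descending score; ties by ascending tuple."""

    hits: tuple[ScreenHit, ...]
    keep: int
    order: int
    n_evaluated: int  # tuples enumerated (each unordered tuple once)


def pseudo_column(G: GenotypeMatrix, idx: PseudoMarkerIndex) -> np.ndarray:
    """Elementwise product of the named ±1 columns (itself a ±1 column)."""
    col = G.column(idx.indices[0])
    for j in idx.indices[1:]:
        col = col * G.column(j)
    return col


def search_space_size(p: int, order: int, convention: str = "unordered") -> int:
    """Number of interaction tuples for p markers.

    ``unordered`` counts each set once: C(p,2) or C(p,3).  ``paper`` is the
    p(p-1)(p-2)/3 counting convention some reports use for the three-way
    search space (twice the unordered count); both conventions agree at order 2.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if p < order:
        raise ValueError("p must be at least the interaction order")
    if convention not in ("paper", "unordered"):
        raise ValueError("convention must be 'paper' or 'unordered'")
    if order == 2:
        return p * (p - 1) // 2
    div = 3 if convention == "paper" else 6
    return p * (p - 1) * (p - 2) // div


# ---------------------------------------------------------------------------
# Bounded top-k kernels
#
# Replacement is strict (>) so that on exact score ties the lexicographically
# earliest tuple — enumerated first — survives, matching the documented
# tie-break without any post-hoc bookkeeping.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _screen_order2(g, yg, yy, keep):  # pragma: no cover - numba
    n, p = g.shape
    scores = np.full(keep, -1.0)
    ii = np.empty(keep, np.int64)
    jj = np.empty(keep, np.int64)
    count = 0
    min_pos = 0
    n_eval = 0
    for a in range(p - 1):
        for b in range(a + 1, p):
            n_eval += 1
            dot = 0.0
            s = 0.0
            for i in range(n):
                prod = g[i, a] * g[i, b]
                dot += prod * yg[i]
                s += prod
            denom = n - s * s / n
            if denom <= 0.0:
                continue  # constant pseudo-column
            score = abs(dot) / np.sqrt(denom * yy)
            if count < keep:
                scores[count] = score
                ii[count] = a
                jj[count] = b
                count += 1
                if count == keep:
                    min_pos = np.argmin(scores)
            elif score > scores[min_pos]:
                scores[min_pos] = score
                ii[min_pos] = a
                jj[min_pos] = b
                min_pos = np.argmin(scores)
    return scores[:count], ii[:count], jj[:count], n_eval


@njit(cache=True)
def _screen_order3(g, yg, yy, keep):  # pragma: no cover - numba
    n, p = g.shape
    scores = np.full(keep, -1.0)
    ii = np.empty(keep, np.int64)
    jj = np.empty(keep, np.int64)
    kk = np.empty(keep, np.int64)
    count = 0
    min_pos = 0
    n_eval = 0
    pair = np.empty(n)
    for a in range(p - 2):
        for b in range(a + 1, p - 1):
            for i in range(n):
                pair[i] = g[i, a] * g[i, b]
            for c in range(b + 1, p):
                n_eval += 1
                dot = 0.0
                s = 0.0
                for i in range(n):
                    prod = pair[i] * g[i, c]
                    dot += prod * yg[i]
                    s += prod
                denom = n - s * s / n
                if denom <= 0.0:
                    continue
                score = abs(dot) / np.sqrt(denom * yy)
                if count < keep:
                    scores[count] = score
                    ii[count] = a
                    jj[count] = b
                    kk[count] = c
                    count += 1
                    if count == keep:
                        min_pos = np.argmin(scores)
                elif score > scores[min_pos]:
                    scores[min_pos] = score
                    ii[min_pos] = a
                    jj[min_pos] = b
                    kk[min_pos] = c
                    min_pos = np.argmin(scores)
    return scores[:count], ii[:count], jj[:count], kk[:count], n_eval


def screen_interactions(
    G: GenotypeMatrix,
    response: np.ndarray,
    order: int,
    keep: int,
) -> ScreenResult:
    """Rank all order-2 or order-3 product pseudomarkers by |r| with the response.

    Every ascending tuple is visited exactly once; zero-variance
    pseudo-columns are skipped (their correlation is undefined).  Only the
    running top-``keep`` buffer is held in memory.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if G.p < order:
        raise ValueError("need at least `order` markers")
    y = np.asarray(response, dtype=np.float64)
    if y.size != G.n:
        raise ValueError("response length must equal line count")
    yc = y - y.mean()
    yy = float(yc @ yc)
    if yy <= 0.0:
        raise ValueError("response is constant; correlations undefined")

    g = G.values.astype(np.float64)
    if order == 2:
        scores, ii, jj, n_eval = _screen_order2(g, yc, yy, keep)
        tuples = list(zip(ii.tolist(), jj.tolist()))
    else:
        scores, ii, jj, kk, n_eval = _screen_order3(g, yc, yy, keep)
        tuples = list(zip(ii.tolist(), jj.tolist(), kk.tolist()))

    ranked = sorted(zip(scores.tolist(), tuples), key=lambda t: (-t[0], t[1]))
    hits = tuple(
        ScreenHit(index=PseudoMarkerIndex(order=order, indices=tuple(tup)), score=sc)
        for sc, tup in ranked
    )
    return ScreenResult(hits=hits, keep=keep, order=order, n_evaluated=int(n_eval))


def write_screen_result(result: ScreenResult, G: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Serialize a ScreenResult as a delimited table of marker ids and scores."""
    with open(path, "w") as fh:
        cols = [f"marker_{k+1}" for k in range(result.order)]
        fh.write(sep.join(["order", *cols, "score"]) + "\n")
        for hit in result.hits:
            ids = [G.marker_ids[j] for j in hit.index.indices]
            fh.write(sep.join([str(result.order), *ids, f"{hit.score:.10g}"]) + "\n")
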