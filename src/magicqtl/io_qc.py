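"""Genotype/phenotype/map I/O, ±1 encoding, duplicate-marker QC and LD.

Doubled-haploid (DH) lines are fully homozygous, so a biallelic marker takes
exactly two states, coded +1 (AA) and -1 (BB).  Near-perfect duplicate
markers destabilise MCMC variable selection (chains arbitrarily split a QTL
signal between interchangeable columns), so they are pruned before model
fitting; linkage disequilibrium between the survivors is quantified as the
squared Pearson correlation r² of the coded columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneticMap",
    "PhenotypeVector",
    "QcReport",
    "encode_genotypes",
    "remove_duplicate_markers",
    "ld_r2",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "export_plink",
    "align_phenotype",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeMatrix:
    """n lines × p markers of ±1-coded homozygous genotypes.

    Column order is map order; every entry is exactly +1 or -1 (no
    heterozygote code exists in a DH population).
    """

    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    values: np.ndarray  # (n, p) int8

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        if v.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"shape {v.shape} does not match {len(self.line_ids)} lines "
                f"× {len(self.marker_ids)} markers"
            )
        if v.size and not np.isin(v, (-1, 1)).all():
            bad = np.argwhere(~np.isin(v, (-1, 1)))[0]
            raise ValueError(
                f"genotype entry at line {self.line_ids[bad[0]]!r}, marker "
                f"{self.marker_ids[bad[1]]!r} is not ±1"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids must be unique")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            line_ids=self.line_ids,
            marker_ids=tuple(self.marker_ids[j] for j in keep),
            values=self.values[:, keep],
        )

    def column(self, j: int) -> np.ndarray:
        """Coded genotype column as float64 (convenient for regression)."""
        return self.values[:, j].astype(np.float64)


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions in centiMorgans, nondecreasing within a chromosome."""

    marker_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions_cm: np.ndarray  # (p,) float64

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=np.float64)
        object.__setattr__(self, "positions_cm", pos)
        if not (len(self.marker_ids) == len(self.chromosomes) == pos.size):
            raise ValueError("map columns must have equal length")
        if pos.size and pos.min() < 0:
            raise ValueError("map positions must be nonnegative cM")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("map marker_ids must be unique")
        for chrom in dict.fromkeys(self.chromosomes):
            idx = [i for i, c in enumerate(self.chromosomes) if c == chrom]
            p = pos[idx]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions on chromosome {chrom} decrease")

    @property
    def p(self) -> int:
        return len(self.marker_ids)

    def subset(self, keep: Sequence[int]) -> "GeneticMap":
        keep = list(keep)
        return GeneticMap(
            marker_ids=tuple(self.marker_ids[j] for j in keep),
            chromosomes=tuple(self.chromosomes[j] for j in keep),
            positions_cm=self.positions_cm[keep],
        )

    def locate(self, marker_id: str) -> tuple[str, float]:
        j = self.marker_ids.index(marker_id)
        return self.chromosomes[j], float(self.positions_cm[j])


@dataclass(frozen=True)
class PhenotypeVector:
    """Trait values (days until heading) per line."""

    line_ids: tuple[str, ...]
    values: np.ndarray  # (n,) float64

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != len(self.line_ids):
            raise ValueError("phenotype values must align with line_ids")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class QcReport:
    removed_marker_ids: tuple[str, ...]
    kept_marker_ids: tuple[str, ...]
    duplicate_groups: tuple[tuple[str, ...], ...]
    threshold_used: float
    monomorphic_marker_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n_in = (
            len(self.removed_marker_ids)
            + len(self.kept_marker_ids)
            + len(self.monomorphic_marker_ids)
        )
        seen = set(self.removed_marker_ids) | set(self.kept_marker_ids) | set(
            self.monomorphic_marker_ids
        )
        if len(seen) != n_in:
            raise ValueError("QC categories overlap")


# ---------------------------------------------------------------------------
# Encoding and QC operations
# ---------------------------------------------------------------------------

def encode_genotypes(raw: pd.DataFrame, missing_code: str = "NA") -> GenotypeMatrix:
    """Encode an allele-call table (rows = lines, columns = markers) as ±1.

    AA → +1 and BB → -1.  Missing calls are imputed with the marker's modal
    code (ties go to +1) so product pseudomarkers stay closed in {±1}.
    Cells already coded 1/-1 (as strings or ints) are passed through.

    Raises ``ValueError`` naming the offending (line, marker) for unknown
    codes and rejecting all-missing markers.
    """
    line_ids = tuple(str(i) for i in raw.index)
    marker_ids = tuple(str(c) for c in raw.columns)
    out = np.empty((len(line_ids), len(marker_ids)), dtype=np.int8)
    code_map = {"AA": 1, "BB": -1, "1": 1, "-1": -1, "+1": 1}
    for j, marker in enumerate(marker_ids):
        col = raw.iloc[:, j]
        enc = np.zeros(len(col), dtype=np.int8)
        missing = np.zeros(len(col), dtype=bool)
        for i, cell in enumerate(col):
            s = str(cell).strip()
            if s == missing_code or (isinstance(cell, float) and np.isnan(cell)):
                missing[i] = True
            elif s in code_map:
                enc[i] = code_map[s]
            else:
                raise ValueError(
                    f"unknown allele code {s!r} at line {line_ids[i]!r}, "
                    f"marker {marker!r}"
                )
        if missing.all():
            raise ValueError(f"marker {marker!r} has no non-missing calls")
        if missing.any():
            n_plus = int((enc[~missing] == 1).sum())
            n_minus = int((enc[~missing] == -1).sum())
            enc[missing] = 1 if n_plus >= n_minus else -1
        out[:, j] = enc
    return GenotypeMatrix(line_ids=line_ids, marker_ids=marker_ids, values=out)


def _column_correlations(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of ±1 columns; NaN rows for constants."""
    x = values.astype(np.float64)
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc * xc).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(norms > 0, xc / norms, np.nan)
    return z.T @ z


def remove_duplicate_markers(
    G: GenotypeMatrix, r_threshold: float = 0.99
) -> tuple[GenotypeMatrix, QcReport]:
    """Greedy map-order pruning of (near-)duplicate markers.

    Scanning markers left to right, a marker is removed iff its absolute
    Pearson correlation with some earlier *kept* marker reaches
    ``r_threshold``; sign-flipped duplicates (r = -1) count.  Monomorphic
    columns (correlation undefined) are removed and reported separately.
    Keep-first resolution is deterministic and idempotent.
    """
    if not (0.0 < r_threshold <= 1.0):
        raise ValueError("r_threshold must be in (0, 1]")
    x = G.values.astype(np.float64)
    const = x.min(axis=0) == x.max(axis=0)
    corr = _column_correlations(G.values)

    kept: list[int] = []
    removed: list[int] = []
    mono: list[int] = []
    groups: dict[int, list[int]] = {}
    for j in range(G.p):
        if const[j]:
            mono.append(j)
            continue
        dup_of = -1
        if kept:
            r_with_kept = np.abs(corr[j, kept])
            hit = np.nonzero(r_with_kept >= r_threshold)[0]
            if hit.size:
                dup_of = kept[int(hit[np.argmax(r_with_kept[hit])])]
        if dup_of >= 0:
            removed.append(j)
            groups.setdefault(dup_of, []).append(j)
        else:
            kept.append(j)

    report = QcReport(
        removed_marker_ids=tuple(G.marker_ids[j] for j in removed),
        kept_marker_ids=tuple(G.marker_ids[j] for j in kept),
        duplicate_groups=tuple(
            tuple(G.marker_ids[j] for j in [k, *members])
            for k, members in sorted(groups.items())
        ),
        threshold_used=float(r_threshold),
        monomorphic_marker_ids=tuple(G.marker_ids[j] for j in mono),
    )
    return G.subset_markers(kept), report


def ld_r2(G: GenotypeMatrix, a: int, b: int) -> float:
    """Squared Pearson correlation of two coded marker columns.

    The standard LD r² for biallelic homozygous data.  Undefined (raises)
    for a constant column.
    """
    if a == b:
        raise ValueError("marker indices must differ")
    xa = G.column(a)
    xb = G.column(b)
    for idx, col in ((a, xa), (b, xb)):
        if col.min() == col.max():
            raise ValueError(
                f"marker {G.marker_ids[idx]!r} is constant; r² undefined"
            )
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def align_phenotype(
    G: GenotypeMatrix, pheno: PhenotypeVector
) -> PhenotypeVector:
    """Reorder the phenotype to match the genotype line order (by line id)."""
    lut = {lid: i for i, lid in enumerate(pheno.line_ids)}
    missing = [lid for lid in G.line_ids if lid not in lut]
    if missing:
        raise ValueError(f"phenotype missing for lines: {missing[:5]}")
    order = [lut[lid] for lid in G.line_ids]
    return PhenotypeVector(line_ids=G.line_ids, values=pheno.values[order])


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, sep: str = "\t", missing_code: str = "NA") -> GenotypeMatrix:
    """Read a delimited genotype table (first column = line id, header = marker ids)."""
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    return encode_genotypes(raw, missing_code=missing_code)


def write_genotypes(G: GenotypeMatrix, path: str | Path, sep: str = "\t",
                    as_alleles: bool = True) -> None:
    """Write a genotype table; ``as_alleles`` chooses AA/BB cells over 1/-1."""
    if as_alleles:
        cells = np.where(G.values == 1, "AA", "BB")
    else:
        cells = G.values.astype(str)
    df = pd.DataFrame(cells, index=list(G.line_ids), columns=list(G.marker_ids))
    df.index.name = "line"
    df.to_csv(path, sep=sep)


def read_map(path: str | Path, sep: str = "\t") -> GeneticMap:
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    return GeneticMap(
        marker_ids=tuple(df.iloc[:, 0].astype(str)),
        chromosomes=tuple(df.iloc[:, 1].astype(str)),
        positions_cm=df.iloc[:, 2].to_numpy(dtype=np.float64),
    )


def write_map(gmap: GeneticMap, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "marker": list(gmap.marker_ids),
            "chromosome": list(gmap.chromosomes),
            "position_cM": gmap.positions_cm,
        }
    ).to_csv(path, sep=sep, index=False)


def read_phenotypes(path: str | Path, sep: str = "\t") -> PhenotypeVector:
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    return PhenotypeVector(
        line_ids=tuple(df.iloc[:, 0].astype(str)),
        values=df.iloc[:, 1].to_numpy(dtype=np.float64),
    )


def write_phenotypes(pheno: PhenotypeVector, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame({"line": list(pheno.line_ids), "value": pheno.values}).to_csv(
        path, sep=sep, index=False
    )


def export_plink(
    G: GenotypeMatrix,
    gmap: GeneticMap,
    pheno: PhenotypeVector | None,
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write PLINK PED/MAP text files for external cross-checking.

    PED: family id = individual id, parents 0, sex 0, phenotype in column 6
    (or -9 if absent), then homozygous allele pairs A A (for +1) / B B (-1).
    MAP: chromosome, marker, 0, position.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    pheno_lut = (
        {lid: v for lid, v in zip(pheno.line_ids, pheno.values)}
        if pheno is not None
        else {}
    )
    with open(ped_path, "w") as fh:
        for i, lid in enumerate(G.line_ids):
            phen = pheno_lut.get(lid, -9)
            cells = ["A A" if g == 1 else "B B" for g in G.values[i]]
            fh.write(f"{lid} {lid} 0 0 0 {phen} " + " ".join(cells) + "\n")
    with open(map_path, "w") as fh:
        for mid in G.marker_ids:
            chrom, pos = gmap.locate(mid)
            fh.write(f"{chrom} {mid} 0 {pos}\n")
    return ped_path, map_path
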