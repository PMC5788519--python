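"""Synthetic MAGIC doubled-haploid populations with known genetic architecture.

Emulates the statistical structure a multiparent (MAGIC) DH panel presents
to the mapping pipeline: eight founder lines crossed through a fixed funnel
— four two-way F1s from founder pairs (1,2),(3,4),(5,6),(7,8), two four-way
crosses, one eight-way cross — and each DH line produced by doubling one
gamete of an eight-way individual.  Every meiosis recombines between
adjacent markers with the Haldane probability r = ½(1 − e^(−2Δd/100)) for a
map gap of Δd cM (no crossover interference; chromosomes independent).  The
resulting lines are fully homozygous, coded ±1, and carry LD blocks induced
by linkage through the funnel.

Phenotypes follow the generative sparse model

    y = β0 + Σ main effects + Σ pairwise products + Σ trio products + N(0, σ²),

so the simulator's truth record supports end-to-end parameter-recovery tests
of the screening, shrinkage, and F-test stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_qc import GeneticMap, GenotypeMatrix, PhenotypeVector

__all__ = [
    "FounderHaplotypes",
    "SimTruth",
    "SimDataset",
    "default_map",
    "simulate_founders",
    "simulate_magic_dh",
    "simulate_phenotype",
    "make_fixture",
    "FIXTURE_PRESETS",
]

N_FOUNDERS = 8
FIXTURE_PRESETS = ("null", "recovery_main", "recovery_epistasis", "duplicates")

# Funnel pairing fixed for determinism; real MAGIC designs randomise funnels.
_FUNNEL = ((0, 1), (2, 3), (4, 5), (6, 7))


@dataclass(frozen=True)
class FounderHaplotypes:
    values: np.ndarray  # (8, p) int8, ±1
    map: GeneticMap

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", v)
        if v.shape[0] != N_FOUNDERS:
            raise ValueError("exactly 8 founders required")
        if v.shape[1] != self.map.p:
            raise ValueError("founder width must match map")

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth architecture: sparse effects plus Gaussian noise."""

    intercept: float
    main_effects: tuple[tuple[int, float], ...]
    pair_effects: tuple[tuple[tuple[int, int], float], ...]
    trio_effects: tuple[tuple[tuple[int, int, int], float], ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for idx, _ in self.pair_effects:
            if not idx[0] < idx[1]:
                raise ValueError("pair indices must be ascending")
        for idx, _ in self.trio_effects:
            if not idx[0] < idx[1] < idx[2]:
                raise ValueError("trio indices must be ascending")


@dataclass(frozen=True)
class SimDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeVector
    map: GeneticMap
    truth: SimTruth
    seed: int
    preset: str = "custom"


# ---------------------------------------------------------------------------
# Map and founders
# ---------------------------------------------------------------------------

def default_map(p: int = 500, n_chromosomes: int = 7, spacing_cm: float = 2.0) -> GeneticMap:
    """Evenly spaced map over barley-style chromosomes 1H..7H."""
    per = [p // n_chromosomes] * n_chromosomes
    for i in range(p % n_chromosomes):
        per[i] += 1
    marker_ids, chroms, pos = [], [], []
    k = 0
    for c, m in enumerate(per, start=1):
        for j in range(m):
            marker_ids.append(f"SNP{k:04d}")
            chroms.append(f"{c}H")
            pos.append(j * spacing_cm)
            k += 1
    return GeneticMap(
        marker_ids=tuple(marker_ids),
        chromosomes=tuple(chroms),
        positions_cm=np.array(pos),
    )


def simulate_founders(
    gmap: GeneticMap, allele_freq: float = 0.5, seed: int = 0
) -> FounderHaplotypes:
    """Draw 8 founder haplotypes, alleles iid +1 with probability allele_freq.

    Markers monomorphic across the founders are resampled once and dropped
    (with their map entries) if still monomorphic.
    """
    if not (0.0 < allele_freq < 1.0):
        raise ValueError("allele_freq must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    vals = np.where(rng.random((N_FOUNDERS, gmap.p)) < allele_freq, 1, -1).astype(np.int8)
    mono = np.nonzero(vals.min(axis=0) == vals.max(axis=0))[0]
    if mono.size:
        vals[:, mono] = np.where(
            rng.random((N_FOUNDERS, mono.size)) < allele_freq, 1, -1
        ).astype(np.int8)
        still = mono[vals[:, mono].min(axis=0) == vals[:, mono].max(axis=0)]
        if still.size:
            keep = np.setdiff1d(np.arange(gmap.p), still)
            return FounderHaplotypes(values=vals[:, keep], map=gmap.subset(keep))
    return FounderHaplotypes(values=vals, map=gmap)


# ---------------------------------------------------------------------------
# Meiosis and the crossing funnel
# ---------------------------------------------------------------------------

def _recomb_probs(gmap: GeneticMap) -> np.ndarray:
    """Per-interval recombination probability (Haldane); 0.5 across chromosome breaks."""
    gaps = np.diff(gmap.positions_cm)
    r = 0.5 * (1.0 - np.exp(-2.0 * gaps / 100.0))
    breaks = np.array(
        [gmap.chromosomes[i] != gmap.chromosomes[i + 1] for i in range(gmap.p - 1)]
    )
    r[breaks] = 0.5
    return r


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, rec: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid (hap_a, hap_b); crossover per interval w.p. rec."""
    p = hap_a.size
    switch = np.empty(p, dtype=bool)
    switch[0] = rng.random() < 0.5  # random starting haplotype
    switch[1:] = rng.random(p - 1) < rec
    origin = np.logical_xor.accumulate(switch)
    return np.where(origin, hap_b, hap_a)


def simulate_magic_dh(
    founders: FounderHaplotypes, n_lines: int, seed: int = 0
) -> GenotypeMatrix:
    """Simulate DH lines through the fixed eight-way funnel.

    Per line: a gamete from each two-way F1, two four-way individuals, one
    eight-way individual, and a single doubled gamete; seven meioses total.
    Output is fully homozygous ±1 (one value per locus).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    rec = _recomb_probs(founders.map)
    f = founders.values
    out = np.empty((n_lines, founders.p), dtype=np.int8)
    for i in range(n_lines):
        g12 = _meiosis(f[0], f[1], rec, rng)
        g34 = _meiosis(f[2], f[3], rec, rng)
        g56 = _meiosis(f[4], f[5], rec, rng)
        g78 = _meiosis(f[6], f[7], rec, rng)
        g1234 = _meiosis(g12, g34, rec, rng)
        g5678 = _meiosis(g56, g78, rec, rng)
        out[i] = _meiosis(g1234, g5678, rec, rng)  # doubled gamete
    return GenotypeMatrix(
        line_ids=tuple(f"DH{i+1:04d}" for i in range(n_lines)),
        marker_ids=founders.map.marker_ids,
        values=out,
    )


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(G: GenotypeMatrix, truth: SimTruth, seed: int = 0) -> PhenotypeVector:
    """y = β0 + Σ mains + Σ pair products + Σ trio products + N(0, σ²)."""
    x = G.values.astype(np.float64)
    y = np.full(G.n, truth.intercept, dtype=np.float64)
    for j, beta in truth.main_effects:
        y += beta * x[:, j]
    for (k, l), beta in truth.pair_effects:
        y += beta * x[:, k] * x[:, l]
    for (j, k, l), beta in truth.trio_effects:
        y += beta * x[:, j] * x[:, k] * x[:, l]
    rng = np.random.default_rng(seed)
    if truth.noise_sd > 0:
        y += rng.normal(0.0, truth.noise_sd, size=G.n)
    return PhenotypeVector(line_ids=G.line_ids, values=y)


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

def _balanced_marker_near(
    G: GenotypeMatrix, gmap: GeneticMap, chrom: str, pos: float, window_cm: float = 15.0
) -> int:
    """Marker on `chrom` near `pos` cM whose coded column is closest to mean zero.

    Product pseudomarkers are orthogonal to their constituent markers only
    when the partners' coded columns have (near-)zero mean, so planted
    interaction effects are placed on frequency-balanced markers; otherwise a
    pure interaction would also induce genuine marginal main effects.
    """
    means = np.abs(G.values.astype(np.float64).mean(axis=0))
    idx = [
        i
        for i, c in enumerate(gmap.chromosomes)
        if c == chrom and abs(gmap.positions_cm[i] - pos) <= window_cm
    ]
    if not idx:
        idx = [i for i, c in enumerate(gmap.chromosomes) if c == chrom]
    if not idx:
        raise ValueError(f"no markers on chromosome {chrom}")
    return min(idx, key=lambda i: (means[i], abs(gmap.positions_cm[i] - pos)))


def make_fixture(preset: str, seed: int = 0) -> SimDataset:
    """Build a named simulated dataset with a known architecture.

    ``null``: n=300, p=500, no genetic effects, noise_sd=1.
    ``recovery_main``: null plus 3 main effects {+2.0, −1.5, +1.0} days on
    distinct chromosomes.
    ``recovery_epistasis``: recovery_main plus 2 pairwise effects
    {+1.5, −1.5} and one trio effect {+2.0} on markers disjoint from the
    main-effect QTL.
    ``duplicates``: recovery_main plus 20 exact-copy marker columns.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    n_lines, p = 300, 500
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    gmap = default_map(p=p)
    founders = simulate_founders(gmap, allele_freq=0.5, seed=sub[0])
    G = simulate_magic_dh(founders, n_lines=n_lines, seed=sub[1])
    gmap = founders.map

    mains: tuple[tuple[int, float], ...] = ()
    pairs: tuple[tuple[tuple[int, int], float], ...] = ()
    trios: tuple[tuple[tuple[int, int, int], float], ...] = ()
    mid = 70.0  # mid-chromosome position on the default 2 cM map
    pick = lambda chrom, pos: _balanced_marker_near(G, gmap, chrom, pos)
    if preset in ("recovery_main", "recovery_epistasis", "duplicates"):
        mains = (
            (pick("1H", mid), 2.0),
            (pick("2H", mid), -1.5),
            (pick("3H", mid), 1.0),
        )
    if preset == "recovery_epistasis":
        p1 = tuple(sorted((pick("4H", 20.0), pick("5H", 20.0))))
        p2 = tuple(sorted((pick("4H", 110.0), pick("6H", 40.0))))
        t1 = tuple(sorted((
            pick("5H", 110.0),
            pick("6H", 110.0),
            pick("7H", 70.0),
        )))
        pairs = ((p1, 1.5), (p2, -1.5))
        trios = ((t1, 2.0),)

    truth = SimTruth(
        intercept=80.0,
        main_effects=mains,
        pair_effects=pairs,
        trio_effects=trios,
        noise_sd=1.0,
    )
    pheno = simulate_phenotype(G, truth, seed=sub[2])

    if preset == "duplicates":
        # copy 20 evenly spread markers, inserting each copy right after its
        # original so the column order still follows the map
        originals = np.linspace(5, G.p - 6, 20).round().astype(int)
        new_ids: list[str] = []
        new_chrom: list[str] = []
        new_pos: list[float] = []
        values = []
        for j in range(G.p):
            values.append(G.values[:, j])
            new_ids.append(G.marker_ids[j])
            new_chrom.append(gmap.chromosomes[j])
            new_pos.append(float(gmap.positions_cm[j]))
            if j in originals:
                values.append(G.values[:, j].copy())
                new_ids.append(G.marker_ids[j] + "_dup")
                new_chrom.append(gmap.chromosomes[j])
                new_pos.append(float(gmap.positions_cm[j]))
        G = GenotypeMatrix(
            line_ids=G.line_ids,
            marker_ids=tuple(new_ids),
            values=np.column_stack(values),
        )
        gmap = GeneticMap(
            marker_ids=tuple(new_ids),
            chromosomes=tuple(new_chrom),
            positions_cm=np.array(new_pos),
        )
        # remap truth indices past the inserted copies
        shift = lambda j: j + int((originals < j).sum())
        truth = SimTruth(
            intercept=truth.intercept,
            main_effects=tuple((shift(j), b) for j, b in truth.main_effects),
            pair_effects=truth.pair_effects,
            trio_effects=truth.trio_effects,
            noise_sd=truth.noise_sd,
        )

    return SimDataset(
        genotypes=G, phenotypes=pheno, map=gmap, truth=truth,
        seed=int(seed), preset=preset,
    )
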