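"""Staged main-effect / two-way / three-way QTL pipeline.

The stages communicate only through residuals, so interaction effects are
never masked by (or refit jointly with) the main effects:

1. fit all markers jointly with the shrinkage model; select main QTL;
2. residual E1 = y − β̄0 − X β̄ over ALL markers;
3. screen all pairwise product pseudomarkers against E1, keep the top d;
4. fit the d pseudo-columns on E1; select interacting pairs;
5. residual E2 = E1 − (pseudo-design reconstruction);
6. screen all three-way products against E2, keep the top t;
7. fit, select candidate trios, and confirm each by the nested F-test on
   the original phenotype at α = 1e−5.

Selected pairs are annotated with the LD r² of their two markers and flagged
as spurious when r² exceeds the LD window threshold (default 0.8): a "pair"
of near-identical markers is an LD artefact, not epistasis.  Selected main
markers within one LD window are merged into a single QTL region indexed by
the strongest marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .gibbs_arm import (
    ArmConfig,
    PosteriorSummary,
    SelectionRule,
    compute_residuals,
    run_chains,
    select_qtl,
)
from .io_qc import (
    GeneticMap,
    GenotypeMatrix,
    PhenotypeVector,
    QcReport,
    align_phenotype,
    ld_r2,
    remove_duplicate_markers,
)
from .sis_screen import PseudoMarkerIndex, ScreenResult, pseudo_column, screen_interactions
from .threeway_ftest import FTestResult, trio_ftest

logger = logging.getLogger("magicqtl")

__all__ = [
    "PipelineConfig",
    "StageResult",
    "QtlReport",
    "run_main_stage",
    "run_twoway_stage",
    "run_threeway_stage",
    "flag_ld_spurious",
    "full_pipeline",
    "write_report",
]

#: chain-length presets: full-scale for real analyses, desk-scale for
#: simulation studies and tests
PRESETS = {
    "full": {"iterations": 50_000, "burn_in": 10_000, "n_chains": 5},
    "desk": {"iterations": 5_000, "burn_in": 1_000, "n_chains": 5},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the staged analysis, with study defaults."""

    preset: str = "full"
    iterations: int | None = None  # override preset if set
    burn_in: int | None = None
    n_chains: int | None = None
    d: int = 1000  # two-way pseudomarkers retained by SIS
    t: int = 1000  # three-way pseudomarkers retained by SIS
    duplicate_r_threshold: float = 0.99
    ld_r2_threshold: float = 0.8
    ftest_alpha: float = 1e-5
    ftest_on_raw_phenotype: bool = True
    selection_alpha: float = 0.05
    effect_threshold: float | None = None  # absolute override, in response units
    variance_floor: float = 1e-10
    residual_floor_fraction: float = 0.1
    master_seed: int = 2024

    def arm_config(self, stage_index: int) -> ArmConfig:
        preset = PRESETS[self.preset]
        iterations = self.iterations or preset["iterations"]
        burn_in = self.burn_in if self.burn_in is not None else preset["burn_in"]
        n_chains = self.n_chains or preset["n_chains"]
        seeds = tuple(
            int(
                np.random.SeedSequence(
                    [self.master_seed, stage_index, chain]
                ).generate_state(1)[0]
                % (2**31 - 1)
            )
            for chain in range(n_chains)
        )
        return ArmConfig(
            iterations=iterations,
            burn_in=burn_in,
            n_chains=n_chains,
            seeds=seeds,
            variance_floor=self.variance_floor,
            residual_floor_fraction=self.residual_floor_fraction,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass(frozen=True)
class StageResult:
    stage: str  # main | twoway | threeway
    design_columns: tuple  # marker indices or PseudoMarkerIndex tuples
    summary: PosteriorSummary
    selected: tuple[int, ...]  # positions into design_columns
    residual: np.ndarray
    screen: ScreenResult | None = None
    effect_threshold: float = 0.0


@dataclass(frozen=True)
class QtlReport:
    main_qtl: tuple[dict, ...]
    twoway_qtl: tuple[dict, ...]
    threeway_qtl: tuple[dict, ...]
    threeway_candidates: tuple[dict, ...]
    qc: QcReport
    provenance: dict
    stages: tuple[StageResult, ...] = field(default=(), repr=False)


def _selection_rule(
    cfg: PipelineConfig, summary: PosteriorSummary, n: int
) -> SelectionRule:
    """Effect threshold for consensus QTL calls.

    Default: a Bonferroni-corrected z-quantile on the sampling standard
    error of one effect, z_{alpha/2q} * sqrt(sigma0_bar^2 / n), using the
    residual variance estimated by the same fit.  This references the
    threshold to the NOISE level rather than the response spread, so a
    pure-noise response yields no calls while effects several standard
    errors large survive.  ``cfg.effect_threshold`` overrides it with an
    absolute value in response units (days).
    """
    if cfg.effect_threshold is not None:
        return SelectionRule(effect_threshold=cfg.effect_threshold,
                             require_all_chains=True)
    q = max(summary.q, 1)
    z = float(stats.norm.isf(cfg.selection_alpha / (2 * q)))
    sigma0_bar = float(np.mean([c.sigma0_sq_mean for c in summary.chains]))
    thr = float(z * np.sqrt(sigma0_bar / n))
    return SelectionRule(effect_threshold=max(thr, float(np.finfo(float).tiny)),
                         require_all_chains=True)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_main_stage(G: GenotypeMatrix, y: np.ndarray, config: PipelineConfig) -> StageResult:
    """Joint shrinkage fit of all markers; select main QTL; residual E1."""
    X = G.values.astype(np.float64)
    arm = config.arm_config(stage_index=0)
    logger.info("main stage: %d markers, %d chains × %d iterations",
                G.p, arm.n_chains, arm.iterations)
    summary = run_chains(X, y, arm)
    rule = _selection_rule(config, summary, G.n)
    selected = tuple(select_qtl(summary, rule))
    residual = compute_residuals(y, X, summary, columns=selected)
    return StageResult(
        stage="main", design_columns=tuple(range(G.p)), summary=summary,
        selected=selected, residual=residual, effect_threshold=rule.effect_threshold,
    )


def _pseudo_design(G: GenotypeMatrix, indices: Sequence[PseudoMarkerIndex]) -> np.ndarray:
    if not indices:
        return np.empty((G.n, 0))
    return np.column_stack([pseudo_column(G, idx) for idx in indices])


def run_twoway_stage(G: GenotypeMatrix, E1: np.ndarray, config: PipelineConfig) -> StageResult:
    """SIS over pairs on E1, shrinkage fit of the top d, residual E2."""
    screen = screen_interactions(G, E1, order=2, keep=config.d)
    cols = tuple(h.index for h in screen.hits)
    X = _pseudo_design(G, cols)
    arm = config.arm_config(stage_index=1)
    logger.info("two-way stage: %d of %d pairs retained", len(cols), screen.n_evaluated)
    summary = run_chains(X, E1, arm)
    rule = _selection_rule(config, summary, G.n)
    selected = tuple(select_qtl(summary, rule))
    residual = compute_residuals(E1, X, summary, columns=selected)
    return StageResult(
        stage="twoway", design_columns=cols, summary=summary,
        selected=selected, residual=residual, screen=screen,
        effect_threshold=rule.effect_threshold,
    )


def run_threeway_stage(
    G: GenotypeMatrix,
    y: np.ndarray,
    E2: np.ndarray,
    config: PipelineConfig,
) -> tuple[StageResult, list[FTestResult]]:
    """SIS over trios on E2, shrinkage fit of the top t, F-test confirmation."""
    screen = screen_interactions(G, E2, order=3, keep=config.t)
    cols = tuple(h.index for h in screen.hits)
    X = _pseudo_design(G, cols)
    arm = config.arm_config(stage_index=2)
    logger.info("three-way stage: %d of %d trios retained", len(cols), screen.n_evaluated)
    summary = run_chains(X, E2, arm)
    rule = _selection_rule(config, summary, G.n)
    selected = tuple(select_qtl(summary, rule))
    residual = compute_residuals(E2, X, summary)
    ftest_response = y if config.ftest_on_raw_phenotype else E2
    ftests = [
        trio_ftest(ftest_response, G, cols[k].indices, alpha=config.ftest_alpha)
        for k in selected
    ]
    stage = StageResult(
        stage="threeway", design_columns=cols, summary=summary,
        selected=selected, residual=residual, screen=screen,
        effect_threshold=rule.effect_threshold,
    )
    return stage, ftests


def flag_ld_spurious(
    pairs: Sequence[PseudoMarkerIndex],
    G: GenotypeMatrix,
    r2_threshold: float = 0.8,
) -> list[dict]:
    """Annotate selected pairs with LD r²; flag spurious when r² > threshold."""
    out = []
    for idx in pairs:
        a, b = idx.indices
        r2 = ld_r2(G, a, b)
        out.append({"pair": (a, b), "ld_r2": r2, "spurious": bool(r2 > r2_threshold)})
    return out


def _merge_main_regions(
    selected: Sequence[int],
    effects: np.ndarray,
    G: GenotypeMatrix,
    r2_threshold: float,
) -> list[list[int]]:
    """Union-find grouping of selected main markers within one LD window."""
    sel = list(selected)
    parent = {j: j for j in sel}

    def find(j):
        while parent[j] != j:
            parent[j] = parent[parent[j]]
            j = parent[j]
        return j

    for i, a in enumerate(sel):
        for b in sel[i + 1:]:
            if ld_r2(G, a, b) > r2_threshold:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for j in sel:
        groups.setdefault(find(j), []).append(j)
    ordered = []
    for members in groups.values():
        members.sort(key=lambda j: (-abs(effects[j]), j))
        ordered.append(members)
    ordered.sort(key=lambda ms: ms[0])
    return ordered


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def full_pipeline(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    gmap: GeneticMap,
    config: PipelineConfig | None = None,
) -> QtlReport:
    """QC → main stage → two-way stage (+LD flags) → three-way stage (+F-test)."""
    config = config or PipelineConfig()
    pheno = align_phenotype(genotypes, phenotypes)
    y = pheno.values

    try:
        G, qc = remove_duplicate_markers(genotypes, config.duplicate_r_threshold)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc
    kept = list(qc.kept_marker_ids)
    kept_map = gmap.subset([gmap.marker_ids.index(m) for m in kept])
    logger.info("QC: removed %d duplicates, %d monomorphic; %d markers kept",
                len(qc.removed_marker_ids), len(qc.monomorphic_marker_ids), G.p)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    main = _stage("main", lambda: run_main_stage(G, y, config))
    twoway = _stage("twoway", lambda: run_twoway_stage(G, main.residual, config))
    threeway, ftests = _stage(
        "threeway", lambda: run_threeway_stage(G, y, twoway.residual, config)
    )

    # --- report assembly ------------------------------------------------
    beta = main.summary.beta_bar
    main_rows = []
    for region in _merge_main_regions(main.selected, beta, G, config.ld_r2_threshold):
        j = region[0]
        chrom, pos = kept_map.chromosomes[j], float(kept_map.positions_cm[j])
        main_rows.append({
            "marker": G.marker_ids[j],
            "chromosome": chrom,
            "position_cM": pos,
            "effect_days": float(beta[j]),
            "region_markers": tuple(G.marker_ids[k] for k in region),
        })

    pair_cols = [twoway.design_columns[k] for k in twoway.selected]
    ld_info = flag_ld_spurious(pair_cols, G, config.ld_r2_threshold)
    pair_rows = []
    for k, info in zip(twoway.selected, ld_info):
        a, b = twoway.design_columns[k].indices
        pair_rows.append({
            "marker_1": G.marker_ids[a],
            "marker_2": G.marker_ids[b],
            "position_1": f"{kept_map.chromosomes[a]}:{kept_map.positions_cm[a]:g}",
            "position_2": f"{kept_map.chromosomes[b]}:{kept_map.positions_cm[b]:g}",
            "effect_days": float(twoway.summary.beta_bar[k]),
            "ld_r2": info["ld_r2"],
            "spurious_ld": info["spurious"],
        })

    trio_candidates = []
    trio_rows = []
    for k, ft in zip(threeway.selected, ftests):
        a, b, c = threeway.design_columns[k].indices
        row = {
            "marker_1": G.marker_ids[a],
            "marker_2": G.marker_ids[b],
            "marker_3": G.marker_ids[c],
            "effect_days": float(threeway.summary.beta_bar[k]),
            "f_stat": ft.f_stat,
            "df2": ft.df2,
            "p_value": ft.p_value,
            "significant": ft.significant,
            "testable": ft.testable,
        }
        trio_candidates.append(row)
        if ft.significant:
            trio_rows.append(row)

    arm0 = config.arm_config(0)
    provenance = {
        "config": asdict(config),
        "chain_seeds": {
            stage: list(config.arm_config(i).seeds)
            for i, stage in enumerate(("main", "twoway", "threeway"))
        },
        "iterations": arm0.iterations,
        "burn_in": arm0.burn_in,
        "n_chains": arm0.n_chains,
        "n_lines": G.n,
        "markers_in": genotypes.p,
        "markers_kept": G.p,
        "duplicates_removed": len(qc.removed_marker_ids),
        "monomorphic_removed": len(qc.monomorphic_marker_ids),
        "effect_thresholds": {
            "main": main.effect_threshold,
            "twoway": twoway.effect_threshold,
            "threeway": threeway.effect_threshold,
        },
    }
    return QtlReport(
        main_qtl=tuple(main_rows),
        twoway_qtl=tuple(pair_rows),
        threeway_qtl=tuple(trio_rows),
        threeway_candidates=tuple(trio_candidates),
        qc=qc,
        provenance=provenance,
        stages=(main, twoway, threeway),
    )


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------

def _write_table(rows: Sequence[dict], path: Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        if not rows:
            fh.write("")
            return
        cols = list(rows[0].keys())
        fh.write(sep.join(cols) + "\n")
        for row in rows:
            fh.write(sep.join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    if isinstance(v, tuple):
        return ",".join(str(x) for x in v)
    return str(v)


def write_report(report: QtlReport, outdir: str | Path) -> None:
    """Emit delimited QTL tables plus a machine-readable run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_table(list(report.main_qtl), outdir / "main_qtl.tsv")
    _write_table(list(report.twoway_qtl), outdir / "twoway_qtl.tsv")
    _write_table(list(report.threeway_qtl), outdir / "threeway_qtl.tsv")
    _write_table(list(report.threeway_candidates), outdir / "threeway_candidates.tsv")
    manifest = dict(report.provenance)
    manifest["qc"] = {
        "removed": list(report.qc.removed_marker_ids),
        "monomorphic": list(report.qc.monomorphic_marker_ids),
        "threshold": report.qc.threshold_used,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def report_text(report: QtlReport) -> str:
    """Deterministic single-string rendering (used for byte-identity checks)."""
    parts = []
    for name, rows in (
        ("main_qtl", report.main_qtl),
        ("twoway_qtl", report.twoway_qtl),
        ("threeway_qtl", report.threeway_qtl),
        ("threeway_candidates", report.threeway_candidates),
    ):
        parts.append(f"## {name}")
        for row in rows:
            parts.append("\t".join(f"{k}={_fmt(v)}" for k, v in row.items()))
    parts.append("## provenance")
    parts.append(yaml.safe_dump(report.provenance, sort_keys=True))
    return "\n".join(parts)
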