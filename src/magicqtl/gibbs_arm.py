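"""Bayesian multilocus shrinkage regression fitted by Gibbs sampling.

The model is y_i = β0 + Σ_j x_ij β_j + e_i with e_i ~ N(0, σ0²) and an
automatic-relevance-determination prior: each effect gets its own variance,
β_j | σ_j² ~ N(0, σ_j²) with the scale-invariant Jeffreys prior
p(σ_j²) ∝ 1/σ_j², p(σ0²) ∝ 1/σ0², and a flat prior on β0.  Effects the data
do not support are shrunk essentially to zero, which is what lets the model
handle far more predictors than observations.

Full conditionals (systematic scan, column order):

    β0 | ·   ~ N( mean(y - Xβ), σ0²/n )
    β_j | ·  ~ N( (x_j·r / σ0²)/c, 1/c ),  c = n/σ0² + 1/σ_j²
               with partial residual r = y - β0 - Σ_{k≠j} x_k β_k
               (x_j·x_j = n exactly for ±1 coding)
    σ_j² | · ~ Inv-Gamma(1/2, β_j²/2), floored at ``variance_floor``
    σ0² | ·  ~ Inv-Gamma(n/2, SSE/2)

Several chains with distinct seeds are run and their posterior-mean effects
averaged; a column counts as a QTL only if it clears the effect threshold in
every chain (consensus selection), which guards against the chain-to-chain
instability that collinear markers cause.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "ArmConfig",
    "ChainSummary",
    "PosteriorSummary",
    "SelectionRule",
    "gibbs_chain",
    "run_chains",
    "select_qtl",
    "compute_residuals",
    "write_posterior_summary",
]

_DEFAULT_SEEDS = (101, 211, 307, 401, 503)


@dataclass(frozen=True)
class ArmConfig:
    """Sampler settings.

    ``iterations``/``burn_in`` default to the full-scale 50,000 / 10,000;
    posterior means use iterations burn_in+1 … iterations with no thinning.
    ``fixed_effect_variance`` pins every σ_j² (ridge/debug mode) and
    ``fixed_residual_variance`` pins σ0²; both default off.
    """

    iterations: int = 50_000
    burn_in: int = 10_000
    n_chains: int = 5
    seeds: tuple[int, ...] = _DEFAULT_SEEDS
    variance_floor: float = 1e-10
    residual_floor_fraction: float = 0.1
    fixed_effect_variance: float | None = None
    fixed_residual_variance: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if len(self.seeds) < self.n_chains:
            raise ValueError("need one seed per chain")
        chain_seeds = self.seeds[: self.n_chains]
        if len(set(chain_seeds)) != self.n_chains:
            raise ValueError("chain seeds must be distinct")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if not (0.0 <= self.residual_floor_fraction < 1.0):
            raise ValueError("residual_floor_fraction must be in [0, 1)")

    def with_seeds(self, seeds: tuple[int, ...]) -> "ArmConfig":
        return ArmConfig(
            iterations=self.iterations,
            burn_in=self.burn_in,
            n_chains=len(seeds),
            seeds=tuple(seeds),
            variance_floor=self.variance_floor,
            residual_floor_fraction=self.residual_floor_fraction,
            fixed_effect_variance=self.fixed_effect_variance,
            fixed_residual_variance=self.fixed_residual_variance,
        )


@dataclass(frozen=True)
class ChainSummary:
    beta0_mean: float
    beta_means: np.ndarray  # (q,)
    sigma0_sq_mean: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "beta_means", np.asarray(self.beta_means, dtype=np.float64)
        )
        if self.sigma0_sq_mean <= 0:
            raise ValueError("sigma0_sq_mean must be positive")


@dataclass(frozen=True)
class PosteriorSummary:
    chains: tuple[ChainSummary, ...]
    beta0_bar: float
    beta_bar: np.ndarray  # (q,) cross-chain average

    @property
    def q(self) -> int:
        return self.beta_bar.size


@dataclass(frozen=True)
class SelectionRule:
    """Consensus QTL call: |per-chain mean effect| ≥ threshold in all chains."""

    effect_threshold: float
    require_all_chains: bool = True

    def __post_init__(self) -> None:
        if self.effect_threshold <= 0:
            raise ValueError("effect_threshold must be positive")


# ---------------------------------------------------------------------------
# Sampler kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_kernel(X, y, iterations, burn_in, seed, variance_floor,
                  residual_floor, fixed_eff_var, fixed_res_var):  # pragma: no cover - numba
    np.random.seed(seed)
    n, q = X.shape
    beta0 = y.mean()
    beta = np.zeros(q)
    # Effect variances start at the floor: every effect begins excluded and
    # must be recruited by the data.  Starting them large instead makes the
    # first sweeps act like unpenalized least squares, which for q >= n
    # drives the chain into a quasi-absorbing interpolation state (residual
    # variance collapses to ~0 and staged residuals lose all signal).
    sigma_j2 = np.full(q, variance_floor)
    if fixed_eff_var > 0.0:
        for j in range(q):
            sigma_j2[j] = fixed_eff_var
    sigma0 = fixed_res_var if fixed_res_var > 0.0 else y.var()
    if sigma0 <= 0.0:
        sigma0 = 1.0

    r = y - beta0  # full residual y - beta0 - X beta (beta starts at 0)
    acc_b0 = 0.0
    acc_beta = np.zeros(q)
    acc_s0 = 0.0
    n_keep = 0

    for it in range(iterations):
        # intercept (flat prior)
        m = beta0 + r.sum() / n
        new_b0 = np.random.normal(m, np.sqrt(sigma0 / n))
        delta0 = new_b0 - beta0
        for i in range(n):
            r[i] -= delta0
        beta0 = new_b0

        for j in range(q):
            xr = 0.0
            for i in range(n):
                xr += X[i, j] * r[i]
            xr += n * beta[j]  # add back own contribution: x_j · partial residual
            c = n / sigma0 + 1.0 / sigma_j2[j]
            mean_j = (xr / sigma0) / c
            new_bj = np.random.normal(mean_j, np.sqrt(1.0 / c))
            d = new_bj - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
            beta[j] = new_bj

            if fixed_eff_var <= 0.0:
                gdraw = np.random.gamma(0.5, 1.0)
                if gdraw > 0.0:
                    s2 = (beta[j] * beta[j] / 2.0) / gdraw
                else:
                    s2 = 1e300
                if not np.isfinite(s2) or s2 > 1e300:
                    s2 = 1e300
                if s2 < variance_floor:
                    s2 = variance_floor
                sigma_j2[j] = s2

        if fixed_res_var <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            gdraw = np.random.gamma(n / 2.0, 1.0)
            sigma0 = (sse / 2.0) / gdraw
            # Floor analogous to variance_floor: the joint posterior also
            # degenerates at sigma0 -> 0 (perfect interpolation), which a
            # design wider than n can reach; the floor keeps the likelihood
            # from rewarding it.
            if sigma0 < residual_floor:
                sigma0 = residual_floor

        if (it + 1) % 256 == 0:
            # refresh residual to stop incremental-update rounding drift
            for i in range(n):
                acc = y[i] - beta0
                for j in range(q):
                    acc -= X[i, j] * beta[j]
                r[i] = acc

        if it >= burn_in:
            acc_b0 += beta0
            for j in range(q):
                acc_beta[j] += beta[j]
            acc_s0 += sigma0
            n_keep += 1

    return acc_b0 / n_keep, acc_beta / n_keep, acc_s0 / n_keep


def _as_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError("response length must match design rows")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    return X, y


def gibbs_chain(X: np.ndarray, y: np.ndarray, config: ArmConfig, seed: int) -> ChainSummary:
    """One Gibbs chain; identical seed gives bit-identical output."""
    X, y = _as_design(X, y)
    residual_floor = config.residual_floor_fraction * float(np.var(y))
    b0, b, s0 = _gibbs_kernel(
        X,
        y,
        config.iterations,
        config.burn_in,
        int(seed),
        config.variance_floor,
        residual_floor,
        -1.0 if config.fixed_effect_variance is None else float(config.fixed_effect_variance),
        -1.0 if config.fixed_residual_variance is None else float(config.fixed_residual_variance),
    )
    return ChainSummary(beta0_mean=float(b0), beta_means=b, sigma0_sq_mean=float(s0),
                        seed=int(seed))


def run_chains(X: np.ndarray, y: np.ndarray, config: ArmConfig) -> PosteriorSummary:
    """Run ``n_chains`` independent chains and average their posterior means."""
    chains = tuple(
        gibbs_chain(X, y, config, seed) for seed in config.seeds[: config.n_chains]
    )
    beta_bar = np.mean([c.beta_means for c in chains], axis=0)
    beta0_bar = float(np.mean([c.beta0_mean for c in chains]))
    return PosteriorSummary(chains=chains, beta0_bar=beta0_bar, beta_bar=beta_bar)


def select_qtl(summary: PosteriorSummary, rule: SelectionRule) -> list[int]:
    """Columns whose |per-chain mean effect| clears the threshold (all chains by default)."""
    flags = np.stack(
        [np.abs(c.beta_means) >= rule.effect_threshold for c in summary.chains]
    )
    mask = flags.all(axis=0) if rule.require_all_chains else flags.any(axis=0)
    return [int(j) for j in np.nonzero(mask)[0]]


def compute_residuals(
    y: np.ndarray,
    X: np.ndarray,
    summary: PosteriorSummary,
    columns: Sequence[int] | None = None,
) -> np.ndarray:
    """Residual y - β̄0 - X β̄ using cross-chain-averaged estimates.

    By default the reconstruction uses all design columns.  ``columns``
    restricts it to a subset (the staged pipeline passes the selected QTL
    columns: with a screened design wider than n the fit is partly an
    in-sample interpolation, and subtracting every column's averaged effect
    would strip the residual of the very signal the next stage searches).
    """
    X, y = _as_design(X, y)
    if X.shape[1] != summary.q:
        raise ValueError("design width does not match summary")
    if columns is None:
        return y - summary.beta0_bar - X @ summary.beta_bar
    cols = list(columns)
    if not cols:
        return y - summary.beta0_bar
    return y - summary.beta0_bar - X[:, cols] @ summary.beta_bar[cols]


def write_posterior_summary(summary: PosteriorSummary, column_ids, path, sep: str = "\t") -> None:
    """Delimited table: column id, per-chain posterior means, cross-chain mean."""
    column_ids = list(column_ids)
    if len(column_ids) != summary.q:
        raise ValueError("column_ids length must match design width")
    with open(path, "w") as fh:
        header = ["column"] + [f"chain_{c.seed}" for c in summary.chains] + ["mean"]
        fh.write(sep.join(header) + "\n")
        for j, cid in enumerate(column_ids):
            row = [str(cid)]
            row += [f"{c.beta_means[j]:.10g}" for c in summary.chains]
            row.append(f"{summary.beta_bar[j]:.10g}")
            fh.write(sep.join(row) + "\n")
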