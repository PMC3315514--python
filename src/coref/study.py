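"""Monte-Carlo power studies and the regression baselines.

This module orchestrates replicated simulation experiments: for a grid of
generative conditions it repeatedly draws synthetic datasets, applies a
chosen test, and tabulates the power (fraction of replicates with
p < alpha) and the median observed coreferentiality coefficient.

Besides the coreferentiality permutation test, two classical baselines are
provided for comparison:

* PCA-score multiple regression — regress one test variable on the leading
  principal-component scores of the standardized reference matrix and use
  the overall F-test (full regression on all k reference columns is often
  infeasible due to collinearity);
* simple bivariate regression of x2 on x1 (equivalently the Pearson-r
  t-test), which ignores the reference data entirely.

Seeding is hierarchical and deterministic: a master seed spawns one seed
per condition, which spawns one (data, permutation) seed pair per
replicate, so any single replicate is reproducible in isolation and
results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import (
    TestPair,
    _as_reference_matrix,
    _as_vector,
    permutation_test,
)
from .exceptions import DimensionError, ParameterError
from .simulate import SimulationSpec, simulate_bivariate_baseline, simulate_dataset

__all__ = [
    "METHODS",
    "PowerCondition",
    "PowerResult",
    "pca_regression_test",
    "bivariate_regression_test",
    "run_power_condition",
    "run_grid",
    "results_table",
]

METHODS = (
    "coreferentiality",
    "pca_regression_10",
    "pca_regression_50",
    "bivariate_regression",
)


@dataclass(frozen=True)
class PowerCondition:
    """One cell of a power study: a generative spec plus a test method.

    ``spec.seed`` is ignored; replicate seeds are derived from the master
    seed passed to :func:`run_power_condition` / :func:`run_grid`.
    """

    spec: SimulationSpec
    n_sims: int = 100
    n_perm: int = 1000
    alpha: float = 0.05
    method: str = "coreferentiality"

    def __post_init__(self):
        if self.n_sims < 1:
            raise ParameterError(f"n_sims must be >= 1, got {self.n_sims}")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}, got {self.method!r}")


@dataclass(frozen=True)
class PowerResult:
    """Aggregated outcome of one power condition."""

    condition: PowerCondition
    power: float
    median_rc: float
    p_values: np.ndarray = field(repr=False)
    rc_values: np.ndarray = field(repr=False)
    seeds: list = field(repr=False, default_factory=list)


def pca_regression_test(x, Y, n_components: int) -> float:
    """Overall F-test p of regressing ``x`` on leading PCA scores of Y.

    The reference matrix is standardized column-wise (PCA on the
    correlation matrix) before extracting ``n_components`` score vectors;
    ``x`` is then fit by ordinary least squares on those scores and the
    regression's overall F-test p-value returned.
    """
    x = _as_vector(x, "x")
    mat, _ = _as_reference_matrix(Y, n_expected=len(x))
    n, k = mat.shape
    if not 1 <= n_components < min(n - 2, k):
        raise DimensionError(
            f"n_components must lie in [1, min(N-2, k)) = "
            f"[1, {min(n - 2, k)}), got {n_components}"
        )
    z = (mat - mat.mean(axis=0)) / mat.std(axis=0, ddof=1)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(z)

    # OLS of x on the scores; overall F-test of the regression
    X = np.column_stack([np.ones(n), scores])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    rss = float(resid @ resid)
    tss = float(((x - x.mean()) ** 2).sum())
    p_reg = n_components
    df_resid = n - p_reg - 1
    if rss <= 0.0:
        return float(np.finfo(float).tiny)
    f_stat = ((tss - rss) / p_reg) / (rss / df_resid)
    return float(stats.f.sf(f_stat, p_reg, df_resid))


def bivariate_regression_test(pair: TestPair, x2=None) -> float:
    """Two-sided p of the slope in an OLS regression of x2 on x1.

    Identical to the Pearson correlation t-test with N - 2 degrees of
    freedom.
    """
    if not isinstance(pair, TestPair):
        pair = TestPair(np.asarray(pair, dtype=float), np.asarray(x2, dtype=float))
    return float(stats.pearsonr(pair.x1, pair.x2).pvalue)


def _replicate_seeds(master_seed, n_sims: int):
    """Per-replicate (data_seed, perm_seed) pairs, each a 31-bit int."""
    ss = np.random.SeedSequence(master_seed)
    out = []
    for child in ss.spawn(n_sims):
        a, b = child.generate_state(2)
        out.append((int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF))
    return out


def run_power_condition(cond: PowerCondition, seed=None) -> PowerResult:
    """Run one power condition: n_sims independent datasets, one test each.

    For the coreferentiality method, the median of the observed R_C values
    across replicates is reported alongside the power; for the regression
    baselines the R_C column is NaN.
    """
    seeds = _replicate_seeds(seed, cond.n_sims)
    p_values = np.empty(cond.n_sims)
    rc_values = np.full(cond.n_sims, np.nan)
    spec = cond.spec

    for i, (data_seed, perm_seed) in enumerate(seeds):
        if cond.method == "bivariate_regression":
            pair = simulate_bivariate_baseline(
                spec.n, spec.delta, sigma=spec.sigma, seed=data_seed
            )
            p_values[i] = bivariate_regression_test(pair)
            continue
        ds = simulate_dataset(spec.with_seed(data_seed))
        if cond.method == "coreferentiality":
            res = permutation_test(
                ds.pair, ds.Y, n_perm=cond.n_perm, seed=perm_seed, exhaustive=False
            )
            p_values[i] = res.p_value
            rc_values[i] = res.r_c
        else:
            n_comp = 10 if cond.method == "pca_regression_10" else 50
            p_values[i] = pca_regression_test(ds.pair.x1, ds.Y, n_comp)

    power = float(np.mean(p_values < cond.alpha))
    median_rc = float(np.nanmedian(rc_values)) if np.any(np.isfinite(rc_values)) else float("nan")
    return PowerResult(
        condition=cond,
        power=power,
        median_rc=median_rc,
        p_values=p_values,
        rc_values=rc_values,
        seeds=seeds,
    )


def run_grid(conditions, seed=None) -> list[PowerResult]:
    """Run every condition of a grid with per-condition derived seeds."""
    conditions = list(conditions)
    if not conditions:
        raise ParameterError("empty condition grid")
    cond_seeds = [
        int(c.generate_state(1)[0]) & 0x7FFFFFFF
        for c in np.random.SeedSequence(seed).spawn(len(conditions))
    ]
    return [run_power_condition(c, s) for c, s in zip(conditions, cond_seeds)]


def results_table(results) -> pd.DataFrame:
    """Tidy one-row-per-condition table of a grid's results."""
    rows = []
    for r in results:
        s = r.condition.spec
        rows.append(
            {
                "method": r.condition.method,
                "n": s.n,
                "k": s.k,
                "delta": s.delta,
                "r_x": s.r_x,
                "mode": s.mode,
                "n_noise_vars": s.n_noise_vars,
                "include_x1_in_y": s.include_x1_in_y,
                "include_x2_in_y": s.include_x2_in_y,
                "n_sims": r.condition.n_sims,
                "n_perm": r.condition.n_perm,
                "alpha": r.condition.alpha,
                "power": r.power,
                "median_rc": r.median_rc,
            }
        )
    return pd.DataFrame(rows)


def plot_power_curves(table: pd.DataFrame, x: str = "n", hue: str = "delta",
                      path=None):
    """Simple line plot of power against one grid axis, one line per level
    of another.  Requires matplotlib; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for level, sub in table.groupby(hue):
        sub = sub.sort_values(x)
        ax.plot(sub[x], 100.0 * sub["power"], marker="o", label=f"{hue}={level}")
    ax.set_xlabel(x)
    ax.set_ylabel("power (% tests p < alpha)")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
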