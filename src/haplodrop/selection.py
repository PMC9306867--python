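"""Trajectory statistics and empirical neutrality tests against the gene-drop null.

Two summary statistics are computed per haplotype over the simulated-year
window:

* **slope** — ordinary least-squares slope of standing-population frequency
  on calendar year, sensitive to directional selection;
* **cumulative change** — the sum of absolute year-to-year frequency
  differences, sensitive to fluctuating selection (upper tail) and to
  selection holding a frequency unusually stable (lower tail).

Each observed statistic is referred to its gene-drop null distribution and
converted to empirical tail probabilities.  A haplotype whose observed
slope falls in the top (bottom) ``alpha_per_tail`` of simulated slopes is
classified as under positive (negative) directional selection; an extreme
upper (lower) cumulative change is classified as fluctuating (balancing)
selection.  Several labels may co-occur; none at all means the trajectory
is consistent with drift.

Tail probabilities use the raw counting estimator ``#{null >= obs}/n`` by
default, with ties counted as extreme in both tails; the bias-corrected
``(k+1)/(n+1)`` variant is selectable.  A tail of exactly zero is rendered
as ``"< 1/n_sim"`` in human-readable output while stored as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genedrop import GeneDropConfig, GeneDropResult, run_genedrop
from .haplotypes import HaplotypeSet
from .pedigree import Pedigree

__all__ = [
    "TrajectoryStatistics",
    "GeneDropTestResult",
    "slope_statistic",
    "cumulative_change_statistic",
    "empirical_tail_probabilities",
    "format_p",
    "classify_haplotype",
    "genedrop_test",
    "GeneDropTest",
    "plot_trajectories",
]

CLASSIFICATIONS = (
    "directional_positive",
    "directional_negative",
    "fluctuating",
    "balancing",
    "consistent_with_drift",
)


@dataclass(frozen=True)
class TrajectoryStatistics:
    haplotype: str
    slope: float
    cumulative_change: float


@dataclass
class GeneDropTestResult:
    """Per-haplotype observed statistics, null distributions and tail tests."""

    haplotype: str
    observed: TrajectoryStatistics
    null_slopes: np.ndarray
    null_cumulative: np.ndarray
    p_slope_lower: float
    p_slope_upper: float
    p_cum_lower: float
    p_cum_upper: float
    classification: tuple[str, ...]


def _clean(years, freqs) -> tuple[np.ndarray, np.ndarray]:
    years = np.asarray(years, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    keep = ~np.isnan(freqs)
    return years[keep], freqs[keep]


def slope_statistic(years: Sequence[float], freqs: Sequence[float]) -> float:
    """OLS slope of frequency on calendar year; undefined years dropped."""
    x, y = _clean(years, freqs)
    if len(y) < 2:
        raise ValueError("slope requires at least two defined frequencies")
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def cumulative_change_statistic(freqs: Sequence[float]) -> float:
    """Sum of absolute consecutive-year frequency differences (undefined dropped)."""
    y = np.asarray(freqs, dtype=float)
    y = y[~np.isnan(y)]
    if len(y) < 2:
        raise ValueError("cumulative change requires at least two defined frequencies")
    return float(np.abs(np.diff(y)).sum())


def empirical_tail_probabilities(
    observed: float,
    null_values: Sequence[float],
    estimator: str = "raw",
) -> tuple[float, float]:
    """(p_lower, p_upper) of the observed value within the simulated null.

    ``raw``: k/n with ties counted in both tails.  ``bias_corrected``:
    (k+1)/(n+1), which never returns exactly 0 and treats the observed
    value as one more exchangeable draw.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    k_lower = int((null <= observed).sum())
    k_upper = int((null >= observed).sum())
    n = null.size
    if estimator == "raw":
        return k_lower / n, k_upper / n
    if estimator == "bias_corrected":
        return (k_lower + 1) / (n + 1), (k_upper + 1) / (n + 1)
    raise ValueError(f"unknown tail estimator {estimator!r}")


def format_p(p: float, n_sim: int) -> str:
    """Human-readable empirical p; exact zeros become a resolution bound."""
    if p == 0.0:
        return f"< {1 / n_sim:g}"
    return f"{p:g}"


def classify_haplotype(
    p_slope_lower: float,
    p_slope_upper: float,
    p_cum_lower: float,
    p_cum_upper: float,
    alpha_per_tail: float = 0.025,
) -> tuple[str, ...]:
    """Closed-tail classification rule; co-occurring labels are all reported."""
    labels = []
    if p_slope_upper <= alpha_per_tail:
        labels.append("directional_positive")
    if p_slope_lower <= alpha_per_tail:
        labels.append("directional_negative")
    if p_cum_upper <= alpha_per_tail:
        labels.append("fluctuating")
    if p_cum_lower <= alpha_per_tail:
        labels.append("balancing")
    if not labels:
        labels.append("consistent_with_drift")
    return tuple(labels)


def _null_statistics(sim_freq: np.ndarray, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised slope and cumulative change per replicate and haplotype.

    ``sim_freq``: (n_sim, n_years, n_hap).  Years undefined (NaN across the
    stack) are dropped before both statistics, mirroring the scalar path.
    """
    defined = ~np.isnan(sim_freq[0, :, 0])
    x = years[defined].astype(float)
    f = sim_freq[:, defined, :]
    xc = x - x.mean()
    denom = xc @ xc
    fc = f - f.mean(axis=1, keepdims=True)
    slopes = np.einsum("y,ryk->rk", xc, fc) / denom
    cums = np.abs(np.diff(f, axis=1)).sum(axis=1)
    return slopes, cums


@dataclass
class GeneDropTest:
    """Container for a full gene-drop neutrality analysis."""

    results: list[GeneDropTestResult]
    run: GeneDropResult
    estimator: str
    alpha_per_tail: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = self.run.n_sim
        for r in self.results:
            rows.append(
                {
                    "haplotype": r.haplotype,
                    "obs_slope": r.observed.slope,
                    "obs_cum": r.observed.cumulative_change,
                    "p_slope_lower": r.p_slope_lower,
                    "p_slope_upper": r.p_slope_upper,
                    "p_cum_lower": r.p_cum_lower,
                    "p_cum_upper": r.p_cum_upper,
                    "p_slope_lower_str": format_p(r.p_slope_lower, n),
                    "p_slope_upper_str": format_p(r.p_slope_upper, n),
                    "p_cum_lower_str": format_p(r.p_cum_lower, n),
                    "p_cum_upper_str": format_p(r.p_cum_upper, n),
                    "classification": ",".join(r.classification),
                }
            )
        return pd.DataFrame(rows)

    def result_for(self, haplotype: str) -> GeneDropTestResult:
        for r in self.results:
            if r.haplotype == haplotype:
                return r
        raise KeyError(haplotype)


def genedrop_test(
    pedigree: Pedigree,
    diplotypes: Mapping[str, tuple[str, str]],
    hs: HaplotypeSet,
    config: GeneDropConfig,
    estimator: str = "raw",
    alpha_per_tail: float = 0.025,
) -> GeneDropTest:
    """Run the gene-drop and test every haplotype's trajectory against its null."""
    run = run_genedrop(pedigree, diplotypes, hs, config)
    null_slopes, null_cums = _null_statistics(run.sim_freq, run.years)
    results = []
    for k, hap in enumerate(run.haplotypes):
        obs_slope = slope_statistic(run.years, run.observed.freq[:, k])
        obs_cum = cumulative_change_statistic(run.observed.freq[:, k])
        psl, psu = empirical_tail_probabilities(obs_slope, null_slopes[:, k], estimator)
        pcl, pcu = empirical_tail_probabilities(obs_cum, null_cums[:, k], estimator)
        results.append(
            GeneDropTestResult(
                haplotype=hap,
                observed=TrajectoryStatistics(hap, obs_slope, obs_cum),
                null_slopes=null_slopes[:, k],
                null_cumulative=null_cums[:, k],
                p_slope_lower=psl,
                p_slope_upper=psu,
                p_cum_lower=pcl,
                p_cum_upper=pcu,
                classification=classify_haplotype(psl, psu, pcl, pcu, alpha_per_tail),
            )
        )
    return GeneDropTest(results=results, run=run, estimator=estimator, alpha_per_tail=alpha_per_tail)


def plot_trajectories(
    test: GeneDropTest,
    path: str,
    max_sim_lines: int = 200,
) -> None:
    """Panel per haplotype: simulated trajectories in grey, observed in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = test.run
    k = len(run.haplotypes)
    ncols = min(4, k)
    nrows = int(np.ceil(k / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False, sharex=True
    )
    show = min(max_sim_lines, run.n_sim)
    for j, hap in enumerate(run.haplotypes):
        ax = axes[j // ncols][j % ncols]
        for r in range(show):
            ax.plot(run.years, run.sim_freq[r, :, j], color="0.6", lw=0.4, alpha=0.3)
        ax.plot(run.years, run.observed.freq[:, j], color="crimson", lw=1.6)
        ax.set_title(
            f"{hap} ({','.join(test.result_for(hap).classification)})", fontsize=8
        )
        ax.set_ylabel("frequency", fontsize=7)
    for j in range(k, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.supxlabel("year")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
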