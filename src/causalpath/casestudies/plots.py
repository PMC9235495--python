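"""Figure reproductions: sampling-distribution boxplots and predictive densities."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_sampling_distribution", "plot_density_vs_observed", "plot_predictive_curves"]


def plot_sampling_distribution(result, ax=None):
    """Boxplots of the query estimates per training-set size, correct variant
    in orange and misspecified in blue, with the truth as a dashed line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    colors = {"correct": "tab:orange", "misspecified": "tab:blue"}
    ns = sorted(result.table["n"].unique())
    variants = [v for v in ("correct", "misspecified") if v in set(result.table["variant"])]
    width = 0.35
    for k, variant in enumerate(variants):
        tbl = result.table
        data = [
            tbl.loc[(tbl["variant"] == variant) & (tbl["n"] == n), "estimate"].to_numpy()
            for n in ns
        ]
        pos = np.arange(len(ns)) + (k - (len(variants) - 1) / 2) * width
        bp = ax.boxplot(data, positions=pos, widths=width * 0.9, patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(colors[variant])
            box.set_alpha(0.7)
    ax.axhline(result.truth, ls="--", color="k", lw=1, label="truth")
    ax.set_xticks(np.arange(len(ns)))
    ax.set_xticklabels([str(n) for n in ns])
    ax.set_xlabel("training replicates N")
    ax.set_ylabel("estimated interventional expectation")
    ax.set_title(result.case)
    ax.legend()
    return ax


def plot_density_vs_observed(estimate, observed_values=(), ax=None, label=None):
    """Posterior interventional density with observed interventional
    measurements overlaid as horizontal markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid, pdf = estimate.density()
    ax.plot(grid, pdf, lw=2, label=label or "estimated P(Y|do(x'))")
    for i, v in enumerate(observed_values):
        ax.axvline(v, ls="--", color="gray", lw=1,
                   label="observed interventional value" if i == 0 else None)
    ax.set_xlabel(estimate.outcomes[0])
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_predictive_curves(estimate, truth_draws=None, outcome=None, ax=None, max_curves=50):
    """Thin per-parameter-draw predictive densities (one per posterior theta)
    against the thick true interventional density."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    outcome = outcome or estimate.outcomes[0]
    draws = estimate.draws
    lo, hi = draws[outcome].min(), draws[outcome].max()
    if truth_draws is not None:
        lo, hi = min(lo, np.min(truth_draws)), max(hi, np.max(truth_draws))
    grid = np.linspace(lo, hi, 256)
    thetas = draws["_theta"].unique()[:max_curves]
    for s in thetas:
        x = draws.loc[draws["_theta"] == s, outcome].to_numpy()
        if x.std() > 1e-9:
            ax.plot(grid, stats.gaussian_kde(x, bw_method="silverman")(grid),
                    color="tab:blue", alpha=0.2, lw=0.7)
    if truth_draws is not None:
        ax.plot(grid, stats.gaussian_kde(np.asarray(truth_draws), bw_method="silverman")(grid),
                color="k", lw=2.5, label="truth")
        ax.legend()
    ax.set_xlabel(outcome)
    ax.set_ylabel("density")
    return ax
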