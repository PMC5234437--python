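"""Figure builders: stacked composition bars, ordination plots, group
comparison panels (box/violin/dot) and correlation graphics.

All functions return a matplotlib Figure; callers decide where to save.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import statsmodels.api as sm


def composition_plot(bins: pd.DataFrame, display_cutoff: float = 0.5,
                     sample_order=None) -> plt.Figure:
    """One stacked bar per sample from a bins x samples percentage table.

    Bins are stacked in descending order of grand-mean abundance; bins whose
    grand mean falls below ``display_cutoff`` percent are merged into an
    "Other" segment for display only (the underlying table is untouched).
    """
    data = bins[sample_order] if sample_order is not None else bins
    order = data.mean(axis=1).sort_values(ascending=False).index
    data = data.loc[order]
    if display_cutoff > 0:
        major = data.index[data.mean(axis=1) >= display_cutoff]
        minor = data.index.difference(major)
        if len(minor):
            other = data.loc[minor].sum(axis=0)
            data = pd.concat([data.loc[major], other.to_frame("Other").T])
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * data.shape[1]), 5))
    bottom = np.zeros(data.shape[1])
    cmap = plt.get_cmap("tab20")
    for i, bin_name in enumerate(data.index):
        vals = data.loc[bin_name].to_numpy(dtype=float)
        ax.bar(range(data.shape[1]), vals, bottom=bottom,
               label=str(bin_name), color=cmap(i % 20))
        bottom += vals
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=7)
    ax.set_ylabel("relative abundance (%)")
    ax.legend(fontsize=6, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    return fig


def ordination_plot(result, groups: pd.Series | None = None) -> plt.Figure:
    """Scatter of the first two ordination axes, colored by group.

    NMDS results are annotated with their stress; group membership draws a
    convex hull around each group when it has >= 3 samples.
    """
    coords = result.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    if groups is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=30)
    else:
        for g in pd.unique(groups):
            idx = [s for s in coords.index if groups.get(s) == g]
            pts = coords.loc[idx]
            sc = ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=30, label=str(g))
            if len(pts) >= 3:
                from scipy.spatial import ConvexHull, QhullError

                try:
                    hull = ConvexHull(pts.iloc[:, :2].to_numpy())
                    poly = pts.iloc[:, :2].to_numpy()[hull.vertices]
                    ax.fill(poly[:, 0], poly[:, 1], alpha=0.15,
                            color=sc.get_facecolor()[0])
                except QhullError:
                    pass
        ax.legend(fontsize=8)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    if result.method == "NMDS" and result.stress is not None:
        ax.set_title(f"NMDS (stress = {result.stress:.4f})")
    else:
        ax.set_title(result.method)
    fig.tight_layout()
    return fig


def comparison_plot(values: pd.DataFrame, groups: pd.Series, variable,
                    style: str = "box", p: float | None = None,
                    p_adj: float | None = None) -> plt.Figure:
    """Per-variable group panel in box, violin or dot style.

    Missing values are excluded; the per-group n annotation counts only
    non-missing observations, and raw/adjusted p-values are shown when
    provided.
    """
    if style not in {"box", "violin", "dot"}:
        raise ValueError(f"unknown style {style!r}")
    labels = list(pd.unique(groups))
    data = [values.loc[variable, groups.index[groups == g]].dropna().to_numpy()
            for g in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    positions = np.arange(1, len(labels) + 1)
    if style == "box":
        ax.boxplot([d for d in data], positions=positions)
    elif style == "violin":
        present = [i for i, d in enumerate(data) if len(d)]
        if present:
            ax.violinplot([data[i] for i in present],
                          positions=positions[present], showmedians=True)
    else:
        for pos, d in zip(positions, data):
            jitter = (np.arange(len(d)) - (len(d) - 1) / 2) * 0.04
            ax.plot(pos + jitter, d, "o", ms=5)
    ax.set_xticks(positions)
    ax.set_xticklabels(
        [f"{g}\n(n={len(d)})" for g, d in zip(labels, data)], fontsize=8
    )
    title = str(variable)
    if p is not None:
        title += f"  p={p:.3g}"
    if p_adj is not None:
        title += f"  p.adj={p_adj:.3g}"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    return fig


def correlation_matrix_plot(records: pd.DataFrame) -> plt.Figure:
    """Circle-matrix overview: circle size grows as raw p shrinks, color by
    the sign of r (blue positive, red negative)."""
    xs = sorted(records["var_x"].unique())
    ys = sorted(records["var_y"].unique())
    fig, ax = plt.subplots(figsize=(0.5 * len(ys) + 2, 0.5 * len(xs) + 2))
    for _, rec in records.iterrows():
        if not np.isfinite(rec["r"]):
            continue
        x, y = ys.index(rec["var_y"]), xs.index(rec["var_x"])
        p = rec["p"] if np.isfinite(rec["p"]) else 1.0
        size = 400 * (1 - p) ** 2 + 5
        ax.scatter(x, y, s=size, c="tab:blue" if rec["r"] >= 0 else "tab:red",
                   alpha=0.8)
    ax.set_xticks(range(len(ys)))
    ax.set_xticklabels(ys, rotation=90, fontsize=7)
    ax.set_yticks(range(len(xs)))
    ax.set_yticklabels(xs, fontsize=7)
    ax.invert_yaxis()
    fig.tight_layout()
    return fig


def correlation_scatter(x: np.ndarray, y: np.ndarray, record: pd.Series) -> plt.Figure:
    """Scatter of one variable pair with an OLS fit and 95% confidence band.

    Annotated with r, raw and adjusted p in the title and n_obs below the
    plot; axes are unit-free (the inputs are transformed values).
    """
    mask = np.isfinite(x) & np.isfinite(y)
    xv, yv = np.asarray(x)[mask], np.asarray(y)[mask]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(xv, yv, "o", ms=5)
    if len(xv) >= 3 and np.std(xv) > 0:
        model = sm.OLS(yv, sm.add_constant(xv)).fit()
        grid = np.linspace(xv.min(), xv.max(), 100)
        pred = model.get_prediction(sm.add_constant(grid))
        frame = pred.summary_frame(alpha=0.05)
        ax.plot(grid, frame["mean"], "k-", lw=2)
        ax.fill_between(grid, frame["mean_ci_lower"], frame["mean_ci_upper"],
                        color="gray", alpha=0.3)
        ax.plot(grid, frame["mean_ci_lower"], "k--", lw=0.8)
        ax.plot(grid, frame["mean_ci_upper"], "k--", lw=0.8)
    ax.set_title(
        f"{record['var_x']} vs {record['var_y']}: r={record['r']:.3f}, "
        f"p={record['p']:.3g}, p.adj={record['p_adj']:.3g}",
        fontsize=9,
    )
    ax.set_xlabel(str(record["var_x"]))
    ax.set_ylabel(str(record["var_y"]))
    ax.annotate(f"n = {int(record['n_obs'])}", xy=(0.5, -0.18),
                xycoords="axes fraction", ha="center", fontsize=8)
    fig.tight_layout()
    return fig
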