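"""Matplotlib renderers for diagrams, tradeoff curves, and diagnostics."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def render_diagram(diagram, path, title: str | None = None) -> None:
    """Space-time diagram as a PNG, one pixel per cell, time downward."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(diagram.rows, cmap="binary", interpolation="nearest", aspect="auto")
    ax.set_xlabel("cell")
    ax.set_ylabel("time")
    if title is None:
        meta = diagram.metadata
        title = f"rule {meta.get('rule', '?')} ({meta.get('regime', '?')})"
    ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_tradeoff(summary, path, sync_records=None) -> None:
    """EMIN step function with the alternative regime's (UN, E) scatter."""
    fig, ax = plt.subplots(figsize=(7, 5))
    m = summary.m
    edges = np.arange(m + 1) / m
    ax.step(edges[1:], summary.emin, where="pre", color="k", lw=1.5, label="sync EMIN")
    if sync_records is not None:
        from .computability import _un_e_arrays

        un_s, e_s = _un_e_arrays(sync_records)
        ax.plot(un_s, e_s, ".", color="0.6", ms=4, label="sync rules")
    broke = summary.break_flag
    ax.plot(summary.un_alt[~broke], summary.e_alt[~broke], "o", mfc="none",
            color="tab:blue", ms=4, label="alt (no break)")
    ax.plot(summary.un_alt[broke], summary.e_alt[broke], "o", color="tab:red",
            ms=4, label=f"alt (break, {summary.break_fraction:.0%})")
    ax.set_xlabel("normalized universality UN(r)")
    ax.set_ylabel("efficiency E(r)  (smaller = more efficient)")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_deviation_hist(summaries: dict, path, bins: int = 20) -> None:
    """Histogram of mean per-interval deviations for one or more regimes."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, summary in summaries.items():
        devs = list(summary.mean_deviation_by_interval.values())
        ax.hist(devs, bins=bins, alpha=0.6, label=label)
    ax.set_xlabel("mean deviation EMIN(k) − E(r) per interval")
    ax.set_ylabel("frequency")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_break_bars(table, path, at_fraction: float | None = None) -> None:
    """Per-p break fractions as bars sorted by size, optional AT bar at right."""
    table = table.sort_values("break_fraction")
    labels = [f"p={p:.2f}" for p in table["p"]]
    values = list(table["break_fraction"])
    colors = ["tab:orange"] * len(values)
    if at_fraction is not None:
        labels.append("asyn-tuned")
        values.append(at_fraction)
        colors.append("tab:blue")
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(values)), values, color=colors)
    ax.set_xticks(range(len(values)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("fraction of rules breaking the tradeoff")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_loglog_fit(x, y, slope, intercept, path, xlabel, ylabel) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.loglog(x, y, ".", ms=3, color="0.4")
    xs = np.array([min(x), max(x)])
    ax.loglog(xs, np.exp(intercept) * xs**slope, "r-", label=f"slope {slope:.3f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
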