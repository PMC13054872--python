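"""Bar-chart summaries of fitted results (matplotlib, non-interactive)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_posteriors", "plot_parameter_performance"]


def plot_posteriors(results, top: int = 20, path=None):
    """Horizontal bars of the top-k posterior taxa of a fitted model."""
    frame = results.results_frame().head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(frame) + 1.2))
    labels = [f"{n} ({t})" for n, t in zip(frame["name"], frame["taxid"])]
    ax.barh(labels, frame["posterior"], color="#2b6f9e")
    ax.set_xlabel("posterior probability of presence")
    ax.set_xlim(0, 1)
    p = results.params
    ax.set_title(f"top taxa (alpha={p.alpha}, beta={p.beta}, gamma={p.gamma})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_parameter_performance(results, path=None):
    """One bar per (alpha, beta, gamma) combination, height = metric M."""
    frame = results.performance_frame()
    labels = [
        f"{a}/{b}/{g}" for a, b, g in zip(frame["alpha"], frame["beta"], frame["gamma"])
    ]
    colors = ["#c23b22" if w else "#999999" for w in frame["winner"]]
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(frame)), 4))
    ax.bar(labels, frame["metric"], color=colors)
    ax.set_ylabel("selection metric M = RBO / S$^2$")
    ax.set_xlabel("alpha / beta / gamma")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
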