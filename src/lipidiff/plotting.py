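"""Optional matplotlib views of the analysis results."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_overabundance(result, path: str | Path, title: str = "") -> None:
    """Observed vs expected discovery counts over the threshold grid.

    The shaded region is the Monte-Carlo null envelope; an observed curve
    escaping it indicates more small p-values than a same-size null
    experiment produces. The vertical line marks the p = 0.05 cut-off.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(result.alphas, result.null_lo, result.null_hi,
                    alpha=0.25, color="grey", label="null envelope")
    ax.plot(result.alphas, result.expected_k, "--", color="grey", label="expected (N·α)")
    ax.plot(result.alphas, result.observed_k, "o-", color="C0", label="observed")
    ax.axvline(0.05, color="red", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("p-value threshold α")
    ax.set_ylabel("lipids with p < α")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_volcano(results, path: str | Path, title: str = "",
                 p_threshold: float = 0.05, log2_threshold: float = 1.0) -> None:
    """Volcano plot: log2 fold change against -log10 p, calls colored."""
    colors = {"up": "C3", "down": "C0", "not_significant": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for call in ("not_significant", "down", "up"):
        xs = [r.log2_fc for r in results if r.call == call]
        ys = [r.neg_log10_p for r in results if r.call == call]
        ax.scatter(xs, ys, s=12, c=colors[call], label=call.replace("_", " "))
    ax.axhline(-math.log10(p_threshold), color="k", lw=0.5, ls=":")
    for x in (-log2_threshold, log2_threshold):
        ax.axvline(x, color="k", lw=0.5, ls=":")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p-value")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
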