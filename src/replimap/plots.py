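"""Optional figure output: violin/box RT comparisons and quantile profiles.

Kept out of the pipeline hot path; import cost is paid only when figures
are requested.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .profiles import QuantileProfile  # noqa: E402

__all__ = ["plot_violin_rt", "plot_quantile_profile"]


def plot_violin_rt(rt_selected: np.ndarray, rt_controls: np.ndarray,
                   sample: str, path: str | Path) -> None:
    """Violin + inner box of RT for enriched windows vs matched controls."""
    fig, ax = plt.subplots(figsize=(3.2, 4))
    data = [np.asarray(rt_selected, float), np.asarray(rt_controls, float)]
    ax.violinplot(data, showextrema=False)
    ax.boxplot(data, widths=0.15, showfliers=False,
               medianprops={"color": "black"})
    ax.set_xticks([1, 2], [sample, "random"])
    ax.set_ylabel("RT = log2(Early/Late)")
    ax.axhline(0, lw=0.5, color="grey")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_quantile_profile(profile: QuantileProfile, path: str | Path) -> None:
    """Box summaries of window TPM per quantile, late/B -> early/A, with
    the mean marked as a dot."""
    s = profile.summary
    fig, ax = plt.subplots(figsize=(6, 3.2))
    q = s["quantile"].to_numpy()
    ax.vlines(q, s["whisker_lo"], s["whisker_hi"], color="grey", lw=0.8)
    ax.bar(q, s["q3"] - s["q1"], bottom=s["q1"], width=0.7,
           color="#9ecae1", edgecolor="none")
    ax.hlines(s["median"], q - 0.35, q + 0.35, color="black", lw=1.0)
    ax.plot(q, s["mean"], "k.", ms=5)
    ax.set_xlabel(f"{profile.scheme} quantile (1 = late/B)")
    ax.set_ylabel("coverage (TPM)")
    ax.set_title(profile.sample)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
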