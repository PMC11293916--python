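"""Oscillogram plotting (endplate index on x, tilt in degrees on y)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .oscillogram_geometry import Curve, Extremum, TiltSeries


def plot_oscillogram(
    series: TiltSeries,
    extrema: list[Extremum] | None = None,
    curves: list[Curve] | None = None,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Plot the 34-endplate tilt oscillogram of one view.

    Detected peaks/troughs are marked and each curve's peak-trough span is
    drawn as a shaded band whose height is the Cobb angle.  Returns the
    matplotlib figure; saves to ``path`` (format from its suffix) if given.
    """
    fig, ax = plt.subplots(figsize=(8, 3.2))
    x = range(len(series.values))
    ax.plot(x, series.values, "-o", ms=3, lw=1.2, color="tab:blue")
    ax.axhline(0.0, color="0.7", lw=0.8)
    if extrema:
        for e in extrema:
            ax.plot(e.index, e.value, "v" if e.polarity == "trough" else "^",
                    color="tab:red", ms=7)
    if curves:
        colors = {"PT": "tab:green", "MT": "tab:red", "TLL": "tab:orange"}
        for c in curves:
            if c.cobb <= 0:
                continue
            ax.axvspan(c.upper_index, c.lower_index, alpha=0.12,
                       color=colors.get(c.region.value, "0.5"))
            ax.text((c.upper_index + c.lower_index) / 2, ax.get_ylim()[1] * 0.9,
                    f"{c.region.value}\n{c.cobb:.1f}°", ha="center", va="top", fontsize=8)
    ticks = range(0, 34, 4)
    ax.set_xticks(list(ticks))
    ax.set_xticklabels([f"{i}" for i in ticks])
    ax.set_xlabel("endplate index (0 = T1 superior, 33 = L5 inferior)")
    ax.set_ylabel("tilt (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path))
        plt.close(fig)
    return fig
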