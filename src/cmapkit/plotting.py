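"""Vector-graphics export of measured traces.

Produces publication-style plots of the averaged CMAP trace: zero line,
artifact-onset marker, measurement cursors at the rising/falling zero
crossings and the peak, and scale bars instead of axes. Written as SVG
and/or EPS for downstream figure assembly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .core import Sweep
from .measure import CmapMeasurement

__all__ = ["plot_measurement"]


def plot_measurement(
    sweep: Sweep,
    measurement: CmapMeasurement,
    path_base,
    formats: Sequence[str] = ("svg",),
    title: str = "",
) -> list:
    """Plot an averaged trace with measurement cursors and scale bars.

    Parameters
    ----------
    sweep : Sweep
        The conditioned (averaged, baseline-subtracted) trace.
    path_base : path-like
        Output path without extension; one file per requested format.
    formats : sequence of {"svg", "eps"}
        Vector formats to write.

    Returns
    -------
    list of Path — the files written.
    """
    t = sweep.times_ms()
    y = sweep.samples
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(t, y, color="black", lw=0.9)
    ax.axhline(0.0, color="0.6", lw=0.6)
    ax.axvline(sweep.meta.artifact_onset, color="0.4", lw=0.6, ls="--")

    if measurement.is_response:
        for x_ms, marker in (
            (measurement.onset_crossing_time, "^"),
            (measurement.offset_crossing_time, "v"),
        ):
            if np.isfinite(x_ms):
                ax.plot(x_ms, 0.0, marker, color="tab:red", ms=6, clip_on=False)
        ax.plot(
            measurement.peak_time,
            measurement.amplitude,
            "o",
            color="tab:blue",
            ms=4,
        )
        label = (
            f"A = {measurement.amplitude:.2f} mV, "
            f"L = {measurement.latency:.2f} ms, "
            f"D = {measurement.duration:.2f} ms"
        )
    else:
        label = "no response"
    ax.set_title(title or label, fontsize=9)

    # scale bars bottom-right instead of axes
    ax.set_axis_off()
    y_span = max(np.ptp(y), 1e-9)
    bar_v = 10 ** np.floor(np.log10(y_span / 2))
    bar_t = 2.0  # ms
    x0 = t[-1] - bar_t - 0.05 * t[-1]
    y0 = y.min() - 0.08 * y_span
    ax.plot([x0, x0 + bar_t], [y0, y0], color="black", lw=1.5)
    ax.plot([x0, x0], [y0, y0 + bar_v], color="black", lw=1.5)
    ax.annotate(f"{bar_t:g} ms", (x0 + bar_t / 2, y0), ha="center", va="top", fontsize=8)
    ax.annotate(
        f"{bar_v:g} mV", (x0, y0 + bar_v / 2), ha="right", va="center", fontsize=8
    )

    written = []
    for fmt in formats:
        out = Path(f"{path_base}.{fmt}")
        fig.savefig(out, format=fmt, bbox_inches="tight")
        written.append(out)
    plt.close(fig)
    return written
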