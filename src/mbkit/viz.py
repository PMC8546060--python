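"""Quick-look plots: displacement/velocity traces and merged beats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import BeatSet, ShorteningWaveform
from .tracking import DisplacementTrace


def beats_to_dataframe(beats: BeatSet) -> pd.DataFrame:
    """Long-format per-beat table: (beat, rel_time_s, fs)."""
    rows = []
    for b, row in enumerate(beats.beats):
        rows.append(pd.DataFrame({"beat": b, "rel_time_s": beats.rel_time, "fs": row}))
    if not rows:
        return pd.DataFrame(columns=["beat", "rel_time_s", "fs"])
    return pd.concat(rows, ignore_index=True)


def plot_contraction_summary(
    waveform: ShorteningWaveform,
    beats: BeatSet,
    prox: DisplacementTrace | None = None,
    dist: DisplacementTrace | None = None,
    axis_angle_deg: float = 0.0,
):
    """Stacked panels: displacements, fs(t), merged beat with 95% band,
    and the merged |velocity| — the standard per-tissue report figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.signal import savgol_filter

    fig, axes = plt.subplots(4, 1, figsize=(7, 9), constrained_layout=True)

    if prox is not None and dist is not None:
        axes[0].plot(prox.times, prox.axial(axis_angle_deg), label="proximal", lw=0.8)
        axes[0].plot(dist.times, dist.axial(axis_angle_deg), label="distal", lw=0.8)
        axes[0].legend(frameon=False, fontsize=8)
    axes[0].set_ylabel("axial displacement (um)")

    axes[1].plot(waveform.time, 100 * waveform.fs, color="k", lw=0.8)
    axes[1].set_ylabel("fractional shortening (%)")
    axes[1].set_xlabel("time (s)")

    if beats.n_beats:
        axes[2].fill_between(
            beats.rel_time, 100 * beats.ci_low, 100 * beats.ci_high, alpha=0.3, lw=0
        )
        axes[2].plot(beats.rel_time, 100 * beats.merged, color="C0")
        axes[2].set_ylabel("merged fs (%)")

        if len(beats.merged) >= 5:
            v = savgol_filter(beats.merged, 5, 3, deriv=1, delta=beats.dt)
            axes[3].plot(beats.rel_time, np.abs(v), color="C1")
        axes[3].set_ylabel("|velocity| (1/s)")
        axes[3].set_xlabel("time from upstroke half-max (s)")
    return fig
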