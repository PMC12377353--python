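"""Minimal plotting helpers (untested surface, for interactive exploration)."""

from __future__ import annotations

import numpy as np

from .kinematics import CycleSegmentation, time_normalize_cycles


def plot_cycle_band(samples, segmentation: CycleSegmentation, n_points: int = 100, ax=None):
    """Mean +/- SD band of a signal over the time-normalized cycle."""
    import matplotlib.pyplot as plt

    mat = time_normalize_cycles(np.asarray(samples, dtype=float), segmentation, n_points)
    mean, sd = mat.mean(axis=0), mat.std(axis=0, ddof=1 if len(mat) > 1 else 0)
    x = np.linspace(0, 100, n_points)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(x, mean, color="tab:red", label="mean")
    ax.fill_between(x, mean - sd, mean + sd, color="grey", alpha=0.3, label="+/- SD")
    ax.set_xlabel("cycle time (%)")
    ax.legend()
    return ax


def plot_phase_cc(cc_table, ax=None):
    """Bar plot of mean coactivation per movement phase (pooled over rows)."""
    import matplotlib.pyplot as plt

    means = cc_table.groupby("phase", sort=False)["cc"].mean()
    sds = cc_table.groupby("phase", sort=False)["cc"].std()
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(means.index, means.to_numpy(), yerr=sds.to_numpy(), capsize=4)
    ax.set_ylabel("coactivation coefficient (%)")
    return ax
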