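"""Mean +/- SEM axon-density-versus-distance figure."""

from __future__ import annotations

import numpy as np


def plot_density_curves(table, ax=None, max_distance_um: float | None = None):
    """Plot per-treatment mean well-mean density vs distance with SEM band.

    ``table`` is an :class:`~axoquant.stats.ExperimentTable`.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    wm = table.well_mean_rows()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for treatment, grp in wm.groupby("treatment"):
        agg = grp.groupby("bin_start_um")["density"].agg(["mean", "sem", "count"])
        if max_distance_um is not None:
            agg = agg[agg.index < max_distance_um]
        d = agg.index.to_numpy() + table.bin_width_um / 2
        ax.plot(d, agg["mean"], label=str(treatment))
        sem = np.nan_to_num(agg["sem"].to_numpy(), nan=0.0)
        ax.fill_between(d, agg["mean"] - sem, agg["mean"] + sem, alpha=0.25)
    ax.set_xlabel("distance from explant origin (µm)")
    ax.set_ylabel("axon density (occupied fraction)")
    ax.legend(title="treatment")
    return ax
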