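"""Quick-look radial profile figures (optional; needs matplotlib)."""

from __future__ import annotations

import numpy as np

from .dde_engine import Trajectory


def profile_panels(traj: Trajectory, days=(0, 1, 3, 5, 7, 10),
                   fields=("C", "S_T", "S_A"), ax=None):
    """Plot radial profiles of cell populations at selected days.

    Mirrors the usual presentation of lesion simulations: one line per
    field per panel, one panel per time point.  Returns the figure.
    """
    import matplotlib.pyplot as plt

    days = [d for d in days if d * 24.0 <= traj.t_end + 1e-9]
    fig, axes = plt.subplots(1, len(days), figsize=(3 * len(days), 3),
                             sharey=True)
    axes = np.atleast_1d(axes)
    r = traj.grid.node_centers
    for ax_, day in zip(axes, days):
        i = int(np.searchsorted(traj.times, day * 24.0))
        for name in fields:
            ax_.plot(r, traj.field(name)[i], label=name)
        ax_.set_title(f"day {day}")
        ax_.set_xlabel("r (mm)")
    axes[0].set_ylabel("cells / mm$^2$")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
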