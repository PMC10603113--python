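"""Basic trajectory figure helper."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .lan import Trajectory


def plot_trajectory(traj: Trajectory, path=None):
    """Two-panel figure: Fe redox couple (mM) and cell densities (OD600)."""
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax1.plot(traj.times, traj.fe2, label="Fe$^{2+}$", color="tab:red")
    ax1.plot(traj.times, traj.fe3, label="Fe$^{3+}$", color="tab:orange", ls="--")
    ax1.set_ylabel("concentration (mM)")
    ax1.legend(frameon=False)
    ax2.plot(traj.times, traj.cells_S, label="reducer", color="tab:blue")
    ax2.plot(traj.times, traj.cells_R, label="oxidizer", color="tab:green")
    ax2.set_xlabel("time (h)")
    ax2.set_ylabel("density (OD$_{600}$)")
    ax2.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
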