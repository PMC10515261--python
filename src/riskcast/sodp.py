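"""Second-order difference plot (SODP) quality-control summaries.

The SODP, a descendant of the Poincaré plot, scatters consecutive first
differences of a series against each other: points (Δ_n, Δ_{n+1}) with
Δ_n = x_{n+1} − x_n. Its shape is a quick visual check of a dataset's
short-range variability pattern. The numeric descriptors follow the standard
Poincaré SD1/SD2 construction: the dispersion perpendicular to the identity
diagonal, sd1 = sd((Δ_{n+1} − Δ_n)/√2), and along it,
sd2 = sd((Δ_{n+1} + Δ_n)/√2). Differencing makes everything invariant to
adding a constant to the series, and scaling the series by c scales points
and descriptors by |c|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError


@dataclass
class SODPData:
    points: np.ndarray  # shape (len(series) - 2, 2)
    centroid: tuple
    sd1: float  # dispersion perpendicular to the identity diagonal
    sd2: float  # dispersion along the identity diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["delta_n", "delta_n1"])


def sodp_points(series) -> SODPData:
    """Build the SODP point cloud and its diagonal dispersion descriptors."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise EmptyInputError(f"SODP needs a 1-D series of length >= 3, got {x.shape}")
    d = np.diff(x)
    points = np.column_stack([d[:-1], d[1:]])
    perp = (points[:, 1] - points[:, 0]) / np.sqrt(2.0)
    diag = (points[:, 1] + points[:, 0]) / np.sqrt(2.0)
    ddof = 1 if len(points) > 1 else 0
    return SODPData(
        points=points,
        centroid=(float(points[:, 0].mean()), float(points[:, 1].mean())),
        sd1=float(np.std(perp, ddof=ddof)),
        sd2=float(np.std(diag, ddof=ddof)),
    )


def plot_sodp(data: SODPData, path: str) -> None:
    """Optional scatter rendering of the SODP cloud (square axes, diagonal)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(data.points[:, 0], data.points[:, 1], s=12, alpha=0.7)
    lim = np.max(np.abs(data.points)) * 1.1 if len(data.points) else 1.0
    ax.plot([-lim, lim], [-lim, lim], lw=0.8, color="grey")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel(r"$\Delta_n$")
    ax.set_ylabel(r"$\Delta_{n+1}$")
    ax.set_title("Second-order difference plot")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
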