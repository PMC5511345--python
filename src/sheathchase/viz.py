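"""Plot helpers (headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .kymograph import Kymogram  # noqa: E402


def plot_kymogram(kym: Kymogram, path=None, ax=None, cmap: str = "magma"):
    """Heat map of a kymogram (distance from line start vs time)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = kym.times_s()
    d = kym.distances_nm() / 1000.0
    im = ax.imshow(kym.values, aspect="auto", origin="lower", cmap=cmap,
                   extent=[t[0], t[-1], d[0], d[-1]])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("distance (um)")
    ax.figure.colorbar(im, ax=ax, label="intensity (counts)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
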