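"""Display helpers: bivariate flow plots and nucleus projection panels."""

from __future__ import annotations

import numpy as np

from .voxel_core import NucleusImage, average_projection, one_micron_window

__all__ = ["plot_flow_bivariate", "plot_nucleus_panel"]


def plot_flow_bivariate(events, gates=None, ax=None):
    """Density-colored DNA-content x EdU scatter with optional gate rectangles.

    ``events`` is a DataFrame from :func:`repli3d.simulate_flow`; the EdU
    axis is logarithmic, as on a cytometer.  Returns the axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    x = events["dna_content"].to_numpy()
    y = np.log10(np.clip(events["edu_intensity"].to_numpy(), 1e-3, None))
    h, xe, ye = np.histogram2d(x, y, bins=(80, 80))
    dens = h[
        np.clip(np.searchsorted(xe, x) - 1, 0, h.shape[0] - 1),
        np.clip(np.searchsorted(ye, y) - 1, 0, h.shape[1] - 1),
    ]
    order = np.argsort(dens)
    ax.scatter(x[order], y[order], c=dens[order], s=2, cmap="viridis", rasterized=True)
    if gates:
        top = y.max() + 0.2
        for g in gates:
            lo = np.log10(max(g.edu_min, 1e-3))
            ax.add_patch(
                Rectangle((g.dna_lo, lo), g.dna_hi - g.dna_lo, top - lo, fill=False, edgecolor="red")
            )
            ax.text(0.5 * (g.dna_lo + g.dna_hi), top, g.label, ha="center", color="red")
    ax.set_xlabel("DNA content (C)")
    ax.set_ylabel("log10 EdU (A-488) intensity")
    return ax


def plot_nucleus_panel(img: NucleusImage, axes=None):
    """Mid-nucleus 1-µm average projections: DAPI, EdU and red/green overlay."""
    import matplotlib.pyplot as plt

    dapi = img.channels["DAPI"]
    edu = img.channels["EDU"]
    n = one_micron_window(dapi)
    z0 = dapi.shape[0] // 2 - n // 2
    d2 = average_projection(dapi, z0, n)
    e2 = average_projection(edu, z0, n)
    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, im, title in zip(axes[:2], (d2, e2), ("DAPI", "EdU (A-488)")):
        ax.imshow(im, cmap="gray")
        ax.set_title(title)
        ax.axis("off")
    rgb = np.zeros(d2.shape + (3,))
    rgb[..., 0] = d2 / max(d2.max(), 1e-9)  # DAPI in red
    rgb[..., 1] = e2 / max(e2.max(), 1e-9)  # EdU in green
    axes[2].imshow(np.clip(rgb, 0, 1))
    axes[2].set_title(f"overlay ({img.meta.get('stage', '?')})")
    axes[2].axis("off")
    return axes
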