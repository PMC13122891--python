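"""Diagnostic plots (size spectrum, depth tracks)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_spectrum", "plot_depth_track"]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_spectrum(spectrum, path) -> None:
    """Log-frequency of unique deletion sizes with the reciprocal reference."""
    plt = _pyplot()
    mids = (spectrum.bin_edges[:-1] + spectrum.bin_edges[1:]) / 2 / 1e6
    fig, axis = plt.subplots(figsize=(6, 4))
    nz = spectrum.counts > 0
    axis.semilogy(mids[nz], spectrum.counts[nz], "r+", label="unique deletions")
    axis.semilogy(mids, np.maximum(spectrum.curve, 1e-3), "k-", lw=0.8, label="c / size")
    axis.set_xlabel("deletion size (Mb)")
    axis.set_ylabel("frequency")
    axis.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_depth_track(depth_norm, stats, line_id, chrom, path) -> None:
    """One line's normalized depth along a chromosome with the mean +/- 3 SD band."""
    plt = _pyplot()
    sl = depth_norm.grid.chrom_window_slice(chrom)
    x = depth_norm.grid.window_start[sl] / 1e6
    y = depth_norm.line(line_id)[sl]
    fig, axis = plt.subplots(figsize=(8, 3))
    axis.plot(x, stats.mu[sl], ".", color="gold", ms=2, label="population mean")
    axis.plot(x, stats.mu[sl] + 3 * stats.sigma[sl], "-", color="grey", lw=0.5)
    axis.plot(x, np.maximum(stats.mu[sl] - 3 * stats.sigma[sl], 0), "-", color="grey", lw=0.5)
    axis.plot(x, y, ".", color="red", ms=2, label=line_id)
    axis.set_xlabel(f"{chrom} position (Mb)")
    axis.set_ylabel("normalized depth")
    axis.legend(frameon=False, markerscale=4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
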