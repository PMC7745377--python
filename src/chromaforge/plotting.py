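"""Static publication-style plots for matrices, tracks and statistics.

Genome-browser-style panels (matrix views, score tracks, gene tracks) are
plain matplotlib figures that can be stacked via ``subplots``; every function
accepts an ``ax`` and returns it, or writes a file when ``path`` is given.
File output strips volatile metadata so re-rendering identical data is
byte-identical.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "chromaforge"  # deterministic SVG ids
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import LogNorm, TwoSlopeNorm  # noqa: E402

def _finish(fig, ax, path):
    # strip volatile metadata so identical data re-renders byte-identically
    if path is not None:
        sfx = str(path).lower()
        if sfx.endswith(".svg"):
            meta = {"Date": None}
        elif sfx.endswith(".pdf"):
            meta = {"CreationDate": None}
        else:
            meta = {"Software": "chromaforge"}
        fig.savefig(path, metadata=meta)
        plt.close(fig)
    return ax


def _get_ax(ax, figsize=(5, 4)):
    if ax is None:
        fig, ax = plt.subplots(figsize=figsize)
    else:
        fig = ax.figure
    return fig, ax


def plot_matrix(matrix, region=None, style: str = "square", oe: bool = False,
                log2: bool = False, other=None, vmax=None, ax=None, path=None):
    """Contact-matrix heatmap: square, triangular, mirrored or split view.

    ``mirrored`` stacks two triangular views of ``matrix`` and ``other``;
    ``split`` shows ``matrix`` above and ``other`` below the diagonal.
    O/E maps use a diverging scale centred on 1 (0 with ``log2``).
    """
    sub, rows, _ = matrix.matrix(region, oe=oe, log2=log2)
    if style == "split" and other is not None:
        sub2, _, _ = other.matrix(region, oe=oe, log2=log2)
        sub = np.triu(np.nan_to_num(sub)) + np.tril(np.nan_to_num(sub2), k=-1)
    fig, ax = _get_ax(ax)
    if oe:
        centre = 0.0 if log2 else 1.0
        lim = vmax or max(abs(np.nanmin(sub) - centre), abs(np.nanmax(sub) - centre)) or 1
        norm = TwoSlopeNorm(vcenter=centre, vmin=centre - lim, vmax=centre + lim)
        cmap = "RdBu_r"
    else:
        pos = sub[np.isfinite(sub) & (sub > 0)]
        norm = LogNorm(vmin=pos.min() if pos.size else 1e-3,
                       vmax=vmax or (pos.max() if pos.size else 1.0))
        cmap = "Reds"
    if style in ("triangular", "mirrored"):
        n = sub.shape[0]
        # rotate 45 degrees: pixel (i, j) plots at ((i+j)/2, (j-i)/2)
        mx, my = _triangular_mesh(n)
        im = ax.pcolormesh(mx, my, sub, norm=norm, cmap=cmap)
        ax.set_ylim(0, n / 2)
        if style == "mirrored" and other is not None:
            sub2, _, _ = other.matrix(region, oe=oe, log2=log2)
            ax.pcolormesh(mx, -my, sub2, norm=norm, cmap=cmap)
            ax.set_ylim(-n / 2, n / 2)
        ax.set_yticks([])
    else:
        im = ax.imshow(sub, norm=norm, cmap=cmap, interpolation="none")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if rows.size:
        r0, r1 = matrix.bins[rows[0]], matrix.bins[rows[-1]]
        ax.set_title(f"{r0.chromosome}:{r0.start}-{r1.end}", fontsize=9)
    return _finish(fig, ax, path)


def _triangular_mesh(n):
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    return (i + j) / 2.0, (j - i) / 2.0


def plot_saddle(saddle, log2: bool = True, ax=None, path=None):
    """Saddle heatmap with the EV-cutoff bar sub-panel underneath."""
    fig, (ax_m, ax_b) = plt.subplots(
        2, 1, figsize=(4.5, 5.6), gridspec_kw={"height_ratios": [4, 1]})
    s = np.log2(saddle.saddle) if log2 else saddle.saddle
    lim = np.nanmax(np.abs(s)) or 1.0
    im = ax_m.imshow(s, cmap="RdBu_r", vmin=-lim, vmax=lim, interpolation="none")
    fig.colorbar(im, ax=ax_m, shrink=0.8,
                 label="log2 O/E" if log2 else "O/E")
    ax_m.set_xticks([])
    ax_m.set_yticks([])
    ax_b.bar(np.arange(saddle.cutoffs.size), saddle.cutoffs, color="grey")
    ax_b.set_ylabel("EV cutoff", fontsize=8)
    ax_b.set_xlabel("EV percentile group", fontsize=8)
    fig.tight_layout()
    return _finish(fig, ax_m, path)


def plot_aggregate(result, log_scale: bool = False, ax=None, path=None):
    fig, ax = _get_ax(ax, figsize=(4, 3.5))
    lim = np.nanmax(np.abs(result.grid)) or 1.0
    im = ax.imshow(result.grid, cmap="RdBu_r", vmin=-lim, vmax=lim,
                   interpolation="none")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"aggregate over {result.n_regions} regions", fontsize=9)
    return _finish(fig, ax, path)


def plot_score_heatmap(track, chromosome=None, ax=None, path=None):
    """Multi-window score heatmap ("flame" plot), smallest window at bottom."""
    fig, ax = _get_ax(ax, figsize=(7, 2.5))
    if chromosome is not None:
        sl = track.bins.chromosome_slice(chromosome)
        data = track.scores[sl].T
    else:
        data = track.scores.T
    order = np.argsort(track.windows)          # smallest window at the bottom row
    data = data[order][::-1]
    lim = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim,
                   interpolation="none")
    ax.set_yticks(range(len(track.windows)))
    ax.set_yticklabels([str(track.windows[k]) for k in order[::-1]], fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    return _finish(fig, ax, path)


def plot_track(bins, values, chromosome=None, kind: str = "line", ax=None,
               path=None, **kw):
    """Line or bar plot of a per-bin score track (e.g. insulation, EV, 4C)."""
    fig, ax = _get_ax(ax, figsize=(7, 1.8))
    if chromosome is not None:
        sl = bins.chromosome_slice(chromosome)
        x = [r.center for r in bins.regions[sl]]
        y = np.asarray(values)[sl]
    else:
        x = [r.center for r in bins]
        y = np.asarray(values)
    if kind == "bar":
        colors = np.where(y >= 0, "firebrick", "steelblue")
        ax.bar(x, y, width=(x[1] - x[0]) if len(x) > 1 else 1, color=colors, **kw)
    else:
        ax.plot(x, y, lw=0.8, **kw)
    ax.axhline(0, color="grey", lw=0.5)
    return _finish(fig, ax, path)


def plot_genes(regions, ax=None, path=None):
    """Gene track: orange = forward strand, cyan = reverse strand."""
    fig, ax = _get_ax(ax, figsize=(7, 1.2))
    for k, r in enumerate(regions):
        color = "orange" if r.strand == "+" else "cyan" if r.strand == "-" else "grey"
        ax.plot([r.start, r.end], [k % 3, k % 3], lw=4, color=color,
                solid_capstyle="butt")
        ax.annotate(r.attributes.get("name", ""), (r.start, k % 3 + 0.15), fontsize=6)
    ax.set_yticks([])
    return _finish(fig, ax, path)


def plot_ligation_error(curves, ax=None, path=None):
    """Orientation fraction vs separation, with the 0.25 expectation line."""
    from .pairs import ORIENTATIONS

    fig, ax = _get_ax(ax)
    for o in ORIENTATIONS:
        if o in curves:
            ax.plot(curves["separation"], curves[o], label=o, lw=1)
    ax.axhline(0.25, ls="--", color="black", lw=0.8, label="expected")
    ax.set_xscale("log")
    ax.set_xlabel("genomic separation (bp)")
    ax.set_ylabel("fraction of pairs")
    ax.legend(fontsize=7)
    return _finish(fig, ax, path)


def plot_insert_size(stats, ax=None, path=None):
    fig, ax = _get_ax(ax)
    h = stats.insert_size
    if len(h):
        ax.fill_between(h["insert_size"], h["count"], step="mid", alpha=0.6)
    if stats.median_insert_size is not None:
        ax.axvline(stats.median_insert_size, ls="--", color="black", lw=0.8)
    ax.set_xlabel("restriction-site distance sum (bp)")
    ax.set_ylabel("pairs")
    return _finish(fig, ax, path)


def plot_filter_summary(stats, ax=None, path=None):
    fig, ax = _get_ax(ax)
    names = list(stats.removed) + ["valid"]
    counts = [stats.removed[k] for k in stats.removed] + [stats.valid]
    ax.bar(range(len(names)), counts, color="steelblue")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("read pairs")
    fig.tight_layout()
    return _finish(fig, ax, path)


def plot_distance_decay(expected_profile, ax=None, path=None):
    """Log-log distance-decay curves, one per chromosome plus genome-wide."""
    fig, ax = _get_ax(ax)
    for chrom, e in expected_profile.intra.items():
        d = np.arange(e.size)
        ok = np.isfinite(e) & (e > 0) & (d > 0)
        ax.plot(d[ok], e[ok], lw=0.8, alpha=0.6, label=chrom)
    g = expected_profile.genome
    d = np.arange(g.size)
    ok = np.isfinite(g) & (g > 0) & (d > 0)
    ax.plot(d[ok], g[ok], lw=1.5, color="black", label="genome")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("distance (bins)")
    ax.set_ylabel("expected contacts")
    ax.legend(fontsize=7)
    return _finish(fig, ax, path)
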