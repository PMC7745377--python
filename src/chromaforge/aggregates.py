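"""Aggregate (pileup) matrices over region lists and region-pair lists.

Averaging the Hi-C submatrix around many features of the same kind (TADs,
boundaries, loop anchors) reveals a consensus pattern. Two modes:

* ``rescaled`` — each region's (optionally expanded) square submatrix is
  interpolated onto a fixed pixel grid before averaging, so TADs of
  different sizes align (the TAD preset expands by half the region size on
  each side, so the domain occupies the central third of the plot);
* ``fixed`` — a fixed-bp window centred on each region midpoint (the
  boundary preset) or on each region pair (the loop/APA preset).

Values default to log2 observed/expected. Averaging happens on the linear
O/E scale and the log is taken of the averaged grid: with shallow counts
many individual pixels are zero, and a per-pixel log would silently drop
them and bias sparse cells upward. Masked cells are excluded from the mean;
cells with no contributors are missing rather than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import ContactMatrix
from .regions import GenomicRegion

logger = logging.getLogger(__name__)


@dataclass
class AggregateResult:
    grid: np.ndarray             # averaged values, NaN where no contributors
    contributors: np.ndarray     # number of finite contributions per cell
    n_regions: int
    mode: str

    def center_ring_ratio(self, ring_width: int = 3) -> float:
        """Centre value over mean of the outer ring (loop/APA statistic)."""
        n = self.grid.shape[0]
        c = n // 2
        centre = self.grid[c, c]
        ring = np.concatenate([
            self.grid[:ring_width, :].ravel(),
            self.grid[-ring_width:, :].ravel(),
            self.grid[ring_width:-ring_width, :ring_width].ravel(),
            self.grid[ring_width:-ring_width, -ring_width:].ravel(),
        ])
        return float(centre / np.nanmean(ring))


def _resample(block: np.ndarray, out_size: int) -> np.ndarray:
    """Area-weighted resampling of a square block onto out_size^2, NaN-aware."""
    n = block.shape[0]
    w = _overlap_weights(n, out_size)
    finite = np.isfinite(block)
    filled = np.where(finite, block, 0.0)
    num = w @ filled @ w.T
    den = w @ finite.astype(float) @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def _overlap_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix of fractional overlaps between in/out cells."""
    w = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for o in range(n_out):
        a, b = o * scale, (o + 1) * scale
        lo, hi = int(np.floor(a)), int(np.ceil(b))
        for i in range(lo, min(hi, n_in)):
            w[o, i] = max(0.0, min(b, i + 1) - max(a, i))
    return w


def _accumulate(total, counts, block):
    finite = np.isfinite(block)
    total[finite] += block[finite]
    counts += finite
    return total, counts


def aggregate_regions(matrix: ContactMatrix, regions, mode: str = "rescaled",
                      pixels: int = 90, expansion: float = 0.5,
                      window: int | None = None, oe: bool = True,
                      log2: bool = True, flip_strand: bool = True) -> AggregateResult:
    """Aggregate submatrix over a region list.

    ``mode='rescaled'`` interpolates each region's expanded square submatrix
    to a ``pixels x pixels`` grid; ``mode='fixed'`` cuts a ``window``-bp
    square centred on each region midpoint (``pixels`` must then be odd so a
    centre bin exists). Minus-strand regions are flipped before averaging
    unless ``flip_strand`` is disabled.
    """
    regions = list(regions)
    if mode == "fixed":
        if window is None:
            raise ValueError("fixed mode requires a window size in bp")
        bin_size = matrix.bins[0].length
        half_bins = int(round(window / 2 / bin_size))
        pixels = 2 * half_bins + 1
    total = np.zeros((pixels, pixels))
    counts = np.zeros((pixels, pixels), dtype=int)
    used = 0
    for r in regions:
        clen = matrix.bins.chromosome_lengths.get(r.chromosome)
        if clen is None:
            logger.warning("skipping %s: unknown chromosome", r)
            continue
        if mode == "rescaled":
            pad = int(round(expansion * r.length))
            start, end = r.start - pad, r.end + pad
            if start < 0 or end > clen:
                logger.warning("skipping %s: expanded window leaves chromosome", r)
                continue
            sub, rows, _ = matrix.matrix(GenomicRegion(r.chromosome, start, end),
                                         oe=oe, log2=False)
            if r.strand == "-" and flip_strand:
                sub = sub[::-1, ::-1]
            block = _resample(sub, pixels)
        else:
            bin_size = matrix.bins[0].length
            centre_bin = matrix.bins.region_at(
                r.chromosome, min(int(r.center), clen - 1)).index
            sl = matrix.bins.chromosome_slice(r.chromosome)
            lo, hi = centre_bin - half_bins, centre_bin + half_bins + 1
            if lo < sl.start or hi > sl.stop:
                logger.warning("skipping %s: window leaves chromosome", r)
                continue
            idx = np.arange(lo, hi)
            block = _dense_window(matrix, idx, idx, oe=oe, log2=False)
            if r.strand == "-" and flip_strand:
                block = block[::-1, ::-1]
        total, counts = _accumulate(total, counts, block)
        used += 1
    grid = _finalise_grid(total, counts, log2)
    return AggregateResult(grid=grid, contributors=counts, n_regions=used, mode=mode)


def _finalise_grid(total, counts, log2):
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
        if log2:
            # log of the averaged grid, not average of per-pixel logs
            grid = np.where(grid > 0, np.log2(np.where(grid > 0, grid, 1.0)), np.nan)
    return grid


def _dense_window(matrix: ContactMatrix, rows, cols, oe=True, log2=True):
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    chrom = matrix.bins[rows[0]].chromosome
    reg1 = GenomicRegion(chrom, matrix.bins[r0].start, matrix.bins[r1 - 1].end)
    reg2 = GenomicRegion(chrom, matrix.bins[c0].start, matrix.bins[c1 - 1].end)
    sub, rr, cc = matrix.matrix(reg1, reg2, oe=oe, log2=log2)
    return sub


def aggregate_pairs(matrix: ContactMatrix, pairs, window: int = 100_000,
                    oe: bool = True, log2: bool = True) -> AggregateResult:
    """Aggregate fixed windows centred on region pairs (loop anchors, APA).

    ``pairs`` is a sequence of ``(region1, region2)`` on the same chromosome;
    the window (bp, full width) is centred on the anchor pixel. Pairs whose
    window would cross the diagonal or a chromosome edge are skipped.
    """
    bin_size = matrix.bins[0].length
    half = int(round(window / 2 / bin_size))
    pixels = 2 * half + 1
    total = np.zeros((pixels, pixels))
    counts = np.zeros((pixels, pixels), dtype=int)
    used = 0
    for r1, r2 in pairs:
        if r1.chromosome != r2.chromosome:
            logger.warning("skipping inter-chromosomal pair %s / %s", r1, r2)
            continue
        clen = matrix.bins.chromosome_lengths.get(r1.chromosome)
        if clen is None:
            continue
        b1 = matrix.bins.region_at(r1.chromosome, min(int(r1.center), clen - 1)).index
        b2 = matrix.bins.region_at(r2.chromosome, min(int(r2.center), clen - 1)).index
        if b1 > b2:
            b1, b2 = b2, b1
        sl = matrix.bins.chromosome_slice(r1.chromosome)
        if (b1 - half < sl.start or b2 + half + 1 > sl.stop
                or (b2 - half) - (b1 + half) < 1):
            logger.warning("skipping pair %s / %s: window leaves range", r1, r2)
            continue
        block = _dense_window(matrix, np.arange(b1 - half, b1 + half + 1),
                              np.arange(b2 - half, b2 + half + 1), oe=oe, log2=False)
        total, counts = _accumulate(total, counts, block)
        used += 1
    grid = _finalise_grid(total, counts, log2)
    return AggregateResult(grid=grid, contributors=counts, n_regions=used, mode="pairs")


def read_bedpe(path):
    """Read a BEDPE file into (region1, region2) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            out.append((GenomicRegion(f[0], int(f[1]), int(f[2])),
                        GenomicRegion(f[3], int(f[4]), int(f[5]))))
    return out
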