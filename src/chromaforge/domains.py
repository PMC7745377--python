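"""Insulation score, directionality index and TAD boundary calling.

The insulation score of bin ``i`` averages contacts in the off-diagonal
square ``[i-w, i) x (i, i+w]`` sliding along the diagonal: contact-depleted
bins (domain boundaries) are local minima. Scores are reported as the log2
ratio to a per-chromosome normaliser — the arithmetic mean of the raw scores
by default, or the geometric mean.

The directionality index contrasts a bin's upstream contact sum ``A`` with
its downstream sum ``B`` via a signed chi-square-like statistic; sign flips
mark boundaries.

Boundary calling finds local minima of the insulation track and scores each
as the mean depth relative to the nearest flanking maxima; a difference
track between conditions can be used as input unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ContactMatrix
from .regions import GenomicRegion, RegionSet

logger = logging.getLogger(__name__)


@dataclass
class ScoreTrack:
    """Per-bin scores, one column per window size (bp)."""

    bins: RegionSet
    windows: list[int]
    scores: np.ndarray  # shape (n_bins, n_windows), NaN where undefined

    def column(self, window: int) -> np.ndarray:
        return self.scores[:, self.windows.index(window)]

    def to_frame(self) -> pd.DataFrame:
        df = self.bins.to_dataframe()
        for k, w in enumerate(self.windows):
            df[f"w_{w}"] = self.scores[:, k]
        return df


@dataclass
class Boundary:
    region: GenomicRegion
    score: float
    window: int
    bin_index: int = -1


def _window_bins(window_bp: int, bin_size: int) -> int:
    w = window_bp // bin_size
    return w


def insulation_score(matrix: ContactMatrix, windows, geometric_mean: bool = False,
                     impute: bool = False, max_masked_fraction: float = 0.5) -> ScoreTrack:
    """Multi-window insulation score track.

    ``windows`` are in bp and floored to whole bins (must be >= 2 bins at the
    matrix resolution). The raw score is the mean pixel value in the
    ``w x w`` square off the diagonal; the final score is the log2 ratio to
    the chromosome normaliser (arithmetic mean by default, geometric with
    ``geometric_mean``). Windows that cross chromosome ends or contain more
    than ``max_masked_fraction`` masked pixels are missing, unless ``impute``
    replaces masked pixels with their distance expectation.
    """
    if np.isscalar(windows):
        windows = [windows]
    windows = [int(w) for w in windows]
    bin_size = matrix.bins[0].length
    scores = np.full((matrix.n_bins, len(windows)), np.nan)
    exp = matrix._expected() if impute else None
    for chrom in matrix.bins.chromosomes:
        sl = matrix.bins.chromosome_slice(chrom)
        nb = sl.stop - sl.start
        if nb == 0:
            continue
        dense, rows, _ = matrix.matrix(chrom, norm=True)
        if impute:
            e = exp.intra[chrom]
            d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
            dense = np.where(np.isnan(dense), e[d], dense)
        for k, wbp in enumerate(windows):
            w = _window_bins(wbp, bin_size)
            if w < 2:
                raise ValueError(
                    f"window {wbp} bp is smaller than 2 bins at {bin_size} bp resolution")
            raw = np.full(nb, np.nan)
            for i in range(w, nb - w):
                square = dense[i - w:i, i + 1:i + 1 + w]
                n_nan = np.isnan(square).sum()
                if n_nan > max_masked_fraction * square.size:
                    continue
                raw[i] = np.nanmean(square)
            defined = np.isfinite(raw) & (raw > 0)
            if not defined.any():
                continue
            if geometric_mean:
                normaliser = np.exp(np.mean(np.log(raw[defined])))
            else:
                normaliser = np.mean(raw[np.isfinite(raw)])
            with np.errstate(divide="ignore", invalid="ignore"):
                scores[sl, k] = np.log2(raw / normaliser)
    return ScoreTrack(bins=matrix.bins, windows=windows, scores=scores)


def directionality_index(matrix: ContactMatrix, windows) -> ScoreTrack:
    """Directionality index track.

    For bin ``i`` with upstream sum ``A`` (contacts to ``[i-w, i)``) and
    downstream sum ``B`` (to ``(i, i+w]``), with ``E = (A + B) / 2``:
    ``DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)``; zero when
    ``A == B`` or ``E == 0``; missing where the window leaves the chromosome.
    """
    if np.isscalar(windows):
        windows = [windows]
    windows = [int(w) for w in windows]
    bin_size = matrix.bins[0].length
    scores = np.full((matrix.n_bins, len(windows)), np.nan)
    for chrom in matrix.bins.chromosomes:
        sl = matrix.bins.chromosome_slice(chrom)
        nb = sl.stop - sl.start
        if nb == 0:
            continue
        dense, _, _ = matrix.matrix(chrom, norm=True)
        for k, wbp in enumerate(windows):
            w = _window_bins(wbp, bin_size)
            if w < 1:
                raise ValueError(f"window {wbp} bp is smaller than 1 bin")
            for i in range(w, nb - w):
                up = dense[i, i - w:i]
                down = dense[i, i + 1:i + 1 + w]
                if np.isnan(up).all() or np.isnan(down).all():
                    continue
                a = np.nansum(up)
                b = np.nansum(down)
                e = (a + b) / 2.0
                if e == 0 or a == b:
                    scores[sl.start + i, k] = 0.0
                else:
                    di = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
                    scores[sl.start + i, k] = di
    return ScoreTrack(bins=matrix.bins, windows=windows, scores=scores)


def _local_extrema(x: np.ndarray):
    """Indices of local minima and maxima of a finite 1-D track.

    Plateaus collapse to their central position (left of centre on even
    plateaus). Endpoints qualify as maxima but not minima.
    """
    n = x.size
    minima, maxima = [], []
    if n < 3:
        return minima, maxima
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        centre = (i + j) // 2
        left = x[i - 1] if i > 0 else None
        right = x[j + 1] if j + 1 < n else None
        if left is not None and right is not None:
            if x[i] < left and x[i] < right:
                minima.append(centre)
            elif x[i] > left and x[i] > right:
                maxima.append(centre)
        elif left is None and right is not None and x[i] > right:
            maxima.append(centre)
        elif right is None and left is not None and x[i] > left:
            maxima.append(centre)
        i = j + 1
    return minima, maxima


def call_boundaries(track: ScoreTrack, window: int | None = None,
                    min_score: float = 1.0,
                    combine: str = "mean") -> list[Boundary]:
    """Call insulation boundaries from one window column of a score track.

    Local minima of the track (split at missing-value runs) become candidate
    boundaries; the boundary score is the mean (or, with ``combine='min'``,
    the minimum) of the differences to the nearest local maxima on either
    side. Boundaries with score >= ``min_score`` are returned in genomic
    order. Works on difference tracks unchanged.
    """
    if window is None:
        window = track.windows[0]
    col = track.column(window)
    boundaries: list[Boundary] = []
    if not np.isfinite(col).any():
        logger.warning("insulation track is entirely missing; no boundaries")
        return boundaries
    for chrom in track.bins.chromosomes:
        sl = track.bins.chromosome_slice(chrom)
        x = col[sl]
        finite = np.isfinite(x)
        # split into contiguous finite segments
        start = None
        segments = []
        for i, f in enumerate(finite):
            if f and start is None:
                start = i
            elif not f and start is not None:
                segments.append((start, i))
                start = None
        if start is not None:
            segments.append((start, finite.size))
        for s0, s1 in segments:
            seg = x[s0:s1]
            minima, maxima = _local_extrema(seg)
            if not minima:
                continue
            maxima_arr = np.array(maxima)
            for m in minima:
                left_max = maxima_arr[maxima_arr < m]
                right_max = maxima_arr[maxima_arr > m]
                deltas = []
                if left_max.size:
                    deltas.append(seg[left_max[-1]] - seg[m])
                if right_max.size:
                    deltas.append(seg[right_max[0]] - seg[m])
                if not deltas:
                    continue
                score = float(min(deltas) if combine == "min" else np.mean(deltas))
                if score >= min_score:
                    b = sl.start + s0 + m
                    boundaries.append(Boundary(
                        region=track.bins[b], score=score, window=window,
                        bin_index=b))
    boundaries.sort(key=lambda b: b.bin_index)
    return boundaries


def boundaries_to_bed(boundaries, path) -> None:
    with open(path, "w") as fh:
        for b in boundaries:
            fh.write(f"{b.region.chromosome}\t{b.region.start}\t{b.region.end}"
                     f"\tboundary\t{b.score:.6g}\t.\n")
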