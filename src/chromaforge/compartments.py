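"""A/B compartment analysis: correlation matrix, eigenvector, saddle, strength.

Compartments are read off the sign of the first eigenvector (EV) of the
per-chromosome Pearson correlation matrix of the observed/expected map.
Because the eigenvector sign is arbitrary, it is oriented with genomic GC
content when a genome is supplied: the A (active) compartment is typically
GC-richer, so signs are flipped per chromosome until the mean GC of
positive-EV bins is at least that of negative-EV bins.

The saddle profile orders bins by EV percentile and reports the mean O/E
between every pair of EV groups; compartment strength summarises it as
``log2(AA * BB / AB^2)`` over the corner groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ContactMatrix
from .regions import gc_content

logger = logging.getLogger(__name__)


@dataclass
class CompartmentTrack:
    ev: np.ndarray              # per-bin EV entry (NaN on masked/skipped bins)
    gc: np.ndarray | None       # per-bin GC fraction if a genome was supplied

    def labels(self) -> np.ndarray:
        """Per-bin compartment label: 'A' (EV > 0), 'B' (EV < 0), '.' undefined."""
        lab = np.full(self.ev.size, ".", dtype=object)
        lab[self.ev > 0] = "A"
        lab[self.ev < 0] = "B"
        return lab


@dataclass
class SaddleResult:
    percentiles: np.ndarray     # upper percentile of each EV group
    cutoffs: np.ndarray         # EV value cutoffs used for grouping
    group_ev: np.ndarray        # mean EV per group
    saddle: np.ndarray          # mean O/E between group pairs (not log)
    strength: float | None = None


def correlation_matrix(matrix: ContactMatrix, chromosome: str,
                       max_missing: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of O/E rows for one chromosome.

    Pairwise-complete over valid bins; bins with more than ``max_missing``
    missing O/E values are dropped. Returns ``(C, global_bin_indices)``.
    """
    oe, rows, _ = matrix.matrix(chromosome, norm=True, oe=True)
    n_missing = np.isnan(oe).sum(axis=1)
    ok = matrix.mask[rows] & (n_missing <= max_missing * oe.shape[1])
    if ok.sum() < 3:
        raise ValueError(f"{chromosome}: fewer than 3 valid bins")
    sub = oe[np.ix_(ok, ok)]
    c = pd.DataFrame(sub).corr(min_periods=2).to_numpy()
    np.fill_diagonal(c, 1.0)
    return c, rows[ok]


def compartment_ev(matrix: ContactMatrix, genome=None,
                   exclude: tuple[str, ...] = ("chrY", "Y")) -> CompartmentTrack:
    """First eigenvector of the correlation matrix, per chromosome.

    The eigenvector of the largest eigenvalue is computed per chromosome with
    a dense symmetric eigensolver and concatenated; unit norm per chromosome.
    With a genome, signs are oriented by GC content (A = GC-rich = positive).
    Without one, the sign is fixed so the EV sums non-negative.
    """
    ev = np.full(matrix.n_bins, np.nan)
    gc = None
    if genome is not None:
        gc = gc_content(matrix.bins.regions, genome)
    for chrom in matrix.bins.chromosomes:
        if chrom in exclude:
            continue
        try:
            c, idx = correlation_matrix(matrix, chrom)
        except ValueError as exc:
            logger.warning("skipping %s: %s", chrom, exc)
            continue
        c = np.where(np.isnan(c), 0.0, c)
        w, v = np.linalg.eigh(c)
        vec = v[:, -1]
        if np.allclose(vec, vec[0]) and np.ptp(c) < 1e-12:
            logger.warning("%s: degenerate (constant) correlation matrix", chrom)
        if gc is not None and np.isfinite(gc[idx]).any():
            pos, neg = vec > 0, vec < 0
            g = gc[idx]
            mean_pos = np.nanmean(g[pos]) if pos.any() else -np.inf
            mean_neg = np.nanmean(g[neg]) if neg.any() else -np.inf
            if np.isfinite(mean_pos) and np.isfinite(mean_neg) and mean_pos < mean_neg:
                vec = -vec
        elif vec.sum() < 0:
            vec = -vec
        ev[idx] = vec
    return CompartmentTrack(ev=ev, gc=gc)


def saddle_profile(matrix: ContactMatrix, ev: np.ndarray | CompartmentTrack,
                   percentiles=None) -> SaddleResult:
    """Mean O/E between EV percentile groups (the saddle matrix).

    Bins are grouped by EV percentile (default cutoffs 5, 10, ..., 100);
    ``S[g, h]`` is the mean O/E over all intra-chromosomal bin pairs with one
    bin in group ``g`` and one in ``h``. Groups without bins give NaN rows.
    """
    if isinstance(ev, CompartmentTrack):
        ev = ev.ev
    if percentiles is None:
        percentiles = np.arange(5, 101, 5)
    percentiles = np.asarray(percentiles, dtype=float)
    if np.any(np.diff(percentiles) <= 0) or percentiles[-1] != 100:
        raise ValueError("percentiles must be strictly increasing and end at 100")
    valid = np.isfinite(ev) & matrix.mask
    cutoffs = np.percentile(ev[valid], percentiles)
    g = len(percentiles)
    group = np.full(matrix.n_bins, -1)
    # rank-based grouping: percentile groups have (near-)equal occupancy
    from scipy.stats import rankdata

    ranks = rankdata(ev[valid], method="ordinal") / valid.sum() * 100.0
    group[valid] = np.searchsorted(percentiles, ranks, side="left")
    group[valid] = np.minimum(group[valid], g - 1)
    sums = np.zeros((g, g))
    cnts = np.zeros((g, g))
    for chrom in matrix.bins.chromosomes:
        sl = matrix.bins.chromosome_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        idx = idx[group[idx] >= 0]
        if idx.size < 2:
            continue
        try:
            oe, rows, _ = matrix.matrix(chrom, norm=True, oe=True)
        except ValueError:
            continue
        keep = np.isin(rows, idx)
        oe = oe[np.ix_(keep, keep)]
        gg = group[rows[keep]]
        iu = np.triu_indices(oe.shape[0])
        vals = oe[iu]
        ok = np.isfinite(vals)
        gi, gj = gg[iu[0][ok]], gg[iu[1][ok]]
        np.add.at(sums, (gi, gj), vals[ok])
        np.add.at(cnts, (gi, gj), 1)
        np.add.at(sums, (gj, gi), vals[ok])
        np.add.at(cnts, (gj, gi), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    group_ev = np.array([
        ev[valid][group[valid] == k].mean() if (group[valid] == k).any() else np.nan
        for k in range(g)
    ])
    return SaddleResult(percentiles=percentiles, cutoffs=cutoffs,
                        group_ev=group_ev, saddle=s)


def compartment_strength(saddle: SaddleResult, corner_fraction: float = 0.2) -> float:
    """Corner-based compartmentalisation score ``log2(AA * BB / AB^2)``.

    ``AA`` is the mean O/E among the top ``corner_fraction`` of EV groups,
    ``BB`` among the bottom, ``AB`` the cross term. Computed on plain (not
    log) O/E saddle values.
    """
    g = saddle.saddle.shape[0]
    k = max(1, int(round(corner_fraction * g)))
    top = slice(g - k, g)
    bot = slice(0, k)
    aa = np.nanmean(saddle.saddle[top, top])
    bb = np.nanmean(saddle.saddle[bot, bot])
    ab = np.nanmean(saddle.saddle[top, bot])
    if not np.isfinite(ab) or ab == 0:
        raise ValueError("cross-compartment (AB) mean is zero or undefined")
    strength = float(np.log2(aa * bb / ab ** 2))
    saddle.strength = strength
    return strength
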