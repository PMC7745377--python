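"""Local-neighbourhood Poisson loop calling (a CPU HICCUPS-style caller).

Chromatin loops appear as focal pixels enriched over their local
neighbourhood. For every intra-chromosomal pixel sufficiently far from the
diagonal, four local expected values are computed — from the donut,
lower-left, horizontal and vertical neighbourhoods of half-width ``w``,
excluding the ``(2p+1)^2`` peak box — by scaling the distance-decay expected
model at the pixel with the observed/expected ratio of the neighbourhood on
the *raw count* scale (the bias product is folded into the expected value so
the observed count stays an integer and the Poisson model applies).

Observed counts are tested against ``Poisson(expected)``; p-values are
corrected per lambda chunk (expected values binned into powers of
``2^(1/3)``) with Benjamini-Hochberg. Pixels passing all four q-value and
enrichment thresholds are clustered by genomic distance and reported with
their cluster centroid. The computation is deterministic for fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import poisson

from .matrix import ContactMatrix

logger = logging.getLogger(__name__)

NEIGHBORHOODS = ("donut", "lower_left", "horizontal", "vertical")


@dataclass
class LoopCall:
    chromosome: str
    i: int                       # global bin indices, j > i
    j: int
    observed: int
    expected: dict               # per-neighbourhood expected count
    enrichment: dict             # observed / expected per neighbourhood
    q_values: dict
    cluster: int = -1
    is_centroid: bool = False


def _kernels(p: int, w: int) -> dict[str, np.ndarray]:
    """Neighbourhood masks on a (2w+1)^2 grid centred on the pixel."""
    size = 2 * w + 1
    di = np.arange(-w, w + 1)[:, None] * np.ones((1, size), dtype=int)
    dj = np.ones((size, 1), dtype=int) * np.arange(-w, w + 1)[None, :]
    peak = (np.abs(di) <= p) & (np.abs(dj) <= p)
    donut = ~peak & (di != 0) & (dj != 0)
    lower_left = (di >= 1) & (di <= w) & (dj <= -1) & (dj >= -w) & ~peak
    horizontal = (np.abs(di) <= p) & (np.abs(dj) > p)
    vertical = (np.abs(dj) <= p) & (np.abs(di) > p)
    return {
        "donut": donut.astype(float),
        "lower_left": lower_left.astype(float),
        "horizontal": horizontal.astype(float),
        "vertical": vertical.astype(float),
    }


def lambda_chunks(expected: np.ndarray, base: float = 2.0 ** (1.0 / 3.0)) -> np.ndarray:
    """Lambda-chunk index per expected value: chunk k covers (base^(k-1), base^k]."""
    out = np.zeros(expected.size, dtype=int)
    pos = expected > 1.0
    out[pos] = np.ceil(np.log(expected[pos]) / np.log(base)).astype(int)
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def chunked_qvalues(p: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """BH correction applied separately within each lambda chunk."""
    chunks = lambda_chunks(expected)
    q = np.empty_like(p)
    for c in np.unique(chunks):
        sel = chunks == c
        q[sel] = bh_qvalues(p[sel])
    return q


_DEFAULT_ENRICHMENT = {"donut": 1.75, "lower_left": 1.75,
                       "horizontal": 1.5, "vertical": 1.5}


def call_loops(matrix: ContactMatrix, p: int = 2, w: int = 5,
               fdr_cutoff: float | dict = 0.1,
               enrichment_cutoff: dict | None = None,
               merge_distance: int = 25_000,
               min_observed: int = 1,
               min_diagonal: int | None = None,
               singleton_enrichment: float = 2.0,
               singleton_q: float = 0.02) -> list[LoopCall]:
    """HICCUPS-style loop calls on a balanced matrix.

    ``p`` is the peak half-width and ``w`` the neighbourhood half-width in
    bins (``w > p >= 1``); pixels closer than ``min_diagonal`` (default
    ``w + p``) bins to the diagonal, or whose neighbourhood leaves the
    chromosome, are skipped. Candidates must pass the per-neighbourhood
    q-value cutoff(s) and enrichment cutoffs; surviving pixels are clustered
    by ``merge_distance`` (bp) with the strongest pixel as centroid.
    Single-pixel clusters face the stricter singleton rule — at least
    ``singleton_enrichment``-fold over the donut and lower-left expecteds
    and all q-values at most ``singleton_q`` — which suppresses isolated
    noise pixels that scrape past the per-neighbourhood thresholds.
    """
    if not matrix.is_balanced:
        raise ValueError("loop calling requires a balanced matrix")
    if w <= p or p < 1:
        raise ValueError("need neighbourhood half-width w > peak half-width p >= 1")
    if min_diagonal is None:
        min_diagonal = w + p
    if not isinstance(fdr_cutoff, dict):
        fdr_cutoff = {n: float(fdr_cutoff) for n in NEIGHBORHOODS}
    enrich = dict(_DEFAULT_ENRICHMENT)
    if enrichment_cutoff:
        enrich.update(enrichment_cutoff)
    exp_profile = matrix._expected()
    kernels = _kernels(p, w)
    bin_size = matrix.bins[0].length

    cand_rows = []
    for chrom in matrix.bins.chromosomes:
        sl = matrix.bins.chromosome_slice(chrom)
        nb = sl.stop - sl.start
        if nb < 2 * w + 2:
            continue
        raw, rows, _ = matrix.matrix(chrom, norm=False)
        raw = np.where(np.isnan(raw), 0.0, raw)
        bias = matrix.bias[sl]
        valid = matrix.mask[sl]
        # raw-scale expected model: e(d) / (b_i * b_j), zero on masked bins
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
        e_norm = exp_profile.intra[chrom][d]
        with np.errstate(divide="ignore", invalid="ignore"):
            bb = np.outer(bias, bias)
            e_raw = np.where(bb > 0, e_norm / np.where(bb > 0, bb, 1.0), 0.0)
        e_raw = np.where(np.isnan(e_raw), 0.0, e_raw)
        vv = np.outer(valid, valid).astype(float)
        raw = raw * vv
        e_raw = e_raw * vv

        iu, ju = np.triu_indices(nb, k=min_diagonal)
        # complete neighbourhood: inside the chromosome and off the diagonal
        ok = (iu >= w) & (ju < nb - w) & ((ju - iu) >= min_diagonal) \
            & valid[iu] & valid[ju]
        obs = raw[iu, ju]
        ok &= obs >= min_observed
        if not ok.any():
            continue

        exp_n = {}
        passing = ok.copy()
        for name, kern in kernels.items():
            num = ndimage.convolve(raw, kern[::-1, ::-1], mode="constant")
            den = ndimage.convolve(e_raw, kern[::-1, ::-1], mode="constant")
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            e_here = scale * e_raw
            exp_n[name] = e_here[iu, ju]
            passing &= np.isfinite(exp_n[name]) & (exp_n[name] > 0)
        if not passing.any():
            continue
        idx = np.where(passing)[0]
        obs_i = np.rint(obs[idx]).astype(int)
        qvals = {}
        keep = np.ones(idx.size, dtype=bool)
        for name in NEIGHBORHOODS:
            lam = exp_n[name][idx]
            pv = poisson.sf(obs_i - 1, lam)
            q = chunked_qvalues(pv, lam)
            qvals[name] = q
            keep &= (q <= fdr_cutoff[name]) & (obs_i / lam >= enrich[name])
        for k in np.where(keep)[0]:
            gi = int(rows[iu[idx[k]]])
            gj = int(rows[ju[idx[k]]])
            cand_rows.append(LoopCall(
                chromosome=chrom, i=gi, j=gj, observed=int(obs_i[k]),
                expected={n: float(exp_n[n][idx[k]]) for n in NEIGHBORHOODS},
                enrichment={n: float(obs_i[k] / exp_n[n][idx[k]])
                            for n in NEIGHBORHOODS},
                q_values={n: float(qvals[n][k]) for n in NEIGHBORHOODS},
            ))

    # deterministic clustering by merge distance
    merge_bins = max(1, int(round(merge_distance / bin_size)))
    cand_rows.sort(key=lambda c: (c.chromosome, c.i, c.j))
    cluster_id = 0
    assigned = [False] * len(cand_rows)
    for a in range(len(cand_rows)):
        if assigned[a]:
            continue
        stack = [a]
        members = []
        assigned[a] = True
        while stack:
            u = stack.pop()
            members.append(u)
            cu = cand_rows[u]
            for b in range(len(cand_rows)):
                if assigned[b]:
                    continue
                cb = cand_rows[b]
                if (cb.chromosome == cu.chromosome
                        and abs(cb.i - cu.i) <= merge_bins
                        and abs(cb.j - cu.j) <= merge_bins):
                    assigned[b] = True
                    stack.append(b)
        if len(members) == 1:
            c = cand_rows[members[0]]
            if (c.enrichment["donut"] < singleton_enrichment
                    or c.enrichment["lower_left"] < singleton_enrichment
                    or max(c.q_values.values()) > singleton_q):
                c.cluster = -1
                continue
        best = max(members, key=lambda m: (cand_rows[m].enrichment["donut"],
                                           -cand_rows[m].i, -cand_rows[m].j))
        for m in members:
            cand_rows[m].cluster = cluster_id
            cand_rows[m].is_centroid = m == best
        cluster_id += 1
    return [c for c in cand_rows if c.cluster >= 0]


def loops_to_frame(calls, bins) -> pd.DataFrame:
    rows = []
    for c in calls:
        r1, r2 = bins[c.i], bins[c.j]
        row = {
            "chromosome1": r1.chromosome, "start1": r1.start, "end1": r1.end,
            "chromosome2": r2.chromosome, "start2": r2.start, "end2": r2.end,
            "observed": c.observed,
        }
        for n in NEIGHBORHOODS:
            row[f"expected_{n}"] = c.expected[n]
            row[f"q_{n}"] = c.q_values[n]
        row["cluster"] = c.cluster
        row["is_centroid"] = c.is_centroid
        rows.append(row)
    return pd.DataFrame(rows)


def write_bedpe(calls, bins, path, centroids_only: bool = True) -> None:
    with open(path, "w") as fh:
        for c in calls:
            if centroids_only and not c.is_centroid:
                continue
            r1, r2 = bins[c.i], bins[c.j]
            fh.write(f"{r1.chromosome}\t{r1.start}\t{r1.end}\t"
                     f"{r2.chromosome}\t{r2.start}\t{r2.end}\t"
                     f"loop_{c.cluster}\t{c.observed}\n")
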