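"""Inter-sample comparisons: difference / fold-change maps and sample PCA.

Comparisons are bin- or pixel-wise between two samples on identical bin
sets: ``difference = a - b`` (minuend first) or ``fold-change = a / b``
(optionally log2). Results are defined only where both operands are, and a
difference track behaves like any score track downstream — in particular it
can be fed to boundary calling unchanged.

Sample-level PCA summarises similarity across many matrices: pixels passing
the configured filters (intra-chromosomal, distance band, largest variance
or value across samples) form each sample's feature vector; features are
centred across samples and decomposed by SVD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .domains import ScoreTrack
from .matrix import ContactMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coordinates: np.ndarray        # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    n_features: int
    filter_description: str


def _check_same_bins(a: ContactMatrix, b: ContactMatrix) -> None:
    if a.n_bins != b.n_bins:
        raise ValueError(f"bin sets differ: {a.n_bins} vs {b.n_bins} bins")
    for ra, rb in zip(a.bins, b.bins):
        if (ra.chromosome, ra.start, ra.end) != (rb.chromosome, rb.start, rb.end):
            raise ValueError(f"bin sets diverge first at {ra} vs {rb}")


def compare_matrices(a: ContactMatrix, b: ContactMatrix,
                     method: str = "difference", log2: bool = False,
                     oe: bool = False) -> ContactMatrix:
    """Pixel-wise comparison of two matrices on the same bins (``a`` minuend).

    Returns a new matrix whose "raw" pixel values hold the comparison;
    masked wherever either input is masked. Fold-change pixels with zero
    denominator are dropped (missing).
    """
    _check_same_bins(a, b)
    mask = a.mask & b.mask
    n = a.n_bins
    import scipy.sparse as sp

    if oe:
        ia, ja, va = a.oe_pixels()
        ib, jb, vb = b.oe_pixels()
        ma = sp.coo_matrix((va, (ia, ja)), shape=(n, n)).tocsr()
        mb = sp.coo_matrix((vb, (ib, jb)), shape=(n, n)).tocsr()
    else:
        ia, ja, va = a.pixels(norm=True)
        ib, jb, vb = b.pixels(norm=True)
        ma = sp.coo_matrix((va, (ia, ja)), shape=(n, n)).tocsr()
        mb = sp.coo_matrix((vb, (ib, jb)), shape=(n, n)).tocsr()
    if method == "difference":
        out = (ma - mb).tocoo()
        i, j, v = out.row, out.col, out.data
    elif method == "fold-change":
        union = (ma != 0) + (mb != 0)
        union = sp.triu(union).tocoo()
        i, j = union.row, union.col
        num = np.asarray(ma[i, j]).ravel()
        den = np.asarray(mb[i, j]).ravel()
        ok = den != 0
        i, j = i[ok], j[ok]
        with np.errstate(divide="ignore"):
            v = num[ok] / den[ok]
            if log2:
                v = np.log2(v)
    else:
        raise ValueError(f"unknown comparison method {method!r}")
    keep = mask[i] & mask[j] & (v != 0)
    result = ContactMatrix(a.bins, (i[keep], j[keep], v[keep]),
                           mask=mask.copy(), auto_mask_zeros=False,
                           metadata={"comparison": method,
                                     "normalisation": "comparison"})
    return result


def compare_tracks(a: ScoreTrack, b: ScoreTrack, method: str = "difference",
                   log2: bool = False) -> ScoreTrack:
    """Bin-wise comparison of two score tracks (``a`` minuend)."""
    if len(a.bins) != len(b.bins) or a.windows != b.windows:
        raise ValueError("score tracks must share bins and window sizes")
    if method == "difference":
        scores = a.scores - b.scores
    elif method == "fold-change":
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(b.scores != 0, a.scores / b.scores, np.nan)
            if log2:
                scores = np.log2(scores)
    else:
        raise ValueError(f"unknown comparison method {method!r}")
    return ScoreTrack(bins=a.bins, windows=list(a.windows), scores=scores)


def compare(a, b, method: str = "difference", log2: bool = False):
    """Dispatch comparison for matrices, score tracks or plain arrays."""
    if isinstance(a, ContactMatrix):
        return compare_matrices(a, b, method=method, log2=log2)
    if isinstance(a, ScoreTrack):
        return compare_tracks(a, b, method=method, log2=log2)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "difference":
        return a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(b != 0, a / b, np.nan)
        return np.log2(fc) if log2 else fc


def matrix_pca(samples, n_components: int = 2, oe: bool = True,
               intra_only: bool = True, min_distance: int = 100_000,
               max_distance: int = 10_000_000,
               top_k_variance: int | None = None,
               top_k_value: int | None = None) -> PcaResult:
    """PCA of samples over filtered matrix pixels.

    All samples must share a bin set. Pixels are filtered to
    intra-chromosomal contacts within a genomic distance band (the
    informative range; near-diagonal and inter pixels are noise-dominated),
    optionally reduced to the ``top_k_variance`` most variable or
    ``top_k_value`` strongest features across samples. Features are centred
    across samples and decomposed with dense SVD (scikit-learn PCA).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    ref = samples[0]
    for s in samples[1:]:
        _check_same_bins(ref, s)
    bins = ref.bins
    bin_size = bins[0].length
    n = ref.n_bins
    chrom_of = np.empty(n, dtype=object)
    for chrom in bins.chromosomes:
        chrom_of[bins.chromosome_slice(chrom)] = chrom
    mask = np.logical_and.reduce([s.mask for s in samples])

    features = []
    for s in samples:
        i, j, v = s.oe_pixels() if oe else s.pixels(norm=True)
        import scipy.sparse as sp

        m = sp.coo_matrix((v, (i, j)), shape=(n, n)).tocsr()
        features.append(m)
    # union of nonzero pixels across samples
    union = features[0] != 0
    for m in features[1:]:
        union = union + (m != 0)
    union = union.tocoo()
    i, j = union.row, union.col
    keep = mask[i] & mask[j]
    if intra_only:
        keep &= chrom_of[i] == chrom_of[j]
        d = np.abs(j - i) * bin_size
        keep &= (d >= min_distance) & (d <= max_distance)
    i, j = i[keep], j[keep]
    x = np.vstack([np.asarray(m[i, j]).ravel() for m in features])
    if top_k_variance is not None:
        var = x.var(axis=0)
        order = np.argsort(-var, kind="stable")[:top_k_variance]
        x = x[:, order]
    if top_k_value is not None:
        val = x.sum(axis=0)
        order = np.argsort(-val, kind="stable")[:top_k_value]
        x = x[:, order]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 pixels survive the PCA filters")
    from sklearn.decomposition import PCA

    n_components = min(n_components, len(samples), x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    desc = (f"oe={oe} intra_only={intra_only} distance={min_distance}-{max_distance}"
            f" top_k_variance={top_k_variance} top_k_value={top_k_value}")
    return PcaResult(coordinates=coords,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     n_features=x.shape[1], filter_description=desc)
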