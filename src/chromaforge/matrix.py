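"""Binned Hi-C contact matrices: construction, filtering, balancing, O/E.

A :class:`ContactMatrix` stores sparse upper-triangle raw counts over a bin
:class:`~chromaforge.regions.RegionSet`, a per-bin bias vector ``b`` produced
by matrix balancing (the normalised value of pixel ``(i, j)`` is
``b_i * b_j * raw_ij``), a per-bin valid mask, and cached expected-value
(distance-decay) profiles. Bins whose contacts sum to zero are always masked;
masked bins never contribute to any downstream quantity.

Balancing finds ``b_i > 0`` such that the normalised matrix has equal row
sums over valid bins (unit row sums by default), either with the Knight-Ruiz
inner-outer Newton iteration or with Sinkhorn-style iterative correction
(ICE). Both are applied per chromosome by default; whole-genome balancing is
available as a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

from .regions import GenomicRegion, RegionSet

logger = logging.getLogger(__name__)


class BalancingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# balancing kernels (dense, symmetric, strictly on valid bins)

def kr_balance(a: np.ndarray, tol: float = 1e-12, max_outer: int = 100) -> np.ndarray:
    """Knight-Ruiz balancing of a symmetric non-negative matrix.

    Returns ``x > 0`` with ``diag(x) @ a @ diag(x)`` doubly stochastic
    (row sums 1). Inner-outer Newton iteration with conjugate-gradient
    inner solves, following the standard bnewt scheme.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise BalancingError("negative entries in contact matrix")
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (a @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    it = 0
    while rout > rt:
        it += 1
        if it > max_outer:
            raise BalancingError("KR balancing did not converge")
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        p = np.zeros(n)
        z = np.zeros(n)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                z = rk / v
                p = z.copy()
                rho_km1 = rk @ z
            else:
                beta = rho_km1 / rho_km2
                p = z + beta * p
            w = x * (a @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                break
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = ((big_delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            z = rk / v
            rho_km1 = rk @ z
            if k > 2 * n:
                break
        x = x * y
        v = x * (a @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold if rold > 0 else 0.0
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, stop_tol))
        if not np.all(np.isfinite(x)) or np.any(x <= 0):
            raise BalancingError("KR balancing produced non-positive factors")
    return x


def ice_balance(a: np.ndarray, tol: float = 1e-12, max_iter: int = 5000) -> np.ndarray:
    """Iterative correction (Sinkhorn-style) of a symmetric non-negative matrix.

    Alternately divides by (mean-normalised) marginals until they are flat,
    then rescales to unit row sums; returns the bias vector ``x``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise BalancingError("negative entries in contact matrix")
    n = a.shape[0]
    w = a.copy()
    b = np.ones(n)
    for _ in range(max_iter):
        s = w.sum(axis=1)
        if np.any(s <= 0):
            raise BalancingError("ICE encountered a zero marginal on a valid bin")
        s = s / s.mean()
        w = w / np.outer(s, s)
        b = b / s
        if np.abs(s - 1.0).max() < tol:
            break
    else:
        raise BalancingError("ICE did not converge")
    # rescale to unit row sums
    rowsum = w.sum(axis=1).mean()
    b = b / np.sqrt(rowsum)
    return b


@dataclass
class ExpectedProfile:
    """Distance-decay expected values with valid-pair denominators."""

    intra: dict[str, np.ndarray]            # per-chromosome e_c(d)
    intra_counts: dict[str, np.ndarray]     # valid bin pairs at distance d
    genome: np.ndarray                      # pooled intra e(d)
    inter: float                            # inter-chromosomal scalar expected

    def expected(self, chromosome: str, d: int | np.ndarray) -> np.ndarray:
        return self.intra[chromosome][d]


class ContactMatrix:
    """Sparse symmetric binned Hi-C matrix with bias, mask and expected values."""

    def __init__(self, bins: RegionSet, pixels=None, bias=None, mask=None,
                 metadata=None, auto_mask_zeros: bool = True):
        self.bins = bins
        n = len(bins)
        if pixels is None:
            m = sp.csr_matrix((n, n), dtype=float)
        elif sp.issparse(pixels):
            m = sp.triu(pixels.tocoo(), k=0).tocsr()
        else:
            i, j, v = pixels
            i = np.asarray(i, dtype=np.int64)
            j = np.asarray(j, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            swap = i > j
            i2 = np.where(swap, j, i)
            j2 = np.where(swap, i, j)
            m = sp.coo_matrix((v, (i2, j2)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        self._m = m
        self.bias = np.ones(n) if bias is None else np.asarray(bias, dtype=float)
        self.mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        self.metadata = dict(metadata or {})
        self.expected_profile: ExpectedProfile | None = None
        # always mask zero-marginal bins (not meaningful for signed comparisons)
        if auto_mask_zeros:
            self.mask &= self.raw_marginals() > 0
            self.bias[~self.mask] = 0.0

    # -- basic accessors ----------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_size(self) -> int:
        return max(r.length for r in self.bins.regions[:1]) if self.bins.regions else 0

    @property
    def is_balanced(self) -> bool:
        return self.metadata.get("normalisation", "none") != "none"

    def raw_marginals(self) -> np.ndarray:
        u = self._m
        return np.asarray(u.sum(axis=1)).ravel() + np.asarray(u.sum(axis=0)).ravel() \
            - u.diagonal()

    def marginals(self, norm: bool = True) -> np.ndarray:
        """Per-bin contact sums; balanced scale by default (NaN on masked bins)."""
        if not norm:
            out = self.raw_marginals().astype(float)
        else:
            b = self.bias
            u = sp.csr_matrix(self._m, copy=True)
            u = sp.diags(b) @ u @ sp.diags(b)
            out = np.asarray(u.sum(axis=1)).ravel() + np.asarray(u.sum(axis=0)).ravel() \
                - u.diagonal()
        out[~self.mask] = np.nan
        return out

    def pixels(self, norm: bool = True):
        """Upper-triangle pixel arrays ``(i, j, value)``, masked bins excluded."""
        coo = self._m.tocoo()
        keep = self.mask[coo.row] & self.mask[coo.col]
        i, j, v = coo.row[keep], coo.col[keep], coo.data[keep]
        if norm:
            v = v * self.bias[i] * self.bias[j]
        return i, j, v

    # -- construction -------------------------------------------------------

    @classmethod
    def from_pairs(cls, pair_sets, bins: RegionSet,
                   fragments: RegionSet | None = None) -> "ContactMatrix":
        """Bin one or more valid-pair streams into a raw contact matrix.

        Bin membership is decided by the fragment midpoint (read position when
        no fragment map is given); multiple pair streams are summed, which
        also covers matrix merging.
        """
        pair_sets = list(pair_sets)
        if pair_sets and hasattr(pair_sets[0], "left"):  # a single pair stream
            pair_sets = [pair_sets]
        ii, jj = [], []
        for pairs in pair_sets:
            for p in pairs:
                locs = []
                for side in (p.left, p.right):
                    if fragments is not None and side.fragment >= 0:
                        frag = fragments[side.fragment]
                        pos = int(frag.center)
                        chrom = frag.chromosome
                    else:
                        pos, chrom = side.position, side.chromosome
                    if chrom not in bins.chromosome_lengths:
                        raise ValueError(f"chromosome {chrom!r} not in bin genome")
                    locs.append(bins.region_at(chrom, min(pos, bins.chromosome_lengths[chrom] - 1)).index)
                a, b = min(locs), max(locs)
                ii.append(a)
                jj.append(b)
        v = np.ones(len(ii))
        return cls(bins, (np.array(ii, dtype=np.int64), np.array(jj, dtype=np.int64), v))

    @classmethod
    def from_dense(cls, bins: RegionSet, dense: np.ndarray, **kw) -> "ContactMatrix":
        dense = np.asarray(dense, dtype=float)
        iu = np.triu_indices(dense.shape[0])
        vals = dense[iu]
        nz = vals != 0
        return cls(bins, (iu[0][nz], iu[1][nz], vals[nz]), **kw)

    # -- matrix-level filters ------------------------------------------------

    def mask_low_coverage(self, cutoff: float | None = None,
                          rel_cutoff: float | None = None) -> np.ndarray:
        """Mask bins whose raw marginal falls below an absolute or relative cutoff.

        In relative mode the cutoff is ``rel_cutoff`` times the median of the
        nonzero marginals. Zero-marginal bins are always masked.
        """
        if cutoff is not None and rel_cutoff is not None:
            raise ValueError("give either an absolute or a relative cutoff, not both")
        marg = self.raw_marginals()
        if rel_cutoff is not None:
            nonzero = marg[marg > 0]
            cutoff = rel_cutoff * (np.median(nonzero) if nonzero.size else 0.0)
        if cutoff is not None:
            self.mask &= marg >= cutoff
        self.mask &= marg > 0
        self.bias[~self.mask] = 0.0
        self.expected_profile = None
        return self.mask

    def drop_diagonals(self, k: int) -> None:
        """Zero out the first ``k`` diagonals (``|i - j| < k``)."""
        coo = self._m.tocoo()
        keep = (coo.col - coo.row) >= k
        self._m = sp.coo_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
        ).tocsr()
        self.expected_profile = None

    # -- balancing -----------------------------------------------------------

    def balance(self, method: str = "kr", tolerance: float = 1e-12,
                max_iter: int = 100, whole_genome: bool = False,
                rescale: bool = True) -> np.ndarray:
        """Compute the bias vector so normalised row sums are equal.

        ``method`` is ``"kr"`` (Knight-Ruiz) or ``"ice"`` (iterative
        correction). Per-chromosome by default. With ``rescale`` (default)
        valid-bin marginals become exactly 1; otherwise the normalised matrix
        keeps the raw total count scale.
        """
        method = method.lower()
        if method not in ("kr", "ice"):
            raise ValueError(f"unknown balancing method {method!r}")
        kernel = kr_balance if method == "kr" else ice_balance
        bias = np.zeros(self.n_bins)
        groups = ([None] if whole_genome else self.bins.chromosomes)
        for chrom in groups:
            if chrom is None:
                idx = np.where(self.mask)[0]
                label = "genome"
            else:
                sl = self.bins.chromosome_slice(chrom)
                idx = np.arange(sl.start, sl.stop)[self.mask[sl]]
                label = chrom
            if idx.size == 0:
                continue
            sub = self._dense_raw(idx)
            try:
                x = kernel(sub, tol=tolerance, max_iter=max_iter) if method == "ice" \
                    else kernel(sub, tol=tolerance, max_outer=max_iter)
            except BalancingError as exc:
                raise BalancingError(f"{label}: {exc}") from exc
            bias[idx] = x
        if not rescale:
            # preserve raw total-count scale
            i, j, v = self.pixels(norm=False)
            total_raw = v.sum()
            total_norm = (v * bias[i] * bias[j]).sum()
            if total_norm > 0:
                bias *= np.sqrt(total_raw / total_norm)
        self.bias = bias
        self.metadata["normalisation"] = method
        self.expected_profile = None
        return bias

    def _dense_raw(self, idx: np.ndarray) -> np.ndarray:
        sub = self._m[np.ix_(idx, idx)].toarray()
        sub = sub + np.triu(sub, k=1).T
        return sub

    # -- expected values and O/E ---------------------------------------------

    def expected_values(self, norm: bool = True) -> ExpectedProfile:
        """Per-chromosome and genome-wide expected contact values by distance.

        ``e_c(d)`` is the sum of (normalised) pixel values at bin distance
        ``d`` within chromosome ``c`` divided by the number of *valid* bin
        pairs at that distance; the genome-wide profile pools chromosomes,
        and the inter-chromosomal expected is a single scalar.
        """
        intra, counts = {}, {}
        max_n = 0
        total_all = 0.0
        i_all, j_all, v_all = self.pixels(norm=norm)
        chrom_of = np.empty(self.n_bins, dtype=object)
        for chrom in self.bins.chromosomes:
            sl = self.bins.chromosome_slice(chrom)
            chrom_of[sl] = chrom
        intra_mask = chrom_of[i_all] == chrom_of[j_all]
        any_intra = False
        for chrom in self.bins.chromosomes:
            sl = self.bins.chromosome_slice(chrom)
            nb = sl.stop - sl.start
            if nb == 0:
                continue
            max_n = max(max_n, nb)
            valid = self.mask[sl]
            nvalid_at = np.zeros(nb)
            vidx = np.where(valid)[0]
            if vidx.size:
                d = np.abs(vidx[:, None] - vidx[None, :])
                du, dc = np.unique(d[np.triu_indices(vidx.size)], return_counts=True)
                nvalid_at[du] = dc
            sums = np.zeros(nb)
            sel = intra_mask & (chrom_of[i_all] == chrom)
            if sel.any():
                np.add.at(sums, (j_all[sel] - i_all[sel]), v_all[sel])
                any_intra = True
            with np.errstate(invalid="ignore", divide="ignore"):
                e = np.where(nvalid_at > 0, sums / np.maximum(nvalid_at, 1), np.nan)
            intra[chrom] = e
            counts[chrom] = nvalid_at
        if not any_intra:
            raise ValueError("no valid intra-chromosomal pixels")
        g_sum = np.zeros(max_n)
        g_cnt = np.zeros(max_n)
        for chrom, e in intra.items():
            nb = e.size
            c = counts[chrom]
            g_sum[:nb] += np.where(c > 0, e * c, 0.0)
            g_cnt[:nb] += c
        with np.errstate(invalid="ignore", divide="ignore"):
            genome = np.where(g_cnt > 0, g_sum / np.maximum(g_cnt, 1), np.nan)
        # inter-chromosomal scalar
        inter_sum = float(v_all[~intra_mask].sum())
        n_valid_per_chrom = {
            c: int(self.mask[self.bins.chromosome_slice(c)].sum())
            for c in self.bins.chromosomes
        }
        tot_valid = sum(n_valid_per_chrom.values())
        inter_pairs = (tot_valid ** 2 - sum(n ** 2 for n in n_valid_per_chrom.values())) // 2
        inter = inter_sum / inter_pairs if inter_pairs > 0 else np.nan
        total_all += float(v_all.sum())
        self.expected_profile = ExpectedProfile(intra, counts, genome, inter)
        return self.expected_profile

    def _expected(self) -> ExpectedProfile:
        if self.expected_profile is None:
            self.expected_values()
        return self.expected_profile

    def oe_pixels(self, log2: bool = False, per_chromosome: bool = True):
        """Observed/expected pixel stream ``(i, j, value)`` over valid bins."""
        exp = self._expected()
        i, j, v = self.pixels(norm=True)
        chrom_of = np.empty(self.n_bins, dtype=object)
        offs = np.zeros(self.n_bins, dtype=np.int64)
        for chrom in self.bins.chromosomes:
            sl = self.bins.chromosome_slice(chrom)
            chrom_of[sl] = chrom
            offs[sl] = sl.start
        out = np.empty_like(v)
        intra = chrom_of[i] == chrom_of[j]
        for chrom in self.bins.chromosomes:
            sel = intra & (chrom_of[i] == chrom)
            if not sel.any():
                continue
            e = exp.intra[chrom] if per_chromosome else exp.genome
            ed = e[j[sel] - i[sel]]
            if np.any((ed == 0) & (v[sel] != 0)):
                raise ValueError("expected value 0 at a distance with nonzero pixels")
            out[sel] = v[sel] / ed
        if (~intra).any():
            if exp.inter == 0:
                raise ValueError("inter-chromosomal expected value is 0")
            out[~intra] = v[~intra] / exp.inter
        if log2:
            with np.errstate(divide="ignore"):
                out = np.log2(out)
        return i, j, out

    # -- dense queries --------------------------------------------------------

    def region_bins(self, region: GenomicRegion | str) -> np.ndarray:
        if isinstance(region, str):
            region = parse_region(region, self.bins.chromosome_lengths)
        hits = self.bins.overlapping(region)
        return np.array([r.index for r in hits], dtype=np.int64)

    def matrix(self, region1=None, region2=None, norm: bool = True,
               oe: bool = False, log2: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense symmetric-completed submatrix with masked bins as NaN.

        Returns ``(array, row_bins, col_bins)`` where the bin arrays are the
        global bin indices of the rows and columns.
        """
        if region1 is None:
            rows = np.arange(self.n_bins)
        else:
            rows = self.region_bins(region1)
        cols = rows if region2 is None else self.region_bins(region2)
        if rows.size == 0 or cols.size == 0:
            raise ValueError("region outside the matrix genome")
        full = self._m[np.ix_(rows, cols)].toarray()
        fullT = self._m[np.ix_(cols, rows)].toarray().T
        sub = full + fullT
        # the diagonal was added twice where row and column bins coincide
        eq = rows[:, None] == cols[None, :]
        if eq.any():
            diag = self._m.diagonal()
            sub -= np.where(eq, diag[rows][:, None], 0.0)
        if norm or oe:
            sub = sub * np.outer(self.bias[rows], self.bias[cols])
        if oe:
            exp = self._expected()
            chrom_r = np.array([self.bins[r].chromosome for r in rows], dtype=object)
            chrom_c = np.array([self.bins[c].chromosome for c in cols], dtype=object)
            e = np.full(sub.shape, exp.inter)
            for chrom in np.unique(chrom_r):
                rsel = chrom_r == chrom
                csel = chrom_c == chrom
                if not csel.any():
                    continue
                sl = self.bins.chromosome_slice(chrom)
                dmat = np.abs(rows[rsel][:, None] - cols[csel][None, :])
                e[np.ix_(rsel, csel)] = exp.intra[chrom][dmat]
            with np.errstate(invalid="ignore", divide="ignore"):
                sub = sub / e
        if log2:
            with np.errstate(divide="ignore", invalid="ignore"):
                sub = np.log2(sub)
        bad_r = ~self.mask[rows]
        bad_c = ~self.mask[cols]
        sub[bad_r, :] = np.nan
        sub[:, bad_c] = np.nan
        return sub, rows, cols

    # spec name
    fetch = matrix

    def virtual_4c(self, anchor, window=None, norm: bool = True,
                   oe: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Mean contact profile of an anchor region across a window.

        Returns ``(values, window_bin_indices)``; masked anchor bins are
        excluded from the mean and masked window bins are NaN. The window
        defaults to the anchor's whole chromosome.
        """
        if window is None:
            if isinstance(anchor, str):
                anchor = parse_region(anchor, self.bins.chromosome_lengths)
            window = anchor.chromosome
        sub, rows, cols = self.matrix(anchor, window, norm=norm, oe=oe)
        good = self.mask[rows]
        if not good.any():
            return np.full(cols.size, np.nan), cols
        vals = np.nanmean(sub[good, :], axis=0)
        return vals, cols

    # -- I/O -------------------------------------------------------------------

    def to_triplets(self, path, norm: bool = False) -> None:
        """Write ``bin1 bin2 value`` upper-triangle text (value-exact)."""
        i, j, v = self.pixels(norm=norm)
        with open(path, "w") as fh:
            fh.write("#bin1\tbin2\tvalue\n")
            for a, b, c in zip(i, j, v):
                fh.write(f"{a}\t{b}\t{float(c)!r}\n")

    @classmethod
    def from_triplets(cls, path, bins: RegionSet, **kw) -> "ContactMatrix":
        i, j, v = [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                a, b, c = line.split()
                i.append(int(a))
                j.append(int(b))
                v.append(float(c))
        return cls(bins, (np.array(i), np.array(j), np.array(v)), **kw)

    def to_bedgraph2(self, path, norm: bool = True) -> None:
        i, j, v = self.pixels(norm=norm)
        with open(path, "w") as fh:
            for a, b, c in zip(i, j, v):
                r1, r2 = self.bins[a], self.bins[b]
                fh.write(f"{r1.chromosome}\t{r1.start}\t{r1.end}\t"
                         f"{r2.chromosome}\t{r2.start}\t{r2.end}\t{float(c)!r}\n")

    @classmethod
    def from_bedgraph2(cls, path, bins: RegionSet, **kw) -> "ContactMatrix":
        i, j, v = [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.split()
                r1 = bins.region_at(f[0], (int(f[1]) + int(f[2])) // 2)
                r2 = bins.region_at(f[3], (int(f[4]) + int(f[5])) // 2)
                i.append(r1.index)
                j.append(r2.index)
                v.append(float(f[6]))
        return cls(bins, (np.array(i), np.array(j), np.array(v)), **kw)

    def save(self, path) -> None:
        """Write the native hierarchical container (HDF5, deterministic order)."""
        with h5py.File(path, "w", track_order=True) as f:
            grp = f.create_group("bins")
            chroms = self.bins.chromosomes
            code = {c: k for k, c in enumerate(chroms)}
            grp.create_dataset("chrom_code",
                               data=np.array([code[r.chromosome] for r in self.bins]))
            grp.create_dataset("start", data=np.array([r.start for r in self.bins]))
            grp.create_dataset("end", data=np.array([r.end for r in self.bins]))
            grp.create_dataset("chrom_names",
                               data=np.array(chroms, dtype=h5py.string_dtype()))
            grp.create_dataset(
                "chrom_lengths",
                data=np.array([self.bins.chromosome_lengths[c] for c in chroms]))
            coo = self._m.tocoo()
            px = f.create_group("pixels")
            px.create_dataset("bin1", data=coo.row)
            px.create_dataset("bin2", data=coo.col)
            px.create_dataset("value", data=coo.data)
            f.create_dataset("bias", data=self.bias)
            f.create_dataset("mask", data=self.mask)
            for k, v in sorted(self.metadata.items()):
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "ContactMatrix":
        with h5py.File(path, "r") as f:
            names = [s.decode() if isinstance(s, bytes) else s
                     for s in f["bins/chrom_names"][:]]
            lengths = dict(zip(names, f["bins/chrom_lengths"][:].tolist()))
            code = f["bins/chrom_code"][:]
            starts = f["bins/start"][:]
            ends = f["bins/end"][:]
            regions = [GenomicRegion(names[c], int(s), int(e))
                       for c, s, e in zip(code, starts, ends)]
            bins = RegionSet(regions, lengths)
            obj = cls(
                bins,
                (f["pixels/bin1"][:], f["pixels/bin2"][:], f["pixels/value"][:]),
                bias=f["bias"][:],
                mask=f["mask"][:],
                metadata=dict(f.attrs),
            )
        return obj


def parse_region(text: str, chromosome_lengths: dict[str, int]) -> GenomicRegion:
    """Parse ``chrom`` or ``chrom:start-end`` region strings (0-based half-open)."""
    if ":" in text:
        chrom, span = text.split(":", 1)
        start, end = span.replace(",", "").split("-")
        return GenomicRegion(chrom, int(start), int(end))
    if text not in chromosome_lengths:
        raise ValueError(f"unknown chromosome {text!r}")
    return GenomicRegion(text, 0, chromosome_lengths[text])
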