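"""Deterministic synthetic Hi-C data with known ground truth.

The generator emulates the large-scale statistical structure of mammalian
Hi-C maps rather than polymer physics: a power-law distance decay
``scale * (1 + d)^-alpha`` modulated by multiplicative factors for
checkerboard (plaid) compartments, within-TAD enrichment and focal loops,
with Poisson sampling noise and optional multiplicative log-normal noise.
Read-pair simulation plants disjoint artefact classes (PCR duplicates,
self-ligations, short inward/outward ligation errors, low-quality and
unmapped mates) at exact counts, so every filter's removal count is known
in advance.

A single integer seed fully determines every output; sub-generators are
spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix
from .pairs import FragmentPair, PairSide, _orientation
from .regions import GenomicRegion, RegionSet, make_bins


@dataclass
class SimulationConfig:
    """Parameters of the synthetic Hi-C generator.

    Defaults describe a small, realistic single-chromosome experiment:
    10 kb bins over 5 Mb, decay exponent 1 (the fractal-globule regime),
    sequencing depth giving ~50 counts on the diagonal.
    """

    seed: int = 0
    chromosome_lengths: dict = field(default_factory=lambda: {"chr1": 5_000_000})
    bin_size: int = 10_000
    decay_exponent: float = 1.0
    scale: float = 50.0
    # compartments: alternating A/B blocks of `compartment_size` bins
    plaid_contrast: float = 0.0
    compartment_size: int = 25
    # TADs: boundaries every `tad_size` bins (jittered), within-TAD enrichment
    n_boundaries: int = 0
    tad_enrichment: float = 2.0
    # loops: list of (chromosome, pos1, pos2, fold); or n_loops random ones
    loops: list = field(default_factory=list)
    n_loops: int = 0
    loop_fold: float = 8.0
    # noise
    poisson: bool = True
    noise_sigma: float = 0.0
    # pair simulation
    n_pairs: int = 10_000
    fragment_size: int = 500
    artefact_fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be positive")
        fr = self.artefact_fractions
        if any(not (0 <= v <= 1) for v in fr.values()) or sum(fr.values()) > 1:
            raise ValueError("artefact fractions must lie in [0,1] and sum to <= 1")


def _streams(seed: int, name: str) -> np.random.Generator:
    # stable sub-stream derivation (hash() is salted per process; avoid it)
    key = sum(ord(c) * 31 ** k for k, c in enumerate(name)) % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def simulate_matrix(config: SimulationConfig):
    """Simulate a contact matrix plus ground-truth feature tables.

    Returns ``(matrix, truth)`` where ``truth`` has keys ``boundaries``
    (list of boundary bin regions), ``loops`` (list of region pairs) and
    ``compartments`` (per-bin +1/-1 labels, 0 where undefined).
    """
    rng = _streams(config.seed, "matrix")
    bins = make_bins(config.chromosome_lengths, config.bin_size)
    n = len(bins)
    labels = np.zeros(n, dtype=int)
    boundaries: list[GenomicRegion] = []
    loop_pairs: list[tuple[GenomicRegion, GenomicRegion]] = []

    ii, jj, vv = [], [], []
    for chrom in bins.chromosomes:
        sl = bins.chromosome_slice(chrom)
        nb = sl.stop - sl.start
        d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
        mu = config.scale * (1.0 + d) ** (-config.decay_exponent)

        if config.plaid_contrast > 0:
            lab = np.where((np.arange(nb) // config.compartment_size) % 2 == 0, 1, -1)
            labels[sl] = lab
            same = lab[:, None] == lab[None, :]
            c = config.plaid_contrast
            mu = mu * np.where(same, 1.0 + c, 1.0 / (1.0 + c))

        if config.n_boundaries > 0:
            # evenly spaced boundaries with small jitter, away from the edges
            base = np.linspace(0, nb, config.n_boundaries + 2)[1:-1]
            jitter = rng.integers(-2, 3, size=config.n_boundaries)
            bpos = np.clip(np.round(base).astype(int) + jitter, 3, nb - 4)
            bpos = np.unique(bpos)
            domain = np.searchsorted(bpos, np.arange(nb), side="right")
            same_tad = domain[:, None] == domain[None, :]
            mu = mu * np.where(same_tad, config.tad_enrichment, 1.0)
            for b in bpos:
                boundaries.append(bins[sl.start + int(b)])

        chrom_loops = [(p1, p2, f) for (c, p1, p2, f) in config.loops if c == chrom]
        if config.n_loops > 0:
            # loops at 100-500 kb-scale offsets, the typical loop range
            min_off, max_off = 10, max(12, min(50, nb // 3))
            placed = set()
            while len(placed) < config.n_loops:
                i0 = int(rng.integers(8, nb - max_off - 8))
                off = int(rng.integers(min_off, max_off))
                if any(abs(i0 - a) + abs(i0 + off - b) < 6 for a, b in placed):
                    continue
                placed.add((i0, i0 + off))
                chrom_loops.append((
                    bins[sl.start + i0].start + config.bin_size // 2,
                    bins[sl.start + i0 + off].start + config.bin_size // 2,
                    config.loop_fold,
                ))
        for p1, p2, fold in chrom_loops:
            b1 = bins.region_at(chrom, p1).index - sl.start
            b2 = bins.region_at(chrom, p2).index - sl.start
            mu[b1, b2] *= fold
            mu[b2, b1] *= fold
            loop_pairs.append((bins[sl.start + min(b1, b2)], bins[sl.start + max(b1, b2)]))

        if config.noise_sigma > 0:
            noise = np.exp(rng.normal(0.0, config.noise_sigma, size=mu.shape))
            noise = np.triu(noise) + np.triu(noise, k=1).T
            mu = mu * noise
        iu = np.triu_indices(nb)
        vals = rng.poisson(mu[iu]).astype(float) if config.poisson else mu[iu]
        nz = vals > 0
        ii.append(iu[0][nz] + sl.start)
        jj.append(iu[1][nz] + sl.start)
        vv.append(vals[nz])

    matrix = ContactMatrix(
        bins,
        (np.concatenate(ii), np.concatenate(jj), np.concatenate(vv)),
        metadata={"simulated": True, "seed": config.seed},
    )
    truth = {"boundaries": boundaries, "loops": loop_pairs, "compartments": labels}
    return matrix, truth


def make_fragments(config: SimulationConfig) -> RegionSet:
    """Regular synthetic restriction-fragment map (gapless per chromosome)."""
    regions = []
    for chrom, length in config.chromosome_lengths.items():
        for start in range(0, length, config.fragment_size):
            regions.append(GenomicRegion(chrom, start, min(start + config.fragment_size, length)))
    return RegionSet(regions, config.chromosome_lengths)


def _make_pair(fragments: RegionSet, f1: int, f2: int, s1: str, s2: str,
               rng, mapq: int = 60, pos1=None, pos2=None) -> FragmentPair:
    fr1, fr2 = fragments[f1], fragments[f2]
    p1 = int(pos1) if pos1 is not None else int(rng.integers(fr1.start, fr1.end))
    p2 = int(pos2) if pos2 is not None else int(rng.integers(fr2.start, fr2.end))
    side1 = PairSide(f1, fr1.chromosome, p1, s1, mapq,
                     re_distance=fr1.end - p1 if s1 == "+" else p1 - fr1.start,
                     re_site=fr1.end if s1 == "+" else fr1.start)
    side2 = PairSide(f2, fr2.chromosome, p2, s2, mapq,
                     re_distance=fr2.end - p2 if s2 == "+" else p2 - fr2.start,
                     re_site=fr2.end if s2 == "+" else fr2.start)
    if (side1.fragment, side1.position) > (side2.fragment, side2.position):
        side1, side2 = side2, side1
    pair = FragmentPair(left=side1, right=side2)
    pair.orientation = _orientation(side1, side2)
    return pair


def simulate_pairs(config: SimulationConfig):
    """Simulate read pairs with disjoint planted artefact classes.

    ``config.artefact_fractions`` maps class name (``pcr_duplicate``,
    ``self_ligation``, ``inward_error``, ``outward_error``, ``low_quality``,
    ``unmapped``) to its fraction of ``n_pairs``; remaining pairs are valid.
    Returns ``(pairs, truth_counts, fragments)`` with exact per-class counts.
    """
    rng = _streams(config.seed, "pairs")
    fragments = make_fragments(config)
    nfrag = len(fragments)
    frac = config.artefact_fractions
    counts = {k: int(round(frac.get(k, 0.0) * config.n_pairs)) for k in
              ("pcr_duplicate", "self_ligation", "inward_error", "outward_error",
               "low_quality", "unmapped")}
    n_valid = config.n_pairs - sum(counts.values())
    min_sep_frags = 5000 // config.fragment_size + 2  # clear of ligation-error range

    strands = np.array(["+", "-"])
    valid: list[FragmentPair] = []
    seen = set()
    while len(valid) < n_valid:
        f1 = int(rng.integers(0, nfrag))
        # power-law-ish separations, min separation clear of error cutoffs
        gap = min_sep_frags + int(rng.pareto(1.0) * 3)
        f2 = f1 + gap
        if f2 >= nfrag or fragments[f1].chromosome != fragments[f2].chromosome:
            continue
        s1, s2 = rng.choice(strands), rng.choice(strands)
        p = _make_pair(fragments, f1, f2, s1, s2, rng)
        key = (p.left.position, p.left.strand, p.right.position, p.right.strand)
        if key in seen:
            continue
        seen.add(key)
        valid.append(p)

    planted: list[FragmentPair] = []
    # PCR duplicates: exact copies of distinct valid pairs, appended after
    if counts["pcr_duplicate"] > len(valid):
        raise ValueError("more duplicates requested than valid source pairs")
    dup_src = rng.choice(len(valid), size=counts["pcr_duplicate"], replace=False)
    for k in dup_src:
        src = valid[int(k)]
        planted.append(_make_pair(fragments, src.left.fragment, src.right.fragment,
                                  src.left.strand, src.right.strand, rng,
                                  pos1=src.left.position, pos2=src.right.position))
    # self-ligations: both mates in one fragment
    for _ in range(counts["self_ligation"]):
        f = int(rng.integers(0, nfrag))
        planted.append(_make_pair(fragments, f, f, "-", "+", rng))
    # ligation errors: short inward / outward pairs (adjacent fragments)
    for name, (sl, sr) in (("inward_error", ("+", "-")), ("outward_error", ("-", "+"))):
        for _ in range(counts[name]):
            f1 = int(rng.integers(0, nfrag - 2))
            f2 = f1 + 1
            if fragments[f1].chromosome != fragments[f2].chromosome:
                f1 -= 1
                f2 -= 1
            planted.append(_make_pair(fragments, f1, f2, sl, sr, rng))
    # low mapping quality
    for _ in range(counts["low_quality"]):
        f1 = int(rng.integers(0, nfrag))
        f2 = min(f1 + min_sep_frags + int(rng.integers(0, 50)), nfrag - 1)
        planted.append(_make_pair(fragments, f1, f2,
                                  rng.choice(strands), rng.choice(strands), rng, mapq=2))
    # unmapped mate
    for _ in range(counts["unmapped"]):
        f1 = int(rng.integers(0, nfrag))
        p = _make_pair(fragments, f1, min(f1 + min_sep_frags, nfrag - 1),
                       "+", "-", rng)
        p.left.is_unmapped = True
        planted.append(p)

    pairs = valid + planted
    truth = dict(counts)
    truth["valid"] = len(valid)
    truth["total"] = len(pairs)
    return pairs, truth, fragments


def genome_from_compartments(bins: RegionSet, labels: np.ndarray, seed: int = 0,
                             gc_a: float = 0.6, gc_b: float = 0.4) -> dict[str, str]:
    """Synthetic genome whose GC content tracks compartment labels.

    A-compartment (label +1) bins are GC-rich; used to exercise eigenvector
    sign orientation.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, length in bins.chromosome_lengths.items():
        seq = np.empty(length, dtype="<U1")
        sl = bins.chromosome_slice(chrom)
        for r, lab in zip(bins.regions[sl], labels[sl]):
            gc = gc_a if lab > 0 else gc_b
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            seq[r.start:r.end] = rng.choice(list("ACGT"), size=r.length, p=p)
        out[chrom] = "".join(seq)
    return out
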