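"""Ligation-junction read splitting, fragment assignment and pair filtering.

Read pairs mapped to restriction fragments are the unit of Hi-C data before
binning. This module classifies pair orientation (inward / outward /
same-strand), applies the artefact filter suite — mapping quality,
multi-mapping, self-ligation, PCR duplicates, ligation errors, restriction
site distance, unusually dense fragments — and produces the diagnostic
statistics used for quality control: ligation-error curves (orientation
fraction vs genomic separation) and the restriction-site-distance ("insert
size") distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet

logger = logging.getLogger(__name__)

ORIENTATIONS = ("inward", "outward", "same-forward", "same-reverse")

# filter bit flags, in application order
FILTER_ORDER = (
    "unmapped",
    "multimapping",
    "quality",
    "self_ligation",
    "pcr_duplicate",
    "ligation_error",
    "re_distance",
    "unusual_density",
)
FILTER_BITS = {name: 1 << i for i, name in enumerate(FILTER_ORDER)}


@dataclass
class ReadAlignment:
    """Minimal single-mate alignment record (5' mapped position)."""

    chromosome: str
    position: int
    strand: str
    mapq: int = 60
    is_unmapped: bool = False
    is_multimapping: bool = False


@dataclass
class PairSide:
    fragment: int          # global fragment index, -1 if unassignable
    chromosome: str
    position: int
    strand: str
    mapq: int
    re_distance: int       # bp from read position to the faced fragment edge
    re_site: int           # position of the faced restriction site
    is_unmapped: bool = False
    is_multimapping: bool = False


@dataclass
class FragmentPair:
    """A read pair assigned to two restriction fragments, canonically ordered."""

    left: PairSide
    right: PairSide
    orientation: str = "."
    filter_mask: int = 0
    first_filter: str | None = None

    @property
    def is_intra(self) -> bool:
        return self.left.chromosome == self.right.chromosome

    @property
    def is_valid(self) -> bool:
        return self.filter_mask == 0

    @property
    def separation(self) -> int | None:
        """Distance between the restriction sites the two reads face (intra only)."""
        if not self.is_intra:
            return None
        return abs(self.right.re_site - self.left.re_site)


@dataclass
class PairStats:
    total: int = 0
    valid: int = 0
    removed: dict = field(default_factory=lambda: {f: 0 for f in FILTER_ORDER})
    ligation_error_curves: pd.DataFrame | None = None
    insert_size: pd.DataFrame | None = None
    median_insert_size: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", self.total)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("valid", self.valid))
        return pd.DataFrame(rows, columns=["statistic", "count"])


def split_at_junction(read: str, junction: str, min_length: int = 20) -> list[str]:
    """Split a chimeric read at every ligation-junction occurrence.

    Each flank keeps the half of the junction up to the ligation point, so the
    restriction-site context is restored on both sides. Flanks shorter than
    ``min_length`` are discarded; a read without the junction is returned as-is.
    """
    if not junction:
        raise ValueError("junction must be non-empty")
    read_u = read.upper()
    half = len(junction) // 2
    hits = []
    start = 0
    while True:
        k = read_u.find(junction.upper(), start)
        if k < 0:
            break
        hits.append(k)
        start = k + 1
    if not hits:
        return [read]
    pieces = []
    prev = 0
    for k in hits:
        pieces.append(read[prev:k + half])
        prev = k + half
    pieces.append(read[prev:])
    return [p for p in pieces if len(p) >= min_length]


def _orientation(left: PairSide, right: PairSide) -> str:
    s = (left.strand, right.strand)
    if s == ("+", "-"):
        return "inward"
    if s == ("-", "+"):
        return "outward"
    if s == ("+", "+"):
        return "same-forward"
    return "same-reverse"


def _make_side(aln: ReadAlignment, fragments: RegionSet) -> PairSide:
    frag_ndx, re_dist, re_site = -1, 0, aln.position
    if not aln.is_unmapped:
        try:
            frag = fragments.region_at(aln.chromosome, aln.position)
            frag_ndx = frag.index
            if aln.strand == "+":
                # read faces the downstream fragment edge
                re_site = frag.end
                re_dist = frag.end - aln.position
            else:
                re_site = frag.start
                re_dist = aln.position - frag.start
        except (KeyError, ValueError):
            frag_ndx = -1
    return PairSide(
        fragment=frag_ndx,
        chromosome=aln.chromosome,
        position=aln.position,
        strand=aln.strand,
        mapq=aln.mapq,
        re_distance=re_dist,
        re_site=re_site,
        is_unmapped=aln.is_unmapped or frag_ndx == -1,
        is_multimapping=aln.is_multimapping,
    )


def assign_pairs(alignment_pairs: Iterable[tuple[ReadAlignment, ReadAlignment]],
                 fragments: RegionSet) -> list[FragmentPair]:
    """Assign mate alignments to restriction fragments and orient each pair.

    Each mate maps to the fragment containing its 5' position; the
    restriction-site distance is measured toward the fragment edge the read
    faces. Pairs are canonically ordered (left fragment index <= right).
    """
    pairs = []
    for a, b in alignment_pairs:
        sa, sb = _make_side(a, fragments), _make_side(b, fragments)
        if (sa.fragment, sa.position) > (sb.fragment, sb.position) and sb.fragment >= 0:
            sa, sb = sb, sa
        pair = FragmentPair(left=sa, right=sb)
        pair.orientation = _orientation(sa, sb)
        pairs.append(pair)
    return pairs


@dataclass
class FilterConfig:
    """Pair-filter thresholds; the defaults mirror standard pipeline settings."""

    min_mapq: int = 3
    filter_self_ligations: bool = True
    filter_pcr_duplicates: bool = True
    inward_cutoff: int = 5000
    outward_cutoff: int = 5000
    re_distance_cutoff: int | None = 10_000
    density_quantile: float = 99.99
    custom_filters: list[tuple[str, Callable[[FragmentPair], bool]]] = field(
        default_factory=list
    )

    def __post_init__(self):
        for v in (self.inward_cutoff, self.outward_cutoff, self.re_distance_cutoff):
            if v is not None and v < 0:
                raise ValueError("filter cutoffs must be non-negative")
        if not (0 < self.density_quantile <= 100):
            raise ValueError("density quantile must be in (0, 100]")


def filter_pairs(pairs: Sequence[FragmentPair],
                 config: FilterConfig | None = None) -> tuple[list[FragmentPair], PairStats]:
    """Apply the pair-filter suite; attribute each removal to the first failure.

    Filters are applied in a fixed documented order: unmapped, multi-mapping,
    mapping quality, self-ligation, PCR duplicate (first occurrence kept),
    ligation error (short inward/outward pairs), restriction-site distance
    and unusual read density. ``filter_mask`` records every failed filter;
    the removal statistics attribute each pair to the first failure only.
    Inter-chromosomal pairs bypass the distance-based filters.
    """
    if config is None:
        config = FilterConfig()
    stats = PairStats(total=len(pairs))

    seen: set[tuple] = set()
    frag_counts: dict[int, int] = {}
    for p in pairs:
        for side in (p.left, p.right):
            if side.fragment >= 0:
                frag_counts[side.fragment] = frag_counts.get(side.fragment, 0) + 1
    dense_fragments: set[int] = set()
    if frag_counts and config.density_quantile < 100:
        counts = np.array(list(frag_counts.values()), dtype=float)
        cutoff = np.percentile(counts, config.density_quantile)
        if cutoff < counts.max():
            dense_fragments = {f for f, c in frag_counts.items() if c > cutoff}

    valid: list[FragmentPair] = []
    for p in pairs:
        p.filter_mask = 0
        p.first_filter = None

        def fail(name: str):
            p.filter_mask |= FILTER_BITS.get(name, 0)
            if p.first_filter is None:
                p.first_filter = name

        if p.left.is_unmapped or p.right.is_unmapped:
            fail("unmapped")
        if p.left.is_multimapping or p.right.is_multimapping:
            fail("multimapping")
        if min(p.left.mapq, p.right.mapq) < config.min_mapq:
            fail("quality")
        if (config.filter_self_ligations and p.is_intra
                and p.left.fragment == p.right.fragment and p.left.fragment >= 0):
            fail("self_ligation")
        if config.filter_pcr_duplicates and not (p.left.is_unmapped or p.right.is_unmapped):
            key = (p.left.chromosome, p.left.position, p.left.strand,
                   p.right.chromosome, p.right.position, p.right.strand)
            if key in seen:
                fail("pcr_duplicate")
            else:
                seen.add(key)
        if p.is_intra and p.left.fragment != p.right.fragment and p.left.fragment >= 0:
            sep = p.separation
            if p.orientation == "inward" and sep < config.inward_cutoff:
                fail("ligation_error")
            elif p.orientation == "outward" and sep < config.outward_cutoff:
                fail("ligation_error")
        if (config.re_distance_cutoff is not None and not p.left.is_unmapped
                and not p.right.is_unmapped
                and p.left.re_distance + p.right.re_distance > config.re_distance_cutoff):
            fail("re_distance")
        if p.left.fragment in dense_fragments or p.right.fragment in dense_fragments:
            fail("unusual_density")
        for name, predicate in config.custom_filters:
            if name not in FILTER_BITS:
                FILTER_BITS[name] = 1 << (len(FILTER_BITS))
                stats.removed.setdefault(name, 0)
            if not predicate(p):
                p.filter_mask |= FILTER_BITS[name]
                if p.first_filter is None:
                    p.first_filter = name

        if p.first_filter is None:
            valid.append(p)
            stats.valid += 1
        else:
            stats.removed.setdefault(p.first_filter, 0)
            stats.removed[p.first_filter] += 1
    return valid, stats


def ligation_error_curves(pairs: Sequence[FragmentPair],
                          n_bins: int = 30) -> pd.DataFrame:
    """Orientation fractions in log-spaced genomic-separation bins.

    For artefact-free libraries all four orientations converge to the 0.25
    expectation; an excess of short inward/outward pairs indicates
    un-ligated or re-ligated fragments.
    """
    seps, orients = [], []
    for p in pairs:
        if p.is_intra and p.left.fragment != p.right.fragment:
            s = p.separation
            if s and s > 0:
                seps.append(s)
                orients.append(p.orientation)
    if not seps:
        return pd.DataFrame(columns=["separation", *ORIENTATIONS, "n"])
    seps = np.asarray(seps, dtype=float)
    edges = np.logspace(np.log10(seps.min()), np.log10(seps.max() + 1), n_bins + 1)
    idx = np.clip(np.digitize(seps, edges) - 1, 0, n_bins - 1)
    rows = []
    orients = np.asarray(orients)
    for b in range(n_bins):
        in_bin = idx == b
        n = int(in_bin.sum())
        if n == 0:
            continue
        row = {"separation": float(np.sqrt(edges[b] * edges[b + 1])), "n": n}
        for o in ORIENTATIONS:
            row[o] = float((orients[in_bin] == o).sum() / n)
        rows.append(row)
    return pd.DataFrame(rows)


def pair_diagnostics(pairs: Sequence[FragmentPair],
                     stats: PairStats | None = None) -> PairStats:
    """Assemble the QC statistics: ligation-error curves, insert sizes, counts."""
    if stats is None:
        stats = PairStats(total=len(pairs), valid=len(pairs))
    stats.ligation_error_curves = ligation_error_curves(pairs)
    sizes = np.array(
        [p.left.re_distance + p.right.re_distance for p in pairs
         if not (p.left.is_unmapped or p.right.is_unmapped)],
        dtype=float,
    )
    if sizes.size:
        hist, edges = np.histogram(sizes, bins=50)
        stats.insert_size = pd.DataFrame(
            {"insert_size": 0.5 * (edges[:-1] + edges[1:]), "count": hist}
        )
        stats.median_insert_size = float(np.median(sizes))
    else:
        stats.insert_size = pd.DataFrame(columns=["insert_size", "count"])
    return stats


# ---------------------------------------------------------------------------
# pair text I/O (tab-separated: chrom1 pos1 strand1 chrom2 pos2 strand2 [mapq1 mapq2])

def write_pairs(pairs: Iterable[FragmentPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosome1\tposition1\tstrand1\tchromosome2\tposition2\tstrand2"
                 "\tmapq1\tmapq2\n")
        for p in pairs:
            fh.write(
                f"{p.left.chromosome}\t{p.left.position}\t{p.left.strand}\t"
                f"{p.right.chromosome}\t{p.right.position}\t{p.right.strand}\t"
                f"{p.left.mapq}\t{p.right.mapq}\n"
            )


def read_pairs(path, fragments: RegionSet) -> list[FragmentPair]:
    """Read a pair text file (our dialect or HiC-Pro validPairs) and assign fragments."""
    aln_pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[1].isdigit():  # our dialect / 4DN-style
                c1, p1, s1, c2, p2, s2 = f[0], int(f[1]), f[2], f[3], int(f[4]), f[5]
                q1 = int(f[6]) if len(f) > 6 else 60
                q2 = int(f[7]) if len(f) > 7 else 60
            else:  # HiC-Pro validPairs: readname chr1 pos1 strand1 chr2 pos2 strand2 ...
                c1, p1, s1, c2, p2, s2 = f[1], int(f[2]), f[3], f[4], int(f[5]), f[6]
                q1 = q2 = 60
            aln_pairs.append(
                (ReadAlignment(c1, p1, s1, q1), ReadAlignment(c2, p2, s2, q2))
            )
    return assign_pairs(aln_pairs, fragments)


def read_sam_pairs(path, fragments: RegionSet) -> list[FragmentPair]:
    """Read a name-sorted paired SAM/BAM file via pysam and assign fragments."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    aln_pairs = []
    pending: dict[str, ReadAlignment] = {}
    with pysam.AlignmentFile(str(path), mode) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            aln = ReadAlignment(
                chromosome=rec.reference_name or "*",
                position=rec.reference_start if not rec.is_unmapped else 0,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                is_unmapped=rec.is_unmapped,
                is_multimapping=rec.has_tag("XS") and rec.get_tag("XS") == rec.get_tag("AS")
                if rec.has_tag("XS") and rec.has_tag("AS") else False,
            )
            if rec.query_name in pending:
                aln_pairs.append((pending.pop(rec.query_name), aln))
            else:
                pending[rec.query_name] = aln
    return assign_pairs(aln_pairs, fragments)
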