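"""Genomic coordinate model, region I/O, in-silico digestion and ligation junctions.

All internal coordinates are 0-based, half-open ``[start, end)`` — the native
BED convention. GFF (1-based, inclusive) is converted on read and write.
Chromosome order follows the input FASTA / chromosome-sizes order and fixes
the global bin indexing used by every contact matrix.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# IUPAC nucleotide ambiguity codes -> regex character classes
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence; NaN on empty/N-only sequence."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


@dataclass
class GenomicRegion:
    """Half-open genomic interval with optional strand, index and attributes."""

    chromosome: str
    start: int
    end: int
    strand: str = "."
    index: int | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chromosome}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"


class RegionSet:
    """Ordered, densely indexed collection of genomic regions.

    Regions are sorted by (chromosome order, start) and assigned dense indices
    0..N-1. For fragment/bin sets, per-chromosome coverage is gapless and a
    (chromosome, position) lookup returns exactly one region.
    """

    def __init__(self, regions: Iterable[GenomicRegion],
                 chromosome_lengths: dict[str, int] | None = None):
        regions = list(regions)
        if chromosome_lengths is not None:
            self.chromosome_lengths = dict(chromosome_lengths)
        else:
            self.chromosome_lengths = {}
            for r in regions:
                cur = self.chromosome_lengths.get(r.chromosome, 0)
                self.chromosome_lengths[r.chromosome] = max(cur, r.end)
        order = {c: i for i, c in enumerate(self.chromosome_lengths)}
        for r in regions:
            if r.chromosome not in order:
                order[r.chromosome] = len(order)
                self.chromosome_lengths.setdefault(r.chromosome, r.end)
        regions.sort(key=lambda r: (order[r.chromosome], r.start, r.end))
        for i, r in enumerate(regions):
            r.index = i
        self.regions = regions
        self._chrom_order = order
        # per-chromosome start arrays for bisect lookup
        self._starts: dict[str, list[int]] = {}
        self._offsets: dict[str, int] = {}
        for i, r in enumerate(regions):
            if r.chromosome not in self._offsets:
                self._offsets[r.chromosome] = i
                self._starts[r.chromosome] = []
            self._starts[r.chromosome].append(r.start)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chromosome_lengths)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def chromosome_regions(self, chromosome: str) -> list[GenomicRegion]:
        if chromosome not in self._offsets:
            return []
        o = self._offsets[chromosome]
        return self.regions[o:o + len(self._starts[chromosome])]

    def chromosome_slice(self, chromosome: str) -> slice:
        """Global index range [start, stop) of a chromosome's regions."""
        if chromosome not in self._offsets:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        o = self._offsets[chromosome]
        return slice(o, o + len(self._starts[chromosome]))

    def region_at(self, chromosome: str, position: int) -> GenomicRegion:
        """The unique region containing ``position`` on ``chromosome``."""
        if chromosome not in self._starts:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        starts = self._starts[chromosome]
        k = bisect.bisect_right(starts, position) - 1
        if k < 0:
            raise ValueError(f"position {position} before first region")
        r = self.regions[self._offsets[chromosome] + k]
        if not (r.start <= position < r.end):
            raise ValueError(f"position {chromosome}:{position} not covered")
        return r

    def overlapping(self, region: GenomicRegion) -> list[GenomicRegion]:
        out = []
        if region.chromosome not in self._starts:
            return out
        starts = self._starts[region.chromosome]
        k = max(bisect.bisect_right(starts, region.start) - 1, 0)
        o = self._offsets[region.chromosome]
        for r in self.regions[o + k:o + len(starts)]:
            if r.start >= region.end:
                break
            if r.overlaps(region):
                out.append(r)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": [r.chromosome for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "strand": [r.strand for r in self.regions],
            }
        )


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Restriction enzyme: IUPAC recognition site and cut offset within it."""

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self):
        site = self.recognition_site.upper()
        if not site or any(b not in _IUPAC for b in site):
            raise ValueError(f"invalid recognition site {self.recognition_site!r}")
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError("cut offset outside recognition site")
        object.__setattr__(self, "recognition_site", site)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition_site) == self.recognition_site

    def site_pattern(self) -> re.Pattern:
        # lookahead allows overlapping matches
        body = "".join(_IUPAC[b] for b in self.recognition_site)
        return re.compile(f"(?=({body}))")


#: Built-in enzymes; Arima-style kits are expressed as multi-enzyme digests.
RESTRICTION_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("HindIII", "AAGCTT", 1),
        RestrictionEnzyme("MboI", "GATC", 0),
        RestrictionEnzyme("DpnII", "GATC", 0),
        RestrictionEnzyme("Sau3AI", "GATC", 0),
        RestrictionEnzyme("EcoRI", "GAATTC", 1),
        RestrictionEnzyme("BglII", "AGATCT", 1),
        RestrictionEnzyme("NcoI", "CCATGG", 1),
        RestrictionEnzyme("HinfI", "GANTC", 1),
        RestrictionEnzyme("ApoI", "RAATTY", 1),
        RestrictionEnzyme("AluI", "AGCT", 2),
        RestrictionEnzyme("HaeIII", "GGCC", 2),
    ]
}

#: Named multi-enzyme digests (union of cut positions).
ENZYME_COCKTAILS: dict[str, tuple[str, ...]] = {
    "Arima": ("MboI", "HinfI"),
}


def get_enzymes(name: str | RestrictionEnzyme |
                Sequence[str | RestrictionEnzyme]) -> list[RestrictionEnzyme]:
    """Resolve an enzyme spec (name, cocktail name, object, or list) to enzymes."""
    if isinstance(name, RestrictionEnzyme):
        return [name]
    if isinstance(name, str):
        if name in ENZYME_COCKTAILS:
            return [RESTRICTION_ENZYMES[n] for n in ENZYME_COCKTAILS[name]]
        if name not in RESTRICTION_ENZYMES:
            known = ", ".join(sorted(RESTRICTION_ENZYMES) + sorted(ENZYME_COCKTAILS))
            raise ValueError(f"unknown enzyme {name!r}; supported: {known}")
        return [RESTRICTION_ENZYMES[name]]
    out: list[RestrictionEnzyme] = []
    for n in name:
        out.extend(get_enzymes(n))
    return out


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    try:
        from pyfaidx import Fasta

        fa = Fasta(str(path), rebuild=False, build_index=False)
        return {name: str(fa[name][:]) for name in fa.keys()}
    except Exception:
        seqs: dict[str, list[str]] = {}
        current = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    current = line[1:].split()[0]
                    seqs[current] = []
                else:
                    seqs[current].append(line)
        return {k: "".join(v) for k, v in seqs.items()}


def cut_positions(sequence: str, enzymes: Sequence[RestrictionEnzyme]) -> list[int]:
    """Sorted union of cut positions (match start + cut offset) in a sequence."""
    seq = sequence.upper()
    cuts: set[int] = set()
    for enz in enzymes:
        pat = enz.site_pattern()
        for m in pat.finditer(seq):
            cuts.add(m.start() + enz.cut_offset)
    return sorted(c for c in cuts if 0 <= c <= len(seq))


def digest_genome(genome: dict[str, str] | str,
                  enzyme: str | RestrictionEnzyme | Sequence) -> RegionSet:
    """In-silico digestion: fragments between successive cut positions.

    ``genome`` is a {chromosome: sequence} dict or a FASTA path. Fragments
    tile each chromosome gaplessly from 0 to its length; zero-length
    fragments (cuts at position 0 or the chromosome end) are dropped.
    """
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        genome = read_fasta(genome)
    enzymes = get_enzymes(enzyme)
    regions: list[GenomicRegion] = []
    lengths: dict[str, int] = {}
    for chrom, seq in genome.items():
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom!r} has empty sequence")
        lengths[chrom] = len(seq)
        edges = [0] + cut_positions(seq, enzymes) + [len(seq)]
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                regions.append(GenomicRegion(chrom, a, b))
    return RegionSet(regions, lengths)


def ligation_junction(enzyme: str | RestrictionEnzyme) -> str:
    """Fill-in ligation junction sequence for a palindromic cutter.

    Cut-and-fill of a 5' overhang followed by blunt ligation duplicates the
    overhang region ``site[cut:len-cut]``; blunt cutters yield the site itself.
    """
    (enz,) = get_enzymes(enzyme) if not isinstance(enzyme, RestrictionEnzyme) else [enzyme]
    if not enz.is_palindromic:
        raise ValueError(
            f"{enz.name}: non-palindromic recognition site, ligation junction ambiguous"
        )
    site, cut = enz.recognition_site, enz.cut_offset
    overhang = site[cut:len(site) - cut]
    return site[:cut] + overhang + overhang + site[len(site) - cut:]


def make_bins(chromosome_lengths: dict[str, int], bin_size: int) -> RegionSet:
    """Equi-distant genome bins; last bin per chromosome truncated at its end."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    regions = []
    for chrom, length in chromosome_lengths.items():
        for start in range(0, length, bin_size):
            regions.append(GenomicRegion(chrom, start, min(start + bin_size, length)))
    return RegionSet(regions, chromosome_lengths)


def read_chromosome_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chromosome", "length"],
                     comment="#")
    return dict(zip(df["chromosome"], df["length"].astype(int)))


def read_regions(path, fmt: str | None = None) -> RegionSet:
    """Read BED / GFF / tabular score files into a RegionSet.

    BED is 0-based half-open and kept as-is; GFF start/end (1-based inclusive)
    become half-open on read. Name/score columns are attached as attributes.
    """
    path = str(path)
    if fmt is None:
        low = path.lower()
        if low.endswith((".gff", ".gff3", ".gtf")):
            fmt = "gff"
        elif low.endswith((".bedgraph", ".bdg")):
            fmt = "bedgraph"
        else:
            fmt = "bed"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if fmt == "gff":
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if len(fields) > 6 and fields[6] in "+-" else "."
                    attrs = {"source": fields[1], "feature": fields[2]}
                    if fields[5] not in (".", ""):
                        attrs["score"] = float(fields[5])
                    if len(fields) > 8:
                        attrs["attributes"] = fields[8]
                elif fmt == "bedgraph":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = "."
                    attrs = {"score": float(fields[3])}
                else:  # bed
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    attrs = {}
                    if len(fields) > 3:
                        attrs["name"] = fields[3]
                    if len(fields) > 4 and fields[4] not in (".", ""):
                        attrs["score"] = float(fields[4])
                    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                rows.append(GenomicRegion(chrom, start, end, strand, attributes=attrs))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line: {exc}") from exc
    if not rows:
        logger.warning("no regions read from %s", path)
    return RegionSet(rows)


def write_bed(regions: Iterable[GenomicRegion], path, scores: bool = True) -> None:
    """Write regions as 6-column BED (fewer columns if no attributes present)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.attributes.get("name", ".")
            score = r.attributes.get("score", ".")
            if isinstance(score, float) and score == int(score):
                score = int(score)
            fields = [r.chromosome, str(r.start), str(r.end)]
            if scores or r.attributes or r.strand != ".":
                fields += [str(name), str(score), r.strand]
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(bins: Sequence[GenomicRegion], values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for r, v in zip(bins, values):
            if np.isnan(v):
                continue
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{v:.6g}\n")


def gc_content(bins: Sequence[GenomicRegion], genome: dict[str, str] | str) -> np.ndarray:
    """Per-bin GC fraction from genome sequence (NaN where sequence missing)."""
    if not isinstance(genome, dict):
        genome = read_fasta(genome)
    out = np.full(len(bins), np.nan)
    for i, r in enumerate(bins):
        seq = genome.get(r.chromosome)
        if seq is not None:
            out[i] = gc_fraction(seq[r.start:r.end])
    return out
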