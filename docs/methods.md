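# Methods

This note documents the models and numerical procedures implemented in
chromaforge, the defaults that matter, what the synthetic-data generator does
and does not emulate, and the design choices made where the design was
genuinely open.

## Coordinate model and digestion

All coordinates are 0-based, half-open (`[start, end)`), the native BED
convention; GFF input (1-based, inclusive) is converted on read. Chromosome
order follows the input genome and fixes global bin indices, so matrix
indexing is deterministic. In-silico digestion scans each chromosome for
IUPAC-degenerate recognition-site matches (overlapping matches included) and
cuts at `match_start + cut_offset`; fragments are the intervals between
successive cuts, gapless per chromosome, with zero-length fragments dropped.
Multi-enzyme digests (e.g. Arima-style MboI + HinfI) take the union of cut
positions. Ligation junctions are derived by the fill-in rule for palindromic
sites: cut-and-fill duplicates the overhang region `site[cut:len-cut]`, so
HindIII (`A^AGCTT`) gives `AAGCTAGCTT` and MboI (`^GATC`) gives `GATCGATC`;
blunt cutters yield the site itself. Non-palindromic and nicking enzymes are
rejected rather than guessed — their junction sequence is ambiguous.

## Read-pair filtering

Each mate maps to the fragment containing its 5' position; the
restriction-site distance is measured toward the fragment edge the read faces
(downstream edge for `+`, upstream for `-`), and the genomic separation used
by the ligation-error filter is the distance between the two faced
restriction sites — not the read positions — because un-ligated and
re-ligated molecules are delimited by restriction sites.

Filters apply in a fixed order, and each removed pair is attributed to the
first failing filter (the order matches the summary-bar semantics of
filter-statistics plots): unmapped mate; multi-mapping mate; mapping quality
below `q` (default 3); self-ligation (both mates in one fragment); PCR
duplicate (exact 5'-position + strand match of both mates, first occurrence
kept); ligation error (inward pairs closer than 5 000 bp, outward pairs
closer than 5 000 bp — both cutoffs configurable); restriction-site distance
sum ("insert size") above 10 kb; and unusual read density (fragments whose
pair count exceeds the 99.99th percentile). The insert-size cutoff and
density quantile are package defaults — no literature value exists for them —
and both are plain configuration. Inter-chromosomal pairs bypass the
self-ligation, ligation-error and insert-size filters, which are only
meaningful within a chromosome. Custom predicate filters can be registered
through the API and are attributed like built-ins.

Diagnostics report (a) orientation fractions (inward / outward / two
same-strand classes) against log-spaced genomic separation with the 0.25
expectation line — random ligation gives each orientation probability 1/4, so
departures at short range expose ligation artefacts; (b) the insert-size
distribution with its median; (c) per-filter removal counts, which conserve:
`total = valid + sum(removed)` exactly.

## Matrix construction, filtering and balancing

Valid pairs increment the pixel of the bin pair containing their two fragment
midpoints (midpoints make membership unambiguous for fragments spanning bin
edges); multiple inputs sum, which doubles as matrix merging. Matrices store
upper-triangle sparse raw counts, a per-bin bias vector and a valid-bin mask.
Bins whose contacts sum to zero are always masked; the low-coverage filter
additionally masks bins below an absolute cutoff or below a fraction (e.g.
0.25) of the median nonzero marginal. Masked bins are excluded from every
downstream quantity — no imputation except the optional expected-value
imputation in insulation and aggregate computations.

Balancing finds `b_i > 0` such that `b_i * b_j * raw_ij` has equal row sums
over valid bins, per chromosome by default (whole-genome optional):

* **Knight–Ruiz (default)** — the inner–outer Newton iteration with
  conjugate-gradient inner solves on the dense per-chromosome submatrix of
  valid bins; tolerance 1e-12 on the residual norm, at most 100 outer
  iterations, error naming the chromosome on failure.
* **ICE** — Sinkhorn-style alternating division by mean-normalised marginals
  until the marginals are flat, then rescaling to unit row sums.

Both scale the output so that every valid marginal is exactly 1 (disable
`rescale` to keep the raw total-count scale). On strictly positive matrices
the two converge to the same normalised matrix to ~1e-5 or better.

## Expected values and O/E

The expected value `e_c(d)` is the sum of (normalised) pixel values at bin
distance `d` within chromosome `c`, divided by the number of valid bin pairs
at that distance — zeros count in the denominator, masked bins do not. A
genome-wide profile pools chromosomes, and a single scalar covers
inter-chromosomal pairs. O/E divides each intra pixel by `e_c(|i-j|)`
(per-chromosome by default; a flag switches to the genome-wide profile) and
each inter pixel by the inter scalar. By construction
`sum(pixels) = sum_d e(d) * pairs(d)` per chromosome, which the tests assert.

## Compartments

The per-chromosome correlation matrix holds the Pearson correlation of O/E
rows, pairwise-complete over valid bins (plain Pearson on O/E, no prior
z-transform; bins with >90% missing O/E are dropped). The compartment
eigenvector is the unit-norm eigenvector of the largest eigenvalue from a
dense symmetric eigensolver, per chromosome, with chromosome Y excluded by
default. Because eigenvector sign is arbitrary, orientation uses genomic GC
content when a genome is supplied: signs flip per chromosome until the mean
GC of positive-EV bins is at least that of negative-EV bins (the A
compartment is typically GC-rich); without a genome the sign is fixed so the
EV sums non-negative.

The saddle profile ranks valid bins by EV and groups them by percentile
(default 5, 10, …, 100 — twenty groups with equal occupancy via ordinal
ranks); `S[g, h]` is the mean O/E over all intra-chromosomal bin pairs across
groups. Compartment strength summarises the saddle as
`log2(AA * BB / AB^2)` with `AA`/`BB` the mean O/E within the top/bottom 20%
of groups and `AB` the cross term — 0 for a structureless map, increasing
monotonically with checkerboard contrast. The corner-based form was chosen
because only the existence of a strength score, not its formula, is
standard; the corner fraction is configurable.

## Insulation, directionality and boundaries

The insulation score of bin `i` at window `w` (bp, floored to whole bins,
minimum 2) is the mean pixel value in the square `[i-w, i) x (i, i+w]`,
reported as `log2(s_i / N_c)` with `N_c` the whole-chromosome arithmetic mean
of defined raw scores (default) or their geometric mean (`--geom-mean`).
Windows crossing chromosome ends, or containing more than 50% masked pixels,
are missing; optional imputation substitutes the distance expectation.
Because the score is a log ratio it is invariant to uniform scaling, and by
AM ≥ GM the geometric normaliser never exceeds the arithmetic one, so
geometric scores are bin-wise ≥ arithmetic scores.

The directionality index contrasts the upstream sum `A` and downstream sum
`B` of each bin: with `E = (A+B)/2`,
`DI = sign(B-A) * ((A-E)^2/E + (B-E)^2/E)`, zero when `A = B` or `E = 0`.

Boundary calling takes one window column, splits it at missing-value runs
(extrema never bridge gaps), finds local minima — plateaus collapse to their
central bin, left-of-centre on even plateaus; segment endpoints can be maxima
but not minima — and scores each minimum as the mean of the differences to
the nearest flanking maxima (a min-of-deltas flag is provided; the combining
rule is not pinned down in the literature). Boundaries with score ≥ 1.0 (the
conventional cutoff) are reported. Difference tracks between conditions are
valid input unchanged.

## Loop calling

The caller re-implements the donut-neighbourhood Poisson approach on the CPU.
For every intra-chromosomal pixel at least `w + p` bins off the diagonal and
`w` bins from the chromosome ends, four local expected values are computed
from the donut, lower-left, horizontal and vertical neighbourhoods of
half-width `w` (default 5), excluding the `(2p+1)^2` peak box (default
`p = 2`): the distance-decay model value at the pixel, on the raw-count scale
(`e(d) / (b_i b_j)` — folding the bias into the expectation keeps the
observation an integer so the Poisson model applies), scaled by the
neighbourhood's observed/model ratio. Neighbourhood sums are 2-D
convolutions, so the whole chromosome is processed at once and the result is
deterministic and independent of any chunking.

Observed counts are tested against `Poisson(expected)`; p-values are
Benjamini–Hochberg-corrected within lambda chunks (expected values binned
into powers of `2^(1/3)`; with a single occupied chunk this reduces exactly
to plain BH). Calls must pass all four q-value cutoffs (default 0.1) and
enrichment cutoffs (defaults 1.75 for donut and lower-left, 1.5 for
horizontal and vertical, following the original algorithm's convention —
the true defaults of other implementations are not documented and these are
exposed configuration). Surviving pixels cluster by Chebyshev distance
(merge distance 25 kb default) with the strongest pixel as centroid;
single-pixel clusters face the stricter singleton rule (≥ 2-fold over donut
and lower-left, all q ≤ 0.02), which suppresses isolated noise pixels that
scrape past the per-neighbourhood thresholds. Note the operating point this
implies: at FDR 0.1 roughly one call in ten can still be a false discovery,
so precision on sparse truth sets hovers near 0.9 by construction.

## Aggregates

Region aggregates come in two modes: `rescaled` interpolates each region's
expanded square submatrix (expansion 0.5× the region size per side, so the
region occupies the central half of the window) onto a fixed grid by
area-weighted, NaN-aware resampling; `fixed` cuts a window of constant bp
width centred on the region midpoint (odd pixel count, so a centre bin
exists). Pair aggregates centre a fixed window on each anchor pixel and
report a centre-vs-outer-ring statistic. Minus-strand regions are flipped
before averaging (disable per call). Averaging happens on the linear O/E
scale and the log2 is taken of the averaged grid: with shallow counts many
individual pixels are zero, and a per-pixel log would drop them from a
NaN-aware mean and bias sparse long-range cells upward. Cells with no
contributors are missing, never zero.

## Comparisons and PCA

Matrix and track comparisons are pixel-/bin-wise on identical bin sets
(`difference = a - b`, minuend first; `fold-change = a / b`, optionally
log2), defined only where both operands are; fold changes with zero
denominator are missing. No on-the-fly rebinning — silent coarsening hides
errors. Sample PCA builds each sample's feature vector from O/E pixels
(normalised counts optional) restricted to intra-chromosomal contacts in a
100 kb – 10 Mb distance band (near-diagonal and inter pixels are dominated by
noise), optionally the top-k most variable or strongest features, centres
features across samples and decomposes with dense SVD.

## Synthetic data

The generator emulates the large-scale statistics of mammalian Hi-C, not
polymer physics. Expected intensity is
`mu_ij = scale * (1 + |i-j|)^-alpha * plaid(i,j) * tad(i,j) * loop(i,j)`:
`alpha = 1` (the decay regime typical of mammalian interphase maps),
alternating A/B blocks multiplying same-label pairs by `1 + c` and
cross-label pairs by `1/(1 + c)`, within-TAD enrichment between jittered
evenly spaced boundaries, and focal loop pixels at 100–500 kb offsets (the
typical loop range) multiplied by their fold. Counts are Poisson draws from
`mu`, optionally perturbed by multiplicative log-normal noise. Default depth
puts ~50 counts on the 10 kb diagonal; the loop and PCA fixtures use deeper
coverage (500 and 10 000) because focal-peak testing and sample discrimination
are depth-limited in exactly the way real experiments are. Pair simulation
plants disjoint artefact classes (duplicates appended after their sources,
self-ligations, adjacent-fragment inward/outward pairs, mapq-2 pairs,
unmapped mates) at exact counts over a regular 500 bp fragment grid, with
valid-pair separations kept clear of the ligation-error cutoffs so each
filter's removal count is known in advance. One integer seed determines every
output; sub-streams derive deterministically from it.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: mappability and GC bias along the genome (bias vectors
here are genuinely flat), translocations and copy-number structure, stripe
and jet features, nested TAD hierarchies, distance-dependent overdispersion
beyond Poisson, or realistic duplicate structure from library PCR. Results on
real libraries depend on those, and the filter and balancing stages exist
precisely because real data violates the generator's cleanliness.

## Problem sizes and determinism

Test fixtures use single chromosomes of 2–10 Mb at 10 kb bins (200–1000
bins), 50-replicate null batteries for the loop caller and 10–20 k simulated
read pairs — sizes chosen so the full suite and the acceptance script each
run in minutes on one CPU while leaving every statistical check well-powered.
All randomness flows through seeded `numpy` generators; plots strip volatile
metadata (and fix the SVG hash salt) so re-rendering identical data is
byte-identical.
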