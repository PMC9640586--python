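# Methods

## Geographic profiling

### Model

Occurrence sites are infested localities, one point per site regardless of
specimen counts (profiling weights localities, not individuals; a weighting
hook exists but is off by default). The score of grid cell *c* is

    score(c) = (1/N) * sum_i exp(-beta * d(c, i) / sigma)

with `d` the haversine great-circle distance (sphere radius 6371.0088 km;
over a ~100 km study extent the error of ignoring ellipsoidal shape is
negligible) and `sigma` the mean pairwise distance among the occurrences.
Normalising by `sigma` makes the decay coefficient `beta` scale-free;
`beta = 1` by default, configurable. There is deliberately *no* buffer
zone — the kernel is maximal at zero distance — because the spread of small
stored-product beetles is dominated by short-range dispersal and
human-mediated transport rather than an offender-style avoidance radius.

The grid is a regular lon/lat raster evaluated at cell centres, row 0
northernmost; the default cell size of 0.005° is roughly 0.5 km at the
latitudes the package targets. Examples and tests mostly use 0.01° cells to
keep problem sizes small.

### Bootstrap aggregation

Each of `n_replicates = 30` replicates draws a uniform fraction
u ∈ [0.25, 0.75] of the N sites and subsamples m = max(2, round(u·N))
of them without replacement (the floor of 2 keeps `sigma` computable).
Each replicate surface is min–max rescaled to [0, 1] before averaging so
that replicates with different subsample sizes contribute comparably; the
profile is the cell-wise mean. Replicate seeds are spawned from one root
seed via `numpy.random.SeedSequence`, so runs are reproducible and
replicates independent.

Numerical choice: the replicate mean is computed as
`r0 + sum(ri - r0)/n` (centred accumulation). This is better conditioned
than a plain running sum and has the property that when all replicates
coincide — e.g. with subsample fractions fixed at 1.0 — the mean is
*bitwise* equal to the single-run surface. For the same reason
`dragnet_score` accumulates occurrence contributions in a canonical
(lexicographic lon/lat) order, making surfaces bitwise invariant to the
order occurrences are supplied in.

### Elevation restriction and source areas

The elevation mask is applied to the *final mean surface*, not per
replicate, and keeps cells with DEM elevation in the closed band
[0, 600] m a.s.l. (600 m is in; 601 m is out); NODATA cells are masked.
Surviving scores are unchanged.

Candidate source areas are the 8-connected clusters of cells at or above a
quantile of the valid scores (default q = 0.95); clusters whose peak cells
lie within 3 km of each other are merged (transitively), and areas are
ranked by peak score. Ties break by (row, col) lexicographic order of the
peak, documented and tested. The rank-1 area is the most likely area of
origin.

### What the defaults do not claim

The Dragnet family's published kernel constants are not fixed anywhere
authoritative; the negative-exponential kernel, the mean-pairwise-distance
normalisation and `beta = 1` are this package's documented defaults, not a
reconstruction of any specific prior software. Multi-modal extraction
benefits from a sharper kernel (the three-source test uses `beta = 3`);
single-source localisation is insensitive to `beta` in our checks.

## Haplotype sampling sufficiency

`prob_all_haplotypes_sampled(n) = (n-1)/(n+1)` is the coalescent probability
that a sample of n sequences contains every haplotype segregating in the
population; its inverse `min_n_for_prob` returns the smallest integer n
meeting a target (computed by ceiling with an exact integer fix-up loop,
because e.g. 1.95/0.05 in floating point can land on either side of 39).

`min_detection_sample_size(p, beta) = ln(1-beta)/ln(1-p)` is the minimum
sample size to observe at least one copy of a haplotype of frequency p with
confidence beta. It returns a *real* by default (the field convention
reports non-integer values); a `ceil` flag gives the next integer.

The iterative procedure feeds sequences in sampling order; after each one
it recomputes observed haplotype frequencies, sets p to the frequency of
the *rarest observed* haplotype (a deliberate, conservative reading of "the
frequency of a given haplotype"), and re-evaluates the formula. Steps where
only one haplotype has been seen are recorded as not computable rather than
erroring. `beta` defaults to 0.95.

Haplotype identity is exact string match after uppercasing, including
ambiguity codes: an N-bearing sequence is its own haplotype unless
identical to another. This is conservative and reproducible; difference
*counts* instead use pairwise deletion (only sites where both residues are
A/C/G/T are compared).

## Group p-distances

`p_distance` is the proportion of differing sites among pairwise-comparable
sites, uncorrected for multiple hits. Group matrices average p-distances
over all cross-group (between) or intra-group (within) sequence pairs;
groups with fewer than two sequences get the "n.c." (not calculable)
marker. Distances are reported in percent.

Standard errors come from a bootstrap over alignment columns: sites are
resampled with replacement (500 replicates by default, seeded), the whole
matrix is recomputed per replicate, and the SE is the across-replicate
standard deviation (ddof = 1), reported on the same percent scale as the
distances. (The bundled reference matrix carries its published SEs
verbatim; those appear to be on the proportion scale while the distances
are percentages — they are not rescaled, and the discrepancy is noted in
the dataset docstring.)

`matrix_summaries` weights each group pair equally (not by pair counts) and
offers both truncation and rounding display modes, truncation being the
default: the reference aggregates were evidently truncated (mean within
1.3957…% prints as 1.39, not 1.40).

## Damage attribution

Clause order, first match wins: (1) live sap-beetle AND live moth stages →
both; (2) live sap-beetle stages → sap_beetle; (3) live moth stages → moth;
(4) no live insects but silk threads or frass > 0.5 mm → moth; (5) frass
≤ 0.1 mm → sap_beetle; (6) frass in (0.1, 0.5] mm with no other evidence →
undetermined; (7) nothing → none. The (0.1, 0.5] gap is not covered by any
stated field rule, so it is deliberately left undetermined rather than
silently attributed. Kernel damage alone attributes nothing.

A site counts as infested when at least one of its fruits classifies as
sap_beetle or both (the site-level criterion is this package's definition;
moth-only sites do not count). Percentages are offered both truncated and
rounded at one decimal; truncation is the display default (10/18 prints as
55.5). Beetles-per-walnut averages use infested fruits only, which is why
the reported ranges start at 1.0.

## Synthetic data

The generators are pure functions of their arguments and seed.

- **DEM**: flat base plus a triangular east–west ridge with closed-form
  profile, so the area above any elevation threshold is analytic; optional
  seeded Gaussian noise; elevations clipped at 0 m.
- **Occurrences**: source chosen by weight, bearing uniform, displacement
  from an exponential (mean = scale) or half-normal kernel, placed with an
  equirectangular small-displacement offset; points landing off-grid, below
  0 m or above the elevation cap are *resampled*, not truncated, keeping n
  exact.
- **Haplotype samples**: multinomial draws at the configured frequencies
  (default 53.8 % / 46.2 %, the two-haplotype structure the analysis
  targets).
- **Alignments**: one random ancestor; each group consensus gets
  `k_g = round(between·L/2) − k_w` private substituted sites and each
  within-group variant `k_w = round(within·L/2)` more, all sites drawn
  without replacement across the whole alignment. Disjointness makes
  realised distances exact sums: any cross-group pair differs at
  2·round(between·L/2) sites and two variants at 2·k_w, so divergence
  round-trips are tight at integer resolution. Defaults: 658 bp, two
  groups, between 12.9 %, within 0.62 %.
- **Fruit records**: per-category Bernoulli infestation (defaults 10.0,
  16.2, 32.5 and 22.5 % for sorted/unsorted/discarded/ground), zero-
  truncated geometric beetle counts (mean 3.3, split binomially between
  adults and larvae), fine frass and kernel damage on infested fruits, a
  sheath crack at rate 0.8, and live moth stages on infested fruits at the
  conditional co-infestation rate 0.15 (≈ 3 % of all fruits labelled
  "both" under the default category mix).

What the generators do *not* emulate: spatial autocorrelation of habitat
quality, anisotropic or human-network dispersal, sequencing error,
alignment gaps/ambiguities (generated alignments are gap-free; the distance
machinery's pairwise deletion is exercised by constructed fixtures
instead), and year-to-year dynamics. Passing the recovery tests therefore
shows the estimators are correct under the assumed generative structure,
not that field data satisfy that structure.

## Problem sizes and tolerances

Tests run the profiler on grids up to 90 × 70 cells with 30-replicate
bootstraps and 20-seed recovery loops (a few seconds in total); the
brute-force oracle equivalence is asserted at 1e−12 per cell on grids up to
20 × 20; divergence recovery is asserted within ±1 percentage point at
1448 bp; frequency recovery within ±0.015 at n = 10 000; fruit-summary
recovery within ~2 SE. Degenerate inputs (coincident occurrences with a
zero normaliser, all-masked surfaces, single-haplotype streams, singleton
groups, zero comparable sites) raise descriptive errors or return the
documented markers rather than NaNs.

## Known limitations

- The profiler scores cell centres only; peak localisation is limited to
  one cell width, and the quantile/merge-radius hotspot extraction is a
  heuristic, not a probabilistic posterior.
- Eq.-style sufficiency formulas assume a neutral coalescent and stable
  frequencies; the iterative trace treats observed frequencies as truth.
- The p-distance SE bootstrap resamples sites independently, ignoring
  within-codon dependence.
- ESRI ASCII is the only raster format (GeoTIFF intentionally out of
  scope); CSV/TSV/FASTA cover all tabular and sequence IO.
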