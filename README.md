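# invasionscope

Source-area inference and surveillance statistics for invasive sap-beetle
outbreaks.

When a stored-product pest such as the sap beetle *Carpophilus truncatus*
erupts across a region, three questions dominate the early response: *where
did the invasion start*, *have we sequenced enough specimens to know the
population's genetic makeup*, and *how much damage is it doing, and is it
really this species*. `invasionscope` packages the computational chain that
answers them from monitoring data:

- **Geographic profiling** (`invasionscope.geo_profile`) — a Dragnet-style
  distance-decay model scores every cell of a lon/lat grid by

  `score(c) = (1/N) Σᵢ exp(−β · d(c, i)/σ)`

  where `d` is the haversine distance from the cell centre to infested site
  *i* and `σ` the mean pairwise distance among sites (no buffer zone: the
  score peaks at zero distance). Robustness comes from bagging: 30 random
  subsamples of 25–75 % of the sites are scored, each replicate surface is
  min–max rescaled to [0, 1], and the cell-wise mean is the profile. The
  surface can be restricted to an elevation band (0–600 m a.s.l. by default,
  matching where the beetle is actually found) and its top-quantile cells are
  clustered into ranked candidate source areas.
- **Haplotype sampling statistics** (`invasionscope.haplotype_stats`) —
  collapse aligned COI sequences into haplotypes and evaluate two closed
  forms: the coalescent probability `p = (n−1)/(n+1)` that a sample of size
  *n* captured every haplotype, and the minimum sample size
  `n = ln(1−β)/ln(1−p)` to detect a haplotype of frequency *p* at confidence
  *β*, including the iterative re-evaluation as sequences accrue.
- **Group p-distances** (`invasionscope.genetic_distances`) — uncorrected
  p-distance matrices within and between species groups with pairwise
  deletion and site-bootstrap standard errors, plus the aggregate summaries
  (mean/max/min between- and within-group divergence) used to weigh
  intra- vs inter-specific variation.
- **Damage attribution** (`invasionscope.surveillance_damage`) — the
  fruit-level rules separating sap-beetle from moth damage (live stages;
  silk threads or frass > 0.5 mm ⇒ moth; fine frass ≤ 0.1 mm ⇒ sap beetle),
  with site-level infestation and per-category damage summaries.
- **Synthetic data** (`invasionscope.synthetic_data`) — seeded generators
  for every input (occurrence clouds from dispersal kernels, DEMs, haplotype
  samples, alignments at controlled divergence, fruit records), so the whole
  pipeline is testable without field data.

## Worked example

```python
from invasionscope import GeographicProfile, BootstrapParams
from invasionscope.synthetic_data import SimulationConfig, generate_bundle

config = SimulationConfig(seed=7, n_occurrences=50)   # one source at (14.43, 40.66)
bundle = generate_bundle(config)

model = GeographicProfile(bundle["occurrences"], grid=config.grid)
results = model.fit(bootstrap=BootstrapParams(seed=7))
masked = results.apply_elevation_mask(bundle["dem"])  # 0-600 m a.s.l.
print(masked.summary())
```

```
Dragnet geographic profile
============================================
occurrences:        50
grid:               70 x 90 cells, 0.01 deg
decay coefficient:  1 (normalised by mean_pairwise_distance)
provenance:         masked
valid cells:        5580 / 6300
bootstrap:          30 replicates, fractions [0.25, 0.75], seed 7
candidate source areas (q=0.95): 1
  rank 1: peak (14.4350, 40.6650) score 0.9941, 279 cells
```

The rank-1 peak lands one cell (≈ 0.7 km) from the true simulated source at
(14.43, 40.66): with 50 occurrence sites dispersed on a 5 km scale, the
bagged profile pinpoints the introduction area. The sampling-sufficiency
side of the analysis is closed-form:

```python
from invasionscope import prob_all_haplotypes_sampled, min_detection_sample_size
prob_all_haplotypes_sampled(39)          # 0.95 - 39 sequences suffice at 95 %
min_detection_sample_size(0.462, 0.95)   # 4.83 - to detect a 46.2 %-frequency haplotype
```

and the bundled eight-species *Carpophilus* COI reference matrix summarises
to a mean between-species distance of 14.8 % against a mean within-species
distance of 1.39 % (truncated; max 3.52 %) — the barcode gap that secures
species identification:

```python
from invasionscope.datasets import carpophilus_coi_pdistance_table
from invasionscope import matrix_summaries
matrix_summaries(carpophilus_coi_pdistance_table())
# mean_between 14.8, max_between ('C. dimidiatus', 'C. davidsoni', 18.49), ...
```

A command-line umbrella mirrors the library:
`invasionscope {simulate, classify, summarize, hapstats, pdist, profile,
mask, hotspots, run}`.

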