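"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
occurrence points dispersed from one or more introduction sites over an
elevation surface, haplotype samples drawn from stated frequencies, aligned
sequence sets with controlled within/between-group divergence, and fruit
inspection records with per-category infestation probabilities — so that
every pipeline stage can be exercised and calibrated without field data.

Defaults mirror the study system the package targets: a two-haplotype
population near 54/46 %, between-species COI divergences of 10–19 %,
category-wise fruit infestation rates of roughly 10–33 %, and occurrence
clouds with a ~5 km dispersal scale.  Every generator is a pure function of
its arguments and seed (byte-identical outputs for identical inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geo_profile import (
    EARTH_RADIUS_KM,
    ElevationGrid,
    GridSpec,
    OccurrenceRecord,
)
from .haplotype_stats import AlignedSequence, _haplotype_label
from .surveillance_damage import FRUIT_CATEGORIES, FruitRecord

__all__ = [
    "SimulationConfig",
    "gen_dem",
    "gen_occurrences",
    "gen_haplotype_samples",
    "gen_alignment",
    "gen_fruit_records",
    "generate_bundle",
]

_SITE_TYPE_CYCLE = ("warehouse", "orchard", "farm")


# ---------------------------------------------------------------------------
# DEM

def gen_dem(
    grid: GridSpec,
    base_elevation: float = 100.0,
    ridge_amplitude: float = 0.0,
    ridge_lat: float | None = None,
    ridge_halfwidth: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ElevationGrid:
    """Synthetic elevation surface: a flat base plus a triangular ridge.

    The ridge runs east–west at latitude ``ridge_lat`` (grid mid-latitude by
    default) and decays linearly to zero over ``ridge_halfwidth`` degrees:

        elev(lat) = base + amplitude * max(0, 1 - |lat - ridge_lat| / halfwidth)

    The profile is analytic, so the land fraction above any threshold has a
    closed form — convenient for checking elevation masking.  Optional
    Gaussian noise (``noise_sd`` m, seeded) roughens the surface; elevations
    are clipped at 0 m.
    """
    _, lats = grid.cell_centers()
    if ridge_lat is None:
        ridge_lat = 0.5 * (grid.min_lat + grid.max_lat)
    profile = base_elevation + ridge_amplitude * np.maximum(
        0.0, 1.0 - np.abs(lats - ridge_lat) / ridge_halfwidth
    )
    values = np.broadcast_to(profile[:, None], grid.shape).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=grid.shape)
    return ElevationGrid(grid, np.maximum(values, 0.0))


# ---------------------------------------------------------------------------
# occurrences

def _displace(lon, lat, distance_km, bearing_rad):
    """Small-displacement spherical offset (equirectangular approximation)."""
    ang = distance_km / EARTH_RADIUS_KM
    dlat = math.degrees(ang * math.cos(bearing_rad))
    dlon = math.degrees(ang * math.sin(bearing_rad)) / math.cos(math.radians(lat))
    return lon + dlon, lat + dlat


def gen_occurrences(
    n: int,
    sources: Sequence[tuple[float, float, float]] = ((14.43, 40.66, 1.0),),
    kernel: str = "exponential",
    scale_km: float = 5.0,
    dem: ElevationGrid | None = None,
    max_elevation: float = 600.0,
    seed: int = 0,
    years: Sequence[int] = (2019, 2020),
) -> list[OccurrenceRecord]:
    """Occurrence points dispersed from weighted source locations.

    Each point picks a source by weight, a uniform bearing, and a kernel
    displacement distance (``exponential``: mean ``scale_km``; ``gaussian``:
    half-normal with sigma ``scale_km``).  When a DEM is supplied, the point
    takes the elevation of its cell, and points landing above
    ``max_elevation`` (or below 0, or off-grid) are resampled rather than
    truncated, keeping ``n`` exact.
    """
    if kernel not in ("exponential", "gaussian"):
        raise ValueError(f"unknown dispersal kernel {kernel!r}")
    sources = list(sources)
    weights = np.array([s[2] for s in sources], float)
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("source weights must be non-negative and not all zero")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        for _attempt in range(10_000):
            k = rng.choice(len(sources), p=weights)
            slon, slat, _ = sources[k]
            d = (
                rng.exponential(scale_km)
                if kernel == "exponential"
                else abs(rng.normal(0.0, scale_km))
            )
            bearing = rng.uniform(0.0, 2.0 * math.pi)
            lon, lat = _displace(slon, slat, d, bearing)
            if dem is not None:
                if not dem.grid.contains(lon, lat):
                    continue
                elev = dem.elevation_at(lon, lat)
                if elev > max_elevation or elev < 0:
                    continue
            else:
                elev = 0.0
            break
        else:
            raise RuntimeError("could not place an occurrence below the elevation cap")
        records.append(
            OccurrenceRecord(
                site_id=f"S{i:04d}",
                longitude=lon,
                latitude=lat,
                elevation=float(elev),
                site_type=_SITE_TYPE_CYCLE[i % len(_SITE_TYPE_CYCLE)],
                year=int(years[i % len(years)]),
                infested=True,
            )
        )
    return records


# ---------------------------------------------------------------------------
# haplotype samples

def gen_haplotype_samples(
    freqs: Sequence[float] = (0.538, 0.462),
    n: int = 65,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> list[str]:
    """Multinomial haplotype label draws at the given frequencies."""
    freqs = np.asarray(freqs, float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies must sum to 1, got {freqs.sum()}")
    if labels is None:
        labels = [_haplotype_label(i) for i in range(len(freqs))]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(freqs), size=n, p=freqs)
    return [labels[i] for i in idx]


# ---------------------------------------------------------------------------
# alignments

_BASES = "ACGT"


def gen_alignment(
    length: int = 658,
    groups: Mapping[str, int] = None,
    between_divergence: float = 0.129,
    within_divergence: float = 0.0062,
    n_variants: int = 2,
    seed: int = 0,
) -> list[AlignedSequence]:
    """Aligned sequence groups hitting divergence targets at integer resolution.

    One random ancestor is drawn; each group's consensus differs from it at
    ``k_g`` private sites and each of the group's ``n_variants`` haplotype
    variants adds ``k_w`` further private sites, with all substituted sites
    disjoint (sampled without replacement across the whole alignment).  With
    disjoint sites the realised distances are exact sums:

        d(between groups) = 2*k_g + 2*k_w   (any cross-group pair)
        d(within group)   = 2*k_w           (distinct variants)

    ``k_w = round(within * L / 2)`` and ``k_g = round(between * L / 2) - k_w``
    so the realised between-group p-distance equals the target to within
    0.5/L.  Individuals are assigned to variants round-robin.
    """
    if groups is None:
        groups = {"groupA": 5, "groupB": 5}
    if not 0 <= between_divergence <= 0.25 or not 0 <= within_divergence <= 0.25:
        raise ValueError("divergence targets must be in [0, 0.25]")
    k_w = int(round(within_divergence * length / 2.0))
    k_g = int(round(between_divergence * length / 2.0)) - k_w
    if k_g < 0:
        raise ValueError("within-group divergence exceeds the between-group target")
    n_groups = len(groups)
    needed = n_groups * k_g + n_groups * n_variants * k_w
    if needed > length:
        raise ValueError(
            f"divergence targets need {needed} distinct sites but the alignment "
            f"has only {length}"
        )
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(list(_BASES), size=length)
    site_pool = list(rng.permutation(length))

    def _take(k: int) -> list[int]:
        return [site_pool.pop() for _ in range(k)]

    def _substitute(seq: np.ndarray, sites: list[int]) -> np.ndarray:
        out = seq.copy()
        for s in sites:
            alternatives = [b for b in _BASES if b != out[s]]
            out[s] = alternatives[rng.integers(len(alternatives))]
        return out

    sequences: list[AlignedSequence] = []
    for gname, n_seqs in groups.items():
        consensus = _substitute(ancestor, _take(k_g))
        variants = [_substitute(consensus, _take(k_w)) for _ in range(n_variants)]
        for i in range(n_seqs):
            residues = "".join(variants[i % n_variants])
            sequences.append(
                AlignedSequence(seq_id=f"{gname}_{i:02d}", residues=residues, group=gname)
            )
    return sequences


# ---------------------------------------------------------------------------
# fruit records

#: Default per-category probability that an inspected fruit is sap-beetle
#: infested (sorted / unsorted / discarded / collected from the ground).
DEFAULT_CATEGORY_PROBS = {
    "sorted": 0.10,
    "unsorted": 0.162,
    "discarded": 0.325,
    "ground": 0.225,
}


def gen_fruit_records(
    category_probs: Mapping[str, float] | None = None,
    n_sites_per_category: int = 5,
    fruits_per_site: int = 20,
    beetle_mean: float = 3.3,
    adult_fraction: float = 0.3,
    moth_co_rate: float = 0.15,
    sheath_crack_rate: float = 0.8,
    year: int = 2019,
    seed: int = 0,
) -> list[FruitRecord]:
    """Fruit inspection records with per-category Bernoulli infestation.

    Infested fruits receive a zero-truncated geometric sap-beetle count with
    the given mean (split between adults and larvae), show kernel damage,
    leave fine frass, and carry a sheath crack at ``sheath_crack_rate``.
    ``moth_co_rate`` is the conditional probability that an infested fruit
    *also* hosts live moth stages (co-infestation); with the default
    category probabilities (overall infestation ~0.20) a rate of 0.15 yields
    roughly 3 % of all fruits labelled "both".
    """
    probs = dict(DEFAULT_CATEGORY_PROBS if category_probs is None else category_probs)
    unknown = set(probs) - set(FRUIT_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown fruit categories: {sorted(unknown)}")
    if beetle_mean < 1.0:
        raise ValueError("zero-truncated beetle count needs mean >= 1")
    rng = np.random.default_rng(seed)
    records: list[FruitRecord] = []
    for cat in FRUIT_CATEGORIES:
        if cat not in probs:
            continue
        p_inf = probs[cat]
        for s in range(n_sites_per_category):
            site_id = f"{cat[:2].upper()}{s:03d}"
            for f in range(fruits_per_site):
                fruit_id = f"{site_id}-F{f:03d}"
                infested = rng.random() < p_inf
                if infested:
                    count = int(rng.geometric(1.0 / beetle_mean))
                    adults = int(rng.binomial(count, adult_fraction))
                    larvae = count - adults
                    moth = rng.random() < moth_co_rate
                    records.append(
                        FruitRecord(
                            fruit_id=fruit_id,
                            site_id=site_id,
                            year=year,
                            category=cat,
                            sap_beetle_adults=adults,
                            sap_beetle_larvae=larvae,
                            moth_stages_present=moth,
                            silk_threads=bool(moth and rng.random() < 0.5),
                            frass_diameter_mm=float(rng.uniform(0.02, 0.1)),
                            kernel_damaged=True,
                            sheath_crack=bool(rng.random() < sheath_crack_rate),
                        )
                    )
                else:
                    records.append(
                        FruitRecord(
                            fruit_id=fruit_id,
                            site_id=site_id,
                            year=year,
                            category=cat,
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# bundle

@dataclass
class SimulationConfig:
    """One config object driving every generator (seeded sub-streams)."""

    seed: int = 0
    # geography
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(14.0, 14.9, 40.4, 41.1, 0.01)
    )
    sources: Sequence[tuple[float, float, float]] = ((14.43, 40.66, 1.0),)
    dispersal_kernel: str = "exponential"
    dispersal_scale_km: float = 5.0
    n_occurrences: int = 50
    base_elevation: float = 100.0
    ridge_amplitude: float = 900.0
    ridge_halfwidth: float = 0.08
    max_elevation: float = 600.0
    # genetics
    haplotype_freqs: Sequence[float] = (0.538, 0.462)
    n_haplotype_samples: int = 65
    alignment_length: int = 658
    alignment_groups: Mapping[str, int] = field(
        default_factory=lambda: {"groupA": 5, "groupB": 5}
    )
    between_divergence: float = 0.129
    within_divergence: float = 0.0062
    n_variants: int = 2
    # fruit surveillance
    category_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    n_sites_per_category: int = 5
    fruits_per_site: int = 20
    beetle_mean: float = 3.3
    moth_co_rate: float = 0.15


def generate_bundle(config: SimulationConfig) -> dict:
    """All pipeline inputs from one config: dem, occurrences, haplotype
    samples, alignment, fruit records (deterministic per-seed sub-streams)."""
    seeds = np.random.SeedSequence(config.seed).generate_state(5)
    dem = gen_dem(
        config.grid,
        base_elevation=config.base_elevation,
        ridge_amplitude=config.ridge_amplitude,
        ridge_halfwidth=config.ridge_halfwidth,
        seed=int(seeds[0] % (2**31)),
    )
    occurrences = gen_occurrences(
        config.n_occurrences,
        sources=config.sources,
        kernel=config.dispersal_kernel,
        scale_km=config.dispersal_scale_km,
        dem=dem,
        max_elevation=config.max_elevation,
        seed=int(seeds[1] % (2**31)),
    )
    haplotypes = gen_haplotype_samples(
        config.haplotype_freqs, config.n_haplotype_samples, seed=int(seeds[2] % (2**31))
    )
    alignment = gen_alignment(
        length=config.alignment_length,
        groups=config.alignment_groups,
        between_divergence=config.between_divergence,
        within_divergence=config.within_divergence,
        n_variants=config.n_variants,
        seed=int(seeds[3] % (2**31)),
    )
    fruit_records = gen_fruit_records(
        category_probs=config.category_probs,
        n_sites_per_category=config.n_sites_per_category,
        fruits_per_site=config.fruits_per_site,
        beetle_mean=config.beetle_mean,
        moth_co_rate=config.moth_co_rate,
        seed=int(seeds[4] % (2**31)),
    )
    return {
        "dem": dem,
        "occurrences": occurrences,
        "haplotype_samples": haplotypes,
        "alignment": alignment,
        "fruit_records": fruit_records,
    }
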