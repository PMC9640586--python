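"""Fruit-level damage attribution and site/category infestation summaries.

Inspected walnut fruits carry direct evidence (live sap-beetle or moth
stages) or indirect evidence (silk threads, frass of a diagnostic particle
size, kernel damage).  Attribution follows a fixed clause order: live
insects dominate; absent those, silk threads or coarse frass (> 0.5 mm)
implicate moths, fine frass (<= 0.1 mm) implicates sap beetles, and frass of
intermediate size with no other evidence is left undetermined rather than
silently attributed.  Summaries aggregate attributions to the site level
("infested site" = at least one sap-beetle-attributed fruit) and to walnut
handling categories (sorted / unsorted / discarded / collected from the
ground), reporting mean +/- SE and range of site-level damage percentages and
of beetle counts per infested fruit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .haplotype_stats import format_percent

__all__ = [
    "FRUIT_CATEGORIES",
    "DAMAGE_LABELS",
    "FruitRecord",
    "DamageAttribution",
    "classify_damage",
    "site_infestation_summary",
    "category_damage_table",
]

FRUIT_CATEGORIES = ("sorted", "unsorted", "discarded", "ground")
DAMAGE_LABELS = ("sap_beetle", "moth", "both", "none", "undetermined")

#: Frass particle diameter (mm) at or below which frass is diagnostic of
#: sap-beetle feeding (fine residues of kernel and excrement).
FINE_FRASS_MM = 0.1
#: Frass diameter (mm) strictly above which frass is attributed to moths.
COARSE_FRASS_MM = 0.5


@dataclass(frozen=True)
class FruitRecord:
    """One inspected walnut fruit."""

    fruit_id: str
    site_id: str
    year: int
    category: str
    sap_beetle_adults: int = 0
    sap_beetle_larvae: int = 0
    moth_stages_present: bool = False
    silk_threads: bool = False
    frass_diameter_mm: float | None = None
    kernel_damaged: bool = False
    sheath_crack: bool = False

    def __post_init__(self):
        if self.category not in FRUIT_CATEGORIES:
            raise ValueError(
                f"fruit {self.fruit_id!r}: category {self.category!r} not one of "
                f"{FRUIT_CATEGORIES}"
            )
        if self.sap_beetle_adults < 0 or self.sap_beetle_larvae < 0:
            raise ValueError(f"fruit {self.fruit_id!r}: negative insect counts")
        if self.frass_diameter_mm is not None and self.frass_diameter_mm < 0:
            raise ValueError(f"fruit {self.fruit_id!r}: negative frass diameter")

    @property
    def sap_beetle_count(self) -> int:
        return self.sap_beetle_adults + self.sap_beetle_larvae


@dataclass(frozen=True)
class DamageAttribution:
    label: str
    rule_fired: str


def classify_damage(fruit: FruitRecord) -> DamageAttribution:
    """Attribute the damage of one fruit; exactly one label always results.

    Clause order (first match wins):
      1. live sap-beetle stages AND live moth stages -> both
      2. live sap-beetle stages -> sap_beetle
      3. live moth stages -> moth
      4. no live insects, silk threads or frass > 0.5 mm -> moth
      5. frass present and <= 0.1 mm -> sap_beetle
      6. frass in (0.1, 0.5] mm without silk -> undetermined
      7. no evidence -> none
    """
    beetles = fruit.sap_beetle_count > 0
    moths = fruit.moth_stages_present
    frass = fruit.frass_diameter_mm
    if beetles and moths:
        return DamageAttribution("both", "live sap-beetle and moth stages present")
    if beetles:
        return DamageAttribution("sap_beetle", "live sap-beetle stages present")
    if moths:
        return DamageAttribution("moth", "live moth stages present")
    if fruit.silk_threads or (frass is not None and frass > COARSE_FRASS_MM):
        return DamageAttribution(
            "moth", f"silk threads or frass > {COARSE_FRASS_MM} mm without live insects"
        )
    if frass is not None and frass <= FINE_FRASS_MM:
        return DamageAttribution(
            "sap_beetle", f"fine frass <= {FINE_FRASS_MM} mm without live insects"
        )
    if frass is not None:
        return DamageAttribution(
            "undetermined",
            f"frass in ({FINE_FRASS_MM}, {COARSE_FRASS_MM}] mm, no other evidence",
        )
    return DamageAttribution("none", "no infestation evidence")


def _is_sap_beetle_fruit(fruit: FruitRecord) -> bool:
    return classify_damage(fruit).label in ("sap_beetle", "both")


def site_infestation_summary(
    records: Sequence[FruitRecord],
    year: int | None = None,
    site_types: Mapping[str, str] | None = None,
) -> dict:
    """Count infested sites (>= 1 sap-beetle-attributed fruit per site).

    Returns total and infested site counts, the infestation percentage in
    both truncated and rounded 1-decimal forms, and, when a site_id ->
    site-type mapping is given, the same breakdown per site type.
    """
    if year is not None:
        records = [r for r in records if r.year == year]
    if not records:
        raise ValueError("no fruit records to summarise")
    sites: dict[str, bool] = {}
    for r in records:
        sites[r.site_id] = sites.get(r.site_id, False) or _is_sap_beetle_fruit(r)
    n_sites = len(sites)
    n_infested = sum(sites.values())
    pct = 100.0 * n_infested / n_sites
    out = {
        "n_sites": n_sites,
        "n_infested": n_infested,
        "percent_truncated": format_percent(pct, 1, "truncate"),
        "percent_rounded": format_percent(pct, 1, "round"),
    }
    if site_types is not None:
        by_type: dict[str, dict] = {}
        for site_id, infested in sites.items():
            st = site_types.get(site_id, "unknown")
            d = by_type.setdefault(st, {"n_sites": 0, "n_infested": 0})
            d["n_sites"] += 1
            d["n_infested"] += int(infested)
        for d in by_type.values():
            p = 100.0 * d["n_infested"] / d["n_sites"]
            d["percent_truncated"] = format_percent(p, 1, "truncate")
            d["percent_rounded"] = format_percent(p, 1, "round")
        out["by_site_type"] = by_type
    return out


def category_damage_table(
    records: Sequence[FruitRecord],
    year: int | None = None,
) -> pd.DataFrame:
    """Per-category damage summary (one row per walnut handling category).

    Columns: site-level percentage of sap-beetle-damaged fruits as
    mean +/- SE (SE = SD / sqrt(n_sites), 0 for a single site) with min-max
    range, and sap beetles per *infested* walnut as mean +/- SE with range.
    Categories with no records are omitted.
    """
    if year is not None:
        records = [r for r in records if r.year == year]
    if not records:
        raise ValueError("no fruit records to summarise")
    rows = []
    for cat in FRUIT_CATEGORIES:
        cat_records = [r for r in records if r.category == cat]
        if not cat_records:
            continue
        site_pcts = []
        for site_id in dict.fromkeys(r.site_id for r in cat_records):
            fruits = [r for r in cat_records if r.site_id == site_id]
            damaged = sum(_is_sap_beetle_fruit(r) for r in fruits)
            site_pcts.append(100.0 * damaged / len(fruits))
        site_pcts = np.array(site_pcts)
        counts = np.array(
            [r.sap_beetle_count for r in cat_records if _is_sap_beetle_fruit(r) and r.sap_beetle_count > 0],
            float,
        )

        def _mean_se(x: np.ndarray) -> tuple[float, float]:
            if x.size == 0:
                return (np.nan, np.nan)
            se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
            return (float(x.mean()), se)

        pct_mean, pct_se = _mean_se(site_pcts)
        cnt_mean, cnt_se = _mean_se(counts)
        rows.append(
            {
                "category": cat,
                "n_sites": len(site_pcts),
                "n_fruits": len(cat_records),
                "damaged_pct_mean": pct_mean,
                "damaged_pct_se": pct_se,
                "damaged_pct_min": float(site_pcts.min()),
                "damaged_pct_max": float(site_pcts.max()),
                "beetles_per_walnut_mean": cnt_mean,
                "beetles_per_walnut_se": cnt_se,
                "beetles_per_walnut_min": float(counts.min()) if counts.size else np.nan,
                "beetles_per_walnut_max": float(counts.max()) if counts.size else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def attribution_counts(records: Iterable[FruitRecord]) -> dict[str, int]:
    """Tally of damage labels over a record set (labels always sum to n)."""
    counts = {label: 0 for label in DAMAGE_LABELS}
    for r in records:
        counts[classify_damage(r).label] += 1
    return counts
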