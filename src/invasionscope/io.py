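"""File formats, validation and the end-to-end pipeline runner.

Formats: FASTA alignments (via Biopython), tab-separated sequence metadata,
CSV occurrence and fruit-inspection records, and ESRI ASCII grids for the
digital elevation model and score surfaces.  Readers reject malformed input
with messages naming the file, 1-based line number and field; there is no
silent coercion.  :func:`run_pipeline` chains the analysis stages and writes
a machine-readable run report (inputs, seed, parameters, output hashes) that
suffices to reproduce the run.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import genetic_distances, haplotype_stats, surveillance_damage
from .geo_profile import (
    BootstrapParams,
    DragnetParams,
    ElevationGrid,
    GeographicProfile,
    GridSpec,
    OccurrenceRecord,
    ScoreSurface,
    SourceArea,
)
from .haplotype_stats import AlignedSequence

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_metadata_tsv",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "read_fruit_records_csv",
    "write_fruit_records_csv",
    "read_asc_grid",
    "write_asc_grid",
    "write_surface_asc",
    "write_source_areas_csv",
    "RunConfig",
    "run_pipeline",
]


class FormatError(ValueError):
    """Raised when an input file is malformed."""


# ---------------------------------------------------------------------------
# FASTA + metadata

def read_fasta(path) -> list[AlignedSequence]:
    """Read a (wrapped) FASTA file; ids are the first whitespace token."""
    path = Path(path)
    records = [
        AlignedSequence(seq_id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, sequences: Sequence[AlignedSequence], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_metadata_tsv(path) -> dict[str, dict]:
    """seq_id -> {locality, group} from a 2- or 3-column TSV (no header)."""
    path = Path(path)
    meta: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}, line {lineno}: expected at least 2 tab-separated "
                    f"fields (seq_id, locality[, group])"
                )
            meta[parts[0]] = {
                "locality": parts[1] or None,
                "group": parts[2] if len(parts) > 2 and parts[2] else None,
            }
    if not meta:
        raise FormatError(f"{path}: empty metadata file")
    return meta


def attach_metadata(
    sequences: Sequence[AlignedSequence], meta: Mapping[str, dict]
) -> list[AlignedSequence]:
    return [
        AlignedSequence(
            seq_id=s.seq_id,
            residues=s.residues,
            locality=meta.get(s.seq_id, {}).get("locality"),
            group=meta.get(s.seq_id, {}).get("group"),
        )
        for s in sequences
    ]


# ---------------------------------------------------------------------------
# CSV records

_OCC_FIELDS = ["site_id", "longitude", "latitude", "elevation_m", "site_type", "year", "infested"]


def _parse_bool(value: str, path, lineno: int, fieldname: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise FormatError(f"{path}, line {lineno}, field {fieldname!r}: not a boolean: {value!r}")


def _parse_num(value: str, path, lineno: int, fieldname: str, kind=float):
    try:
        return kind(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}, line {lineno}, field {fieldname!r}: not a number: {value!r}"
        ) from None


def read_occurrences_csv(path) -> list[OccurrenceRecord]:
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_OCC_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    OccurrenceRecord(
                        site_id=row["site_id"],
                        longitude=_parse_num(row["longitude"], path, lineno, "longitude"),
                        latitude=_parse_num(row["latitude"], path, lineno, "latitude"),
                        elevation=_parse_num(row["elevation_m"], path, lineno, "elevation_m"),
                        site_type=row["site_type"],
                        year=_parse_num(row["year"], path, lineno, "year", int),
                        infested=_parse_bool(row["infested"], path, lineno, "infested"),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}, line {lineno}: {exc}") from None
    if not records:
        raise FormatError(f"{path}: no occurrence records")
    return records


def write_occurrences_csv(path, records: Sequence[OccurrenceRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_OCC_FIELDS)
        for r in records:
            writer.writerow(
                [r.site_id, f"{r.longitude:.6f}", f"{r.latitude:.6f}",
                 f"{r.elevation:.1f}", r.site_type, r.year, str(r.infested).lower()]
            )


_FRUIT_FIELDS = [
    "fruit_id", "site_id", "year", "category", "sap_beetle_adults",
    "sap_beetle_larvae", "moth_stages_present", "silk_threads",
    "frass_diameter_mm", "kernel_damaged", "sheath_crack",
]


def read_fruit_records_csv(path) -> list[surveillance_damage.FruitRecord]:
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_FRUIT_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            frass = row["frass_diameter_mm"].strip()
            try:
                records.append(
                    surveillance_damage.FruitRecord(
                        fruit_id=row["fruit_id"],
                        site_id=row["site_id"],
                        year=_parse_num(row["year"], path, lineno, "year", int),
                        category=row["category"],
                        sap_beetle_adults=_parse_num(
                            row["sap_beetle_adults"], path, lineno, "sap_beetle_adults", int
                        ),
                        sap_beetle_larvae=_parse_num(
                            row["sap_beetle_larvae"], path, lineno, "sap_beetle_larvae", int
                        ),
                        moth_stages_present=_parse_bool(
                            row["moth_stages_present"], path, lineno, "moth_stages_present"
                        ),
                        silk_threads=_parse_bool(row["silk_threads"], path, lineno, "silk_threads"),
                        frass_diameter_mm=(
                            None if frass == "" else _parse_num(frass, path, lineno, "frass_diameter_mm")
                        ),
                        kernel_damaged=_parse_bool(row["kernel_damaged"], path, lineno, "kernel_damaged"),
                        sheath_crack=_parse_bool(row["sheath_crack"], path, lineno, "sheath_crack"),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}, line {lineno}: {exc}") from None
    if not records:
        raise FormatError(f"{path}: no fruit records")
    return records


def write_fruit_records_csv(path, records) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FRUIT_FIELDS)
        for r in records:
            writer.writerow(
                [r.fruit_id, r.site_id, r.year, r.category, r.sap_beetle_adults,
                 r.sap_beetle_larvae, str(r.moth_stages_present).lower(),
                 str(r.silk_threads).lower(),
                 "" if r.frass_diameter_mm is None else f"{r.frass_diameter_mm:.3f}",
                 str(r.kernel_damaged).lower(), str(r.sheath_crack).lower()]
            )


# ---------------------------------------------------------------------------
# ESRI ASCII grid

_ASC_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_asc_grid(path) -> ElevationGrid:
    """Parse an ESRI ASCII grid; NODATA cells become invalid (masked).

    The file stores rows north-first, matching the in-memory convention.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    nodata = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASC_KEYS + ("nodata_value",):
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}, line {lineno}: header key {parts[0]!r} needs one value"
                    )
                if key == "nodata_value":
                    nodata = float(parts[1])
                else:
                    header[key] = float(parts[1])
            else:
                data_lines.append(line)
    missing = [k for k in _ASC_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: missing header key(s) {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    try:
        values = np.loadtxt(data_lines, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed data block: {exc}") from None
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: data block shape {values.shape} does not match header "
            f"({nrows} rows x {ncols} cols)"
        )
    grid = GridSpec(
        min_lon=header["xllcorner"],
        max_lon=header["xllcorner"] + ncols * cell,
        min_lat=header["yllcorner"],
        max_lat=header["yllcorner"] + nrows * cell,
        cell_size=cell,
    )
    valid = np.ones_like(values, bool) if nodata is None else values != nodata
    vals = values.copy()
    vals[~valid] = np.nan
    return ElevationGrid(grid, vals, valid)


def write_asc_grid(path, dem: ElevationGrid, nodata: float = -9999.0) -> None:
    g = dem.grid
    values = np.where(dem.valid, dem.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.min_lon:.10g}\n")
        fh.write(f"yllcorner {g.min_lat:.10g}\n")
        fh.write(f"cellsize {g.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def write_surface_asc(path, surface: ScoreSurface, nodata: float = -9999.0) -> None:
    write_asc_grid(path, ElevationGrid(surface.grid, surface.scores, surface.mask), nodata)


def write_source_areas_csv(path, areas: Sequence[SourceArea]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "peak_lon", "peak_lat", "peak_score", "n_cells"])
        for a in areas:
            writer.writerow(
                [a.rank, f"{a.peak_lon:.6f}", f"{a.peak_lat:.6f}",
                 f"{a.peak_score:.6f}", a.n_cells]
            )


# ---------------------------------------------------------------------------
# pipeline

_RUNCONFIG_KEYS = None  # filled after class definition


@dataclass
class RunConfig:
    """Inputs, outputs and stage parameters for one pipeline run."""

    occurrences_csv: str
    dem_asc: str
    fasta: str
    fruit_csv: str
    out_dir: str
    meta_tsv: str | None = None
    seed: int = 0
    decay_coefficient: float = 1.0
    n_replicates: int = 30
    fraction_low: float = 0.25
    fraction_high: float = 0.75
    max_elevation: float = 600.0
    quantile_threshold: float = 0.95
    merge_radius_km: float = 3.0
    beta: float = 0.95
    bootstrap_reps: int = 200
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        for attr in ("occurrences_csv", "dem_asc", "fasta", "fruit_csv"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FormatError(f"configured path does not exist ({attr}): {p}")
        if self.meta_tsv is not None and not Path(self.meta_tsv).exists():
            raise FormatError(f"configured path does not exist (meta_tsv): {self.meta_tsv}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run classify -> summarize -> hapstats -> pdist -> profile -> mask ->
    hotspots and write outputs plus a reproducibility report.

    Returns the report dict (also written to ``out_dir/run_report.json``).
    Raises on the first failing stage, naming it.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "stages": [],
        "outputs": {},
    }

    def _stage(name):
        report["stages"].append(name)

    def _record(name, path: Path):
        report["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        # 1. classify
        _stage("classify")
        fruits = read_fruit_records_csv(config.fruit_csv)
        labels = [surveillance_damage.classify_damage(f) for f in fruits]
        p = out_dir / "damage_labels.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fruit_id", "label", "rule_fired"])
            for f, lab in zip(fruits, labels):
                w.writerow([f.fruit_id, lab.label, lab.rule_fired])
        _record("damage_labels", p)

        # 2. summarize
        _stage("summarize")
        site_summary = surveillance_damage.site_infestation_summary(fruits)
        cat_table = surveillance_damage.category_damage_table(fruits)
        p = out_dir / "site_summary.json"
        p.write_text(json.dumps(site_summary, indent=2, sort_keys=True))
        _record("site_summary", p)
        p = out_dir / "category_damage.csv"
        cat_table.to_csv(p)
        _record("category_damage", p)

        # 3. hapstats
        _stage("hapstats")
        alignment = read_fasta(config.fasta)
        if config.meta_tsv:
            alignment = attach_metadata(alignment, read_metadata_tsv(config.meta_tsv))
        table = haplotype_stats.collapse_haplotypes(alignment)
        order = []
        for seq in alignment:
            for e in table.entries:
                if seq.seq_id in e.members:
                    order.append(e.haplotype_id)
                    break
        trace = (
            haplotype_stats.iterative_sufficiency(order, beta=config.beta)
            if len(order) >= 2
            else None
        )
        p = out_dir / "haplotypes.csv"
        table.to_frame().to_csv(p, index=False)
        _record("haplotypes", p)
        if trace is not None:
            p = out_dir / "sufficiency_trace.csv"
            trace.to_frame().to_csv(p, index=False)
            _record("sufficiency_trace", p)

        # 4. pdist
        _stage("pdist")
        groups = {s.seq_id: (s.group or "all") for s in alignment}
        if len(set(groups.values())) >= 2:
            matrix = genetic_distances.group_distance_matrix(
                alignment, groups, bootstrap_reps=config.bootstrap_reps, seed=config.seed
            )
            p = out_dir / "pdistance_matrix.csv"
            matrix.to_frame().to_csv(p)
            _record("pdistance_matrix", p)

        # 5. profile
        _stage("profile")
        occurrences = read_occurrences_csv(config.occurrences_csv)
        dem = read_asc_grid(config.dem_asc)
        model = GeographicProfile(
            occurrences,
            grid=dem.grid,
            params=DragnetParams(decay_coefficient=config.decay_coefficient),
        )
        boot = BootstrapParams(
            n_replicates=config.n_replicates,
            fraction_low=config.fraction_low,
            fraction_high=config.fraction_high,
            seed=config.seed,
        )
        results = model.fit(bootstrap=boot)
        p = out_dir / "profile_surface.asc"
        write_surface_asc(p, results.surface)
        _record("profile_surface", p)

        # 6. mask
        _stage("mask")
        masked = results.apply_elevation_mask(dem, config.max_elevation)
        p = out_dir / "profile_surface_masked.asc"
        write_surface_asc(p, masked.surface)
        _record("profile_surface_masked", p)

        # 7. hotspots
        _stage("hotspots")
        areas = masked.source_areas(config.quantile_threshold, config.merge_radius_km)
        p = out_dir / "source_areas.csv"
        write_source_areas_csv(p, areas)
        _record("source_areas", p)
    except Exception as exc:
        report["failed_stage"] = report["stages"][-1] if report["stages"] else None
        report["error"] = str(exc)
        (out_dir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise

    report["n_stages_completed"] = len(report["stages"])
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
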