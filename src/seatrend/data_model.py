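"""Domain types, CSV ingestion, annual aggregation and inclusion filtering.

The analysis operates on *populations*: one taxon observed at one monitoring
station. Raw monitoring rows (possibly several per year) are aggregated to
annual mean abundances; populations observed for fewer than five years, or
present in less than half of their monitoring period, are excluded so that
sporadic records of extreme abundances do not masquerade as trends.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("seatrend")

#: Ecosystem component labels used throughout; the set is extensible — these
#: are the canonical ones, validation only warns on others.
KNOWN_COMPONENTS = (
    "phytoplankton",
    "zooplankton",
    "macrozoobenthos",
    "fish",
    "birds",
    "plants",
)

TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

YEAR_MIN, YEAR_MAX = 1900, 2100


@dataclasses.dataclass(frozen=True)
class MonitoringRecord:
    """One raw monitoring observation (pre-aggregation)."""

    station_id: str
    taxon_id: str
    year: int
    abundance: float
    component: str = ""

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(
                f"negative abundance {self.abundance} for "
                f"(station={self.station_id}, taxon={self.taxon_id}, year={self.year})"
            )
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(
                f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}] for "
                f"(station={self.station_id}, taxon={self.taxon_id})"
            )


@dataclasses.dataclass(frozen=True)
class TaxonomyEntry:
    """Taxonomic classification of one taxon, kingdom down to species.

    Ranks may be empty strings from genus down (records identified only to a
    coarser rank).
    """

    taxon_id: str
    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def rank_path(self) -> tuple[str, ...]:
        return (
            self.kingdom,
            self.phylum,
            self.class_,
            self.order,
            self.family,
            self.genus,
            self.species,
        )


@dataclasses.dataclass
class PopulationSeries:
    """Annual-mean abundance series of one taxon at one station."""

    station_id: str
    taxon_id: str
    years: np.ndarray
    values: np.ndarray
    component: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have the same length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def n_obs(self) -> int:
        """Number of years with observations."""
        return int(self.years.size)

    @property
    def span(self) -> int:
        """Monitoring period in years, endpoints inclusive."""
        if self.years.size == 0:
            return 0
        return int(self.years[-1] - self.years[0] + 1)

    @property
    def centered_years(self) -> np.ndarray:
        """Years relative to the first observed year (fitting scale)."""
        return (self.years - self.years[0]).astype(float)

    def key(self) -> tuple[str, str]:
        return (self.station_id, self.taxon_id)


def aggregate_annual_means(
    records: Iterable[MonitoringRecord],
) -> list[PopulationSeries]:
    """Aggregate raw records to one annual-mean series per (station, taxon).

    Years without records are simply absent from the series — gaps are never
    zero-filled; a recorded zero abundance, by contrast, is a true
    observation and counts as an observed year.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no monitoring records to aggregate")
    df = pd.DataFrame(
        {
            "station_id": [r.station_id for r in recs],
            "taxon_id": [r.taxon_id for r in recs],
            "year": [r.year for r in recs],
            "abundance": [r.abundance for r in recs],
            "component": [r.component for r in recs],
        }
    )
    out: list[PopulationSeries] = []
    grouped = df.groupby(["station_id", "taxon_id"], sort=True)
    for (station, taxon), sub in grouped:
        annual = sub.groupby("year", sort=True)["abundance"].mean()
        component = sub["component"].iloc[0]
        out.append(
            PopulationSeries(
                station_id=station,
                taxon_id=taxon,
                years=annual.index.to_numpy(),
                values=annual.to_numpy(),
                component=component,
            )
        )
    return out


def inclusion_filter(
    series: PopulationSeries,
    min_years: int = 5,
    min_presence: float = 0.5,
    *,
    station_span: int | None = None,
) -> bool:
    """Inclusion rule: at least ``min_years`` observed years and presence in
    at least ``min_presence`` of the monitoring period.

    The monitoring period defaults to the population's own first-to-last
    observed year; pass ``station_span`` to assess presence against the
    station's full monitoring period instead.
    """
    span = station_span if station_span is not None else series.span
    if span <= 0:
        return False
    return series.n_obs >= min_years and series.n_obs / span >= min_presence


# ---------------------------------------------------------------------------
# CSV ingestion


DEFAULT_SCHEMA = {
    "station": "station",
    "taxon": "taxon",
    "year": "year",
    "date": None,
    "abundance": "abundance",
    "component": "component",
}


@dataclasses.dataclass
class IngestReport:
    rows_read: int = 0
    rows_kept: int = 0
    rows_dropped: int = 0
    errors: list[str] = dataclasses.field(default_factory=list)


def load_schema(path: str | Path) -> dict:
    """Load a YAML/JSON column-mapping config for :func:`read_monitoring_csv`."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    return {**DEFAULT_SCHEMA, **(schema or {})}


def read_monitoring_csv(
    path: str | Path,
    schema: dict | None = None,
) -> tuple[list[MonitoringRecord], IngestReport]:
    """Read a long-format monitoring CSV into validated records.

    ``schema`` maps the logical fields (station, taxon, year or date,
    abundance, component) to column names. A ``date`` column, when mapped, is
    reduced to its calendar year. Rows with missing or unparseable year or
    abundance, or negative abundance, are dropped and counted in the report.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    report = IngestReport(rows_read=len(df))

    for field in ("station", "taxon", "abundance"):
        col = schema.get(field)
        if col not in df.columns:
            raise KeyError(f"mapped column {col!r} for {field!r} not in {list(df.columns)}")
    year_col, date_col = schema.get("year"), schema.get("date")
    if year_col not in df.columns and date_col not in df.columns:
        raise KeyError("neither a year nor a date column is present")

    if year_col in df.columns:
        years = pd.to_numeric(df[year_col], errors="coerce")
    else:
        years = pd.to_datetime(df[date_col], errors="coerce").dt.year

    abundances = pd.to_numeric(df[schema["abundance"]], errors="coerce")
    comp_col = schema.get("component")
    components = (
        df[comp_col].astype(str) if comp_col in df.columns else pd.Series([""] * len(df))
    )

    records: list[MonitoringRecord] = []
    for i in range(len(df)):
        y, a = years.iloc[i], abundances.iloc[i]
        if pd.isna(y) or pd.isna(a):
            report.rows_dropped += 1
            report.errors.append(f"row {i}: unparseable year/abundance")
            continue
        try:
            records.append(
                MonitoringRecord(
                    station_id=str(df[schema["station"]].iloc[i]),
                    taxon_id=str(df[schema["taxon"]].iloc[i]),
                    year=int(y),
                    abundance=float(a),
                    component=str(components.iloc[i]),
                )
            )
            report.rows_kept += 1
        except ValueError as exc:
            report.rows_dropped += 1
            report.errors.append(f"row {i}: {exc}")
    logger.info(
        "ingest %s: %d read, %d kept, %d dropped",
        path,
        report.rows_read,
        report.rows_kept,
        report.rows_dropped,
    )
    return records, report


def read_taxonomy_csv(path: str | Path) -> dict[str, TaxonomyEntry]:
    """Read the taxonomy table (taxon_id plus the seven rank columns).

    Raises on an inconsistent hierarchy: the same taxon_id mapping to two
    different classifications.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    col_map = {"class": "class_"}
    entries: dict[str, TaxonomyEntry] = {}
    for _, row in df.iterrows():
        kwargs = {
            col_map.get(rank, rank): str(row.get(rank, "")) for rank in TAXONOMIC_RANKS
        }
        entry = TaxonomyEntry(taxon_id=str(row["taxon_id"]), **kwargs)
        prior = entries.get(entry.taxon_id)
        if prior is not None and prior != entry:
            raise ValueError(f"taxon {entry.taxon_id} has conflicting classifications")
        entries[entry.taxon_id] = entry
    validate_taxonomy(entries.values())
    return entries


def validate_taxonomy(entries: Iterable[TaxonomyEntry]) -> None:
    """Check that ranks form a consistent tree: a named taxon at any rank has
    a single parent at the rank above."""
    parent: dict[tuple[int, str], tuple[str, ...]] = {}
    for e in entries:
        path = e.rank_path()[:-1]  # species level may legitimately repeat names
        for depth in range(1, len(path)):
            name = path[depth]
            if not name:
                continue
            key = (depth, name)
            anc = path[:depth]
            if key in parent and parent[key] != anc:
                raise ValueError(
                    f"taxonomy conflict: {TAXONOMIC_RANKS[depth]} {name!r} "
                    f"has two parent paths {parent[key]} vs {anc}"
                )
            parent[key] = anc


# ---------------------------------------------------------------------------
# Result writers — tidy CSVs, round-trippable field for field.


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
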