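"""Per-feather moult scoring weighted by feather-tract areas.

Post-juvenile (first partial) moult is recorded on museum skins and live
birds feather by feather: each wing and tail feather gets a score of 0
(retained juvenile feather) or 1 (moulted feather).  Ten tracts are covered:
lesser coverts (LC) and median coverts (MC) as moulted proportions (the
individual feathers are too small to score reliably), and 48 discrete
feathers — greater coverts GC1–GC10, the carpal covert CC, alula AL1–AL3,
primary coverts PC1–PC9, primaries P1–P10, secondaries S1–S6, tertials
T7–T9 and rectrices R1–R6.  Numbering is descendant for coverts and
ascendant where conventional; P1 is the innermost primary — the labels are
a fixed I/O convention, not re-interpreted.

The extent statistic is the moulted plumage *area*: each tract's moulted
fraction times the species-specific mean tract area in mm², summed over
tracts.  A normalised variant (relative extent, fraction of total wing+tail
area) supports cross-species averaging, and the year-averaged, min–max
normalised moult index summarises the whole dataset as one [0, 1] series.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ScoringError(ValueError):
    """Raised for inconsistent moult records, layouts or area tables."""


# ---------------------------------------------------------------------------
# Feather tract layout
# ---------------------------------------------------------------------------

#: canonical tract definitions: (name, feather labels or None for proportion tracts)
_TRACT_FEATHERS: dict[str, tuple[str, ...] | None] = {
    "LC": None,
    "MC": None,
    "GC": tuple(f"GC{i}" for i in range(1, 11)),
    "CC": ("CC",),
    "AL": tuple(f"AL{i}" for i in range(1, 4)),
    "PC": tuple(f"PC{i}" for i in range(1, 10)),
    "P": tuple(f"P{i}" for i in range(1, 11)),
    "S": tuple(f"S{i}" for i in range(1, 7)),
    "T": tuple(f"T{i}" for i in range(7, 10)),
    "R": tuple(f"R{i}" for i in range(1, 7)),
}

#: default tract filling order used by the synthetic generator; approximates a
#: typical passerine post-juvenile moult sequence (coverts first, flight
#: feathers last).
DEFAULT_PRIORITY_ORDER: tuple[str, ...] = (
    "LC", "MC", "GC", "CC", "AL", "T", "R", "PC", "S", "P",
)


@dataclasses.dataclass(frozen=True)
class TractSpec:
    """One feather tract: name, its feather labels (None = proportion tract)
    and its moult-priority rank (1 = moulted first)."""

    name: str
    labels: tuple[str, ...] | None
    priority: int

    @property
    def is_proportion(self) -> bool:
        return self.labels is None

    @property
    def n_feathers(self) -> int:
        return 0 if self.labels is None else len(self.labels)


@dataclasses.dataclass(frozen=True)
class FeatherTractLayout:
    """The canonical ten-tract wing+tail layout (2 proportion tracts, 48
    discrete feathers) with a moult-priority ordering over tracts."""

    tracts: tuple[TractSpec, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.tracts]
        if len(set(names)) != len(names):
            raise ScoringError("tract names must be unique")
        if set(names) != set(_TRACT_FEATHERS):
            raise ScoringError(
                f"layout must contain exactly the canonical tracts, got {sorted(names)}"
            )
        n_discrete = sum(t.n_feathers for t in self.tracts)
        if n_discrete != 48:
            raise ScoringError(f"discrete feather count must be 48, got {n_discrete}")
        prios = sorted(t.priority for t in self.tracts)
        if prios != list(range(1, len(self.tracts) + 1)):
            raise ScoringError("tract priorities must be a permutation of 1..n_tracts")

    @property
    def discrete_labels(self) -> tuple[str, ...]:
        """All 48 discrete feather labels in canonical column order."""
        out: list[str] = []
        for name in _TRACT_FEATHERS:
            labels = _TRACT_FEATHERS[name]
            if labels is not None:
                out.extend(labels)
        return tuple(out)

    @property
    def by_priority(self) -> tuple[TractSpec, ...]:
        return tuple(sorted(self.tracts, key=lambda t: t.priority))

    def tract(self, name: str) -> TractSpec:
        for t in self.tracts:
            if t.name == name:
                return t
        raise ScoringError(f"unknown tract {name!r}")


def default_layout(priority_order: Sequence[str] = DEFAULT_PRIORITY_ORDER) -> FeatherTractLayout:
    """Build the canonical layout with the given tract moult-priority order."""
    if sorted(priority_order) != sorted(_TRACT_FEATHERS):
        raise ScoringError("priority_order must be a permutation of the tract names")
    rank = {name: i + 1 for i, name in enumerate(priority_order)}
    tracts = tuple(
        TractSpec(name=name, labels=labels, priority=rank[name])
        for name, labels in _TRACT_FEATHERS.items()
    )
    return FeatherTractLayout(tracts=tracts)


# ---------------------------------------------------------------------------
# Records and area tables
# ---------------------------------------------------------------------------

SEXES = ("male", "female", "unknown")


@dataclasses.dataclass
class MoultRecord:
    """One specimen's moult scores.

    ``feather_scores`` maps each of the 48 discrete feather labels to 0, 1 or
    None (feather missing/damaged on the skin); ``lc_proportion`` and
    ``mc_proportion`` are the estimated moulted fractions of the lesser- and
    median-covert tracts.
    """

    specimen_id: str
    species_id: str
    collection_year: int
    sex: str
    feather_scores: dict[str, int | None]
    lc_proportion: float
    mc_proportion: float

    def validate(self, layout: FeatherTractLayout) -> None:
        if self.sex not in SEXES:
            raise ScoringError(f"{self.specimen_id}: sex must be one of {SEXES}, got {self.sex!r}")
        expected = set(layout.discrete_labels)
        got = set(self.feather_scores)
        if got != expected:
            missing = sorted(expected - got)[:5]
            extra = sorted(got - expected)[:5]
            raise ScoringError(
                f"{self.specimen_id}: feather scores must cover exactly the 48 "
                f"discrete labels (missing {missing}, unexpected {extra})"
            )
        for label, s in self.feather_scores.items():
            if s is not None and s not in (0, 1):
                raise ScoringError(f"{self.specimen_id}: score for {label} must be 0, 1 or missing")
        for name, p in (("lc_proportion", self.lc_proportion), ("mc_proportion", self.mc_proportion)):
            if not (0.0 <= p <= 1.0):
                raise ScoringError(f"{self.specimen_id}: {name}={p} outside [0, 1]")


class TractAreaTable:
    """Species-specific mean feather-tract areas (mm²), used as scoring weights."""

    def __init__(self, areas: Mapping[tuple[str, str], float]):
        self._areas: dict[tuple[str, str], float] = {}
        for (species, tract), a in areas.items():
            a = float(a)
            if not (a > 0.0) or not math.isfinite(a):
                raise ScoringError(f"area for ({species}, {tract}) must be strictly positive, got {a}")
            self._areas[(str(species), str(tract))] = a

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TractAreaTable":
        return cls({(r.species_id, r.tract): r.area_mm2 for r in frame.itertuples(index=False)})

    @classmethod
    def from_csv(cls, path) -> "TractAreaTable":
        frame = pd.read_csv(path, comment="#")
        required = {"species_id", "tract", "area_mm2"}
        if not required.issubset(frame.columns):
            raise ScoringError(f"tract-area CSV needs columns {sorted(required)}")
        return cls.from_frame(frame)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species_id": sp, "tract": tr, "area_mm2": a}
            for (sp, tr), a in sorted(self._areas.items())
        ]
        return pd.DataFrame(rows, columns=["species_id", "tract", "area_mm2"])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({sp for sp, _ in self._areas}))

    def area(self, species_id: str, tract: str) -> float:
        try:
            return self._areas[(species_id, tract)]
        except KeyError:
            raise ScoringError(
                f"no tract area for species {species_id!r}, tract {tract!r}"
            ) from None

    def total_area(self, species_id: str, layout: FeatherTractLayout) -> float:
        return sum(self.area(species_id, t.name) for t in layout.tracts)

    def check_complete(self, species_ids: Iterable[str], layout: FeatherTractLayout) -> None:
        for sp in species_ids:
            for t in layout.tracts:
                self.area(sp, t.name)


# ---------------------------------------------------------------------------
# Area statistics
# ---------------------------------------------------------------------------

def tract_fraction(record: MoultRecord, tract: TractSpec) -> float:
    """Moulted fraction of one tract: the stored proportion for LC/MC, else
    (count of 1-scores) / (count of non-missing scores).

    Missing feathers rescale the denominator rather than counting as
    non-moulted, so damaged skins do not bias extent downward.
    """
    if tract.is_proportion:
        return record.lc_proportion if tract.name == "LC" else record.mc_proportion
    scores = [record.feather_scores[label] for label in tract.labels]
    observed = [s for s in scores if s is not None]
    if not observed:
        raise ScoringError(
            f"{record.specimen_id}: tract {tract.name} has no observed feathers; "
            "moulted fraction is undefined"
        )
    return sum(observed) / len(observed)


def compute_moulted_area(
    record: MoultRecord, areas: TractAreaTable, layout: FeatherTractLayout
) -> float:
    """Moulted plumage area (mm²) of one specimen: sum over tracts of the
    tract's moulted fraction times its species-specific area."""
    return sum(
        tract_fraction(record, t) * areas.area(record.species_id, t.name)
        for t in layout.tracts
    )


def compute_relative_extent(
    record: MoultRecord, areas: TractAreaTable, layout: FeatherTractLayout
) -> float:
    """Moulted area as a fraction of the species' total wing+tail area, in [0, 1]."""
    return compute_moulted_area(record, areas, layout) / areas.total_area(
        record.species_id, layout
    )


def score_records(
    records: Iterable[MoultRecord], areas: TractAreaTable, layout: FeatherTractLayout
) -> pd.DataFrame:
    """Per-specimen extent table: one row per record with the moulted area and
    relative extent alongside species, year and sex."""
    rows = []
    for rec in records:
        area = compute_moulted_area(rec, areas, layout)
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "species_id": rec.species_id,
                "year": rec.collection_year,
                "sex": rec.sex,
                "area_mm2": area,
                "relative_extent": area / areas.total_area(rec.species_id, layout),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["specimen_id", "species_id", "year", "sex", "area_mm2", "relative_extent"],
    )


# ---------------------------------------------------------------------------
# Annual moult index
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MoultIndexSeries:
    """Year-averaged, min–max normalised moult index.

    ``table`` has columns year, n_species, n_specimens, raw_mean, index; the
    raw mean is the equal-species-weight average of per-species mean relative
    extents within a year, and index = (raw_mean − min) / (max − min) so the
    lowest yearly mean maps to 0 and the highest to 1.
    """

    table: pd.DataFrame
    raw_min: float
    raw_max: float

    @property
    def values(self) -> pd.Series:
        return self.table.set_index("year")["index"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def annual_moult_index(
    records: Iterable[MoultRecord],
    areas: TractAreaTable,
    layout: FeatherTractLayout,
    min_species: int = 1,
) -> MoultIndexSeries:
    """Compute the annual moult index.

    Per year: average relative extent within each species, then average those
    species means with equal weight; finally min–max normalise the yearly
    averages to [0, 1].  Years represented by fewer than ``min_species``
    species are dropped before normalisation.
    """
    extents = score_records(records, areas, layout)
    if extents.empty:
        raise ScoringError("no records to index")
    per_species_year = (
        extents.groupby(["year", "species_id"])
        .agg(mean_extent=("relative_extent", "mean"), n=("relative_extent", "size"))
        .reset_index()
    )
    yearly = (
        per_species_year.groupby("year")
        .agg(
            n_species=("species_id", "nunique"),
            n=("n", "sum"),
            raw_mean=("mean_extent", "mean"),
        )
        .reset_index()
    )
    yearly = yearly[yearly["n_species"] >= min_species].reset_index(drop=True)
    if len(yearly) < 2:
        raise ScoringError("moult index needs records from at least two years")
    lo, hi = float(yearly["raw_mean"].min()), float(yearly["raw_mean"].max())
    if hi - lo <= 0.0:
        raise ScoringError(
            "all yearly mean extents are identical; min–max normalisation is undefined"
        )
    yearly["index"] = (yearly["raw_mean"] - lo) / (hi - lo)
    table = yearly.rename(columns={"n": "n_specimens"})[
        ["year", "n_species", "n_specimens", "raw_mean", "index"]
    ]
    return MoultIndexSeries(table=table, raw_min=lo, raw_max=hi)


# ---------------------------------------------------------------------------
# Specimen CSV I/O
# ---------------------------------------------------------------------------

SPECIMEN_META_COLUMNS = ("specimen_id", "species_id", "year", "sex", "lc_prop", "mc_prop")


def specimen_columns(layout: FeatherTractLayout) -> tuple[str, ...]:
    return SPECIMEN_META_COLUMNS + layout.discrete_labels


def read_specimen_csv(path, layout: FeatherTractLayout | None = None) -> list[MoultRecord]:
    """Read the specimen table; empty feather cells mean a missing (damaged)
    feather, an empty or absent sex means 'unknown'."""
    layout = layout or default_layout()
    frame = pd.read_csv(path, comment="#")
    expected = specimen_columns(layout)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ScoringError(f"specimen CSV missing columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        sex = d.get("sex")
        sex = "unknown" if (sex is None or (isinstance(sex, float) and math.isnan(sex))) else str(sex).lower()
        scores = {}
        for label in layout.discrete_labels:
            v = d[label]
            scores[label] = None if pd.isna(v) else int(v)
        rec = MoultRecord(
            specimen_id=str(d["specimen_id"]),
            species_id=str(d["species_id"]),
            collection_year=int(d["year"]),
            sex=sex,
            feather_scores=scores,
            lc_proportion=float(d["lc_prop"]),
            mc_proportion=float(d["mc_prop"]),
        )
        rec.validate(layout)
        records.append(rec)
    return records


def records_to_frame(records: Iterable[MoultRecord], layout: FeatherTractLayout) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "specimen_id": rec.specimen_id,
            "species_id": rec.species_id,
            "year": rec.collection_year,
            "sex": rec.sex,
            "lc_prop": rec.lc_proportion,
            "mc_prop": rec.mc_proportion,
        }
        for label in layout.discrete_labels:
            s = rec.feather_scores[label]
            row[label] = np.nan if s is None else s
        rows.append(row)
    return pd.DataFrame(rows, columns=specimen_columns(layout))


def write_specimen_csv(records: Iterable[MoultRecord], path, layout: FeatherTractLayout | None = None) -> None:
    layout = layout or default_layout()
    frame = records_to_frame(records, layout)
    # keep integer formatting for scores while allowing empty cells for missing
    frame.to_csv(path, index=False, float_format="%.10g")
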