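"""Global mean temperature anomaly (GMTA) covariate series.

Anomalies are in °C relative to the mean temperature of the 1951–1980
reference period.  Two sources are composited: an instrumental series
(1880 onward) and an earlier reconstruction (glacier-length based);
instrumental values take precedence wherever both cover a year.  The series
is annual only — GMTA cannot resolve small spatial or sub-annual scales, so
no interpolation is offered, just exact per-year lookup.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

REFERENCE_WINDOW = (1951, 1980)

SOURCE_INSTRUMENTAL = "instrumental"
SOURCE_RECONSTRUCTED = "reconstructed"
_SOURCES = (SOURCE_INSTRUMENTAL, SOURCE_RECONSTRUCTED)


class GmtaError(ValueError):
    """Raised for malformed or incomplete anomaly series."""


@dataclasses.dataclass
class GmtaSeries:
    """Contiguous year-indexed anomaly series with per-year source tags."""

    years: np.ndarray
    anomalies: np.ndarray
    sources: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.anomalies = np.asarray(self.anomalies, dtype=float)
        self.sources = np.asarray(self.sources, dtype=object)
        if not (len(self.years) == len(self.anomalies) == len(self.sources)):
            raise GmtaError("years, anomalies and sources must have equal length")
        if len(self.years) == 0:
            raise GmtaError("empty anomaly series")
        if len(np.unique(self.years)) != len(self.years):
            dup = int(pd.Series(self.years).loc[pd.Series(self.years).duplicated()].iloc[0])
            raise GmtaError(f"duplicate year {dup} in anomaly series")
        order = np.argsort(self.years)
        self.years = self.years[order]
        self.anomalies = self.anomalies[order]
        self.sources = self.sources[order]
        gaps = np.where(np.diff(self.years) != 1)[0]
        if gaps.size:
            y = int(self.years[gaps[0]])
            raise GmtaError(f"anomaly series has a gap after year {y}")
        bad = set(self.sources) - set(_SOURCES)
        if bad:
            raise GmtaError(f"unknown source tags {sorted(bad)}")

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def covers(self, year: int) -> bool:
        return self.start_year <= int(year) <= self.end_year

    def anomaly_for_year(self, year: int) -> float:
        """Exact stored anomaly for ``year``; no interpolation."""
        year = int(year)
        if not self.covers(year):
            raise GmtaError(
                f"year {year} outside series range {self.start_year}–{self.end_year}"
            )
        return float(self.anomalies[year - self.start_year])

    def source_for_year(self, year: int) -> str:
        year = int(year)
        if not self.covers(year):
            raise GmtaError(
                f"year {year} outside series range {self.start_year}–{self.end_year}"
            )
        return str(self.sources[year - self.start_year])

    def to_frame(self, include_source: bool = True) -> pd.DataFrame:
        frame = pd.DataFrame({"year": self.years, "anomaly_c": self.anomalies})
        if include_source:
            frame["source"] = self.sources
        return frame

    def to_csv(self, path, include_source: bool = True) -> None:
        self.to_frame(include_source=include_source).to_csv(
            path, index=False, float_format="%.10g"
        )


def load_gmta_table(path, source_tag: str) -> GmtaSeries:
    """Load a single-source anomaly CSV (columns year, anomaly_c)."""
    if source_tag not in _SOURCES:
        raise GmtaError(f"source_tag must be one of {_SOURCES}")
    frame = pd.read_csv(path, comment="#")
    if not {"year", "anomaly_c"}.issubset(frame.columns):
        raise GmtaError(f"{path}: GMTA CSV needs columns year, anomaly_c")
    if frame.empty:
        raise GmtaError(f"{path}: empty GMTA file")
    anomalies = pd.to_numeric(frame["anomaly_c"], errors="coerce")
    bad = anomalies.isna() & frame["anomaly_c"].notna() | frame["anomaly_c"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise GmtaError(f"{path}: non-numeric anomaly at line {line}")
    years = pd.to_numeric(frame["year"], errors="coerce")
    if years.isna().any():
        line = int(years.isna().idxmax()) + 2
        raise GmtaError(f"{path}: non-numeric year at line {line}")
    dupes = years[years.duplicated()]
    if not dupes.empty:
        raise GmtaError(f"{path}: duplicate year {int(dupes.iloc[0])}")
    return GmtaSeries(
        years=years.to_numpy(dtype=int),
        anomalies=anomalies.to_numpy(dtype=float),
        sources=np.array([source_tag] * len(frame), dtype=object),
    )


def composite_series(instrumental: GmtaSeries, reconstruction: GmtaSeries) -> GmtaSeries:
    """Composite the two sources over the union of their year ranges, with
    instrumental values overriding reconstructed ones on overlap years."""
    lo = min(instrumental.start_year, reconstruction.start_year)
    hi = max(instrumental.end_year, reconstruction.end_year)
    years, values, sources = [], [], []
    for year in range(lo, hi + 1):
        if instrumental.covers(year):
            values.append(instrumental.anomaly_for_year(year))
            sources.append(SOURCE_INSTRUMENTAL)
        elif reconstruction.covers(year):
            values.append(reconstruction.anomaly_for_year(year))
            sources.append(SOURCE_RECONSTRUCTED)
        else:
            raise GmtaError(f"year {year} covered by neither source")
        years.append(year)
    return GmtaSeries(
        years=np.array(years), anomalies=np.array(values), sources=np.array(sources, dtype=object)
    )
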