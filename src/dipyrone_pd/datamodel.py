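"""Domain types and CSV I/O for single-dose hemorheology time-course datasets.

The study design this package models is a single intramuscular dose of
dipyrone (metamizole) given to a small cohort of piglets at time 0, with
blood parameters sampled over a baseline window [-36, 0] h and a post-dose
window (0, 72] h, alongside plasma concentration profiles of the two active
metabolites 4-methylaminoantipyrine (4MAA) and 4-aminoantipyrine (4AA).

Times are stored in hours as signed decimals relative to the dose (baseline
times are <= 0). The single on-disk format is a long/tidy CSV with the exact
header ``animal_id,time_h,parameter,value,unit``; units are mandatory per row
and validated against the canonical unit table because the measured panel
mixes %, g/dL, fL, pg, seconds and cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PARAMETER_UNITS",
    "ANALYTE_UNITS",
    "POSITIVE_PARAMETERS",
    "COHORT_LABEL",
    "DatasetFormatError",
    "SamplingSchedule",
    "ObservationSeries",
    "MetaboliteProfile",
    "StudyDataset",
    "read_dataset",
    "write_dataset",
]

#: Canonical unit for every parameter in the measured panel.
PARAMETER_UNITS: dict[str, str] = {
    "WBC": "10^9/L",
    "RBC": "10^12/L",
    "Hb": "g/dL",
    "Hct": "%",
    "MCV": "fL",
    "MCH": "pg",
    "MCHC": "g/dL",
    "Plt": "10^9/L",
    "PT": "%",            # prothrombin time index, percent of reference
    "APTT": "s",
    "APTT_ratio": "ratio",
    "fibrinogen": "g/L",
    "CT_ADP": "s",        # PFA closure time, collagen/ADP cartridge
    "CT_EPI": "s",        # PFA closure time, collagen/epinephrine cartridge
}

#: Plasma metabolite analytes carried in the same CSV layout.
ANALYTE_UNITS: dict[str, str] = {"4MAA": "ug/mL", "4AA": "ug/mL"}

#: Parameters that are physically positive (counts / concentrations).
POSITIVE_PARAMETERS = frozenset({"WBC", "RBC", "Hb", "Hct", "Plt", "fibrinogen"})

#: animal_id used for cohort-level (mean) metabolite profiles.
COHORT_LABEL = "cohort"

CSV_COLUMNS = ["animal_id", "time_h", "parameter", "value", "unit"]


class DatasetFormatError(ValueError):
    """Raised when a dataset file or in-memory dataset violates an invariant."""


def _strictly_increasing(times) -> bool:
    return all(b > a for a, b in zip(times, times[1:]))


@dataclass(frozen=True)
class SamplingSchedule:
    """Blood-sampling times (hours relative to the dose at t = 0).

    ``baseline_times`` span the pre-dose window [-36, 0]; ``post_times`` the
    post-dose window up to 72 h.
    """

    baseline_times: tuple[float, ...] = (-36.0, -24.0, -12.0, 0.0)
    post_times: tuple[float, ...] = (
        0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0, 48.0, 72.0,
    )

    def __post_init__(self) -> None:
        bt, pt = self.baseline_times, self.post_times
        if not bt or not pt:
            raise DatasetFormatError("schedule needs baseline and post-dose times")
        if not _strictly_increasing(bt) or not _strictly_increasing(pt):
            raise DatasetFormatError("schedule times must be strictly increasing")
        if bt[0] != -36.0 or bt[-1] != 0.0:
            raise DatasetFormatError(
                f"baseline window must span [-36, 0] h, got [{bt[0]}, {bt[-1]}]"
            )
        if any(t <= 0 for t in pt) or pt[-1] != 72.0:
            raise DatasetFormatError(
                "post-dose times must be > 0 and extend to exactly 72 h"
            )

    @property
    def all_times(self) -> tuple[float, ...]:
        return self.baseline_times + self.post_times


@dataclass(frozen=True)
class ObservationSeries:
    """One animal x one blood parameter x its full sampled time course."""

    animal_id: str
    parameter: str
    samples: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETER_UNITS:
            raise DatasetFormatError(f"unknown parameter {self.parameter!r}")
        times = [t for t, _ in self.samples]
        if not _strictly_increasing(times):
            raise DatasetFormatError(
                f"{self.animal_id}/{self.parameter}: times must strictly increase"
            )
        for t, v in self.samples:
            if not math.isfinite(v):
                raise DatasetFormatError(
                    f"{self.animal_id}/{self.parameter}: non-finite value at t={t}"
                )
            if self.parameter in POSITIVE_PARAMETERS and v <= 0:
                raise DatasetFormatError(
                    f"{self.animal_id}/{self.parameter}: value must be > 0 at t={t}"
                )

    @property
    def unit(self) -> str:
        return PARAMETER_UNITS[self.parameter]

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.samples)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.samples)


@dataclass(frozen=True)
class MetaboliteProfile:
    """Plasma concentration time course of one analyte (4MAA or 4AA).

    The dose is given at t = 0, so the concentration is 0 at every t <= 0.
    """

    analyte: str
    samples: tuple[tuple[float, float], ...]
    animal_id: str = COHORT_LABEL

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTE_UNITS:
            raise DatasetFormatError(f"unknown analyte {self.analyte!r}")
        times = [t for t, _ in self.samples]
        if not _strictly_increasing(times):
            raise DatasetFormatError(f"{self.analyte}: times must strictly increase")
        for t, c in self.samples:
            if not math.isfinite(c) or c < 0:
                raise DatasetFormatError(f"{self.analyte}: concentration < 0 at t={t}")
            if t <= 0 and c != 0:
                raise DatasetFormatError(
                    f"{self.analyte}: pre-dose concentration must be 0 (t={t})"
                )

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.samples)

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(c for _, c in self.samples)


@dataclass
class StudyDataset:
    """A complete study: schedule, all observation series, metabolite profiles."""

    schedule: SamplingSchedule
    series: list[ObservationSeries] = field(default_factory=list)
    metabolites: list[MetaboliteProfile] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        sched = set(self.schedule.all_times)
        for s in self.series:
            key = (s.animal_id, s.parameter)
            if key in seen:
                raise DatasetFormatError(f"duplicate series for {key}")
            seen.add(key)
            extra = set(s.times) - sched
            if extra:
                raise DatasetFormatError(
                    f"{key}: times {sorted(extra)} not in the sampling schedule"
                )

    # -- lookups -----------------------------------------------------------
    @property
    def animals(self) -> list[str]:
        return sorted({s.animal_id for s in self.series})

    @property
    def parameters(self) -> list[str]:
        return sorted({s.parameter for s in self.series})

    def get_series(self, animal_id: str, parameter: str) -> ObservationSeries:
        for s in self.series:
            if s.animal_id == animal_id and s.parameter == parameter:
                return s
        raise KeyError(f"no series for ({animal_id!r}, {parameter!r})")

    def get_metabolite(self, analyte: str, animal_id: str = COHORT_LABEL) -> MetaboliteProfile:
        for m in self.metabolites:
            if m.analyte == analyte and m.animal_id == animal_id:
                return m
        raise KeyError(f"no metabolite profile for ({animal_id!r}, {analyte!r})")

    # -- tabular views ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long/tidy frame, deterministically ordered (animal, parameter, time)."""
        rows = []
        for s in sorted(self.series, key=lambda s: (s.animal_id, s.parameter)):
            for t, v in s.samples:
                rows.append((s.animal_id, t, s.parameter, v, s.unit))
        for m in sorted(self.metabolites, key=lambda m: (m.animal_id, m.analyte)):
            for t, c in m.samples:
                rows.append((m.animal_id, t, m.analyte, c, ANALYTE_UNITS[m.analyte]))
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _infer_schedule(times: set[float]) -> SamplingSchedule:
    baseline = tuple(sorted(t for t in times if t <= 0))
    post = tuple(sorted(t for t in times if t > 0))
    return SamplingSchedule(baseline_times=baseline, post_times=post)


def read_dataset(path, schedule: SamplingSchedule | None = None) -> StudyDataset:
    """Read a study dataset from the long CSV layout.

    Validation is total: any offending row aborts the read with its 1-based
    file line number; no partial dataset is ever returned. The sampling
    schedule is inferred from the observation times unless given explicitly.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "parameter": str, "unit": str})
    if list(df.columns) != CSV_COLUMNS:
        raise DatasetFormatError(
            f"{path}: expected header {','.join(CSV_COLUMNS)}, got {','.join(df.columns)}"
        )

    obs_rows: dict[tuple[str, str], list[tuple[float, float]]] = {}
    met_rows: dict[tuple[str, str], list[tuple[float, float]]] = {}
    seen_rows: set[tuple[str, str, float]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        name = row.parameter
        try:
            t = float(row.time_h)
            v = float(row.value)
        except (TypeError, ValueError):
            raise DatasetFormatError(f"{path}:{line}: non-numeric time or value") from None
        if not (math.isfinite(t) and math.isfinite(v)):
            raise DatasetFormatError(f"{path}:{line}: non-finite time or value")
        if name in PARAMETER_UNITS:
            expected = PARAMETER_UNITS[name]
            target = obs_rows
        elif name in ANALYTE_UNITS:
            expected = ANALYTE_UNITS[name]
            target = met_rows
        else:
            raise DatasetFormatError(f"{path}:{line}: unknown parameter {name!r}")
        if row.unit != expected:
            raise DatasetFormatError(
                f"{path}:{line}: unit {row.unit!r} for {name}; expected {expected!r}"
            )
        key3 = (row.animal_id, name, t)
        if key3 in seen_rows:
            raise DatasetFormatError(f"{path}:{line}: duplicate row for {key3}")
        seen_rows.add(key3)
        target.setdefault((row.animal_id, name), []).append((t, v))

    hem_times = {t for rows in obs_rows.values() for t, _ in rows}
    if schedule is None:
        if not hem_times:
            raise DatasetFormatError(f"{path}: no observation rows to infer a schedule from")
        schedule = _infer_schedule(hem_times)

    try:
        series = [
            ObservationSeries(a, p, tuple(sorted(rows)))
            for (a, p), rows in obs_rows.items()
        ]
        mets = [
            MetaboliteProfile(analyte, tuple(sorted(rows)), animal_id=a)
            for (a, analyte), rows in met_rows.items()
        ]
        return StudyDataset(schedule=schedule, series=series, metabolites=mets,
                            provenance=f"file:{path}")
    except DatasetFormatError as exc:
        raise DatasetFormatError(f"{path}: {exc}") from None


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write the exact long CSV layout, one row per observation.

    Row order is deterministic (animal, parameter, time) and floats use a
    12-significant-digit format, so write -> read -> write is byte-identical.
    """
    df = dataset.to_frame()
    with open(path, "w", newline="") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for animal, t, name, v, unit in df.itertuples(index=False):
            fh.write(f"{animal},{t:.12g},{name},{v:.12g},{unit}\n")
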