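"""Survival-cohort domain types and CSV input/output.

A cohort is a per-patient table of right-censored follow-up for grade >=2
late breast fibrosis after adjuvant radiotherapy: follow-up time in months
since the start of radiotherapy, an event indicator, the baseline RILA
assay value (radiation-induced CD8 T-lymphocyte apoptosis, in %), and two
optional binary covariates (tobacco smoking status and adjuvant
hormonotherapy).

Markers are carried in a :class:`MarkerSeries` that records whether the raw
values were negated.  RILA is protective (low values mean higher risk of
late fibrosis), so analyses run on ``-RILA``; the orientation flag lets
thresholds be reported back on the original percentage scale.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: canonical CSV header written by :func:`write_cohort`
CSV_COLUMNS = ("id", "time_months", "event", "rila", "tobacco", "ht")


class CohortError(ValueError):
    """Raised for invalid cohort data (row-level validation failures)."""


@dataclass(frozen=True)
class Patient:
    """One subject of the cohort.

    Parameters
    ----------
    id : str
        Unique identifier.
    time : float
        Months from the start of radiotherapy until the event or censoring.
        Must be positive.
    event : int
        1 if grade >=2 late fibrosis was observed at ``time``; 0 if the
        subject was right-censored at ``time``.
    rila : float
        Baseline RILA (% apoptosis), in [0, 100].
    tobacco : int or None
        1 for active/former smoker, 0 for never; ``None`` if missing.
    ht : int or None
        1 if adjuvant hormonotherapy was given; ``None`` if missing.
    """

    id: str
    time: float
    event: int
    rila: float
    tobacco: Optional[int] = None
    ht: Optional[int] = None

    def __post_init__(self) -> None:
        if not (isinstance(self.time, (int, float)) and math.isfinite(self.time)):
            raise CohortError(f"patient {self.id!r}: time must be a finite number")
        if self.time <= 0:
            raise CohortError(f"patient {self.id!r}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise CohortError(f"patient {self.id!r}: event must be 0 or 1, got {self.event}")
        if not (0.0 <= self.rila <= 100.0):
            raise CohortError(f"patient {self.id!r}: rila must lie in [0, 100], got {self.rila}")
        for name in ("tobacco", "ht"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise CohortError(f"patient {self.id!r}: {name} must be 0, 1 or missing, got {v}")


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of :class:`Patient` with unique ids."""

    patients: tuple[Patient, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        if len(self.patients) < 2:
            raise CohortError(f"cohort needs at least 2 patients, got {len(self.patients)}")
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient ids: {dup}")

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time for p in self.patients], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([p.event for p in self.patients], dtype=int)

    @property
    def rila(self) -> np.ndarray:
        return np.array([p.rila for p in self.patients], dtype=float)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def covariate(self, name: str) -> np.ndarray:
        """Covariate column as float array with NaN for missing."""
        vals = [getattr(p, name) for p in self.patients]
        return np.array([np.nan if v is None else float(v) for v in vals])

    def complete_cases(self, fields: Sequence[str] = ("tobacco", "ht")) -> "Cohort":
        """Sub-cohort of patients with none of `fields` missing.

        Exclusions are logged with a count, mirroring the complete-case
        convention for composite-marker analyses.
        """
        keep = [p for p in self.patients if all(getattr(p, f) is not None for f in fields)]
        n_dropped = self.n - len(keep)
        if n_dropped:
            logger.info(
                "complete-case filter on %s excluded %d of %d patients",
                list(fields), n_dropped, self.n,
            )
        return Cohort(tuple(keep))

    def subset(self, indices: Iterable[int]) -> "Cohort":
        return Cohort(tuple(self.patients[i] for i in indices))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Cohort) and self.patients == other.patients


@dataclass(frozen=True)
class MarkerSeries:
    """Per-patient scalar marker values aligned with a cohort.

    ``orientation`` is ``"raw"`` for values on their native scale and
    ``"negated"`` when the raw values were multiplied by -1 so that larger
    marker values mean higher risk.  :meth:`to_original_scale` undoes the
    negation when reporting thresholds.
    """

    values: np.ndarray
    orientation: str = "raw"
    label: str = "marker"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.orientation not in ("raw", "negated"):
            raise ValueError(f"orientation must be 'raw' or 'negated', got {self.orientation!r}")
        if vals.ndim != 1:
            raise ValueError("marker values must be one-dimensional")
        if np.isnan(vals).any():
            raise ValueError(
                f"marker {self.label!r} contains missing values; exclude incomplete "
                "patients upstream (complete_cases) before building the series"
            )

    def __len__(self) -> int:
        return len(self.values)

    def to_original_scale(self, threshold: float) -> float:
        """Map a threshold on the analysis scale back to the raw scale."""
        return -threshold if self.orientation == "negated" else threshold

    def subset(self, indices: Iterable[int]) -> "MarkerSeries":
        idx = list(indices)
        return replace(self, values=self.values[idx])


def negate_marker(values: Sequence[float] | np.ndarray, label: str = "rila") -> MarkerSeries:
    """Negate raw marker values so low raw values rank as high risk.

    Applying it to an already-negated :class:`MarkerSeries` restores the raw
    orientation (the operation is an involution).
    """
    if isinstance(values, MarkerSeries):
        flipped = "raw" if values.orientation == "negated" else "negated"
        return MarkerSeries(-values.values, orientation=flipped, label=values.label)
    return MarkerSeries(-np.asarray(values, dtype=float), orientation="negated", label=label)


def _parse_field(raw: str, caster, row_num: int, col: str):
    try:
        return caster(raw)
    except (TypeError, ValueError) as exc:
        raise CohortError(f"row {row_num}: column {col!r}: cannot parse {raw!r}") from exc


def _parse_optional_binary(raw: str, row_num: int, col: str) -> Optional[int]:
    if raw is None or raw.strip() == "":
        return None
    value = _parse_field(raw, float, row_num, col)
    if value not in (0.0, 1.0):
        raise CohortError(f"row {row_num}: column {col!r}: must be 0, 1 or empty, got {raw!r}")
    return int(value)


def load_cohort(path, column_map: Optional[dict] = None) -> Cohort:
    """Read a cohort CSV (UTF-8, comma-separated, header row).

    Parameters
    ----------
    path : path-like
        CSV file with at least the mapped columns.
    column_map : dict, optional
        Maps canonical names (``id``, ``time_months``, ``event``, ``rila``,
        ``tobacco``, ``ht``) to the file's column names.  Defaults to the
        identity mapping.

    Raises
    ------
    CohortError
        On missing columns or any invalid row; messages carry the
        1-based data row number.
    """
    cmap = {c: c for c in CSV_COLUMNS}
    if column_map:
        cmap.update(column_map)
    patients = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [cmap[c] for c in CSV_COLUMNS if cmap[c] not in header]
        if missing:
            raise CohortError(f"missing column(s) {missing} in {path}")
        for row_num, row in enumerate(reader, start=1):
            pid = row[cmap["id"]]
            time = _parse_field(row[cmap["time_months"]], float, row_num, "time_months")
            event_f = _parse_field(row[cmap["event"]], float, row_num, "event")
            if event_f not in (0.0, 1.0):
                raise CohortError(f"row {row_num}: column 'event': must be 0 or 1, got {event_f}")
            rila = _parse_field(row[cmap["rila"]], float, row_num, "rila")
            tobacco = _parse_optional_binary(row[cmap["tobacco"]], row_num, "tobacco")
            ht = _parse_optional_binary(row[cmap["ht"]], row_num, "ht")
            try:
                patients.append(
                    Patient(id=pid, time=time, event=int(event_f), rila=rila,
                            tobacco=tobacco, ht=ht)
                )
            except CohortError as exc:
                raise CohortError(f"row {row_num}: {exc}") from exc
    return Cohort(tuple(patients))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV with the canonical header; missing values are
    written as empty fields.  ``load_cohort(write_cohort(c)) == c``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for p in cohort.patients:
            writer.writerow([
                p.id,
                repr(p.time),
                p.event,
                repr(p.rila),
                "" if p.tobacco is None else p.tobacco,
                "" if p.ht is None else p.ht,
            ])
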