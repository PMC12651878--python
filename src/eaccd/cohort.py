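"""Cohort construction: patient records, factor-level combinations, inclusion filters.

Patients in a registry extract are described by a survival outcome (follow-up
time in months plus a vital-status indicator) and a handful of categorical
prognostic factors — for TNM staging these are tumor extent (T), nodal
involvement (N) and distant metastasis (M), optionally extended with a
dichotomized age (A).  Every patient is mapped to one *combination* of factor
levels (e.g. ``T2N0M0``); combinations, not individual patients, are the
objects the clustering stages operate on.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PatientRecord",
    "FactorScheme",
    "Observations",
    "CombinationCohort",
    "ReadAudit",
    "ExclusionReport",
    "TNM_SCHEME",
    "TNMA_SCHEME",
    "read_cohort",
    "dichotomize_age",
    "enumerate_combinations",
    "build_combinations",
    "filter_small_combinations",
]


@dataclass(frozen=True)
class PatientRecord:
    """One patient: follow-up time (months), event indicator, factor levels.

    ``event`` is 1 when death was observed and 0 when follow-up was censored.
    ``age`` (years) is carried separately so it can be dichotomized into the
    A factor on demand.
    """

    time: float
    event: int
    factors: Mapping[str, str]
    age: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"survival time must be nonnegative, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


class FactorScheme:
    """Ordered factors with ordered level labels, e.g. T:[T1..T4], N:[N0,N1].

    The order of factors fixes the combination-label convention (levels are
    concatenated in scheme order: ``T2N0M0``), and the order of levels fixes
    the enumeration order of combinations.
    """

    def __init__(self, factors: Sequence[tuple[str, Sequence[str]]]):
        if not factors:
            raise ValueError("a factor scheme needs at least one factor")
        self._factors: list[tuple[str, tuple[str, ...]]] = []
        for name, levels in factors:
            levels = tuple(levels)
            if len(set(levels)) != len(levels):
                raise ValueError(f"duplicate level labels in factor {name!r}")
            if not levels:
                raise ValueError(f"factor {name!r} has no levels")
            self._factors.append((name, levels))

    @property
    def factor_names(self) -> list[str]:
        return [name for name, _ in self._factors]

    def levels(self, name: str) -> tuple[str, ...]:
        for fname, levels in self._factors:
            if fname == name:
                return levels
        raise KeyError(name)

    def __iter__(self):
        return iter(self._factors)

    def __len__(self) -> int:
        return len(self._factors)

    def __eq__(self, other) -> bool:
        return isinstance(other, FactorScheme) and self._factors == other._factors

    def label(self, levels: Mapping[str, str]) -> str:
        """Combination label for a full set of factor levels, in scheme order."""
        parts = []
        for name, allowed in self._factors:
            try:
                level = levels[name]
            except KeyError:
                raise ValueError(f"missing level for factor {name!r}") from None
            if level not in allowed:
                raise ValueError(
                    f"level {level!r} is not a valid level of factor {name!r} "
                    f"(allowed: {list(allowed)})"
                )
            parts.append(level)
        return "".join(parts)

    def subset(self, names: Sequence[str]) -> "FactorScheme":
        return FactorScheme([(n, self.levels(n)) for n in names])


#: AJCC-style T/N/M levels for pancreatic neuroendocrine tumors.
TNM_SCHEME = FactorScheme(
    [
        ("T", ["T1", "T2", "T3", "T4"]),
        ("N", ["N0", "N1"]),
        ("M", ["M0", "M1"]),
    ]
)

#: T/N/M extended with dichotomized age (A1: <50 years, A2: >=50 years).
TNMA_SCHEME = FactorScheme(
    [
        ("T", ["T1", "T2", "T3", "T4"]),
        ("N", ["N0", "N1"]),
        ("M", ["M0", "M1"]),
        ("A", ["A1", "A2"]),
    ]
)


@dataclass(frozen=True)
class Observations:
    """Right-censored survival sample as aligned arrays (times in months)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be aligned 1-d arrays")
        if (time < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return self.time.size

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord]) -> "Observations":
        recs = list(records)
        return cls(
            np.array([r.time for r in recs], dtype=float),
            np.array([r.event for r in recs], dtype=int),
        )

    def concat(self, other: "Observations") -> "Observations":
        return Observations(
            np.concatenate([self.time, other.time]),
            np.concatenate([self.event, other.event]),
        )


@dataclass
class CombinationCohort:
    """Map from combination label to its survival observations."""

    scheme: FactorScheme
    groups: dict[str, Observations]

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @property
    def counts(self) -> dict[str, int]:
        return {label: len(obs) for label, obs in self.groups.items()}

    @property
    def n_patients(self) -> int:
        return sum(len(obs) for obs in self.groups.values())

    def pooled(self, labels: Sequence[str] | None = None) -> Observations:
        """Pool observations across the given combinations (all by default)."""
        labels = list(self.groups) if labels is None else list(labels)
        times = np.concatenate([self.groups[l].time for l in labels])
        events = np.concatenate([self.groups[l].event for l in labels])
        return Observations(times, events)


@dataclass
class ReadAudit:
    """Accounting for a cohort read: rows in = rows kept + rows dropped."""

    n_rows: int = 0
    n_records: int = 0
    n_dropped_missing: int = 0
    n_dropped_invalid: int = 0
    row_errors: list[str] = field(default_factory=list)

    def conserved(self) -> bool:
        return self.n_rows == self.n_records + self.n_dropped_missing + self.n_dropped_invalid


def _load_column_map(column_map: Mapping[str, str] | str | Path) -> dict[str, str]:
    if isinstance(column_map, (str, Path)):
        text = Path(column_map).read_text()
        if str(column_map).endswith(".json"):
            return dict(json.loads(text))
        return dict(yaml.safe_load(text))
    return dict(column_map)


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path,
) -> tuple[list[PatientRecord], ReadAudit]:
    """Read patient records from a delimited text file.

    Parameters
    ----------
    path
        CSV or TSV file with a header row (delimiter chosen by extension:
        ``.tsv``/``.txt`` tab, otherwise comma).
    column_map
        Mapping from the keys ``time``, ``event``, optional ``age`` and any
        factor names (``T``, ``N``, ``M``, ...) to column names in the file;
        may also be a path to a YAML/JSON file holding that mapping.

    Returns
    -------
    (records, audit)
        Records for rows with complete mapped values; the audit counts the
        rows dropped for missing values and collects row-level parse errors
        (never silently skipped).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = _load_column_map(column_map)
    for required in ("time", "event"):
        if required not in cmap:
            raise ValueError(f"column map must define the {required!r} column")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [c for c in cmap.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"mapped columns not present in {path.name}: {missing_cols}")

    factor_keys = [k for k in cmap if k not in ("time", "event", "age")]
    audit = ReadAudit(n_rows=len(df))
    records: list[PatientRecord] = []
    for idx, row in df.iterrows():
        values = {key: row[col] for key, col in cmap.items()}
        if any(pd.isna(v) or str(v).strip() == "" for v in values.values()):
            audit.n_dropped_missing += 1
            continue
        try:
            time = float(values["time"])
            event = int(float(values["event"]))
            age = float(values["age"]) if "age" in values else None
            record = PatientRecord(
                time=time,
                event=event,
                factors={k: str(values[k]).strip() for k in factor_keys},
                age=age,
            )
        except (ValueError, TypeError) as exc:
            audit.n_dropped_invalid += 1
            audit.row_errors.append(f"row {idx}: {exc}")
            continue
        records.append(record)
    audit.n_records = len(records)
    return records, audit


def dichotomize_age(age_years: float) -> str:
    """Dichotomize age at diagnosis: A1 for <50 years, A2 for >=50 years."""
    if age_years < 0:
        raise ValueError(f"age must be nonnegative, got {age_years}")
    return "A1" if age_years < 50 else "A2"


def enumerate_combinations(scheme: FactorScheme) -> list[str]:
    """All combination labels of a scheme, in lexicographic scheme order.

    The count is the product of the factors' level counts (16 for T/N/M,
    32 for T/N/M/A).
    """
    level_lists = [levels for _, levels in scheme]
    return ["".join(combo) for combo in itertools.product(*level_lists)]


def build_combinations(
    records: Sequence[PatientRecord],
    scheme: FactorScheme,
    *,
    dichotomize_age_factor: str = "A",
) -> CombinationCohort:
    """Group records into factor-level combinations.

    If the scheme includes the age factor (``A`` by default) and a record
    carries ``age`` but no explicit A level, the level is derived by
    dichotomizing at 50 years.  A record with a level outside the scheme is an
    error naming the record and the offending level; empty combinations are
    simply absent from the result (``enumerate_combinations`` gives the full
    universe if needed).
    """
    buckets: dict[str, list[PatientRecord]] = {}
    for i, record in enumerate(records):
        levels = dict(record.factors)
        if (
            dichotomize_age_factor in scheme.factor_names
            and dichotomize_age_factor not in levels
            and record.age is not None
        ):
            levels[dichotomize_age_factor] = dichotomize_age(record.age)
        try:
            label = scheme.label(levels)
        except ValueError as exc:
            raise ValueError(f"record {i}: {exc}") from None
        buckets.setdefault(label, []).append(record)
    # keep deterministic enumeration order for the labels that occur
    ordered = {
        label: Observations.from_records(buckets[label])
        for label in enumerate_combinations(scheme)
        if label in buckets
    }
    return CombinationCohort(scheme=scheme, groups=ordered)


@dataclass
class ExclusionReport:
    """Combinations removed by the minimum-size filter."""

    min_n: int
    excluded: dict[str, int]

    @property
    def n_excluded_combinations(self) -> int:
        return len(self.excluded)

    @property
    def n_excluded_patients(self) -> int:
        return sum(self.excluded.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"combination": list(self.excluded), "n_patients": list(self.excluded.values())}
        )


def filter_small_combinations(
    cohort: CombinationCohort, min_n: int = 15
) -> tuple[CombinationCohort, ExclusionReport]:
    """Drop combinations with fewer than ``min_n`` patients.

    Small cells give unstable survival-difference estimates; registry analyses
    conventionally require a minimum cell size (15 by default here) before a
    combination enters the clustering.  The report lists what was removed so
    patient counts stay fully accounted for.
    """
    if min_n < 1:
        raise ValueError("min_n must be a positive integer")
    kept = {l: obs for l, obs in cohort.groups.items() if len(obs) >= min_n}
    excluded = {l: len(obs) for l, obs in cohort.groups.items() if len(obs) < min_n}
    report = ExclusionReport(min_n=min_n, excluded=excluded)
    return CombinationCohort(scheme=cohort.scheme, groups=kept), report
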