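"""Conception-cycle records: validation, I/O and tabulation.

A conception cycle carries the sex of the resulting baby (0 = male,
1 = female), intercourse indicators for each of the 12 days of the
mucus-peak-anchored fertile window (relative days -8 .. +3, day 0 being the
mucus peak used as the ovulation proxy), and the follicular-phase length in
days — the number of days from the first day of menstruation to the mucus
reference day — categorised into four ordinal classes
(<=13, 14-16, 17-19, >19 days).

External files use signed relative days; internally days are indexed
k = 1..12 with k = day + 9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sexratio")

__all__ = [
    "ValidationError",
    "ConceptionCycle",
    "CycleDataset",
    "N_DAYS",
    "RELATIVE_DAYS",
    "DAY_COLUMNS",
    "FOLLICULAR_CLASS_LABELS",
    "categorize_follicular_length",
    "relative_day_to_index",
    "index_to_relative_day",
    "parse_sex",
    "read_cycles",
    "read_cycles_with_report",
    "write_cycles",
    "tabulate_intercourse",
    "tabulate_follicular",
]


class ValidationError(ValueError):
    """A record violates the cycle-data contract."""


N_DAYS = 12
RELATIVE_DAYS = tuple(range(-8, 4))  # -8 .. +3 inclusive

#: Canonical CSV column names for the 12 intercourse indicators.
DAY_COLUMNS = tuple(
    f"ic_m{-d}" if d < 0 else ("ic_0" if d == 0 else f"ic_p{d}")
    for d in RELATIVE_DAYS
)

CSV_COLUMNS = ("woman_id", "cycle_id", "sex", "foll_len") + DAY_COLUMNS + ("study",)

FOLLICULAR_CLASS_LABELS = ("<=13", "14-16", "17-19", ">19")

#: Representative in-bin lengths used when only the class is known.
REPRESENTATIVE_LENGTHS = (12, 15, 18, 22)


def categorize_follicular_length(w) -> int:
    """Map a follicular-phase length in days to its ordinal class 1..4.

    Bins are <=13, 14-16, 17-19, >19 days.
    """
    if isinstance(w, bool) or not (
        isinstance(w, (int, np.integer)) or (isinstance(w, float) and float(w).is_integer())
    ):
        raise ValidationError(f"follicular length must be a positive integer, got {w!r}")
    w = int(w)
    if w < 1:
        raise ValidationError(f"follicular length must be >= 1, got {w}")
    if w <= 13:
        return 1
    if w <= 16:
        return 2
    if w <= 19:
        return 3
    return 4


def relative_day_to_index(day: int) -> int:
    """Signed relative day (-8..3) -> 1-based window index k (1..12)."""
    if not isinstance(day, (int, np.integer)) or isinstance(day, bool):
        raise ValidationError(f"relative day must be an integer, got {day!r}")
    day = int(day)
    if day < -8 or day > 3:
        raise ValidationError(f"relative day {day} outside fertile window -8..3")
    return day + 9


def index_to_relative_day(k: int) -> int:
    """Inverse of :func:`relative_day_to_index`."""
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ValidationError(f"window index must be an integer, got {k!r}")
    k = int(k)
    if k < 1 or k > 12:
        raise ValidationError(f"window index {k} outside 1..12")
    return k - 9


def parse_sex(value) -> int:
    """Normalise a sex code to 0 (male) / 1 (female); accepts 0/1 and M/F."""
    if isinstance(value, (int, np.integer)) and not isinstance(value, bool):
        if int(value) in (0, 1):
            return int(value)
        raise ValidationError(f"sex code must be 0 or 1, got {value!r}")
    s = str(value).strip().lower()
    if s in ("0", "m", "male"):
        return 0
    if s in ("1", "f", "female"):
        return 1
    raise ValidationError(f"unparseable sex code {value!r}")


@dataclass(frozen=True)
class ConceptionCycle:
    """One conception cycle.

    ``follicular_class`` is derived from ``follicular_length`` when not given;
    when both are present they must be consistent under the class bins.
    """

    woman_id: str
    cycle_id: str
    sex: int
    intercourse: tuple
    follicular_length: int | None = None
    follicular_class: int | None = None
    study_label: str | None = None

    def __post_init__(self):
        if self.sex not in (0, 1):
            raise ValidationError(
                f"cycle {self.cycle_id}: sex must be 0 (male) or 1 (female), got {self.sex!r}"
            )
        ic = tuple(int(v) for v in self.intercourse)
        if len(ic) != N_DAYS:
            raise ValidationError(
                f"cycle {self.cycle_id}: expected {N_DAYS} intercourse indicators, got {len(ic)}"
            )
        if any(v not in (0, 1) for v in ic):
            raise ValidationError(
                f"cycle {self.cycle_id}: intercourse indicators must be 0/1"
            )
        if sum(ic) == 0:
            raise ValidationError(
                f"cycle {self.cycle_id}: no intercourse in the fertile window"
            )
        object.__setattr__(self, "intercourse", ic)
        if self.follicular_length is not None:
            derived = categorize_follicular_length(self.follicular_length)
            object.__setattr__(self, "follicular_length", int(self.follicular_length))
            if self.follicular_class is None:
                object.__setattr__(self, "follicular_class", derived)
            elif int(self.follicular_class) != derived:
                raise ValidationError(
                    f"cycle {self.cycle_id}: follicular_class {self.follicular_class} "
                    f"inconsistent with length {self.follicular_length} (expected {derived})"
                )
        if self.follicular_class is not None:
            fc = int(self.follicular_class)
            if fc not in (1, 2, 3, 4):
                raise ValidationError(
                    f"cycle {self.cycle_id}: follicular_class must be in 1..4, got {fc}"
                )
            object.__setattr__(self, "follicular_class", fc)


@dataclass(frozen=True)
class CycleDataset:
    """Ordered, validated collection of conception cycles."""

    cycles: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "cycles", tuple(self.cycles))

    @property
    def n(self) -> int:
        return len(self.cycles)

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    # -- array views ---------------------------------------------------

    def design_matrix(self) -> np.ndarray:
        """n x 12 intercourse indicator matrix (columns = days -8..+3)."""
        return np.array([c.intercourse for c in self.cycles], dtype=np.int8).reshape(
            len(self.cycles), N_DAYS
        )

    def sexes(self) -> np.ndarray:
        return np.array([c.sex for c in self.cycles], dtype=np.int8)

    def follicular_class_array(self) -> np.ndarray:
        """Classes as floats, NaN where missing."""
        return np.array(
            [np.nan if c.follicular_class is None else c.follicular_class for c in self.cycles],
            dtype=float,
        )

    def to_arrays(self, covariate: bool = True):
        """(X, y, z, n_dropped) ready for fitting.

        With ``covariate`` on, cycles lacking a follicular class are excluded
        (count returned and logged); with it off, z is all ones.
        """
        if not covariate:
            X = self.design_matrix()
            return X, self.sexes(), np.ones(len(self.cycles), dtype=np.int64), 0
        keep = [c for c in self.cycles if c.follicular_class is not None]
        dropped = len(self.cycles) - len(keep)
        if dropped:
            logger.info(
                "excluding %d cycle(s) without follicular class from covariate fit", dropped
            )
        if not keep:
            raise ValidationError("no cycles with follicular class available for covariate fit")
        sub = CycleDataset(keep)
        z = np.array([c.follicular_class for c in keep], dtype=np.int64)
        return sub.design_matrix(), sub.sexes(), z, dropped

    def filter_study(self, exclude: str) -> "CycleDataset":
        """Drop cycles whose study label equals ``exclude`` (sensitivity refits)."""
        kept = tuple(c for c in self.cycles if c.study_label != exclude)
        logger.info(
            "study filter: excluded %d cycle(s) labelled %r, %d remain",
            len(self.cycles) - len(kept), exclude, len(kept),
        )
        if not kept:
            raise ValidationError(f"excluding study {exclude!r} leaves no cycles")
        return CycleDataset(kept)


# -- file I/O ----------------------------------------------------------


def _cycle_from_row(row: dict) -> ConceptionCycle:
    foll = row.get("foll_len", "")
    foll_len = None
    if foll is not None and str(foll).strip() != "":
        try:
            foll_len = int(str(foll).strip())
        except ValueError:
            raise ValidationError(f"unparseable follicular length {foll!r}")
    ic = []
    for col in DAY_COLUMNS:
        v = str(row[col]).strip()
        if v not in ("0", "1"):
            raise ValidationError(f"intercourse indicator {col}={row[col]!r} not in {{0,1}}")
        ic.append(int(v))
    study = row.get("study", "")
    study = None if study is None or str(study).strip() == "" else str(study).strip()
    return ConceptionCycle(
        woman_id=str(row["woman_id"]),
        cycle_id=str(row["cycle_id"]),
        sex=parse_sex(row["sex"]),
        intercourse=tuple(ic),
        follicular_length=foll_len,
        study_label=study,
    )


def read_cycles_with_report(path):
    """Read the canonical cycle CSV; returns ``(dataset, rejected)``.

    ``rejected`` is a list of ``(row_number, message)`` for rows failing
    validation; valid rows are kept in file order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "study"]
    if missing:
        raise ValidationError(f"missing mandatory columns: {', '.join(missing)}")
    cycles, rejected = [], []
    for i, row in enumerate(df.to_dict("records")):
        try:
            cycles.append(_cycle_from_row(row))
        except ValidationError as exc:
            rejected.append((i + 2, str(exc)))  # +2: header line + 1-based
    for line_no, msg in rejected:
        logger.warning("%s line %d rejected: %s", path, line_no, msg)
    if not cycles:
        raise ValidationError(f"{path}: no valid cycles ({len(rejected)} row(s) rejected)")
    return CycleDataset(cycles), rejected


def read_cycles(path) -> CycleDataset:
    """Read and validate the canonical cycle CSV (invalid rows logged+dropped)."""
    dataset, _ = read_cycles_with_report(path)
    return dataset


def write_cycles(data: CycleDataset, path) -> None:
    """Write a dataset in the canonical CSV dialect (lossless round-trip)."""
    rows = []
    for c in data:
        row = {
            "woman_id": c.woman_id,
            "cycle_id": c.cycle_id,
            "sex": c.sex,
            "foll_len": "" if c.follicular_length is None else c.follicular_length,
        }
        row.update(dict(zip(DAY_COLUMNS, c.intercourse)))
        row["study"] = "" if c.study_label is None else c.study_label
        rows.append(row)
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


# -- tabulations -------------------------------------------------------


def tabulate_intercourse(data: CycleDataset) -> pd.DataFrame:
    """Per-day intercourse counts and relative frequency (% of n, 2 d.p.).

    Counts may sum to more than n: a cycle can have intercourse on several
    days of the window.
    """
    if data.n == 0:
        raise ValidationError("cannot tabulate an empty dataset")
    counts = data.design_matrix().sum(axis=0).astype(int)
    pct = np.round(100.0 * counts / data.n, 2)
    return pd.DataFrame(
        {"day": list(RELATIVE_DAYS), "count": counts, "percent": pct}
    )


def tabulate_follicular(data: CycleDataset) -> pd.DataFrame:
    """Follicular-class counts (partitioning n) and relative frequency (%)."""
    if data.n == 0:
        raise ValidationError("cannot tabulate an empty dataset")
    missing = [c.cycle_id for c in data if c.follicular_class is None]
    if missing:
        raise ValidationError(
            "cycles without follicular class: " + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    z = np.array([c.follicular_class for c in data])
    counts = np.array([(z == k).sum() for k in (1, 2, 3, 4)], dtype=int)
    pct = np.round(100.0 * counts / data.n, 2)
    return pd.DataFrame(
        {"follicular_length": list(FOLLICULAR_CLASS_LABELS), "count": counts, "percent": pct}
    )
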