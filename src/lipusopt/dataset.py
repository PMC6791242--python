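"""Domain types and I/O for LIPUS stimulation-response data.

A stimulation condition is a point (voltage [V], frequency [MHz],
duration [min]) in the treatment parameter box; the unstimulated control
is encoded with frequency 0 MHz. Viability is the CCK-8 absorbance of a
treated group expressed as a percentage of the control group's
absorbance, so the control group sits at exactly 100%.

Two CSV dialects are supported:

* ``replicate``: one row per measurement,
  ``voltage_v,frequency_mhz,duration_min,viability_pct``
* ``summary``: one row per condition,
  ``voltage_v,frequency_mhz,duration_min,mean_pct,sd_pct,n``

The packaged study fixtures (a 4 voltages x 4 frequencies x 3 durations
factorial grid of normalized viability summaries with n = 20 per cell,
plus verification-experiment summaries and the measured acoustic
intensities) are exposed through :func:`load_study_grid`,
:func:`load_verification_groups`, :func:`load_printed_intervals` and
:func:`load_acoustic_intensity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulationCondition",
    "GroupSummary",
    "ReplicateRecord",
    "ResponseGrid",
    "CONTROL",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "read_replicates",
    "write_replicates",
    "aggregate_replicates",
    "normalize_to_control",
    "load_study_grid",
    "load_verification_groups",
    "load_printed_intervals",
    "load_acoustic_intensity",
]

REPLICATE_COLUMNS = ("voltage_v", "frequency_mhz", "duration_min", "viability_pct")
SUMMARY_COLUMNS = ("voltage_v", "frequency_mhz", "duration_min", "mean_pct", "sd_pct", "n")


class GridFormatError(ValueError):
    """A CSV file does not conform to the declared dialect."""


@dataclass(frozen=True, order=True)
class StimulationCondition:
    """One (voltage, frequency, duration) point in the parameter box.

    ``frequency == 0`` encodes the unstimulated control; only then may
    voltage and duration be zero as well.
    """

    voltage: float
    frequency: float
    duration: float

    def __post_init__(self) -> None:
        for name in ("voltage", "frequency", "duration"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.frequency < 0:
            raise ValueError(f"frequency must be >= 0, got {self.frequency}")
        if self.frequency > 0 and (self.voltage <= 0 or self.duration <= 0):
            raise ValueError(
                "treated conditions need voltage > 0 and duration > 0, got "
                f"({self.voltage} V, {self.frequency} MHz, {self.duration} min)"
            )
        if self.frequency == 0 and (self.voltage < 0 or self.duration < 0):
            raise ValueError("control condition cannot have negative voltage/duration")

    @property
    def is_control(self) -> bool:
        return self.frequency == 0

    def as_array(self) -> np.ndarray:
        return np.array([self.voltage, self.frequency, self.duration], dtype=float)


#: Canonical encoding of the unstimulated (0 MHz) control group.
CONTROL = StimulationCondition(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroupSummary:
    """Normalized viability statistics for one condition (mean %, SD points, n)."""

    condition: StimulationCondition
    mean_viability: float
    sd_viability: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.sd_viability < 0:
            raise ValueError(f"sd_viability must be >= 0, got {self.sd_viability}")
        if not math.isfinite(self.mean_viability):
            raise ValueError("mean_viability must be finite")


@dataclass(frozen=True)
class ReplicateRecord:
    """One normalized viability measurement at one condition."""

    condition: StimulationCondition
    viability: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.viability) and self.viability > 0):
            raise ValueError(f"viability must be finite and > 0, got {self.viability}")


class ResponseGrid:
    """A factorial table of viability summaries, keyed by condition.

    ``summaries`` holds the treated cells (unique per condition); the
    control group, when present, is stored separately on ``control`` and
    is excluded from surrogate training by default. ``len(grid)`` counts
    treated cells only.
    """

    def __init__(
        self,
        summaries: Iterable[GroupSummary],
        control: GroupSummary | None = None,
    ) -> None:
        cells: dict[StimulationCondition, GroupSummary] = {}
        for s in summaries:
            if s.condition.is_control:
                if control is not None:
                    raise ValueError("duplicate control group")
                control = s
                continue
            if s.condition in cells:
                raise ValueError(f"duplicate condition {s.condition}")
            cells[s.condition] = s
        if control is not None:
            if not control.condition.is_control:
                raise ValueError("control summary must have frequency 0")
            if control.mean_viability != 100:
                raise ValueError(
                    "control group mean must be exactly 100 after normalization, "
                    f"got {control.mean_viability}"
                )
        self._cells = dict(sorted(cells.items()))
        self.control = control

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self):
        return iter(self._cells.values())

    def __contains__(self, condition: StimulationCondition) -> bool:
        return condition in self._cells

    def __getitem__(self, condition: StimulationCondition) -> GroupSummary:
        return self._cells[condition]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseGrid):
            return NotImplemented
        return self._cells == other._cells and self.control == other.control

    @property
    def summaries(self) -> tuple[GroupSummary, ...]:
        """Treated-cell summaries, sorted by (voltage, frequency, duration)."""
        return tuple(self._cells.values())

    @property
    def conditions(self) -> tuple[StimulationCondition, ...]:
        return tuple(self._cells.keys())

    @property
    def levels(self) -> tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]]:
        """Distinct (voltages, frequencies, durations) of the treated cells."""
        return (
            tuple(sorted({c.voltage for c in self._cells})),
            tuple(sorted({c.frequency for c in self._cells})),
            tuple(sorted({c.duration for c in self._cells})),
        )

    @property
    def is_complete_factorial(self) -> bool:
        v, f, d = self.levels
        return len(self) == len(v) * len(f) * len(d)

    @property
    def box(self) -> np.ndarray:
        """Bounding box of the treated levels, shape (3, 2)."""
        v, f, d = self.levels
        return np.array([[v[0], v[-1]], [f[0], f[-1]], [d[0], d[-1]]], dtype=float)

    def to_frame(self, include_control: bool = True) -> pd.DataFrame:
        rows = list(self._cells.values())
        if include_control and self.control is not None:
            rows = [self.control] + rows
        return pd.DataFrame(
            {
                "voltage_v": [s.condition.voltage for s in rows],
                "frequency_mhz": [s.condition.frequency for s in rows],
                "duration_min": [s.condition.duration for s in rows],
                "mean_pct": [s.mean_viability for s in rows],
                "sd_pct": [s.sd_viability for s in rows],
                "n": [s.n_replicates for s in rows],
            }
        )

    def training_arrays(self, include_control: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) pairs — one per cell: condition coordinates -> mean viability."""
        rows = list(self._cells.values())
        if include_control and self.control is not None:
            rows = [self.control] + rows
        X = np.array([s.condition.as_array() for s in rows])
        y = np.array([s.mean_viability for s in rows])
        return X, y


# ---------------------------------------------------------------------------
# CSV I/O


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        raise GridFormatError(f"{path}: missing column(s) {missing}")
    if extra:
        raise GridFormatError(f"{path}: unexpected column(s) {extra}")


def _numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise GridFormatError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r} at row {bad[0] + 2}"
            )
        out[col] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_grid(path, dialect: str = "summary") -> ResponseGrid:
    """Read a :class:`ResponseGrid` from a CSV file.

    ``dialect='replicate'`` aggregates per-replicate rows to group
    summaries (mean, sample SD with the n-1 denominator, n);
    ``dialect='summary'`` reads one row per condition and rejects
    duplicates. Rows with frequency 0 become the control group.
    """
    if dialect == "replicate":
        return ResponseGrid(aggregate_replicates(read_replicates(path)))
    if dialect != "summary":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, SUMMARY_COLUMNS, path)
    df = _numeric(df, path)
    summaries = [
        GroupSummary(
            StimulationCondition(float(r.voltage_v), float(r.frequency_mhz), float(r.duration_min)),
            float(r.mean_pct),
            float(r.sd_pct),
            int(r.n),
        )
        for r in df.itertuples()
    ]
    seen: set[StimulationCondition] = set()
    for s in summaries:
        if s.condition in seen:
            raise GridFormatError(f"{path}: duplicate condition {s.condition}")
        seen.add(s.condition)
    return ResponseGrid(summaries)


def write_grid(grid: ResponseGrid, path) -> None:
    """Write a grid in summary dialect; floats use ``repr`` so that a
    read_grid round trip reproduces every field bit-identically."""
    rows = []
    if grid.control is not None:
        rows.append(grid.control)
    rows.extend(grid.summaries)
    with open(path, "w") as fh:
        fh.write(",".join(SUMMARY_COLUMNS) + "\n")
        for s in rows:
            c = s.condition
            fh.write(
                f"{c.voltage!r},{c.frequency!r},{c.duration!r},"
                f"{s.mean_viability!r},{s.sd_viability!r},{s.n_replicates}\n"
            )


def read_replicates(path) -> list[ReplicateRecord]:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, REPLICATE_COLUMNS, path)
    df = _numeric(df, path)
    return [
        ReplicateRecord(
            StimulationCondition(float(r.voltage_v), float(r.frequency_mhz), float(r.duration_min)),
            float(r.viability_pct),
        )
        for r in df.itertuples()
    ]


def write_replicates(records: Iterable[ReplicateRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(REPLICATE_COLUMNS) + "\n")
        for r in records:
            c = r.condition
            fh.write(f"{c.voltage!r},{c.frequency!r},{c.duration!r},{r.viability!r}\n")


def aggregate_replicates(records: Iterable[ReplicateRecord]) -> list[GroupSummary]:
    """Collapse replicates to per-condition (mean, sample SD, n).

    The sample SD uses the n-1 denominator; a single replicate is stored
    with SD 0 (its sample SD is undefined).
    """
    groups: dict[StimulationCondition, list[float]] = {}
    for r in records:
        groups.setdefault(r.condition, []).append(r.viability)
    out = []
    for cond, vals in sorted(groups.items()):
        arr = np.asarray(vals, dtype=float)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        out.append(GroupSummary(cond, float(np.mean(arr)), sd, len(arr)))
    return out


def normalize_to_control(
    raw: Iterable[ReplicateRecord],
    control_condition: StimulationCondition = CONTROL,
) -> list[ReplicateRecord]:
    """Express raw measurements (e.g. CCK-8 absorbances) as percent of the
    control-group mean, so the control group's mean becomes exactly 100.

    Idempotent: normalizing already-normalized data is a no-op up to
    floating-point roundoff.
    """
    raw = list(raw)
    control_vals = [r.viability for r in raw if r.condition == control_condition]
    if not control_vals:
        raise ValueError(f"control condition {control_condition} absent from data")
    control_mean = float(np.mean(control_vals))
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    scale = 100.0 / control_mean
    return [ReplicateRecord(r.condition, r.viability * scale) for r in raw]


# ---------------------------------------------------------------------------
# Packaged study fixtures


def _data_path(name: str) -> Path:
    return Path(resources.files("lipusopt.data") / name)


def load_study_grid() -> ResponseGrid:
    """The packaged 48-cell factorial viability grid (means, SDs, n = 20)
    transcribed from the published stimulation study, plus its control row."""
    return read_grid(_data_path("viability_grid.csv"))


def load_verification_groups() -> pd.DataFrame:
    """Summaries of the verification experiment (control, grid-best LIPUS
    treatment, GA-BPNN-optimized treatment), as printed (n = 5)."""
    return pd.read_csv(_data_path("verification_groups.csv"))


def load_printed_intervals() -> pd.DataFrame:
    """The published per-cell 95% confidence intervals, P values and
    significance flags, for cross-checking the stats module."""
    return pd.read_csv(_data_path("printed_intervals.csv"))


def load_acoustic_intensity() -> pd.DataFrame:
    """Measured acoustic intensity (mW/cm^2) per voltage x frequency; data
    passthrough only, not modelled."""
    return pd.read_csv(_data_path("acoustic_intensity.csv"))
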