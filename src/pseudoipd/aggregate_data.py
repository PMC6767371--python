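"""Data model and I/O for per-arm aggregate summaries of a continuous outcome.

The unit of input is one study with two arms (control = 0, treated/exposed = 1),
each summarised by its sample mean, sample standard deviation (n-1 denominator)
and sample size.  These three numbers per arm are the sufficient statistics for
every model in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "ArmSummary",
    "Study",
    "AggregateDataset",
    "StructuralError",
    "ValidationError",
    "read_aggregate_csv",
    "write_aggregate_csv",
    "load_fixture",
    "FIXTURES",
]


class StructuralError(ValueError):
    """The table shape is wrong (missing/duplicate arms, duplicate studies)."""


class ValidationError(ValueError):
    """A field value violates an invariant (n < 2, negative sd, non-finite)."""


@dataclass(frozen=True)
class ArmSummary:
    """Sufficient statistics for one study arm.

    ``sd`` is the sample standard deviation with an ``n - 1`` denominator.
    """

    study_id: str
    arm: int
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.arm not in (0, 1):
            raise ValidationError(
                f"arm must be 0 (control) or 1 (treated), got {self.arm!r} "
                f"for study {self.study_id!r}"
            )
        if int(self.n) != self.n or self.n < 2:
            raise ValidationError(
                f"n must be an integer >= 2, got {self.n!r} for study "
                f"{self.study_id!r} arm {self.arm}"
            )
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise ValidationError(
                f"mean/sd must be finite for study {self.study_id!r} arm {self.arm}"
            )
        if self.sd < 0:
            raise ValidationError(
                f"sd must be >= 0, got {self.sd} for study {self.study_id!r} "
                f"arm {self.arm}"
            )

    @property
    def ss(self) -> float:
        """Within-arm corrected sum of squares, (n - 1) * sd**2."""
        return (self.n - 1) * self.sd**2


@dataclass(frozen=True)
class Study:
    study_id: str
    control: ArmSummary
    treated: ArmSummary

    def __post_init__(self) -> None:
        if self.control.arm != 0 or self.treated.arm != 1:
            raise StructuralError(
                f"study {self.study_id!r}: control must carry arm=0 and "
                "treated arm=1"
            )

    @property
    def arms(self) -> tuple[ArmSummary, ArmSummary]:
        return (self.control, self.treated)

    @property
    def n_total(self) -> int:
        return self.control.n + self.treated.n


@dataclass(frozen=True)
class AggregateDataset:
    """An ordered collection of two-arm studies sharing one outcome."""

    studies: tuple[Study, ...]
    outcome_label: str = ""
    outcome_units: str = ""

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise StructuralError(f"duplicate study_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[Study]:
        return iter(self.studies)

    @property
    def m(self) -> int:
        """Number of studies."""
        return len(self.studies)

    @property
    def n_total(self) -> int:
        return sum(s.n_total for s in self.studies)

    def study(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def arms(self) -> Iterator[ArmSummary]:
        """All arms in study order, control before treated."""
        for s in self.studies:
            yield s.control
            yield s.treated

    def to_frame(self, layout: str = "wide") -> pd.DataFrame:
        if layout == "wide":
            rows = [
                {
                    "study_id": s.study_id,
                    "mean0": s.control.mean,
                    "sd0": s.control.sd,
                    "n0": s.control.n,
                    "mean1": s.treated.mean,
                    "sd1": s.treated.sd,
                    "n1": s.treated.n,
                }
                for s in self.studies
            ]
        elif layout == "long":
            rows = [
                {"study_id": a.study_id, "arm": a.arm, "mean": a.mean,
                 "sd": a.sd, "n": a.n}
                for a in self.arms()
            ]
        else:
            raise ValueError(f"unknown layout {layout!r}")
        return pd.DataFrame(rows)


_WIDE_COLS = {"study_id", "mean0", "sd0", "n0", "mean1", "sd1", "n1"}
_LONG_COLS = {"study_id", "arm", "mean", "sd", "n"}


def _studies_from_long(df: pd.DataFrame) -> list[Study]:
    studies: list[Study] = []
    for study_id, grp in df.groupby("study_id", sort=False):
        arms = {}
        for idx, row in grp.iterrows():
            arm = int(row["arm"])
            if arm in arms:
                raise StructuralError(
                    f"study {study_id!r}: duplicate arm {arm} (row {idx})"
                )
            try:
                arms[arm] = ArmSummary(
                    study_id=str(study_id), arm=arm,
                    mean=float(row["mean"]), sd=float(row["sd"]),
                    n=int(row["n"]),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {idx}: {exc}") from exc
        if set(arms) != {0, 1}:
            raise StructuralError(
                f"study {study_id!r}: expected one control (0) and one "
                f"treated (1) arm, found arms {sorted(arms)}"
            )
        studies.append(Study(str(study_id), control=arms[0], treated=arms[1]))
    return studies


def _studies_from_wide(df: pd.DataFrame) -> list[Study]:
    ids = df["study_id"].astype(str)
    studies = []
    for idx, row in df.iterrows():
        sid = str(row["study_id"])
        try:
            control = ArmSummary(sid, 0, float(row["mean0"]),
                                 float(row["sd0"]), int(row["n0"]))
            treated = ArmSummary(sid, 1, float(row["mean1"]),
                                 float(row["sd1"]), int(row["n1"]))
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        studies.append(Study(sid, control=control, treated=treated))
    del ids
    return studies


def read_aggregate_csv(
    path,
    dialect: Mapping[str, str] | None = None,
    outcome_label: str = "",
    outcome_units: str = "",
) -> AggregateDataset:
    """Read an aggregate-summary CSV in wide or long layout.

    Wide layout has one row per study with columns
    ``study_id, mean0, sd0, n0, mean1, sd1, n1``; long layout has one row per
    arm with columns ``study_id, arm, mean, sd, n``.  The layout is
    auto-detected from the header.  ``dialect`` optionally maps the canonical
    column names to the names actually present in the file.

    Row order is preserved as study order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    cols = set(df.columns)
    if _WIDE_COLS <= cols:
        studies = _studies_from_wide(df)
    elif _LONG_COLS <= cols:
        studies = _studies_from_long(df)
    else:
        raise StructuralError(
            "could not detect CSV layout: need wide columns "
            f"{sorted(_WIDE_COLS)} or long columns {sorted(_LONG_COLS)}; "
            f"found {sorted(cols)}"
        )
    return AggregateDataset(tuple(studies), outcome_label=outcome_label,
                            outcome_units=outcome_units)


def write_aggregate_csv(data: AggregateDataset, path, layout: str = "wide") -> None:
    """Write a dataset back to CSV at full float precision (lossless)."""
    data.to_frame(layout).to_csv(path, index=False, float_format="%.17g")


FIXTURES: dict[str, tuple[str, str]] = {
    "iron": ("iron blood level", "ug/dL"),
    "folate": ("folate level", "nmol/L"),
}


def load_fixture(name: str) -> AggregateDataset:
    """Load one of the bundled example datasets (``"iron"`` or ``"folate"``)."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    label, units = FIXTURES[name]
    ref = resources.files("pseudoipd.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return read_aggregate_csv(p, outcome_label=label, outcome_units=units)
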