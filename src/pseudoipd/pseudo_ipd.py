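"""Reconstruction of participant-level outcomes from per-arm summaries.

Because the per-arm mean, SD and sample size are sufficient for every
Gaussian linear mixed model considered here, any participant-level sample
that reproduces them exactly yields the identical likelihood — and hence
identical fits — as the unobserved true data.  Two constructions are
provided: an affine rescaling of arbitrary random draws, and a deterministic
two-point configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .aggregate_data import AggregateDataset, ArmSummary, StructuralError

__all__ = [
    "PseudoIPD",
    "generate_pseudo_ipd",
    "rescale_to_moments",
    "two_point_sample",
    "verify_sufficiency",
    "SufficiencyReport",
    "from_frame",
    "aggregate_from_ipd",
]

METHODS = ("two_point", "rescale_normal")


@dataclass(frozen=True)
class PseudoIPD:
    """Long-format participant-level outcomes.

    ``study_ids``/``arms``/``y`` are parallel arrays, ordered by study then
    arm (control first).  ``provenance`` records the generation method and
    seed so a run can be reproduced.
    """

    study_ids: np.ndarray  # dtype object/str
    arms: np.ndarray       # int, 0/1
    y: np.ndarray          # float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (len(self.study_ids) == len(self.arms) == len(self.y)):
            raise ValueError("study_ids, arms and y must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def groups(self) -> Iterator[tuple[str, int, np.ndarray]]:
        """Yield (study_id, arm, values) in first-appearance order."""
        df = self.to_frame()
        for (sid, arm), grp in df.groupby(["study_id", "arm"], sort=False):
            yield sid, int(arm), grp["y"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"study_id": self.study_ids, "arm": self.arms, "y": self.y}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def from_frame(df: pd.DataFrame, provenance: str = "external") -> PseudoIPD:
    """Build a :class:`PseudoIPD` from a long data frame (study_id, arm, y)."""
    return PseudoIPD(
        study_ids=df["study_id"].to_numpy(),
        arms=df["arm"].to_numpy(dtype=int),
        y=df["y"].to_numpy(dtype=float),
        provenance=provenance,
    )


def rescale_to_moments(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely map ``values`` so the sample mean/SD (n-1) match exactly.

    Requires len(values) >= 2 and a nonzero spread unless sd == 0.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values to fix a sample SD")
    if sd == 0.0:
        return np.full(n, mean)
    centred = values - values.mean()
    spread = np.sqrt(centred @ centred / (n - 1))
    if spread == 0.0:
        raise ValueError("input sample has zero spread; cannot rescale")
    return mean + sd * centred / spread


def two_point_sample(mean: float, sd: float, n: int) -> np.ndarray:
    """The unique (up to permutation) sample with one high value.

    First value ``mean + sd*(n-1)/sqrt(n)``, remaining ``mean - sd/sqrt(n)``;
    sample mean is exactly ``mean`` and sample SD (n-1 denominator) exactly
    ``sd``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    root_n = np.sqrt(n)
    out = np.full(n, mean - sd / root_n)
    out[0] = mean + sd * (n - 1) / root_n
    return out


def _generate_arm(arm: ArmSummary, method: str,
                  rng: np.random.Generator | None) -> np.ndarray:
    if arm.sd == 0.0:
        warnings.warn(
            f"arm (study {arm.study_id!r}, arm {arm.arm}) has sd = 0; "
            "models with a free variance for this arm will be singular",
            stacklevel=3,
        )
        return np.full(arm.n, float(arm.mean))
    if method == "two_point":
        return two_point_sample(arm.mean, arm.sd, arm.n)
    # rescale_normal: redraw on a (measure-zero) degenerate draw
    for _ in range(100):
        draw = rng.standard_normal(arm.n)
        if np.ptp(draw) > 0:
            return rescale_to_moments(draw, arm.mean, arm.sd)
    raise RuntimeError("could not obtain a non-degenerate normal draw")


def generate_pseudo_ipd(
    data: AggregateDataset,
    method: str = "two_point",
    seed: int | None = None,
) -> PseudoIPD:
    """Generate pseudo participant data matching every arm's mean/SD exactly.

    ``method="rescale_normal"`` draws standard normals per arm and rescales
    them; ``method="two_point"`` (default) is deterministic and ignores the
    seed.  Either way the per-arm sample mean and sample SD equal the
    aggregate summaries to machine precision, so all likelihood-based fits
    are invariant to the choice.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    rng = None
    if method == "rescale_normal":
        if seed is None:
            raise ValueError("rescale_normal requires a seed")
        rng = np.random.default_rng(seed)

    sids: list[str] = []
    arms: list[int] = []
    ys: list[np.ndarray] = []
    for study in data:
        for arm in study.arms:
            vals = _generate_arm(arm, method, rng)
            sids.extend([arm.study_id] * arm.n)
            arms.extend([arm.arm] * arm.n)
            ys.append(vals)
    return PseudoIPD(
        study_ids=np.array(sids, dtype=object),
        arms=np.array(arms, dtype=int),
        y=np.concatenate(ys),
        provenance=f"method={method} seed={seed}",
    )


def aggregate_from_ipd(
    ipd: PseudoIPD, outcome_label: str = "", outcome_units: str = ""
) -> AggregateDataset:
    """Reduce participant-level data to per-arm (mean, sd, n) summaries."""
    from .aggregate_data import Study  # local import to keep module load light

    per_study: dict[str, dict[int, ArmSummary]] = {}
    for sid, arm, vals in ipd.groups():
        summ = ArmSummary(
            study_id=sid, arm=arm,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
            n=int(len(vals)),
        )
        per_study.setdefault(sid, {})[arm] = summ
    studies = []
    for sid, arms in per_study.items():
        if set(arms) != {0, 1}:
            raise StructuralError(
                f"study {sid!r}: expected both arms, found {sorted(arms)}")
        studies.append(Study(sid, control=arms[0], treated=arms[1]))
    return AggregateDataset(tuple(studies), outcome_label=outcome_label,
                            outcome_units=outcome_units)


@dataclass(frozen=True)
class SufficiencyReport:
    max_mean_error: float
    max_sd_error: float
    tol: float
    per_arm: pd.DataFrame

    @property
    def passed(self) -> bool:
        return self.max_mean_error <= self.tol and self.max_sd_error <= self.tol


def verify_sufficiency(
    pipd: PseudoIPD, data: AggregateDataset, tol: float = 1e-12
) -> SufficiencyReport:
    """Check that the pseudo data reproduce every arm's summaries.

    Errors are relative (scaled by max(1, |target|)).  Raises
    :class:`StructuralError` on a study/arm mismatch, naming the arm.
    """
    observed = {(sid, arm): vals for sid, arm, vals in pipd.groups()}
    expected = {(a.study_id, a.arm): a for a in data.arms()}
    if set(observed) != set(expected):
        missing = sorted(set(expected) - set(observed))
        extra = sorted(set(observed) - set(expected))
        raise StructuralError(
            f"study/arm mismatch: missing {missing}, unexpected {extra}"
        )
    rows = []
    for (sid, arm), target in expected.items():
        vals = observed[(sid, arm)]
        if len(vals) != target.n:
            raise StructuralError(
                f"arm (study {sid!r}, arm {arm}): expected n={target.n}, "
                f"got {len(vals)}"
            )
        mean_err = abs(vals.mean() - target.mean) / max(1.0, abs(target.mean))
        sd_err = abs(vals.std(ddof=1) - target.sd) / max(1.0, abs(target.sd))
        rows.append({"study_id": sid, "arm": arm,
                     "mean_error": mean_err, "sd_error": sd_err,
                     "ok": mean_err <= tol and sd_err <= tol})
    table = pd.DataFrame(rows)
    return SufficiencyReport(
        max_mean_error=float(table["mean_error"].max()),
        max_sd_error=float(table["sd_error"].max()),
        tol=tol,
        per_arm=table,
    )
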