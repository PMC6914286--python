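"""Long-format repeated-measures trial data and pre-model transforms.

The whole pipeline operates on a single container, :class:`TrialDataset`: one
row per (subject, timepoint, variable) with a binary arm code (0 = control,
1 = exercise/intervention) and a binary timepoint code (0 = baseline,
1 = follow-up, e.g. week 12).  Variables are tagged with an analysis role
(outcome / mediator / covariate) and an optional scalar transform; the only
transform implemented is the natural logarithm, used for right-skewed
positive biomarkers (BDNF, CRP, HOMA2-IR and the like).

T-score helpers for patient-reported outcomes (PROMIS-style scales,
standardized to mean 50 / SD 10 in a reference population) live here too,
together with the conventional 3-point clinically-meaningful-change rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, IntegrityError

__all__ = [
    "Measurement",
    "TrialDataset",
    "read_long_csv",
    "log_transform",
    "to_t_score",
    "classify_meaningful_change",
    "MEANINGFUL_CHANGE_T_POINTS",
]

#: Conventional clinically meaningful difference on the T-score metric.
MEANINGFUL_CHANGE_T_POINTS = 3.0

REQUIRED_COLUMNS = ("subject_id", "arm", "timepoint", "variable", "value")

_ARM_CODES = {
    "0": 0, "1": 1,
    "control": 0, "exercise": 1, "intervention": 1, "treatment": 1,
}
_TIME_CODES = {
    "0": 0, "1": 1,
    "baseline": 0,
    "week12": 1, "week-12": 1, "week_12": 1, "12 weeks": 1, "12weeks": 1,
    "followup": 1, "follow-up": 1,
}

VALID_ROLES = frozenset({"outcome", "mediator", "covariate"})
VALID_TRANSFORMS = frozenset({"none", "log"})


class Measurement(NamedTuple):
    """One observed value: subject x timepoint x variable."""

    subject_id: str
    arm: int
    timepoint: int
    variable: str
    value: float


def _decode(series: pd.Series, codes: Mapping[str, int], what: str) -> pd.Series:
    decoded = (
        series.astype(str).str.strip().str.lower().map(codes)
    )
    if decoded.isna().any():
        bad = series[decoded.isna()].unique()[:5]
        raise FormatError(f"cannot decode {what} values {list(bad)} to 0/1")
    return decoded.astype(np.int8)


@dataclass
class TrialDataset:
    """Validated long-format trial data plus variable roles and transforms.

    Parameters
    ----------
    data
        DataFrame with columns ``subject_id, arm, timepoint, variable, value``.
    roles
        Map variable name -> ``outcome`` | ``mediator`` | ``covariate``.
    transforms
        Map variable name -> ``none`` | ``log``.  Variables flagged ``log``
        must be strictly positive until :meth:`apply_transforms` is called.
    transformed
        True once transforms have been applied; model-fitting stages require
        this when any variable carries a ``log`` flag.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)
    transformed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")

        dup = df.duplicated(subset=["subject_id", "timepoint", "variable"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["subject_id", "timepoint", "variable"]]
            raise IntegrityError(
                "duplicate record for "
                f"(subject={first['subject_id']}, timepoint={first['timepoint']}, "
                f"variable={first['variable']})"
            )

        arms = df.groupby("subject_id", sort=False)["arm"].nunique()
        if (arms > 1).any():
            bad = arms.index[arms > 1][0]
            raise IntegrityError(f"subject {bad} appears in more than one arm")

        # dropout may remove follow-up rows but baseline must exist
        has_baseline = df.groupby("subject_id", sort=False)["timepoint"].min()
        if (has_baseline > 0).any():
            bad = has_baseline.index[has_baseline > 0][0]
            raise IntegrityError(f"subject {bad} has no baseline records")

        for var, role in self.roles.items():
            if role not in VALID_ROLES:
                raise FormatError(f"unknown role {role!r} for variable {var!r}")
            if var not in set(df["variable"]):
                raise IntegrityError(f"role declared for absent variable {var!r}")

        for var, tr in self.transforms.items():
            if tr not in VALID_TRANSFORMS:
                raise FormatError(f"unknown transform {tr!r} for variable {var!r}")

        if not self.transformed:
            for var, tr in self.transforms.items():
                if tr == "log":
                    vals = df.loc[df["variable"] == var, "value"]
                    if (vals <= 0).any():
                        raise DomainError(
                            f"variable {var!r} flagged for log transform has "
                            "non-positive values"
                        )

    # -- accessors -------------------------------------------------------

    @property
    def subjects(self) -> pd.DataFrame:
        """One row per subject with its arm code."""
        return (
            self.data[["subject_id", "arm"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    @property
    def n_subjects_per_arm(self) -> tuple[int, int]:
        """(control count, exercise count)."""
        counts = self.subjects["arm"].value_counts()
        return int(counts.get(0, 0)), int(counts.get(1, 0))

    @property
    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    @property
    def measurements(self) -> Iterator[Measurement]:
        for row in self.data.itertuples(index=False):
            yield Measurement(
                str(row.subject_id), int(row.arm), int(row.timepoint),
                str(row.variable), float(row.value),
            )

    def wide(self, variables: Iterable[str] | None = None) -> pd.DataFrame:
        """Pivot to one row per subject x timepoint, one column per variable.

        Missing (subject, timepoint, variable) cells become NaN; subjects who
        dropped out before follow-up simply lack those rows entirely.
        """
        df = self.data
        if variables is not None:
            variables = list(variables)
            df = df[df["variable"].isin(variables)]
        wide = (
            df.pivot_table(
                index=["subject_id", "arm", "timepoint"],
                columns="variable", values="value", aggfunc="first",
            )
            .reset_index()
        )
        wide.columns.name = None
        if variables is not None:
            for v in variables:
                if v not in wide.columns:
                    wide[v] = np.nan
        return wide.sort_values(["subject_id", "timepoint"], kind="stable").reset_index(drop=True)

    # -- transforms ------------------------------------------------------

    def apply_transforms(self) -> "TrialDataset":
        """Return a copy with declared transforms applied to the values.

        Idempotent at the dataset level: calling on an already transformed
        dataset returns it unchanged.
        """
        if self.transformed:
            return self
        df = self.data.copy()
        for var, tr in self.transforms.items():
            if tr == "log":
                mask = df["variable"] == var
                df.loc[mask, "value"] = log_transform(df.loc[mask, "value"].to_numpy())
        return TrialDataset(df, dict(self.roles), dict(self.transforms), transformed=True)

    def subset(self, subject_ids: Iterable[str]) -> "TrialDataset":
        ids = set(subject_ids)
        df = self.data[self.data["subject_id"].isin(ids)].reset_index(drop=True)
        return replace(self, data=df)

    # -- I/O -------------------------------------------------------------

    def write_long_csv(self, path) -> None:
        """Write the long table in a canonical row order."""
        out = self.data.sort_values(
            ["subject_id", "timepoint", "variable"], kind="stable"
        )
        out.to_csv(path, index=False)


def read_long_csv(
    path,
    roles: Mapping[str, str] | None = None,
    transforms: Mapping[str, str] | None = None,
) -> TrialDataset:
    """Read a long-format CSV into a validated :class:`TrialDataset`.

    The file must have columns ``subject_id, arm, timepoint, variable,
    value``.  Arm accepts 0/1 or control/exercise labels; timepoint accepts
    0/1 or baseline/week12-style labels.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "variable": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["arm"] = _decode(df["arm"], _ARM_CODES, "arm")
    df["timepoint"] = _decode(df["timepoint"], _TIME_CODES, "timepoint")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    return TrialDataset(
        df[list(REQUIRED_COLUMNS)],
        dict(roles or {}),
        dict(transforms or {}),
    )


def log_transform(values) -> np.ndarray:
    """Natural log, elementwise; raises :class:`DomainError` on values <= 0."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise DomainError("log transform requires strictly positive values")
    return np.log(arr)


def to_t_score(raw, ref_mean: float, ref_sd: float):
    """Map a raw score to the T-score metric: 50 + 10 * (raw - mean) / sd."""
    if ref_sd <= 0:
        raise DomainError("reference SD must be positive")
    return 50.0 + 10.0 * (np.asarray(raw, dtype=float) - ref_mean) / ref_sd


def classify_meaningful_change(
    delta: float, threshold: float = MEANINGFUL_CHANGE_T_POINTS
) -> bool:
    """True when |delta| meets the clinically meaningful threshold (inclusive)."""
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    return bool(abs(delta) >= threshold)
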