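"""Synthetic two-arm, two-timepoint trials with known mediation structure.

The generator emulates a small randomized exercise trial in breast cancer
survivors: 43 intervention and 44 control subjects, repeated measures at
baseline and week 12, a subject-level random intercept for each variable,
and one dropout per arm whose follow-up visit is missing completely at
random.  Variables live on the patient-reported-outcome T-score scale
(population mean 50, SD 10) unless biomarker mode is on, in which case the
linear model holds on the natural-log scale and strictly positive
(log-normal) values are emitted.

Generative model for subject i in arm g (0 control, 1 exercise) at
timepoint t (0, 1):

    M_it = mu_M + trend_M * t + a * g * t + u_i + eps_it
    Y_it = mu_Y + trend_Y * t + d * g * t + b * M_it + v_i + eta_it

with u_i ~ N(0, tau2_m), eps ~ N(0, sigma2_m) and v, eta analogous.  The
implied total intervention effect on Y is d + a * b, so the indirect effect
equals a * b - and, because the model is linear and Gaussian with no
exposure-mediator interaction, the difference-of-coefficients estimator
c - c' targets the same quantity.  That identity is what makes this
generator a usable oracle for the whole pipeline.

Default effect magnitudes are anchored to what such trials report for
anxiety (intervention effect about -1.5 T-score points) with total
per-variable SD near 8.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .trial_data import TrialDataset

__all__ = ["SyntheticSpec", "generate", "apply_dropout"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic trial.

    Variance defaults give each variable a total SD of 8 (tau2 + sigma2 =
    64) with intraclass correlation 0.625 - plausible for patient-reported
    T-scores measured twice over 12 weeks.  In ``biomarker_mode`` all
    mediator-scale parameters are interpreted on the natural-log scale and
    should be overridden accordingly (e.g. mean 14.3, variances near 1 for
    a log-CRP-like marker).
    """

    n_exercise: int = 43
    n_control: int = 44
    a_effect: float = -1.5
    b_effect: float = 0.4
    direct_effect: float = 0.0
    mediator_baseline_mean: float = 55.2
    outcome_baseline_mean: float = 45.4
    tau2_m: float = 40.0
    tau2_y: float = 40.0
    sigma2_m: float = 24.0
    sigma2_y: float = 24.0
    time_trend_m: float = -0.3
    time_trend_y: float = 0.5
    biomarker_mode: bool = False
    dropout_per_arm: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("tau2_m", "tau2_y", "sigma2_m", "sigma2_y"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.n_exercise < 2 or self.n_control < 2:
            raise DomainError("need at least 2 subjects per arm")
        if self.dropout_per_arm < 0:
            raise DomainError("dropout_per_arm must be non-negative")
        if self.dropout_per_arm >= min(self.n_exercise, self.n_control):
            raise DomainError("dropout_per_arm must be smaller than each arm")

    @property
    def total_effect(self) -> float:
        """Implied total intervention effect c = direct + a * b."""
        return self.direct_effect + self.a_effect * self.b_effect

    @property
    def indirect_effect(self) -> float:
        """True indirect effect a * b."""
        return self.a_effect * self.b_effect


def _random_intercept_panel(
    rng: np.random.Generator, n: int, mean: float, trend: float,
    effect: float, g: np.ndarray, tau2: float, sigma2: float,
) -> np.ndarray:
    """(n, 2) array of values at t=0 and t=1 for one variable."""
    u = rng.normal(0.0, np.sqrt(tau2), size=n)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=(n, 2))
    t = np.array([0.0, 1.0])
    return mean + trend * t + effect * np.outer(g, t) + u[:, None] + eps


def generate(
    spec: SyntheticSpec,
    *,
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
    null_mediators: Sequence[str] = (),
    null_outcomes: Sequence[str] = (),
) -> TrialDataset:
    """Generate one synthetic trial as a :class:`TrialDataset`.

    ``null_mediators`` / ``null_outcomes`` add extra variables with the same
    covariance structure but no intervention effect and no link to anything
    else - useful for exercising multi-pair analyses where only one pair has
    true signal.  Dropout (``spec.dropout_per_arm`` subjects per arm losing
    their follow-up visit) is applied last, from a seed-derived substream,
    independent of all values.
    """
    ss = np.random.SeedSequence(spec.seed)
    ss_values, ss_dropout = ss.spawn(2)
    rng = np.random.default_rng(ss_values)

    n = spec.n_control + spec.n_exercise
    ids = np.array(
        [f"C{i + 1:03d}" for i in range(spec.n_control)]
        + [f"E{i + 1:03d}" for i in range(spec.n_exercise)]
    )
    g = np.concatenate([np.zeros(spec.n_control), np.ones(spec.n_exercise)])

    M = _random_intercept_panel(
        rng, n, spec.mediator_baseline_mean, spec.time_trend_m,
        spec.a_effect, g, spec.tau2_m, spec.sigma2_m,
    )
    v = rng.normal(0.0, np.sqrt(spec.tau2_y), size=n)
    eta = rng.normal(0.0, np.sqrt(spec.sigma2_y), size=(n, 2))
    t = np.array([0.0, 1.0])
    Y = (
        spec.outcome_baseline_mean
        + spec.time_trend_y * t
        + spec.direct_effect * np.outer(g, t)
        + spec.b_effect * M
        + v[:, None]
        + eta
    )

    columns: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {mediator_name: "mediator", outcome_name: "outcome"}
    transforms: dict[str, str] = {}
    if spec.biomarker_mode:
        columns[mediator_name] = np.exp(M)
        transforms[mediator_name] = "log"
    else:
        columns[mediator_name] = M
        transforms[mediator_name] = "none"
    columns[outcome_name] = Y
    transforms[outcome_name] = "none"

    for name in null_mediators:
        columns[name] = _random_intercept_panel(
            rng, n, 50.0, 0.0, 0.0, g, spec.tau2_m, spec.sigma2_m
        )
        roles[name] = "mediator"
        transforms[name] = "none"
    for name in null_outcomes:
        columns[name] = _random_intercept_panel(
            rng, n, 50.0, 0.0, 0.0, g, spec.tau2_y, spec.sigma2_y
        )
        roles[name] = "outcome"
        transforms[name] = "none"

    records = []
    for var, values in columns.items():
        for tp in (0, 1):
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": ids,
                        "arm": g.astype(np.int8),
                        "timepoint": np.int8(tp),
                        "variable": var,
                        "value": values[:, tp],
                    }
                )
            )
    df = (
        pd.concat(records, ignore_index=True)
        .sort_values(["subject_id", "timepoint", "variable"], kind="stable")
        .reset_index(drop=True)
    )
    dataset = TrialDataset(df, roles, transforms)
    if spec.dropout_per_arm:
        dataset = apply_dropout(
            dataset, spec.dropout_per_arm,
            seed=int(ss_dropout.generate_state(1)[0] % (2**31)),
        )
    return dataset


def apply_dropout(dataset: TrialDataset, per_arm: int, seed: int) -> TrialDataset:
    """Remove all follow-up records of ``per_arm`` random subjects per arm.

    Baseline records are kept, and selection depends only on the seed, never
    on observed values - missingness is MCAR by construction, which implies
    the missing-at-random condition the mixed models rely on.
    """
    if per_arm == 0:
        return dataset
    subjects = dataset.subjects
    rng = np.random.default_rng(seed)
    dropped: list[str] = []
    for arm_code in (0, 1):
        ids = subjects.loc[subjects["arm"] == arm_code, "subject_id"].to_numpy()
        if per_arm >= len(ids):
            raise DomainError("per_arm must be smaller than each arm's size")
        dropped.extend(rng.choice(np.sort(ids), size=per_arm, replace=False))
    df = dataset.data
    keep = ~(df["subject_id"].isin(dropped) & (df["timepoint"] == 1))
    return replace(dataset, data=df[keep].reset_index(drop=True))
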