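"""Causal-steps mediation: paths a, b, c, c', the significance gate and the
difference-of-coefficients indirect effect.

For one (mediator, outcome) pair in a two-arm, two-timepoint trial:

* path a  - group:time coefficient from the mixed model of the mediator
  (did the intervention move the mediator?);
* path c  - group:time coefficient from the mixed model of the outcome
  (total intervention effect on the outcome);
* path c' - group:time coefficient from the outcome model that additionally
  adjusts for the concurrent mediator value (direct effect);
* path b  - the mediator coefficient from that same adjusted model.

Mediation is only quantified when paths a, b and c all clear a liberal
significance gate (default alpha = 0.10, strict inequality, chosen a priori
for small pilot samples).  The indirect effect is c - c'; in the linear
Gaussian model without exposure-mediator interaction this coincides with
the product a*b, and its uncertainty is assessed by the subject-resampling
bootstrap in :mod:`mediboot.bootstrap_ci`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError
from .lmm_engine import (
    TERM_GROUP_TIME,
    TERM_MEDIATOR,
    LmmFit,
    ModelSpec,
    PathEstimate,
    fit_lmm,
)
from .trial_data import TrialDataset

__all__ = [
    "MediationPaths",
    "GateDecision",
    "MediationResult",
    "estimate_paths",
    "gate",
    "indirect_effect",
    "pair_seed",
]

DEFAULT_GATE_ALPHA = 0.10


@dataclass(frozen=True)
class MediationPaths:
    a: PathEstimate
    b: PathEstimate
    c: PathEstimate
    c_prime: PathEstimate

    def as_dict(self) -> dict[str, PathEstimate]:
        return {"a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime}


@dataclass(frozen=True)
class GateDecision:
    """Causal-steps gate: proceed to the bootstrap iff a, b and c all pass."""

    passed_a: bool
    passed_b: bool
    passed_c: bool
    alpha: float = DEFAULT_GATE_ALPHA

    @property
    def proceed(self) -> bool:
        return self.passed_a and self.passed_b and self.passed_c


@dataclass
class MediationResult:
    """Full inference for one (mediator, outcome) pair.

    ``boot_ci95`` and ``significant`` are present only when the gate passed;
    ``significant`` means the bootstrap CI excludes zero.
    """

    mediator: str
    outcome: str
    paths: MediationPaths
    gate: GateDecision
    indirect: float
    boot_ci95: tuple[float, float] | None = None
    n_boot: int = 0
    n_failed: int = 0
    seed: int | None = None
    significant: bool | None = None


def _did_path(fit: LmmFit, path: str) -> PathEstimate:
    c = fit.coefficients[TERM_GROUP_TIME]
    return PathEstimate(c.estimate, c.se, c.p_value, c.ci95, TERM_GROUP_TIME, path)


def _fit_or_raise(dataset: TrialDataset, spec: ModelSpec, path: str) -> LmmFit:
    fit = fit_lmm(dataset, spec)
    if not fit.converged:
        raise ConvergenceError(
            f"model for path {path} ({spec.outcome!r}) did not converge", path=path
        )
    return fit


def estimate_paths(
    dataset: TrialDataset,
    mediator: str,
    outcome: str,
    *,
    covariance_mode: str = "compound_symmetry",
    adjusted_b: bool = True,
) -> MediationPaths:
    """Fit the three path models and return the four path estimates.

    ``adjusted_b=False`` reads path b from a plain mediator-outcome
    association model instead of the multivariable c' model; the default
    (adjusted) reading follows standard causal-steps practice.

    Mediator and outcome are just variable names: swapping them runs the
    reverse-direction (exploratory) mediation with no special handling.
    """
    fit_m = _fit_or_raise(
        dataset, ModelSpec(outcome=mediator, covariance_mode=covariance_mode), "a"
    )
    fit_y = _fit_or_raise(
        dataset, ModelSpec(outcome=outcome, covariance_mode=covariance_mode), "c"
    )
    fit_yc = _fit_or_raise(
        dataset,
        ModelSpec(outcome=outcome, mediator=mediator, covariance_mode=covariance_mode),
        "c_prime",
    )
    if adjusted_b:
        b_coef = fit_yc.coefficients[TERM_MEDIATOR]
    else:
        fit_b = _fit_or_raise(
            dataset,
            ModelSpec(
                outcome=outcome,
                mediator=mediator,
                covariance_mode=covariance_mode,
                include_group_terms=False,
            ),
            "b",
        )
        b_coef = fit_b.coefficients[TERM_MEDIATOR]
    return MediationPaths(
        a=_did_path(fit_m, "a"),
        b=PathEstimate(
            b_coef.estimate, b_coef.se, b_coef.p_value, b_coef.ci95,
            TERM_MEDIATOR, "b",
        ),
        c=_did_path(fit_y, "c"),
        c_prime=_did_path(fit_yc, "c_prime"),
    )


def gate(paths: MediationPaths, alpha: float = DEFAULT_GATE_ALPHA) -> GateDecision:
    """Apply the causal-steps gate with strict inequality P < alpha."""
    return GateDecision(
        passed_a=paths.a.p_value < alpha,
        passed_b=paths.b.p_value < alpha,
        passed_c=paths.c.p_value < alpha,
        alpha=alpha,
    )


def indirect_effect(c_est: PathEstimate, cprime_est: PathEstimate) -> float:
    """Indirect effect by the difference-of-coefficients method: c - c'."""
    return c_est.beta - cprime_est.beta


def pair_seed(master_seed: int, mediator: str, outcome: str) -> np.random.SeedSequence:
    """Deterministic per-pair random substream.

    Mixing the master seed with a CRC of the pair's names means adding or
    removing one pair from an analysis never perturbs any other pair's
    bootstrap draws.
    """
    tag = zlib.crc32(f"{mediator}->{outcome}".encode("utf-8"))
    return np.random.SeedSequence([int(master_seed), tag])
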