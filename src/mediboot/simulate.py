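"""Monte-Carlo calibration harnesses built on the synthetic generator.

These run many independent synthetic trials through the real pipeline to
measure operating characteristics: parameter recovery of the indirect
effect, percentile-CI coverage at the trial's own design size, and the
false-positive rate of the gate-plus-bootstrap procedure under a null
model.  They back both the test suite and the ``mediboot calibrate``
command.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .bootstrap_ci import BootstrapConfig, bootstrap_indirect, decide_significance
from .mediation import estimate_paths, gate, indirect_effect
from .synthetic_trial import SyntheticSpec, generate

__all__ = [
    "indirect_consistency",
    "coverage_simulation",
    "null_simulation",
]


def _trial_seed(master: int, rep: int) -> int:
    # independent per-replicate seeds below 2**31
    return int(np.random.SeedSequence([int(master), rep]).generate_state(1)[0] % (2**31))


def indirect_consistency(
    spec: SyntheticSpec, n_reps: int = 100, seed: int = 0
) -> dict:
    """Estimate c - c' across replicate trials and compare with a * b.

    Returns the Monte-Carlo mean and SE of the difference-of-coefficients
    indirect effect, and of its per-replicate disagreement with the
    product-of-coefficients estimator computed on the same data.
    """
    diffs = np.empty(n_reps)
    prods = np.empty(n_reps)
    for r in range(n_reps):
        ds = generate(replace(spec, seed=_trial_seed(seed, r)))
        paths = estimate_paths(ds, "mediator", "outcome")
        diffs[r] = indirect_effect(paths.c, paths.c_prime)
        prods[r] = paths.a.beta * paths.b.beta
    delta = diffs - prods
    return {
        "true_indirect": spec.indirect_effect,
        "mean_indirect": float(diffs.mean()),
        "se_indirect": float(diffs.std(ddof=1) / np.sqrt(n_reps)),
        "mean_diff_vs_product": float(delta.mean()),
        "se_diff_vs_product": float(delta.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def coverage_simulation(
    spec: SyntheticSpec,
    n_trials: int = 100,
    n_boot: int = 199,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Fraction of replicate trials whose percentile CI covers a * b.

    The CI is computed for every trial (no gate), since coverage is a
    property of the interval itself.
    """
    true = spec.indirect_effect
    covered = 0
    for r in range(n_trials):
        s = _trial_seed(seed, r)
        ds = generate(replace(spec, seed=s))
        dist = bootstrap_indirect(
            ds, "mediator", "outcome",
            BootstrapConfig(n_boot=n_boot, level=level, seed=s),
        )
        lo, hi = dist.ci(level)
        if lo <= true <= hi:
            covered += 1
    return {
        "true_indirect": true,
        "coverage": covered / n_trials,
        "n_trials": n_trials,
        "n_boot": n_boot,
        "level": level,
    }


def null_simulation(
    spec: SyntheticSpec | None = None,
    n_trials: int = 100,
    n_boot: int = 199,
    alpha_gate: float = 0.10,
    seed: int = 0,
) -> dict:
    """False-positive rate of the full gated procedure under no mediation.

    Each trial is generated with a = b = direct = 0; a false positive is a
    trial where the gate passes *and* the bootstrap CI excludes zero.
    """
    base = spec or SyntheticSpec()
    base = replace(base, a_effect=0.0, b_effect=0.0, direct_effect=0.0)
    n_gate_passed = 0
    n_significant = 0
    for r in range(n_trials):
        s = _trial_seed(seed, r)
        ds = generate(replace(base, seed=s))
        paths = estimate_paths(ds, "mediator", "outcome")
        decision = gate(paths, alpha_gate)
        if not decision.proceed:
            continue
        n_gate_passed += 1
        dist = bootstrap_indirect(
            ds, "mediator", "outcome",
            BootstrapConfig(n_boot=n_boot, seed=s),
        )
        if decide_significance(dist.ci()):
            n_significant += 1
    return {
        "n_trials": n_trials,
        "n_gate_passed": n_gate_passed,
        "n_significant": n_significant,
        "false_positive_rate": n_significant / n_trials,
        "alpha_gate": alpha_gate,
    }
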