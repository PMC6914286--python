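"""Subject-resampling (cluster) bootstrap of the indirect effect.

The resampling unit is the whole subject: every draw carries both of the
subject's timepoints, which preserves the within-subject correlation that
the random-intercept model relies on.  Resampling is stratified by arm by
default, so every replicate reproduces the trial's per-arm allocation.  Each
replicate refits the total-effect (c) and direct-effect (c') models and
records c - c'; the percentile interval of that sampling distribution is the
reported CI, and mediation is declared significant when the interval
excludes zero strictly.

Replicates whose refit fails to converge are redrawn a bounded number of
times and then counted as failed - failures are reported, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError, InputError
from .lmm_engine import _fit_core
from .mediation import pair_seed
from .trial_data import TrialDataset

__all__ = [
    "BootstrapConfig",
    "BootstrapDistribution",
    "bootstrap_indirect",
    "percentile_ci",
    "decide_significance",
]

#: Fraction of failed replicates above which a warning is attached.
FAILURE_WARN_FRACTION = 0.10


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    200 replicates is the historical default for this design; for production
    analyses >= 1999 replicates is recommended so the percentile bounds are
    order statistics rather than interpolations deep in the tails.
    """

    n_boot: int = 200
    level: float = 0.95
    seed: int = 0
    stratified: bool = True
    max_retries_per_replicate: int = 5

    def __post_init__(self):
        if self.n_boot < 2:
            raise DomainError("n_boot must be at least 2")
        if not 0.0 < self.level < 1.0:
            raise DomainError("CI level must be in (0, 1)")


@dataclass
class BootstrapDistribution:
    """The bootstrap sampling distribution of the indirect effect."""

    samples: np.ndarray
    point_estimate: float
    n_failed: int = 0
    warnings: list[str] = field(default_factory=list)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        return percentile_ci(self.samples, level)


class _RowSet:
    """Rows of one model's design, grouped by subject for fast resampling.

    Rows are stored sorted by subject; ``indptr`` delimits each subject's
    contiguous block so a bootstrap replicate is assembled with pure array
    gathers (no per-subject Python loop).
    """

    def __init__(self, frame: pd.DataFrame, subj_codes: pd.Series, n_subjects: int,
                 mediator_col: str | None, outcome_col: str):
        order = np.argsort(subj_codes.to_numpy(), kind="stable")
        f = frame.iloc[order]
        sc = subj_codes.to_numpy()[order]
        self.y = f[outcome_col].to_numpy(dtype=float)
        g = f["arm"].to_numpy(dtype=float)
        t = f["timepoint"].to_numpy(dtype=float)
        cols = [np.ones(len(f)), g, t, g * t]
        if mediator_col is not None:
            cols.append(f[mediator_col].to_numpy(dtype=float))
        self.X = np.column_stack(cols)
        self.time = f["timepoint"].to_numpy(dtype=int)
        counts = np.bincount(sc, minlength=n_subjects)
        self.counts = counts
        self.indptr = np.concatenate([[0], np.cumsum(counts)])

    def gather(self, draws: np.ndarray):
        """Rows for the drawn subjects, relabelled 0..len(draws)-1."""
        lens = self.counts[draws]
        starts = self.indptr[draws]
        tot = int(lens.sum())
        offs = np.arange(tot) - np.repeat(np.cumsum(lens) - lens, lens)
        rows = np.repeat(starts, lens) + offs
        new_subj = np.repeat(np.arange(len(draws)), lens)
        return self.y[rows], self.X[rows], new_subj, self.time[rows]


def _indirect_from_rowsets(rs_c: _RowSet, rs_cp: _RowSet, draws: np.ndarray,
                           *, het: bool) -> tuple[float, bool]:
    y, X, s, t = rs_c.gather(draws)
    fit_c = _fit_core(y, X, s, t, het=het)
    y, X, s, t = rs_cp.gather(draws)
    fit_cp = _fit_core(y, X, s, t, het=het)
    ok = fit_c.converged and fit_cp.converged
    # group:time is design column 3 in both models
    return float(fit_c.beta[3] - fit_cp.beta[3]), ok


def bootstrap_indirect(
    dataset: TrialDataset,
    mediator: str,
    outcome: str,
    config: BootstrapConfig = BootstrapConfig(),
    *,
    covariance_mode: str = "compound_symmetry",
) -> BootstrapDistribution:
    """Bootstrap the indirect effect c - c' for one (mediator, outcome) pair.

    Fully reproducible: the random stream is derived from ``config.seed``
    and the pair's names, so each pair owns an isolated substream.
    """
    for var in (mediator, outcome):
        if dataset.transforms.get(var) == "log" and not dataset.transformed:
            raise ContractError(
                f"variable {var!r} needs its log transform applied before "
                "bootstrapping"
            )
    wide = dataset.wide([mediator, outcome])
    subjects = wide[["subject_id", "arm"]].drop_duplicates().reset_index(drop=True)
    n_subjects = len(subjects)
    code_of = {s: i for i, s in enumerate(subjects["subject_id"])}
    arm = subjects["arm"].to_numpy()

    frame_c = wide.dropna(subset=[outcome])
    frame_cp = wide.dropna(subset=[outcome, mediator])
    if frame_c.empty or frame_cp.empty:
        raise InputError("no usable rows for bootstrap models")
    rs_c = _RowSet(frame_c, frame_c["subject_id"].map(code_of), n_subjects,
                   None, outcome)
    rs_cp = _RowSet(frame_cp, frame_cp["subject_id"].map(code_of), n_subjects,
                    mediator, outcome)
    het = covariance_mode == "heteroscedastic_time"

    all_idx = np.arange(n_subjects)
    point, ok = _indirect_from_rowsets(rs_c, rs_cp, all_idx, het=het)
    if not ok:
        raise ContractError("full-data models did not converge; cannot bootstrap")

    rng = np.random.default_rng(pair_seed(config.seed, mediator, outcome))
    idx_ctrl = all_idx[arm == 0]
    idx_exer = all_idx[arm == 1]

    def draw() -> np.ndarray:
        if config.stratified:
            return np.concatenate([
                rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True),
                rng.choice(idx_exer, size=len(idx_exer), replace=True),
            ])
        return rng.choice(all_idx, size=n_subjects, replace=True)

    samples: list[float] = []
    n_failed = 0
    for _ in range(config.n_boot):
        value, ok = _indirect_from_rowsets(rs_c, rs_cp, draw(), het=het)
        retries = 0
        while not ok and retries < config.max_retries_per_replicate:
            value, ok = _indirect_from_rowsets(rs_c, rs_cp, draw(), het=het)
            retries += 1
        if ok:
            samples.append(value)
        else:
            n_failed += 1

    dist = BootstrapDistribution(
        samples=np.asarray(samples), point_estimate=point, n_failed=n_failed
    )
    if n_failed > FAILURE_WARN_FRACTION * config.n_boot:
        dist.warnings.append(
            f"{n_failed}/{config.n_boot} bootstrap replicates failed to "
            "converge after retries"
        )
    return dist


def percentile_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval: empirical (1-level)/2 and (1+level)/2
    quantiles with linear interpolation between order statistics."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise InputError("percentile CI needs at least 2 samples")
    if not 0.0 < level < 1.0:
        raise DomainError("CI level must be in (0, 1)")
    lo, hi = np.quantile(arr, [(1.0 - level) / 2.0, (1.0 + level) / 2.0],
                         method="linear")
    return float(lo), float(hi)


def decide_significance(ci: tuple[float, float]) -> bool:
    """True iff zero lies strictly outside the interval."""
    lo, hi = ci
    return bool(lo > 0.0 or hi < 0.0)
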