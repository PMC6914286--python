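"""Pipeline orchestration and report rendering.

``run_pipeline`` drives the whole analysis for a configured set of
(mediator, outcome) pairs: apply transforms, fit the three path models per
pair, apply the significance gate, bootstrap the gated pairs, and collect
everything - together with baseline between-arm comparisons - into a
:class:`ReportTable` that renders deterministically as text, TSV or JSON.

Conventions mirror small-trial reporting practice: baseline continuous
variables get per-arm mean (SD) with a Welch t-test, categorical variables
get counts (%) with a chi-square test (no continuity correction), mediation
rows show the four path coefficients with solid/dashed significance markers,
and no multiplicity adjustment is applied - the number of pairs tested is
printed instead.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap_ci import BootstrapConfig, bootstrap_indirect, decide_significance
from .errors import InputError, MedibootError
from .mediation import (
    DEFAULT_GATE_ALPHA,
    MediationResult,
    estimate_paths,
    gate,
    indirect_effect,
)
from .synthetic_trial import SyntheticSpec, generate
from .trial_data import TrialDataset, read_long_csv

logger = logging.getLogger("mediboot")

__all__ = [
    "AnalysisConfig",
    "BaselineRow",
    "MediationRow",
    "ReportTable",
    "baseline_table",
    "analyze_pair",
    "run_pipeline",
    "render_report",
]


@dataclass
class AnalysisConfig:
    """Everything needed to run one full analysis.

    Exactly one of ``input_path`` and ``synthetic`` must be given.
    ``reverse_pairs`` lists (mediator, outcome) tuples analysed with roles
    swapped relative to the main direction (exploratory reverse mediation);
    they use the same machinery, only the names differ.
    """

    input_path: str | None = None
    synthetic: SyntheticSpec | None = None
    roles: dict[str, str] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)
    mediators: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    reverse_pairs: list[tuple[str, str]] = field(default_factory=list)
    categorical: list[str] = field(default_factory=list)
    alpha_gate: float = DEFAULT_GATE_ALPHA
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    covariance_mode: str = "compound_symmetry"
    output_dir: str | None = None

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise InputError("provide exactly one of input_path or synthetic")
        overlap = set(self.mediators) & set(self.outcomes)
        if overlap:
            raise InputError(
                f"mediators and outcomes must be disjoint; both list {sorted(overlap)}"
            )


@dataclass
class BaselineRow:
    variable: str
    kind: str  # continuous | categorical
    control: str
    exercise: str
    pooled: str
    p_value: float | None
    note: str = ""


@dataclass
class MediationRow:
    mediator: str
    outcome: str
    direction: str  # forward | reverse
    beta_a: float | None = None
    p_a: float | None = None
    beta_b: float | None = None
    p_b: float | None = None
    beta_c: float | None = None
    p_c: float | None = None
    beta_c_prime: float | None = None
    p_c_prime: float | None = None
    passed_a: bool | None = None
    passed_b: bool | None = None
    passed_c: bool | None = None
    proceed: bool | None = None
    indirect: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    significant: bool | None = None
    n_boot: int = 0
    n_failed: int = 0
    error: str = ""


@dataclass
class ReportTable:
    baseline: list[BaselineRow] = field(default_factory=list)
    mediation: list[MediationRow] = field(default_factory=list)
    n_pairs_tested: int = 0
    alpha_gate: float = DEFAULT_GATE_ALPHA


def _fmt_mean_sd(values: np.ndarray) -> str:
    sd = values.std(ddof=1) if len(values) > 1 else float("nan")
    return f"{values.mean():.2f} ({sd:.2f})"


def baseline_table(
    dataset: TrialDataset,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    *,
    pooled_t: bool = False,
) -> list[BaselineRow]:
    """Between-arm baseline comparisons.

    Continuous variables: per-arm and pooled mean (SD) plus a two-sided
    t-test P (Welch by default; ``pooled_t=True`` switches to the
    pooled-variance test).  Categorical variables: per-arm counts (%) plus a
    chi-square P without continuity correction; a single-level variable gets
    a note instead of a test.
    """
    base = dataset.data[dataset.data["timepoint"] == 0]
    rows: list[BaselineRow] = []
    for var in continuous:
        sub = base[base["variable"] == var]
        if sub.empty:
            raise InputError(f"no baseline records for variable {var!r}")
        ctrl = sub.loc[sub["arm"] == 0, "value"].to_numpy()
        exer = sub.loc[sub["arm"] == 1, "value"].to_numpy()
        _, p = stats.ttest_ind(exer, ctrl, equal_var=bool(pooled_t))
        rows.append(
            BaselineRow(
                variable=var, kind="continuous",
                control=_fmt_mean_sd(ctrl), exercise=_fmt_mean_sd(exer),
                pooled=_fmt_mean_sd(sub["value"].to_numpy()),
                p_value=float(p),
            )
        )
    for var in categorical:
        sub = base[base["variable"] == var]
        if sub.empty:
            raise InputError(f"no baseline records for variable {var!r}")
        table = pd.crosstab(sub["value"], sub["arm"])
        def fmt(arm_code: int) -> str:
            col = table[arm_code] if arm_code in table else pd.Series(0, index=table.index)
            tot = col.sum()
            return "; ".join(
                f"{lvl}: {int(cnt)} ({100.0 * cnt / tot:.0f}%)"
                for lvl, cnt in col.items()
            )
        pooled_counts = table.sum(axis=1)
        pooled = "; ".join(
            f"{lvl}: {int(cnt)} ({100.0 * cnt / pooled_counts.sum():.0f}%)"
            for lvl, cnt in pooled_counts.items()
        )
        if len(table.index) < 2:
            rows.append(
                BaselineRow(var, "categorical", fmt(0), fmt(1), pooled, None,
                            note="single level; comparison skipped")
            )
            continue
        chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
        note = ""
        if (expected < 5).any():
            note = "expected count < 5 in some cells"
        rows.append(BaselineRow(var, "categorical", fmt(0), fmt(1), pooled,
                                float(p), note=note))
    return rows


def analyze_pair(
    dataset: TrialDataset,
    mediator: str,
    outcome: str,
    *,
    alpha_gate: float = DEFAULT_GATE_ALPHA,
    bootstrap: BootstrapConfig = BootstrapConfig(),
    covariance_mode: str = "compound_symmetry",
) -> MediationResult:
    """Paths, gate, and (if gated in) the bootstrap CI for one pair."""
    paths = estimate_paths(dataset, mediator, outcome,
                           covariance_mode=covariance_mode)
    decision = gate(paths, alpha_gate)
    result = MediationResult(
        mediator=mediator, outcome=outcome, paths=paths, gate=decision,
        indirect=indirect_effect(paths.c, paths.c_prime), seed=bootstrap.seed,
    )
    if decision.proceed:
        dist = bootstrap_indirect(dataset, mediator, outcome, bootstrap,
                                  covariance_mode=covariance_mode)
        ci = dist.ci(bootstrap.level)
        result.boot_ci95 = ci
        result.n_boot = len(dist.samples)
        result.n_failed = dist.n_failed
        result.significant = decide_significance(ci)
    return result


def _row_from_result(res: MediationResult, direction: str) -> MediationRow:
    row = MediationRow(
        mediator=res.mediator, outcome=res.outcome, direction=direction,
        beta_a=res.paths.a.beta, p_a=res.paths.a.p_value,
        beta_b=res.paths.b.beta, p_b=res.paths.b.p_value,
        beta_c=res.paths.c.beta, p_c=res.paths.c.p_value,
        beta_c_prime=res.paths.c_prime.beta, p_c_prime=res.paths.c_prime.p_value,
        passed_a=res.gate.passed_a, passed_b=res.gate.passed_b,
        passed_c=res.gate.passed_c, proceed=res.gate.proceed,
        indirect=res.indirect,
        n_boot=res.n_boot, n_failed=res.n_failed,
    )
    if res.boot_ci95 is not None:
        row.ci_low, row.ci_high = res.boot_ci95
        row.significant = res.significant
    return row


def load_dataset(config: AnalysisConfig) -> TrialDataset:
    if config.input_path is not None:
        return read_long_csv(config.input_path, config.roles, config.transforms)
    ds = generate(config.synthetic)
    if config.roles:
        ds.roles.update(config.roles)
    if config.transforms:
        ds.transforms.update(config.transforms)
    return ds


def run_pipeline(config: AnalysisConfig) -> ReportTable:
    """Run the configured analysis end to end.

    All randomized subjects enter every model (intent-to-treat; dropouts
    contribute their baseline rows).  A fit failure in one pair is recorded
    on that pair's row and does not stop the others.  If ``output_dir`` is
    set, the text, TSV and JSON renderings are written there.
    """
    dataset = load_dataset(config).apply_transforms()
    mediators = config.mediators or [
        v for v, r in dataset.roles.items() if r == "mediator"
    ]
    outcomes = config.outcomes or [
        v for v, r in dataset.roles.items() if r == "outcome"
    ]
    if not mediators or not outcomes:
        raise InputError(
            "no mediators/outcomes configured and none derivable from roles"
        )
    continuous = [v for v in mediators + outcomes if v not in config.categorical]

    table = ReportTable(alpha_gate=config.alpha_gate)
    table.baseline = baseline_table(dataset, continuous, config.categorical)

    pairs = [(m, o, "forward") for m in mediators for o in outcomes]
    pairs += [(m, o, "reverse") for m, o in config.reverse_pairs]
    table.n_pairs_tested = len(pairs)

    for mediator, outcome, direction in pairs:
        t0 = _time.perf_counter()
        try:
            res = analyze_pair(
                dataset, mediator, outcome,
                alpha_gate=config.alpha_gate, bootstrap=config.bootstrap,
                covariance_mode=config.covariance_mode,
            )
            row = _row_from_result(res, direction)
        except MedibootError as exc:
            logger.warning("pair (%s, %s) failed: %s", mediator, outcome, exc)
            row = MediationRow(mediator=mediator, outcome=outcome,
                               direction=direction, error=str(exc))
        logger.info(
            "pair (%s, %s): proceed=%s, %.3fs",
            mediator, outcome, row.proceed, _time.perf_counter() - t0,
        )
        table.mediation.append(row)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fmt, name in (("text", "report.txt"), ("tsv", "report.tsv"),
                          ("json", "report.json")):
            (outdir / name).write_text(render_report(table, fmt))
    return table


# -- rendering -----------------------------------------------------------

_MED_COLUMNS = [
    "mediator", "outcome", "direction",
    "beta_a", "p_a", "beta_b", "p_b", "beta_c", "p_c",
    "beta_c_prime", "p_c_prime",
    "passed_a", "passed_b", "passed_c", "proceed",
    "indirect", "ci_low", "ci_high", "significant",
    "n_boot", "n_failed", "error",
]


def _r2(x):
    if x is None:
        return None
    if isinstance(x, bool):
        return x
    if isinstance(x, float):
        if not np.isfinite(x):
            return None
        return round(x, 2)
    return x


def _table_dict(table: ReportTable) -> dict:
    return {
        "alpha_gate": table.alpha_gate,
        "n_pairs_tested": table.n_pairs_tested,
        "baseline": [
            {
                "variable": r.variable, "kind": r.kind, "control": r.control,
                "exercise": r.exercise, "pooled": r.pooled,
                "p_value": _r2(r.p_value), "note": r.note,
            }
            for r in table.baseline
        ],
        "mediation": [
            {col: _r2(getattr(r, col)) for col in _MED_COLUMNS}
            for r in table.mediation
        ],
    }


def _marker(p: float | None, alpha: float) -> str:
    if p is None:
        return "?"
    return "solid" if p < alpha else "dashed"


def render_report(table: ReportTable, format: str = "text") -> str:
    """Render deterministically; numbers at 2 decimals in every format."""
    if format == "json":
        return json.dumps(_table_dict(table), indent=2) + "\n"

    if format == "tsv":
        buf = StringIO()
        d = _table_dict(table)
        print("# baseline", file=buf)
        base_cols = ["variable", "kind", "control", "exercise", "pooled",
                     "p_value", "note"]
        print("\t".join(base_cols), file=buf)
        for r in d["baseline"]:
            print("\t".join("" if r[c] is None else str(r[c]) for c in base_cols),
                  file=buf)
        print("# mediation", file=buf)
        print("\t".join(_MED_COLUMNS), file=buf)
        for r in d["mediation"]:
            print("\t".join("" if r[c] is None else str(r[c]) for c in _MED_COLUMNS),
                  file=buf)
        return buf.getvalue()

    if format == "text":
        buf = StringIO()
        a = table.alpha_gate
        print("Baseline comparisons (t test / chi-square)", file=buf)
        for r in table.baseline:
            p = "" if r.p_value is None else f"  P={r.p_value:.2f}"
            note = f"  [{r.note}]" if r.note else ""
            print(f"  {r.variable:<24} control {r.control:<16} "
                  f"exercise {r.exercise:<16} pooled {r.pooled}{p}{note}",
                  file=buf)
        print(file=buf)
        print(f"Mediation results ({table.n_pairs_tested} pairs tested, "
              f"gate P<{a:g}, no multiplicity adjustment)", file=buf)
        for r in table.mediation:
            print(f"  {r.mediator} -> {r.outcome} ({r.direction})", file=buf)
            if r.error:
                print(f"    failed: {r.error}", file=buf)
                continue
            for label, beta, p in (
                ("a", r.beta_a, r.p_a), ("b", r.beta_b, r.p_b),
                ("c", r.beta_c, r.p_c), ("c'", r.beta_c_prime, r.p_c_prime),
            ):
                print(f"    path {label:<2} beta={beta:>7.2f}  P={p:.2f}  "
                      f"[{_marker(p, a)}]", file=buf)
            if r.proceed:
                sig = "significant" if r.significant else "not significant"
                print(f"    indirect (c-c') = {r.indirect:.2f}, bootstrap "
                      f"95% CI {r.ci_low:.2f} to {r.ci_high:.2f} ({sig}; "
                      f"{r.n_boot} replicates, {r.n_failed} failed)", file=buf)
            else:
                print(f"    indirect (c-c') = {r.indirect:.2f}; gate not met, "
                      "no bootstrap CI", file=buf)
        return buf.getvalue()

    raise InputError(f"unknown report format {format!r}")
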