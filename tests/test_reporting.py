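import json

import numpy as np
import pytest

from mediboot import (
    AnalysisConfig,
    BootstrapConfig,
    InputError,
    ReportTable,
    baseline_table,
    render_report,
    run_pipeline,
)
from mediboot.synthetic_trial import SyntheticSpec, generate

from conftest import make_dataset


def baseline_only(values_by_arm, variable):
    records = []
    for arm, values in values_by_arm.items():
        for i, v in enumerate(values):
            records.append((f"A{arm}S{i:03d}", arm, 0, variable, v))
    return make_dataset(records)


def symmetric_values(mean, n, spread=5.0):
    return mean + np.linspace(-spread, spread, n)


class TestBaselineTable:
    def test_identical_arms_give_p_one(self):
        vals = [48.0, 50.0, 52.0, 55.0]
        ds = baseline_only({0: vals, 1: vals}, "anxiety")
        (row,) = baseline_table(ds, continuous=["anxiety"])
        assert row.p_value == pytest.approx(1.0)

    def test_pooled_mean_from_per_arm_means(self):
        # exercise mean 54.8 (n=43), control mean 55.6 (n=44):
        # weighted pooled mean = (43*54.8 + 44*55.6) / 87 = 55.2
        ds = baseline_only(
            {0: symmetric_values(55.6, 44), 1: symmetric_values(54.8, 43)},
            "anxiety",
        )
        (row,) = baseline_table(ds, continuous=["anxiety"])
        pooled_mean = float(row.pooled.split()[0])
        assert round(pooled_mean, 1) == 55.2

    def test_balanced_categorical_gives_p_one(self):
        ds = baseline_only(
            {0: [0.0] * 10 + [1.0] * 10, 1: [0.0] * 10 + [1.0] * 10},
            "employed",
        )
        (row,) = baseline_table(ds, categorical=["employed"])
        assert row.p_value == pytest.approx(1.0)
        assert "10 (50%)" in row.control

    def test_single_level_categorical_skipped(self):
        ds = baseline_only({0: [1.0] * 5, 1: [1.0] * 5}, "stage")
        (row,) = baseline_table(ds, categorical=["stage"])
        assert row.p_value is None
        assert "skipped" in row.note

    def test_welch_vs_pooled_option(self):
        ds = baseline_only(
            {0: symmetric_values(50, 30, spread=2),
             1: symmetric_values(51, 10, spread=12)},
            "x",
        )
        (welch,) = baseline_table(ds, continuous=["x"])
        (pooled,) = baseline_table(ds, continuous=["x"], pooled_t=True)
        assert welch.p_value != pooled.p_value

    def test_missing_variable_rejected(self):
        ds = baseline_only({0: [1.0], 1: [2.0]}, "x")
        with pytest.raises(InputError):
            baseline_table(ds, continuous=["y"])


STRONG = SyntheticSpec(a_effect=-6.0, b_effect=0.6, direct_effect=-1.0, seed=14)


def write_multi_trial(tmp_path, with_nulls=True):
    kwargs = {}
    if with_nulls:
        kwargs = dict(
            null_mediators=("depression", "fatigue", "physical_functioning",
                            "bdnf", "crp", "homa2_ir"),
            null_outcomes=("processing_speed",),
        )
    ds = generate(STRONG, mediator_name="anxiety",
                  outcome_name="cognitive_abilities", **kwargs)
    path = tmp_path / "trial.csv"
    ds.write_long_csv(path)
    return path, ds


class TestRunPipeline:
    def test_pair_cardinality(self, tmp_path):
        path, ds = write_multi_trial(tmp_path)
        config = AnalysisConfig(
            input_path=str(path), roles=ds.roles, transforms=ds.transforms,
            bootstrap=BootstrapConfig(n_boot=30, seed=5),
        )
        table = run_pipeline(config)
        assert table.n_pairs_tested == 14  # 7 mediators x 2 outcomes
        assert len(table.mediation) == 14
        gated_out = [r for r in table.mediation if not r.proceed]
        for row in gated_out:
            assert row.ci_low is None and row.significant is None
            assert row.beta_a is not None  # paths shown even when gate fails

    def test_reverse_pairs_run_with_roles_swapped(self, tmp_path):
        path, ds = write_multi_trial(tmp_path, with_nulls=False)
        config = AnalysisConfig(
            input_path=str(path), roles=ds.roles, transforms=ds.transforms,
            reverse_pairs=[("cognitive_abilities", "anxiety")],
            bootstrap=BootstrapConfig(n_boot=30, seed=5),
        )
        table = run_pipeline(config)
        directions = {(r.mediator, r.outcome): r.direction for r in table.mediation}
        assert directions[("anxiety", "cognitive_abilities")] == "forward"
        assert directions[("cognitive_abilities", "anxiety")] == "reverse"

    def test_byte_identical_reports_for_same_config_and_seed(self, tmp_path):
        path, ds = write_multi_trial(tmp_path, with_nulls=False)

        def run():
            config = AnalysisConfig(
                input_path=str(path), roles=ds.roles, transforms=ds.transforms,
                bootstrap=BootstrapConfig(n_boot=60, seed=7),
            )
            return render_report(run_pipeline(config), "text")

        assert run() == run()

    def test_row_order_invariance(self, tmp_path):
        path, ds = write_multi_trial(tmp_path, with_nulls=False)
        shuffled = ds.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        spath = tmp_path / "shuffled.csv"
        shuffled.to_csv(spath, index=False)

        def run(p):
            config = AnalysisConfig(
                input_path=str(p), roles=ds.roles, transforms=ds.transforms,
                bootstrap=BootstrapConfig(n_boot=40, seed=7),
            )
            return render_report(run_pipeline(config), "text")

        assert run(path) == run(spath)

    def test_pair_removal_leaves_other_pairs_unchanged(self, tmp_path):
        path, ds = write_multi_trial(tmp_path)
        common = dict(input_path=str(path), roles=ds.roles,
                      transforms=ds.transforms)

        def anxiety_row(mediators):
            config = AnalysisConfig(
                mediators=mediators, outcomes=["cognitive_abilities"],
                bootstrap=BootstrapConfig(n_boot=60, seed=7), **common,
            )
            table = run_pipeline(config)
            return next(r for r in table.mediation if r.mediator == "anxiety")

        full = anxiety_row(["anxiety", "depression", "fatigue"])
        alone = anxiety_row(["anxiety"])
        assert full.proceed  # strong synthetic effects pass the gate
        assert full.__dict__ == alone.__dict__

    def test_requires_exactly_one_input(self):
        with pytest.raises(InputError):
            AnalysisConfig()
        with pytest.raises(InputError):
            AnalysisConfig(input_path="x", synthetic=SyntheticSpec())

    def test_mediators_outcomes_must_be_disjoint(self):
        with pytest.raises(InputError, match="disjoint"):
            AnalysisConfig(synthetic=SyntheticSpec(),
                           mediators=["x"], outcomes=["x"])


class TestRenderReport:
    def test_empty_table_renders_headers(self):
        table = ReportTable()
        tsv = render_report(table, "tsv")
        assert "# mediation" in tsv and "mediator\toutcome" in tsv
        data = json.loads(render_report(table, "json"))
        assert data["mediation"] == []

    def test_unknown_format_rejected(self):
        with pytest.raises(InputError):
            render_report(ReportTable(), "pdf")

    def test_solid_dashed_markers(self, tmp_path):
        path, ds = write_multi_trial(tmp_path, with_nulls=False)
        config = AnalysisConfig(
            input_path=str(path), roles=ds.roles, transforms=ds.transforms,
            bootstrap=BootstrapConfig(n_boot=30, seed=5),
        )
        text = render_report(run_pipeline(config), "text")
        assert "[solid]" in text or "[dashed]" in text

    def test_tsv_json_round_trip(self, tmp_path):
        path, ds = write_multi_trial(tmp_path)
        config = AnalysisConfig(
            input_path=str(path), roles=ds.roles, transforms=ds.transforms,
            bootstrap=BootstrapConfig(n_boot=30, seed=5),
        )
        table = run_pipeline(config)
        data = json.loads(render_report(table, "json"))
        lines = render_report(table, "tsv").splitlines()
        start = lines.index("# mediation") + 1
        header = lines[start].split("\t")
        rows = [dict(zip(header, l.split("\t"))) for l in lines[start + 1:]]
        assert len(rows) == len(data["mediation"])
        for tsv_row, json_row in zip(rows, data["mediation"]):
            for key, jv in json_row.items():
                tv = tsv_row[key]
                if jv is None:
                    assert tv == ""
                elif isinstance(jv, bool):
                    assert tv == str(jv)
                elif isinstance(jv, float):
                    assert float(tv) == pytest.approx(jv, abs=1e-9)
                else:
                    assert str(jv) == tv
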