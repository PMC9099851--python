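"""Study orchestration: report shape, determinism, graceful failures,
table formatting, config files, CLI."""

import pandas as pd
import pytest

from bifurcbench.flow import SolverError
from bifurcbench.study import (
    RunConfig,
    cfd_profile_cohort,
    format_median_iqr,
    render_tables,
    run_study,
)


@pytest.fixture(scope="module")
def tiny_report():
    cfg = RunConfig(cohort=cfd_profile_cohort(n_per_group=1, seed=3))
    return cfg, run_study(cfg)


class TestRunStudy:
    def test_report_shape(self, tiny_report):
        cfg, rep = tiny_report
        df = rep.per_sample
        assert sorted(df["group"].unique()) == ["BD-DES", "KBI", "KIO"]
        for col in ("A_high_roi_mm2", "shear_max_roi", "pct_floating", "EI",
                    "thrombus_top3_mm2", "damage_cat4", "mass_imbalance"):
            assert col in df.columns
        assert len(df) == 3
        assert len(rep.stats) >= 6
        assert not rep.failures

    def test_every_row_mass_conserving(self, tiny_report):
        _, rep = tiny_report
        assert (rep.per_sample["mass_imbalance"] < 1e-8).all()

    def test_config_hash_traceability(self, tiny_report):
        cfg, rep = tiny_report
        assert (rep.per_sample["config_hash"] == cfg.config_hash()).all()
        assert (rep.stats_frame()["config_hash"] == cfg.config_hash()).all()

    def test_oct_only_rerun_is_deterministic(self, tmp_path):
        # determinism of the study path is cheap to check without CFD
        cfg1 = RunConfig(cohort=cfd_profile_cohort(n_per_group=3, seed=8),
                         do_cfd=False, outdir=str(tmp_path / "a"))
        cfg2 = RunConfig(cohort=cfd_profile_cohort(n_per_group=3, seed=8),
                         do_cfd=False, outdir=str(tmp_path / "b"))
        run_study(cfg1)
        run_study(cfg2)
        a = (tmp_path / "a" / "per_sample.csv").read_text()
        b = (tmp_path / "b" / "per_sample.csv").read_text()
        assert a == b

    def test_failed_sample_dropped_with_warning(self, monkeypatch):
        import bifurcbench.study as study_mod

        calls = {"n": 0}
        real = study_mod.solve_steady_flow

        def flaky(*args, **kwargs):
            calls["n"] += 1
            if calls["n"] == 1:
                raise SolverError("synthetic divergence", [1.0])
            return real(*args, **kwargs)

        monkeypatch.setattr(study_mod, "solve_steady_flow", flaky)
        cfg = RunConfig(cohort=cfd_profile_cohort(n_per_group=2, seed=3))
        rep = run_study(cfg)
        assert len(rep.failures) == 1
        assert len(rep.per_sample) == 5

    def test_group_without_survivors_aborts(self, monkeypatch):
        import bifurcbench.study as study_mod

        def always_fails(*args, **kwargs):
            raise SolverError("synthetic divergence", [1.0])

        monkeypatch.setattr(study_mod, "solve_steady_flow", always_fails)
        cfg = RunConfig(cohort=cfd_profile_cohort(n_per_group=1, seed=3))
        with pytest.raises(RuntimeError, match="no successful samples"):
            run_study(cfg)


class TestRendering:
    def test_median_iqr_formatting_examples(self):
        assert format_median_iqr([1, 2, 3, 4, 5], "count") == "3 (2–4)"
        assert format_median_iqr([7.0], "count") == "7 (7–7)"

    def test_rounding_conventions(self):
        vals = [5.5049, 5.512, 5.52]
        assert format_median_iqr(vals, "mm") == "5.51 (5.51–5.52)"
        assert format_median_iqr([15.93, 12.99, 17.65], "pct") == "15.9 (14.5–16.8)"
        assert format_median_iqr([0.123, 0.127, 0.126], "area") == "0.13 (0.12–0.13)"

    def test_tables_contain_groups_and_p_column(self, tiny_report):
        _, rep = tiny_report
        text = render_tables(rep)
        for lab in ("KIO", "KBI", "BD-DES"):
            assert lab in text
        assert "p (KW)" in text
        assert rep.config_hash in text


class TestConfigFiles:
    def test_ini_round_trip(self, tmp_path):
        from bifurcbench.config import dump_run_config, load_run_config

        cfg = RunConfig(cohort=cfd_profile_cohort(n_per_group=2, seed=4))
        path = tmp_path / "run.ini"
        dump_run_config(cfg, str(path))
        back = load_run_config(str(path))
        assert back.cohort.n_per_group == 2
        assert back.cohort.geometry.L_prox == cfg.cohort.geometry.L_prox
        assert back.mesh.h_max == cfg.mesh.h_max
        assert back.conditions.inlet_mean_velocity == pytest.approx(0.14)

    def test_overrides_applied(self, tmp_path):
        from bifurcbench.config import load_run_config

        path = tmp_path / "run.ini"
        path.write_text(
            "[geometry]\nd_prox = 6.0\n\n[flow]\ninlet_mean_velocity = 0.2\n"
            "\n[metrics]\nshear_threshold = 800\n"
        )
        cfg = load_run_config(str(path))
        assert cfg.cohort.geometry.D_prox == 6.0
        assert cfg.conditions.inlet_mean_velocity == 0.2
        assert cfg.shear_threshold == 800.0


class TestCli:
    def test_synth_writes_cohort(self, tmp_path):
        from click.testing import CliRunner

        from bifurcbench.cli import main

        out = tmp_path / "cohort"
        res = CliRunner().invoke(
            main, ["synth", "--seed", "3", "--n", "1", "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        assert (out / "cohort.json").exists()

    def test_stats_command_on_long_csv(self, tmp_path):
        from click.testing import CliRunner

        from bifurcbench.cli import main

        rows = []
        for g, base in (("KIO", 10.0), ("KBI", 3.0), ("BD-DES", 0.5)):
            for i in range(5):
                rows.append({"sample_id": f"{g}-{i}", "group": g,
                             "metric": "floating_pct", "value": base + 0.1 * i})
        csv = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(csv, index=False)
        res = CliRunner().invoke(main, ["stats", "--csv", str(csv)])
        assert res.exit_code == 0, res.output
        assert "floating_pct" in res.output
        assert "Dunn" in res.output
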