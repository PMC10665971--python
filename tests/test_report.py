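"""Pipeline orchestration, table rendering, plot-data export, CLI plumbing."""

import json
import subprocess
import sys
from pathlib import Path

import numpy as np
import pytest

from rule48.cohort_data import round_half_up
from rule48.report import (
    ConvergenceGateError,
    RunConfig,
    export_plot_data,
    paper_run_config,
    render_table,
    run_pipeline,
    write_artifacts,
)


class TestRunPipeline:
    def test_fixture_produces_full_contrast_set(self, paper_quadrature_bundle):
        bundle = paper_quadrature_bundle
        pp = [c for c in bundle.contrasts if c.scale == "pp"]
        inc = [c for c in bundle.contrasts if c.scale == "per_100_games"]
        assert len(pp) == 16          # one row per published proportion variable
        assert len(inc) == 17         # 16 variables + overall incidence
        assert {c.variable for c in pp} == {
            c.variable for c in inc if c.variable != "overall"
        }

    def test_overall_raw_cells_match_published_rates(self, paper_quadrature_bundle):
        raw = paper_quadrature_bundle.raw
        row = raw[(raw.variable == "overall") & (raw.scale == "per100")].iloc[0]
        assert round_half_up(row.raw_pre) == 6.1
        assert round_half_up(row.raw_post) == 8.3

    def test_identical_configs_give_byte_identical_results(self, tmp_path):
        config = paper_run_config(engine="quadrature", seed=99, scale="pp")
        paths = []
        for name in ("a", "b"):
            bundle = run_pipeline(config)
            out = write_artifacts(bundle, tmp_path / name)
            paths.append(out["results.csv"])
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_missing_counterpart_variable_skipped_with_warning(self, tmp_path):
        counts = tmp_path / "counts.csv"
        counts.write_text(
            "cohort,variable,numerator,denominator,denominator_kind\n"
            "2006-2010,open ice,108,231,events_with_video\n"
            "2014-2019,open ice,167,455,events_with_video\n"
            "2006-2010,glove,8,231,events_with_video\n"
        )
        cohorts = tmp_path / "counts_cohorts.csv"
        cohorts.write_text(
            "label,n_games,n_concussions_total,n_concussions_video\n"
            "2006-2010,4920,301,231\n"
            "2014-2019,6232,516,457\n"
        )
        config = RunConfig(
            counts_path=counts, engine="quadrature", scale="pp", seed=1
        )
        with pytest.warns(UserWarning, match="glove"):
            bundle = run_pipeline(config)
        assert [c.variable for c in bundle.contrasts] == ["open ice"]
        assert any("glove" in w for w in bundle.warnings)

    def test_empty_counts_file_yields_empty_bundle(self, tmp_path):
        counts = tmp_path / "empty.csv"
        counts.write_text("cohort,variable,numerator,denominator,denominator_kind\n")
        with pytest.warns(UserWarning, match="empty"):
            bundle = run_pipeline(RunConfig(counts_path=counts, seed=1))
        assert bundle.contrasts == []
        assert bundle.raw.empty

    def test_mcmc_gate_failure_raises_unless_forced(self, monkeypatch):
        from rule48 import posterior_engine, report

        real = posterior_engine.split_rhat
        monkeypatch.setattr(report, "posterior_mcmc", _broken_mcmc)
        config = paper_run_config(scale="pp", seed=2)
        with pytest.raises(ConvergenceGateError, match="rhat"):
            run_pipeline(config)
        bundle = run_pipeline(config.model_copy(update={"force": True}))
        assert not bundle.all_converged
        assert real is posterior_engine.split_rhat  # sanity: only report patched


def _broken_mcmc(y, n, prior, n_chains=4, iterations=2000, seed=0, variable="", cohort=""):
    """Stub returning deliberately separated chains (diagnostic must fail)."""
    from rule48.posterior_engine import ConvergenceReport, PosteriorDraws, split_rhat

    rng = np.random.default_rng(seed)
    kept = iterations - iterations // 2
    chains = 0.01 * rng.standard_normal((n_chains, kept))
    chains[0] += 5.0
    draws = PosteriorDraws(
        variable=variable, cohort=cohort, draws_logit=chains.reshape(-1),
        engine="mcmc", seed=seed, chains_logit=chains,
    )
    report = ConvergenceReport(split_rhat(chains), n_chains, iterations)
    return draws, report


class TestRendering:
    def test_proportions_table_lateral_row(self, paper_quadrature_bundle):
        text, frame = render_table(paper_quadrature_bundle, "proportions")
        row = frame[frame.characteristic == "lateral hit to head"].iloc[0]
        assert row["2006-2010"] == "80 (34.6)"
        assert row["2014-2019"] == "61 (13.4)"
        assert float(row.iloc[-1].split()[0]) == pytest.approx(-18.8, abs=1.5)
        assert "lateral hit to head" in text

    def test_incidence_table_raw_cells(self, paper_quadrature_bundle):
        _, frame = render_table(paper_quadrature_bundle, "incidence")
        row = frame[frame.characteristic == "overall"].iloc[0]
        assert row["2006-2010"] == "6.1"
        assert row["2014-2019"] == "8.3"

    def test_text_and_csv_carry_identical_numbers(self, paper_quadrature_bundle):
        text, frame = render_table(paper_quadrature_bundle, "proportions")
        for cell in frame.iloc[:, 2:].to_numpy().ravel():
            assert str(cell) in text

    def test_unicode_minus_flag(self, paper_quadrature_bundle):
        _, frame = render_table(paper_quadrature_bundle, "proportions", unicode_minus=True)
        joined = " ".join(frame.iloc[:, -1])
        assert "−" in joined and "-" not in joined.replace("−", "")


class TestPlotData:
    def test_masses_sum_to_one_and_intervals_match(self, paper_quadrature_bundle):
        data = export_plot_data(paper_quadrature_bundle)
        assert data["panels"]
        by_key = {
            (c.variable, "pp" if c.scale == "pp" else "per100"): c
            for c in paper_quadrature_bundle.contrasts
        }
        for key, panel in data["panels"].items():
            variable, scale = key.split("|")
            contrast = by_key[(variable, scale)]
            total = (
                panel["mass_above_zero"] + panel["mass_below_zero"] + panel["mass_at_zero"]
            )
            assert total == pytest.approx(1.0, abs=1e-12)
            assert tuple(panel["cri90"]) == contrast.cri90
            assert tuple(panel["cri70"]) == contrast.cri70

    def test_lateral_shading_mass_is_below_zero(self, paper_quadrature_bundle):
        data = export_plot_data(paper_quadrature_bundle)
        panel = data["panels"]["lateral hit to head|pp"]
        assert panel["mass_below_zero"] == pytest.approx(1.0, abs=0.005)

    def test_discarded_draws_give_actionable_error(self):
        bundle = run_pipeline(
            paper_run_config(engine="quadrature", scale="pp", seed=3, keep_draws=False)
        )
        with pytest.raises(ValueError, match="keep_draws"):
            export_plot_data(bundle)

    def test_plotdata_json_serializable(self, paper_quadrature_bundle):
        json.dumps(export_plot_data(paper_quadrature_bundle))


class TestCli:
    def run_cli(self, *args):
        return subprocess.run(
            [sys.executable, "-m", "rule48.cli", *args],
            capture_output=True, text=True,
        )

    def test_module_invocation_fails_cleanly_without_entrypoint(self):
        # the console script is `rule48`; `python -m rule48.cli --help` also works
        result = self.run_cli("--help")
        assert result.returncode == 0
        assert "fit" in result.stdout and "simulate" in result.stdout

    def test_fit_quadrature_writes_artifacts(self, tmp_path):
        out = tmp_path / "run"
        result = self.run_cli(
            "fit", "--engine", "quadrature", "--scale", "pp",
            "--seed", "5", "--out", str(out),
        )
        assert result.returncode == 0, result.stderr
        for name in ("results.csv", "priors.csv", "diagnostics.json",
                     "table_proportions.txt", "plotdata.json", "run_config.json"):
            assert (out / name).exists(), name

    def test_report_renders_saved_tables(self, tmp_path):
        out = tmp_path / "run"
        self.run_cli("fit", "--engine", "quadrature", "--scale", "pp",
                     "--seed", "5", "--out", str(out))
        result = self.run_cli("report", "--results-dir", str(out))
        assert result.returncode == 0
        assert "lateral hit to head" in result.stdout

    def test_simulate_writes_event_table(self, tmp_path):
        out = tmp_path / "events.csv"
        result = self.run_cli("simulate", "--cohort", "pre", "--seed", "3",
                              "--out", str(out))
        assert result.returncode == 0, result.stderr
        header = out.read_text().splitlines()[0]
        assert header.startswith("game,cohort,event")

    def test_tune_prior_prints_parameters(self):
        result = self.run_cli("tune-prior", "--numerator", "80",
                              "--denominator", "231", "--target", "10")
        assert result.returncode == 0, result.stderr
        assert "sigma=" in result.stdout and "achieved_sd=" in result.stdout
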