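"""Configuration, dispatch, aggregation, I/O, and the parameter search."""

import numpy as np
import pandas as pd
import pytest

from bgrisk import bee, harness
from bgrisk.fitting import SearchConfig, fit_parameters
from bgrisk.params import AgentParams


class TestConfig:
    def test_minimal_config_gets_task_defaults(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: bee\n")
        cfg = harness.load_config(p)
        assert cfg.params == bee.BEE_PARAMS
        assert cfg.n_agents == 1000

    def test_json_accepted(self, tmp_path):
        p = tmp_path / "c.json"
        p.write_text('{"experiment": "rtd", "n_agents": 7}')
        cfg = harness.load_config(p)
        assert cfg.experiment == "rtd" and cfg.n_agents == 7
        assert cfg.params.beta == pytest.approx(0.044)

    def test_invalid_alpha_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: bee\nparams:\n  alpha: -1\n")
        with pytest.raises(ValueError, match="alpha"):
            harness.load_config(p)

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: bee\nbogus: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            harness.load_config(p)
        p.write_text("experiment: bee\nparams:\n  zeta: 1\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            harness.load_config(p)
        p.write_text("experiment: bee\ntask:\n  n_trials_per_state: 5\n")
        with pytest.raises(ValueError, match="unknown task keys"):
            harness.load_config(p)

    def test_unknown_experiment_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("experiment: maze\n")
        with pytest.raises(ValueError, match="experiment"):
            harness.load_config(p)

    def test_round_trip_identity(self, tmp_path):
        cfg = harness.ExperimentConfig(
            experiment="reversal",
            params=AgentParams(alpha=0.3, beta=10.0),
            n_agents=12,
            seed=5,
            task={"alphas": {"balanced": 0.5, "depleted": 0.3}},
        )
        p = tmp_path / "c.yaml"
        harness.save_config(cfg, p)
        assert harness.load_config(p) == cfg


class TestSummarize:
    def test_constant_vector(self):
        assert harness.summarize([0.5, 0.5, 0.5]) == (0.5, 0.0, 3)

    def test_two_points(self):
        m, se, n = harness.summarize([0.0, 1.0])
        assert m == pytest.approx(0.5)
        assert se == pytest.approx(0.5)  # sd = 0.7071, / sqrt(2)
        assert n == 2

    def test_single_value_se_zero(self):
        assert harness.summarize([0.3]) == (0.3, 0.0, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            harness.summarize([])


class TestRunExperiment:
    def _bee_cfg(self, n=40, seed=0):
        return harness.ExperimentConfig(
            experiment="bee", params=bee.BEE_PARAMS, n_agents=n, seed=seed
        )

    def test_bit_reproducible(self):
        a = harness.run_experiment(self._bee_cfg())
        b = harness.run_experiment(self._bee_cfg())
        pd.testing.assert_frame_equal(a, b)

    def test_schema(self):
        df = harness.run_experiment(self._bee_cfg())
        assert list(df.columns) == harness.RESULT_COLUMNS
        assert set(df["condition"]) == {"pre-reversal", "post-reversal"}

    def test_single_agent_se_zero(self):
        df = harness.run_experiment(self._bee_cfg(n=1))
        assert (df["se"] == 0.0).all()

    def test_reversal_dispatch_has_both_conditions(self):
        cfg = harness.ExperimentConfig(
            experiment="reversal",
            params=harness.default_params("reversal"),
            n_agents=3,
            seed=1,
        )
        df = harness.run_experiment(cfg)
        assert set(df["condition"]) == {"balanced", "depleted"}

    def test_se_scales_with_agent_count(self):
        """SE of the pre-reversal choice rate shrinks like 1/sqrt(N).

        Estimated by averaging the reported SE over disjoint agent
        groups of each size (a single group's sample SD is too noisy
        to resolve the ratio)."""
        res = bee.run_bee_experiment(n_agents=1600, seed=3)
        per_agent = (res.choices[:, :14] == 0).mean(axis=1)
        ses = {}
        for n in (25, 100, 400):
            chunk_ses = [
                harness.summarize(per_agent[i : i + n])[1]
                for i in range(0, 1600, n)
            ]
            ses[n] = float(np.mean(chunk_ses))
        assert ses[25] / ses[100] == pytest.approx(2.0, rel=0.2)
        assert ses[100] / ses[400] == pytest.approx(2.0, rel=0.2)


class TestWriteResults:
    def test_round_trip(self, tmp_path):
        df = harness.run_experiment(
            harness.ExperimentConfig(
                experiment="bee", params=bee.BEE_PARAMS, n_agents=20, seed=0
            )
        )
        out = tmp_path / "res.csv"
        harness.write_results(df, out)
        back = pd.read_csv(out)
        assert list(back.columns) == harness.RESULT_COLUMNS
        assert len(back) == len(df)
        np.testing.assert_allclose(back["mean"], df["mean"], rtol=1e-10)

    def test_unwritable_path_rejected(self, tmp_path):
        df = pd.DataFrame(columns=harness.RESULT_COLUMNS)
        with pytest.raises(ValueError):
            harness.write_results(df, tmp_path / "missing" / "res.csv")


class TestFitParameters:
    def test_recovers_quadratic_optimum(self):
        res = fit_parameters(
            lambda p: (p["x"] - 0.7) ** 2,
            {"x": (0.0, 2.0)},
            SearchConfig(population_size=30, generations=40),
            seed=0,
        )
        assert res.best["x"] == pytest.approx(0.7, abs=0.01)
        assert res.best_loss < 1e-4

    def test_reproducible(self):
        args = (lambda p: (p["x"] - 0.3) ** 2 + (p["y"] + 1) ** 2,
                {"x": (-2, 2), "y": (-2, 2)},
                SearchConfig(population_size=10, generations=5))
        a = fit_parameters(*args, seed=4)
        b = fit_parameters(*args, seed=4)
        assert a.best == b.best and a.trace == b.trace

    def test_candidates_respect_bounds(self):
        seen = []

        def objective(p):
            seen.append(p["x"])
            return p["x"] ** 2

        fit_parameters(
            objective, {"x": (0.5, 1.5)},
            SearchConfig(population_size=8, generations=10), seed=1,
        )
        assert min(seen) >= 0.5 and max(seen) <= 1.5

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValueError):
            fit_parameters(lambda p: 0.0, {})

    def test_loss_trace_monotone_nonincreasing(self):
        res = fit_parameters(
            lambda p: abs(p["x"]), {"x": (-1, 1)},
            SearchConfig(population_size=12, generations=15, elitism=1), seed=2,
        )
        assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))


class TestCLI:
    def test_bee_subcommand_runs(self):
        from click.testing import CliRunner

        from bgrisk.cli import main

        r = CliRunner().invoke(main, ["bee", "--n-agents", "20", "--seed", "1"])
        assert r.exit_code == 0, r.output
        assert "p_blue" in r.output

    def test_result_file_written(self, tmp_path):
        from click.testing import CliRunner

        from bgrisk.cli import main

        out = tmp_path / "bee.csv"
        r = CliRunner().invoke(
            main, ["bee", "--n-agents", "10", "--seed", "1", "--out", str(out)]
        )
        assert r.exit_code == 0, r.output
        assert out.exists()
        assert len(pd.read_csv(out)) >= 2
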