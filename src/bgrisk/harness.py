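"""Batch running, configuration, aggregation and result I/O.

An :class:`ExperimentConfig` names one of the four experiments, the
agent parameters and run sizes; ``run_experiment`` dispatches to the
task modules and returns a tidy :class:`pandas.DataFrame` of
per-condition statistics (mean, SE over agents).  Configs load from
YAML or JSON with per-experiment defaults matching the fitted
parameter sets of each task module, and unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bee, delayed, reversal, rtd
from .params import AgentParams

__all__ = [
    "ExperimentConfig",
    "EXPERIMENTS",
    "default_params",
    "load_config",
    "save_config",
    "run_experiment",
    "summarize",
    "write_results",
    "RESULT_COLUMNS",
]

EXPERIMENTS = ("bee", "rtd", "delayed", "reversal")

RESULT_COLUMNS = [
    "experiment",
    "condition",
    "statistic",
    "mean",
    "se",
    "n",
    "seed",
    "alpha",
    "beta",
    "gamma",
    "eta_q",
    "eta_h",
]

_DEFAULT_N_AGENTS = {"bee": 1000, "rtd": 100, "delayed": 2000, "reversal": 100}

# task-level knobs accepted under `task:` per experiment
_TASK_KEYS = {
    "bee": {"reversal_trial", "total_trials"},
    "rtd": {"n_trials_per_state", "alphas", "measure_last"},
    "delayed": {"n_train_passes", "n_measure_passes", "spread"},
    "reversal": {"alphas", "counted_classes"},
}


def default_params(experiment: str) -> AgentParams:
    """The fitted parameter set reproduced by default for each task."""
    if experiment == "bee":
        return bee.BEE_PARAMS
    if experiment == "rtd":
        return AgentParams(alpha=rtd.ALPHA_BASELINE, beta=rtd.RTD_BETA)
    if experiment == "delayed":
        return delayed.DELAYED_PARAMS
    if experiment == "reversal":
        return reversal.REVERSAL_PARAMS
    raise ValueError(f"unknown experiment {experiment!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    params: AgentParams
    n_agents: int
    seed: int = 0
    output: str | None = None
    task: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        unknown = set(self.task) - _TASK_KEYS[self.experiment]
        if unknown:
            raise ValueError(
                f"unknown task keys for {self.experiment}: {sorted(unknown)}"
            )


_PARAM_FIELDS = {f.name for f in dataclasses.fields(AgentParams)}
_TOP_KEYS = {"experiment", "n_agents", "seed", "output", "task", "params"}


def _config_from_dict(raw: dict) -> ExperimentConfig:
    if "experiment" not in raw:
        raise ValueError("config must name an 'experiment'")
    experiment = raw["experiment"]
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    pdict = dict(raw.get("params") or {})
    unknown = set(pdict) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
    try:
        params = default_params(experiment).with_(**pdict)
    except ValueError as e:
        raise ValueError(f"invalid agent parameters: {e}") from e
    return ExperimentConfig(
        experiment=experiment,
        params=params,
        n_agents=int(raw.get("n_agents", _DEFAULT_N_AGENTS[experiment])),
        seed=int(raw.get("seed", 0)),
        output=raw.get("output"),
        task=dict(raw.get("task") or {}),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration.

    Omitted fields fall back to the experiment's fitted defaults; an
    empty mapping with only ``experiment`` set reproduces the
    published parameter set of that task.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    if raw is None:
        raise ValueError("config file is empty (needs at least 'experiment')")
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return _config_from_dict(raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write a config back to YAML; load_config(save_config(c)) == c."""
    d = {
        "experiment": config.experiment,
        "params": dataclasses.asdict(config.params),
        "n_agents": config.n_agents,
        "seed": config.seed,
        "task": config.task,
    }
    if config.output is not None:
        d["output"] = config.output
    Path(path).write_text(yaml.safe_dump(d))


def summarize(per_agent_values) -> tuple[float, float, int]:
    """Mean, standard error (sample SD / sqrt(N)) and N of a vector."""
    v = np.asarray(per_agent_values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return mean, se, int(v.size)


def _row(config, condition, statistic, mean, se, n, params=None) -> dict:
    p = params or config.params
    return {
        "experiment": config.experiment,
        "condition": condition,
        "statistic": statistic,
        "mean": mean,
        "se": se,
        "n": n,
        "seed": config.seed,
        "alpha": p.alpha,
        "beta": p.beta,
        "gamma": p.gamma,
        "eta_q": p.eta_q,
        "eta_h": p.eta_h,
    }


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run one configured experiment; deterministic given (config, seed)."""
    rows: list[dict] = []
    if config.experiment == "bee":
        spec = bee.BeeTaskSpec(
            reversal_trial=config.task.get("reversal_trial", 15),
            total_trials=config.task.get("total_trials", 40),
        )
        res = bee.run_bee_experiment(config.params, spec, config.n_agents, config.seed)
        pre = (res.choices[:, : spec.reversal_trial - 1] == 0).mean(axis=1)
        post = (res.choices[:, spec.reversal_trial - 1 :] == 0).mean(axis=1)
        for cond, vals in (("pre-reversal", pre), ("post-reversal", post)):
            m, se, n = summarize(vals)
            rows.append(_row(config, cond, "p_blue", m, se, n))
        rows.append(
            _row(config, "post-reversal", "switch_latency_trials",
                 float(res.switch_latency()), 0.0, config.n_agents)
        )
    elif config.experiment == "rtd":
        alphas = config.task.get(
            "alphas", {"baseline": rtd.ALPHA_BASELINE, "rtd": rtd.ALPHA_RTD}
        )
        for cond, alpha in alphas.items():
            p = config.params.with_(alpha=float(alpha))
            res = rtd.run_rtd_experiment(
                p,
                n_agents=config.n_agents,
                n_trials_per_state=config.task.get("n_trials_per_state", 200),
                seed=config.seed,
                measure_last=config.task.get("measure_last"),
            )
            for stat, m, se in (
                ("p_safe_overall", res.p_safe_overall, res.se_overall),
                ("p_safe_eev", res.p_safe_eev, res.se_eev),
                ("p_safe_uev", res.p_safe_uev, res.se_uev),
            ):
                rows.append(_row(config, cond, stat, m, se, config.n_agents, p))
    elif config.experiment == "delayed":
        res = delayed.run_delayed_experiment(
            config.params,
            n_agents=config.n_agents,
            seed=config.seed,
            n_train_passes=config.task.get("n_train_passes", 50),
            n_measure_passes=config.task.get("n_measure_passes", 10),
            spread=config.task.get("spread", "uniform"),
        )
        rows.append(
            _row(config, f"gamma={config.params.gamma}", "p_large_delayed",
                 res.p_yellow, res.se, config.n_agents)
        )
    elif config.experiment == "reversal":
        alphas = config.task.get(
            "alphas",
            {"balanced": reversal.ALPHA_BALANCED, "depleted": reversal.ALPHA_DEPLETED},
        )
        counted = tuple(config.task.get("counted_classes", ("non-reversal",)))
        for cond, alpha in alphas.items():
            p = config.params.with_(alpha=float(alpha))
            tally = reversal.run_reversal_experiment(
                float(alpha), config.n_agents, config.seed, params=config.params,
                counted_classes=counted,
            )
            tmeans, tses = tally.type_stats
            cmeans, cses = tally.condition_stats
            for j, tt in enumerate(reversal.TRIAL_TYPES):
                rows.append(
                    _row(config, cond, f"sqrt_errors_{tt}", tmeans[j], tses[j],
                         config.n_agents, p)
                )
            for j, cc in enumerate(reversal.CONDITIONS):
                rows.append(
                    _row(config, cond, f"sqrt_errors_{cc}", cmeans[j], cses[j],
                         config.n_agents, p)
                )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df


def write_results(
    summary: pd.DataFrame, path: str | Path, records: pd.DataFrame | None = None
) -> None:
    """Write the summary (and optional per-trial records) as CSV."""
    path = Path(path)
    if path.parent and not path.parent.exists():
        raise ValueError(f"output directory {path.parent} does not exist")
    summary.to_csv(path, index=False, float_format="%.10g")
    if records is not None:
        records.to_csv(path.with_suffix(".records.csv"), index=False)
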