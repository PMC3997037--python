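"""Recover a risk weight from behavior with the genetic-algorithm search.

We simulate 'observed' behavior at a known alpha, then fit alpha by
minimising the squared distance between the simulated and observed
overall safe-choice rate in the saccade task.  (Kept small so it runs
in under a minute; enlarge the search budget for real fits.)
"""

from bgrisk import rtd
from bgrisk.fitting import SearchConfig, fit_parameters
from bgrisk.params import AgentParams

TRUE_ALPHA = 1.8


def safe_rate(alpha: float) -> float:
    params = AgentParams(alpha=alpha, beta=rtd.RTD_BETA)
    res = rtd.run_rtd_experiment(params, n_agents=20, n_trials_per_state=100, seed=7)
    return res.p_safe_overall


target = safe_rate(TRUE_ALPHA)
print(f"observed safe-choice rate at alpha={TRUE_ALPHA}: {target:.3f}")

# common random numbers (same seed in target and candidate simulations)
# make the noisy objective exactly zero at the generating alpha
fit = fit_parameters(
    lambda p: (safe_rate(p["alpha"]) - target) ** 2,
    bounds={"alpha": (0.0, 3.0)},
    search_config=SearchConfig(population_size=8, generations=6),
    seed=7,
)
print(f"fitted alpha = {fit.best['alpha']:.3f} (loss {fit.best_loss:.2e})")
print(
    "Simulation statistics are noisy and non-differentiable, which is why a\n"
    "population-based evolutionary search is used; precision is limited by\n"
    "how strongly the statistic responds to alpha near the optimum."
)
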