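import numpy as np
import pytest

from twostep import AgentParams, TaskConfig, generate_walks, simulate_subject

#: group-level parameter means reported for this task's population
TABLE_PARAMS = AgentParams(
    beta1=5.00, beta2=3.63, alpha1=0.39, alpha2=0.25, lam=0.45, omega=0.49, p=0.12
)


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def walks(config):
    return generate_walks(config, seed=12345)


@pytest.fixture(scope="session")
def table_params():
    return TABLE_PARAMS


@pytest.fixture(scope="session")
def simulated_trials(config, walks, table_params):
    return simulate_subject(table_params, config, walks, seed=777)


def simulate_omega_cohort(omega, n_agents, config, seed0=0, params=TABLE_PARAMS):
    """Cohort of agents identical except for a forced model-based weight."""
    out = []
    p = params.replace(omega=omega)
    for i in range(n_agents):
        w = generate_walks(config, seed0 + 10_000 + i)
        out.append(simulate_subject(p, config, w, seed=seed0 + 20_000 + i))
    return out


def brute_force_bh(p):
    """Independent step-up implementation of the Benjamini-Hochberg
    adjustment, straight from the definition: sort, scale by m/rank,
    enforce monotonicity from the largest p down, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)
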