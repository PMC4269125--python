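"""Hybrid model-free / model-based reinforcement-learning agent.

The agent mixes two valuation systems at the first stage of the two-step task:
a SARSA(lambda) model-free learner that caches stage-1 action values, and a
model-based planner that computes stage-1 values on the fly from the known
transition probabilities and the current stage-2 values.  A weight ``omega``
arbitrates between them (0 = purely model-free, 1 = purely model-based); a
perseveration bonus ``p`` adds a logit preference for repeating the previous
stage-1 choice.

Seven free parameters:

==========  =====================================================  ==========
name        role                                                   range
==========  =====================================================  ==========
beta1       stage-1 softmax inverse temperature                    [0, inf)
beta2       stage-2 softmax inverse temperature                    [0, inf)
alpha1      stage-1 learning rate                                  [0, 1]
alpha2      stage-2 learning rate                                  [0, 1]
lam         eligibility of the stage-2 prediction error at stage 1 [0, 1]
omega       model-based weight                                     [0, 1]
p           first-order perseveration bonus (logit scale)          reals
==========  =====================================================  ==========

For fitting, the bounded parameters are mapped to an unconstrained scale:
log for the inverse temperatures, logit for the unit-interval parameters,
identity for ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .task import TaskConfig, WalkSet, common_state_for

__all__ = [
    "PARAM_NAMES",
    "AgentParams",
    "QState",
    "TrialRecord",
    "transform_params",
    "untransform_params",
    "model_based_values",
    "stage1_probs",
    "stage2_probs",
    "sarsa_update",
    "simulate_subject",
    "negloglik",
    "trials_to_arrays",
]

PARAM_NAMES = ("beta1", "beta2", "alpha1", "alpha2", "lam", "omega", "p")

#: default initial Q-value: midpoint of the reward-probability band
Q_INIT = 0.5


@dataclass(frozen=True)
class AgentParams:
    beta1: float
    beta2: float
    alpha1: float
    alpha2: float
    lam: float
    omega: float
    p: float

    def __post_init__(self) -> None:
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be nonnegative")
        for name in ("alpha1", "alpha2", "lam", "omega"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "AgentParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (7,):
            raise ValueError("expected 7 parameters")
        return cls(**dict(zip(PARAM_NAMES, x)))

    def replace(self, **kw) -> "AgentParams":
        return replace(self, **kw)


@dataclass
class QState:
    """Learned values: stage-2 table (2 states x 2 actions), stage-1
    model-free pair, and the previous stage-1 choice (None before trial 1)."""

    q2: np.ndarray
    q_mf: np.ndarray
    prev_choice: int | None = None

    @classmethod
    def initial(cls, q_init: float = Q_INIT) -> "QState":
        return cls(q2=np.full((2, 2), q_init), q_mf=np.full(2, q_init))

    def copy(self) -> "QState":
        return QState(self.q2.copy(), self.q_mf.copy(), self.prev_choice)


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    a1: int
    s2: int
    common: bool
    a2: int
    r: int


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def transform_params(params: AgentParams, clamp: bool = False) -> np.ndarray:
    """Map to the unconstrained fitting scale.

    log(beta), logit(alpha/lam/omega), identity(p).  Boundary values of the
    unit-interval parameters (and beta = 0) map to +/-inf and are rejected
    unless ``clamp`` nudges them inside by 1e-9.
    """
    x = params.to_array()
    eps = 1e-9
    if clamp:
        x[:2] = np.maximum(x[:2], eps)
        x[2:6] = np.clip(x[2:6], eps, 1 - eps)
    if (x[:2] <= 0).any() or ((x[2:6] <= 0) | (x[2:6] >= 1)).any():
        raise ValueError("boundary parameter values have no finite transform; pass clamp=True")
    out = np.empty(7)
    out[0], out[1] = math.log(x[0]), math.log(x[1])
    out[2:6] = [_logit(v) for v in x[2:6]]
    out[6] = x[6]
    return out


def untransform_params(x) -> AgentParams:
    """Inverse of :func:`transform_params`: exp / sigmoid / identity."""
    x = np.asarray(x, dtype=float)
    if x.shape != (7,):
        raise ValueError("expected 7 unconstrained parameters")
    with np.errstate(over="ignore"):
        sig = 1.0 / (1.0 + np.exp(-x[2:6]))
    return AgentParams(
        beta1=math.exp(min(x[0], 700.0)),
        beta2=math.exp(min(x[1], 700.0)),
        alpha1=sig[0],
        alpha2=sig[1],
        lam=sig[2],
        omega=sig[3],
        p=x[6],
    )


def model_based_values(q2: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Prospective stage-1 values from the fixed transition structure.

    Q_MB(a) = p_common * max_a' q2(common(a), a')
            + (1 - p_common) * max_a' q2(rare(a), a')
    """
    q2 = np.asarray(q2, dtype=float)
    state_max = q2.max(axis=1)
    pc = config.p_common
    out = np.empty(2)
    for a in (0, 1):
        c = common_state_for(a)
        out[a] = pc * state_max[c] + (1.0 - pc) * state_max[1 - c]
    return out


def _softmax2(x0: float, x1: float) -> tuple[float, float]:
    m = x0 if x0 > x1 else x1
    e0, e1 = math.exp(x0 - m), math.exp(x1 - m)
    z = e0 + e1
    return e0 / z, e1 / z


def stage1_probs(
    q_mf: np.ndarray,
    q_mb: np.ndarray,
    params: AgentParams,
    prev_choice: int | None,
) -> np.ndarray:
    """Softmax over beta1 * (omega*Q_MB + (1-omega)*Q_MF) + perseveration bonus."""
    w = params.omega
    x = [params.beta1 * (w * q_mb[a] + (1.0 - w) * q_mf[a]) for a in (0, 1)]
    if prev_choice is not None:
        x[prev_choice] += params.p
    return np.array(_softmax2(x[0], x[1]))


def stage2_probs(q2_row: np.ndarray, params: AgentParams) -> np.ndarray:
    """Softmax over beta2 * q2(s2, .)."""
    return np.array(_softmax2(params.beta2 * q2_row[0], params.beta2 * q2_row[1]))


def sarsa_update(qstate: QState, trial: TrialRecord, params: AgentParams) -> QState:
    """One SARSA(lambda) learning step; returns a new QState.

    The stage-1 model-free value of the chosen action is moved toward the
    stage-2 value of the visited pair (delta1), the stage-2 value toward the
    reward (delta2), and the reward prediction error additionally feeds back
    to stage 1 with eligibility lam.
    """
    q = qstate.copy()
    a1, s2, a2, r = trial.a1, trial.s2, trial.a2, trial.r
    delta1 = q.q2[s2, a2] - q.q_mf[a1]
    q.q_mf[a1] += params.alpha1 * delta1
    delta2 = r - q.q2[s2, a2]
    q.q2[s2, a2] += params.alpha2 * delta2
    q.q_mf[a1] += params.alpha1 * params.lam * delta2
    q.prev_choice = a1
    return q


def simulate_subject(
    params: AgentParams,
    config: TaskConfig,
    walks: WalkSet,
    n_trials: int | None = None,
    seed: int | np.random.Generator = 0,
    q_init: float = Q_INIT,
) -> list[TrialRecord]:
    """Generate a full session of choices, transitions and rewards.

    Deterministic given the seed: one uniform draw per stage-1 choice,
    transition, stage-2 choice and reward, in that order per trial.
    """
    if n_trials is None:
        n_trials = walks.n_trials
    if walks.n_trials < n_trials:
        raise ValueError(f"walks cover {walks.n_trials} trials, need {n_trials}")
    rng = np.random.default_rng(seed)
    u = rng.random(size=(n_trials, 4))

    beta1, beta2 = params.beta1, params.beta2
    alpha1, alpha2, lam, omega, pers = (
        params.alpha1, params.alpha2, params.lam, params.omega, params.p,
    )
    pc = config.p_common
    q2 = [[q_init, q_init], [q_init, q_init]]
    q_mf = [q_init, q_init]
    prev: int | None = None
    probs = walks.probs
    records: list[TrialRecord] = []

    for t in range(n_trials):
        m0 = q2[0][0] if q2[0][0] > q2[0][1] else q2[0][1]
        m1 = q2[1][0] if q2[1][0] > q2[1][1] else q2[1][1]
        qmb0 = pc * m0 + (1.0 - pc) * m1
        qmb1 = pc * m1 + (1.0 - pc) * m0
        x0 = beta1 * (omega * qmb0 + (1.0 - omega) * q_mf[0])
        x1 = beta1 * (omega * qmb1 + (1.0 - omega) * q_mf[1])
        if prev == 0:
            x0 += pers
        elif prev == 1:
            x1 += pers
        p0, _ = _softmax2(x0, x1)
        a1 = 0 if u[t, 0] < p0 else 1
        was_common = u[t, 1] < pc
        s2 = a1 if was_common else 1 - a1
        p20, _ = _softmax2(beta2 * q2[s2][0], beta2 * q2[s2][1])
        a2 = 0 if u[t, 2] < p20 else 1
        r = 1 if u[t, 3] < probs[t, s2 * 2 + a2] else 0
        records.append(TrialRecord(t, a1, s2, bool(was_common), a2, r))
        # SARSA(lambda) update, same order as sarsa_update()
        delta1 = q2[s2][a2] - q_mf[a1]
        q_mf[a1] += alpha1 * delta1
        delta2 = r - q2[s2][a2]
        q2[s2][a2] += alpha2 * delta2
        q_mf[a1] += alpha1 * lam * delta2
        prev = a1
    return records


def trials_to_arrays(trials: list[TrialRecord]) -> tuple[list[int], ...]:
    """Unzip trial records into parallel (a1, s2, a2, r) lists for fast replay."""
    a1 = [t.a1 for t in trials]
    s2 = [t.s2 for t in trials]
    a2 = [t.a2 for t in trials]
    r = [t.r for t in trials]
    return a1, s2, a2, r


def negloglik(
    params: AgentParams,
    trials: list[TrialRecord] | tuple[list[int], ...],
    config: TaskConfig | None = None,
    q_init: float = Q_INIT,
) -> float:
    """Negative log-likelihood of the observed choices at both stages.

    Q-values are replayed through the SARSA(lambda) update on the observed
    sequence; the likelihood is the product of the softmax probabilities of
    the chosen stage-1 and stage-2 actions.  ``trials`` may be pre-unzipped
    via :func:`trials_to_arrays` (hot path for fitting).
    """
    if isinstance(trials, tuple):
        a1s, s2s, a2s, rs = trials
    else:
        a1s, s2s, a2s, rs = trials_to_arrays(trials)
    if len(a1s) == 0:
        raise ValueError("trial sequence is empty")
    pc = (config or TaskConfig()).p_common
    beta1, beta2 = params.beta1, params.beta2
    alpha1, alpha2, lam, omega, pers = (
        params.alpha1, params.alpha2, params.lam, params.omega, params.p,
    )
    q2 = [[q_init, q_init], [q_init, q_init]]
    q_mf = [q_init, q_init]
    prev = -1
    log = math.log
    exp = math.exp
    nll = 0.0
    for a1, s2, a2, r in zip(a1s, s2s, a2s, rs):
        m0 = q2[0][0] if q2[0][0] > q2[0][1] else q2[0][1]
        m1 = q2[1][0] if q2[1][0] > q2[1][1] else q2[1][1]
        qmb0 = pc * m0 + (1.0 - pc) * m1
        qmb1 = pc * m1 + (1.0 - pc) * m0
        x0 = beta1 * (omega * qmb0 + (1.0 - omega) * q_mf[0])
        x1 = beta1 * (omega * qmb1 + (1.0 - omega) * q_mf[1])
        if prev == 0:
            x0 += pers
        elif prev == 1:
            x1 += pers
        # log softmax of the chosen action
        d = x1 - x0 if a1 == 0 else x0 - x1
        nll += log(1.0 + exp(d)) if d < 35.0 else d
        row = q2[s2]
        d2 = beta2 * (row[1 - a2] - row[a2])
        nll += log(1.0 + exp(d2)) if d2 < 35.0 else d2
        delta1 = row[a2] - q_mf[a1]
        q_mf[a1] += alpha1 * delta1
        delta2 = r - row[a2]
        row[a2] += alpha2 * delta2
        q_mf[a1] += alpha1 * lam * delta2
        prev = a1
    return nll
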