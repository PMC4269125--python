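"""Synthetic cohort generation.

No subject-level dataset accompanies the study this package models, so the
cohort generator produces complete stand-in cohorts with the statistical
structure the analyses assume: ability scores from a Gaussian copula matched
to the published cohort moments and pairwise correlations; agent parameters
from the published population estimates with a configurable linkage between
processing speed (DSST) and the model-based weight, moderated by working
memory; and trial-by-trial choice data simulated from the hybrid agent on
the two-step task.  Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .abilities import ABILITY_COLUMNS
from .agent import (
    PARAM_NAMES,
    TrialRecord,
    simulate_subject,
    transform_params,
    untransform_params,
    AgentParams,
)
from .task import TaskConfig, WalkSet, generate_walks

__all__ = [
    "TABLE1_MEANS",
    "TABLE1_SDS",
    "TABLE1_RANGES",
    "TABLE1_CORR",
    "POPULATION_MEANS_MODEL",
    "POPULATION_SDS_UNCONSTRAINED",
    "SyntheticConfig",
    "SyntheticCohort",
    "draw_ability_scores",
    "draw_population_params",
    "generate_cohort",
    "parameter_recovery",
]

# Published cohort moments of the five ability measures
# (dsst, tmt_a_s, tmt_ratio, digit_span_bw, mwt)
TABLE1_MEANS = {"dsst": 68.6, "tmt_a_s": 34.2, "tmt_ratio": 2.2,
                "digit_span_bw": 7.6, "mwt": 32.0}
TABLE1_SDS = {"dsst": 15.9, "tmt_a_s": 12.1, "tmt_ratio": 0.76,
              "digit_span_bw": 2.6, "mwt": 3.2}
TABLE1_RANGES = {"dsst": (35.0, 98.0), "tmt_a_s": (20.0, 70.0),
                 "tmt_ratio": (1.1, 4.7), "digit_span_bw": (4.0, 14.0),
                 "mwt": (24.0, 37.0)}
INTEGER_SCORES = ("dsst", "digit_span_bw", "mwt")

# Published pairwise correlations, order = ABILITY_COLUMNS
TABLE1_CORR = np.array(
    [
        [1.000, -0.575, -0.099, 0.306, 0.576],
        [-0.575, 1.000, -0.282, -0.121, -0.490],
        [-0.099, -0.282, 1.000, -0.090, -0.205],
        [0.306, -0.121, -0.090, 1.000, 0.379],
        [0.576, -0.490, -0.205, 0.379, 1.000],
    ]
)

# Published group-level parameter estimates: means on the model scale,
# between-subject SDs on the unconstrained fitting scale (a model-scale SD of
# 0.80 is impossible for the [0,1]-bounded weight, so the SD row must refer to
# the fitting scale).
POPULATION_MEANS_MODEL = np.array([5.00, 3.63, 0.39, 0.25, 0.45, 0.49, 0.12])
POPULATION_SDS_UNCONSTRAINED = np.array([0.46, 0.18, 0.34, 0.51, 0.44, 0.80, 0.16])


def _mu_unconstrained() -> np.ndarray:
    return transform_params(AgentParams.from_array(POPULATION_MEANS_MODEL))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for one synthetic cohort.

    ``linkage_r`` is the target correlation between DSST and the
    unconstrained model-based weight; ``ws_moderation`` scales the asymmetry
    of that linkage between high and low working-memory subgroups (slope
    proportional to 1 +/- ws_moderation), emulating the finding that
    processing speed boosts model-based control mainly under high working
    memory.
    """

    n_subjects: int = 27
    n_trials: int = 201
    linkage_r: float = 0.42
    ws_moderation: float = 0.8
    pop_mu: tuple = tuple(_mu_unconstrained())
    pop_sigma: tuple = tuple(POPULATION_SDS_UNCONSTRAINED)
    ability_means: tuple = tuple(TABLE1_MEANS[c] for c in ABILITY_COLUMNS)
    ability_sds: tuple = tuple(TABLE1_SDS[c] for c in ABILITY_COLUMNS)
    ability_ranges: tuple = tuple(TABLE1_RANGES[c] for c in ABILITY_COLUMNS)
    shared_walks: bool = True
    round_scores: bool = True
    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not abs(self.linkage_r) < 1:
            raise ValueError("|linkage_r| must be < 1")
        load = self.linkage_r**2 * (1 + self.ws_moderation**2)
        if load >= 1:
            raise ValueError(
                f"linkage infeasible: r^2(1 + m^2) = {load:.3f} >= 1; "
                "reduce linkage_r or ws_moderation"
            )

    def hash(self) -> str:
        payload = asdict(self)
        payload["task"] = asdict(self.task)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    abilities: pd.DataFrame
    true_params: pd.DataFrame
    trials: dict[str, list[TrialRecord]]
    walks: dict[str, WalkSet]
    seed: int

    @property
    def subject_ids(self) -> list[str]:
        return list(self.abilities["subject_id"])

    def walks_for(self, subject_id: str) -> WalkSet:
        if self.config.shared_walks:
            return self.walks["shared"]
        return self.walks[subject_id]


def _clipped_normal_moments(mu: float, sd: float, lo: float, hi: float):
    """Mean and s.d. of clip(N(mu, sd^2), lo, hi) in closed form."""
    from scipy.stats import norm

    a, b = (lo - mu) / sd, (hi - mu) / sd
    Fa, Fb = norm.cdf(a), norm.cdf(b)
    fa, fb = norm.pdf(a), norm.pdf(b)
    m = Fb - Fa  # interior mass
    if m < 1e-12:
        ex = lo * Fa + hi * (1 - Fb)
        return ex, 0.0
    mu_t = mu + sd * (fa - fb) / m
    var_t = sd**2 * (1 + (a * fa - b * fb) / m - ((fa - fb) / m) ** 2)
    ex = lo * Fa + hi * (1 - Fb) + m * mu_t
    ex2 = lo**2 * Fa + hi**2 * (1 - Fb) + m * (var_t + mu_t**2)
    return ex, float(np.sqrt(max(ex2 - ex**2, 0.0)))


def _latent_moments(target_mean, target_sd, lo, hi):
    """Latent Gaussian (mu, sd) whose clipped version has the target moments.

    The published score ranges sit near +-2 s.d., so clipping biases the
    plain Gaussian moments; this inverts that bias numerically.
    """
    from scipy.optimize import root

    if target_sd == 0:
        return target_mean, 0.0

    def eqs(v):
        ex, xsd = _clipped_normal_moments(v[0], abs(v[1]), lo, hi)
        return [ex - target_mean, xsd - target_sd]

    sol = root(eqs, [target_mean, target_sd], method="hybr")
    if not sol.success:  # fall back to the uncorrected moments
        return target_mean, target_sd
    return float(sol.x[0]), float(abs(sol.x[1]))


def _attenuation_factor(mu: float, sd: float, lo: float, hi: float,
                        rounded: bool) -> float:
    """corr(latent z, observed score) for one measure.

    Clipping and integer rounding both shave correlation off the latent
    Gaussian; the latent correlation matrix is inflated by the product of the
    per-measure factors so the *observed* pairwise correlations match their
    targets.
    """
    if sd == 0:
        return 1.0
    z, w = np.polynomial.hermite_e.hermegauss(80)
    x = np.clip(mu + sd * z, lo, hi)
    w = w / w.sum()
    ex = (w * x).sum()
    var = (w * (x - ex) ** 2).sum()
    cov = (w * z * (x - ex)).sum()
    if rounded:
        var = var + 1.0 / 12.0  # independent rounding noise
    return float(cov / np.sqrt(var)) if var > 0 else 1.0


def draw_ability_scores(
    config: SyntheticConfig, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Sample an ability table with the published moments and correlations.

    Latent multivariate normal with the published correlation matrix; each
    marginal is scaled by moment-matched latent parameters so that after
    clipping to the published ranges the sample mean/SD hit the published
    targets, then rounded where the instrument is integer-valued (symbol
    counts, digit span, vocabulary score).  A non-PSD correlation matrix is
    repaired by eigenvalue flooring with a warning.
    """
    rng = np.random.default_rng(seed)
    latents = []
    for j, name in enumerate(ABILITY_COLUMNS):
        lo, hi = config.ability_ranges[j]
        mu_lat, sd_lat = _latent_moments(
            config.ability_means[j], config.ability_sds[j], lo, hi
        )
        rounded = config.round_scores and name in INTEGER_SCORES
        att = _attenuation_factor(mu_lat, sd_lat, lo, hi, rounded)
        latents.append((mu_lat, sd_lat, lo, hi, rounded, att))

    att = np.array([l[5] for l in latents])
    corr = np.clip(TABLE1_CORR / np.outer(att, att), -0.999, 0.999)
    np.fill_diagonal(corr, 1.0)
    w, V = np.linalg.eigh(corr)
    if w.min() < 1e-8:
        import warnings

        warnings.warn("repairing non-PSD ability correlation matrix", stacklevel=2)
        w = np.maximum(w, 1e-8)
        corr = (V * w) @ V.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    L = np.linalg.cholesky(corr)
    z = rng.standard_normal((config.n_subjects, 5)) @ L.T
    out = {}
    for j, name in enumerate(ABILITY_COLUMNS):
        mu_lat, sd_lat, lo, hi, rounded, _ = latents[j]
        v = np.clip(mu_lat + sd_lat * z[:, j], lo, hi)
        if rounded:
            v = np.rint(v)
        out[name] = v
    df = pd.DataFrame(out)
    df.insert(0, "subject_id", [f"s{i:03d}" for i in range(config.n_subjects)])
    return df


def draw_population_params(
    config: SyntheticConfig,
    ability_table: pd.DataFrame,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Draw per-subject agent parameters with the ability linkage.

    All parameters are Gaussian on the unconstrained scale.  The model-based
    weight's deviation from its population mean is built as
    sigma * (c_g * z_dsst + sqrt(1 - c^2(1+m^2)) * noise) where c is
    ``linkage_r`` and c_g = c(1 + m) in the high digit-span subgroup,
    c(1 - m) in the low — with balanced groups the implied corr(DSST, omega')
    is c and the marginal variance stays sigma^2.  Returns one row per
    subject with both unconstrained and model-scale columns.
    """
    from .stay import split_scores

    rng = np.random.default_rng(seed)
    n = len(ability_table)
    mu = np.asarray(config.pop_mu)
    sigma = np.asarray(config.pop_sigma)
    theta = mu + sigma * rng.standard_normal((n, 7))

    dsst = ability_table["dsst"].to_numpy(dtype=float)
    z = (dsst - dsst.mean()) / dsst.std(ddof=0)
    group = split_scores(ability_table["digit_span_bw"].to_numpy(dtype=float), "median")
    c = config.linkage_r
    m = config.ws_moderation
    c_g = np.where(group == 1, c * (1 + m), c * (1 - m))
    noise_scale = np.sqrt(1.0 - c**2 * (1 + m**2))
    k = PARAM_NAMES.index("omega")
    theta[:, k] = mu[k] + sigma[k] * (
        c_g * z + noise_scale * rng.standard_normal(n)
    )

    rows = {}
    for j, name in enumerate(PARAM_NAMES):
        rows[f"{name}_unc"] = theta[:, j]
    model = np.array([untransform_params(t).to_array() for t in theta])
    for j, name in enumerate(PARAM_NAMES):
        rows[name] = model[:, j]
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", list(ability_table["subject_id"]))
    return df


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Full synthetic cohort: abilities, true parameters, walks, trial logs.

    Child seeds are spawned deterministically from ``config.seed``; by
    default all subjects face the same reward-probability sequence, as
    subjects in the study did.
    """
    ss = np.random.SeedSequence(config.seed)
    s_walk, s_abil, s_par, s_sim = ss.spawn(4)
    abilities = draw_ability_scores(config, s_abil)
    params = draw_population_params(config, abilities, s_par)

    task = config.task
    if task.n_trials != config.n_trials:
        task = TaskConfig(**{**asdict(task), "n_trials": config.n_trials})

    walks: dict[str, WalkSet] = {}
    if config.shared_walks:
        walks["shared"] = generate_walks(task, np.random.default_rng(s_walk))
    else:
        for sid, child in zip(abilities["subject_id"], s_walk.spawn(config.n_subjects)):
            walks[sid] = generate_walks(task, np.random.default_rng(child))

    trials: dict[str, list[TrialRecord]] = {}
    sim_seeds = s_sim.spawn(config.n_subjects)
    for i, sid in enumerate(abilities["subject_id"]):
        p = AgentParams.from_array(
            params.loc[i, list(PARAM_NAMES)].to_numpy(dtype=float)
        )
        w = walks["shared"] if config.shared_walks else walks[sid]
        trials[sid] = simulate_subject(
            p, task, w, config.n_trials, seed=np.random.default_rng(sim_seeds[i])
        )
    return SyntheticCohort(
        config=config,
        abilities=abilities,
        true_params=params,
        trials=trials,
        walks=walks,
        seed=config.seed,
    )


def parameter_recovery(
    config: SyntheticConfig,
    em_kwargs: dict | None = None,
) -> dict:
    """Generate a cohort, refit it hierarchically, and score the recovery.

    Returns the fitted prior, per-subject fits, and a per-parameter report
    with corr(true, recovered) and mean bias on both scales.
    """
    from .hierarchy import em_fit, summarize_population

    if config.n_trials <= 0:
        raise ValueError("n_trials must be positive")
    cohort = generate_cohort(config)
    prior, fits = em_fit(
        [cohort.trials[sid] for sid in cohort.subject_ids],
        config=config.task,
        **(em_kwargs or {}),
    )
    true_unc = cohort.true_params[[f"{n}_unc" for n in PARAM_NAMES]].to_numpy()
    est_unc = np.array([f.map_estimate for f in fits])
    true_model = cohort.true_params[list(PARAM_NAMES)].to_numpy()
    est_model = np.array(
        [untransform_params(f.map_estimate).to_array() for f in fits]
    )
    report = pd.DataFrame(
        {
            "corr_unc": [
                np.corrcoef(true_unc[:, j], est_unc[:, j])[0, 1] for j in range(7)
            ],
            "corr_model": [
                np.corrcoef(true_model[:, j], est_model[:, j])[0, 1] for j in range(7)
            ],
            "bias_model": (est_model - true_model).mean(axis=0),
            "true_mean_model": true_model.mean(axis=0),
            "recovered_mean_model": est_model.mean(axis=0),
        },
        index=list(PARAM_NAMES),
    )
    return {
        "cohort": cohort,
        "prior": prior,
        "fits": fits,
        "report": report,
        "population_summary": summarize_population(prior, fits),
    }
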