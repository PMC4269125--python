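"""Factorial stay-probability analysis.

Choice repetition ("stay") at the first stage is analysed as a function of
the previous trial's reward and transition type.  A model-free controller
predicts a main effect of reward (repeat what was rewarded regardless of how
the reward was reached); a model-based controller predicts a reward x
transition interaction (a reward after a rare transition argues for the
*other* first-stage action).  Per subject we compute simple 2x2 stay
proportions, the derived indices, and ridge-penalised logistic coefficients;
group-level inference and ability moderation operate on those per-subject
summaries (a two-stage summary-statistics design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .agent import TrialRecord

__all__ = [
    "StayCoefficients",
    "ModerationResult",
    "build_stay_design",
    "stay_table",
    "simple_indices",
    "fit_subject_stay",
    "group_effects",
    "moderation_test",
    "fdr_adjust",
    "split_scores",
]

STAY_TERMS = ("intercept", "reward", "transition", "reward_x_transition")


@dataclass(frozen=True)
class StayCoefficients:
    """Per-subject logistic coefficients on the logit scale."""

    b0: float
    b_rew: float
    b_trans: float
    b_rxt: float

    def to_array(self) -> np.ndarray:
        return np.array([self.b0, self.b_rew, self.b_trans, self.b_rxt])


@dataclass(frozen=True)
class ModerationResult:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_unc: float
    p_fdr: float | None = None


def build_stay_design(trials: list[TrialRecord]) -> pd.DataFrame:
    """One row per trial from the second onward.

    Columns: ``stay`` (1 = repeated the previous stage-1 choice),
    ``reward_prev`` (+0.5 rewarded / -0.5 not), ``transition_prev``
    (+0.5 common / -0.5 rare) and their product ``interaction`` — the
    effect-coded factorial design lagged by one trial.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to define stay behaviour")
    a1 = np.array([t.a1 for t in trials])
    r = np.array([t.r for t in trials], dtype=float)
    common = np.array([t.common for t in trials], dtype=float)
    stay = (a1[1:] == a1[:-1]).astype(int)
    reward_prev = np.where(r[:-1] > 0, 0.5, -0.5)
    transition_prev = np.where(common[:-1] > 0, 0.5, -0.5)
    return pd.DataFrame(
        {
            "stay": stay,
            "reward_prev": reward_prev,
            "transition_prev": transition_prev,
            "interaction": reward_prev * transition_prev,
        }
    )


def stay_table(design: pd.DataFrame) -> pd.DataFrame:
    """2x2 stay proportions (rows: rewarded/unrewarded; cols: common/rare).

    Empty cells are returned as NaN — downstream indices flag them rather
    than fabricating a value.
    """
    tab = pd.DataFrame(
        np.nan,
        index=pd.Index(["rewarded", "unrewarded"], name="prev_reward"),
        columns=pd.Index(["common", "rare"], name="prev_transition"),
    )
    for rew_label, rew in (("rewarded", 0.5), ("unrewarded", -0.5)):
        for tr_label, tr in (("common", 0.5), ("rare", -0.5)):
            cell = design[
                (design["reward_prev"] == rew) & (design["transition_prev"] == tr)
            ]["stay"]
            if len(cell):
                tab.loc[rew_label, tr_label] = cell.mean()
    return tab


def simple_indices(table: pd.DataFrame) -> tuple[float, float, float]:
    """(mf_index, mb_index, w_repeat) from the 2x2 stay table.

    mf = P(stay | rewarded) - P(stay | unrewarded), averaged over transition;
    mb = rewarded-common - rewarded-rare - unrewarded-common + unrewarded-rare;
    w_repeat = mb - mf, the relative preference for model-based control.
    Any missing cell makes all three NaN.
    """
    if table.isna().any().any():
        return (float("nan"),) * 3
    rc = table.loc["rewarded", "common"]
    rr = table.loc["rewarded", "rare"]
    uc = table.loc["unrewarded", "common"]
    ur = table.loc["unrewarded", "rare"]
    mf = (rc + rr) / 2 - (uc + ur) / 2
    mb = rc - rr - uc + ur
    return float(mf), float(mb), float(mb - mf)


def _ridge_logistic(X: np.ndarray, y: np.ndarray, penalty: np.ndarray) -> np.ndarray:
    """Newton solver for logistic regression with per-coefficient L2 penalty.

    Minimises -loglik + 0.5 * sum_j penalty_j * b_j^2.  The quadratic penalty
    keeps the optimum finite under complete separation.
    """
    b = np.zeros(X.shape[1])
    for _ in range(100):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (mu - y) + penalty * b
        w = mu * (1.0 - mu)
        H = (X.T * w) @ X + np.diag(penalty)
        step = np.linalg.solve(H + 1e-10 * np.eye(len(b)), grad)
        b = b - step
        if np.abs(step).max() < 1e-10:
            break
    return b


def fit_subject_stay(design: pd.DataFrame, ridge: float = 0.1) -> StayCoefficients:
    """Penalised logistic fit of stay on the lagged factorial predictors.

    ``ridge`` (default 0.1) penalises the three slopes, never the intercept,
    so that perfectly separable single-subject designs still yield finite
    coefficients.  With ridge = 0 a degenerate (constant-stay) design raises.
    """
    if len(design) < 8:
        raise ValueError("need at least 8 design rows for a per-subject fit")
    y = design["stay"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(design)),
            design["reward_prev"].to_numpy(dtype=float),
            design["transition_prev"].to_numpy(dtype=float),
            design["interaction"].to_numpy(dtype=float),
        ]
    )
    if ridge == 0 and (y.min() == y.max()):
        raise ValueError("constant stay outcome is separable; use ridge > 0")
    penalty = np.array([0.0, ridge, ridge, ridge])
    b = _ridge_logistic(X, y, penalty)
    if not np.isfinite(b).all():
        raise ValueError("stay fit diverged; increase ridge")
    return StayCoefficients(*b)


def group_effects(coefs: list[StayCoefficients], level: float = 0.95) -> pd.DataFrame:
    """One-sample t-tests of the per-subject coefficients against zero.

    Returns one row per term with the group mean, between-subject SD,
    t-based CI and two-sided p (p = 1 when every coefficient is exactly 0).
    """
    if len(coefs) < 3:
        raise ValueError("group inference needs at least 3 subjects")
    B = np.array([c.to_array() for c in coefs])
    n = B.shape[0]
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, mean / se, np.nan)
    p = np.where(
        np.isnan(tval), 1.0, 2 * stats.t.sf(np.abs(np.nan_to_num(tval)), df=n - 1)
    )
    return pd.DataFrame(
        {
            "estimate": mean,
            "sd_between": sd,
            "ci_low": mean - tcrit * se,
            "ci_high": mean + tcrit * se,
            "t": tval,
            "p": p,
        },
        index=list(STAY_TERMS),
    )


def moderation_test(
    coefs: list[StayCoefficients],
    ability: np.ndarray,
    quadratic: bool = True,
    term: str = "reward_x_transition",
    level: float = 0.95,
    drop_nonsig_quadratic: bool = True,
    alpha: float = 0.05,
) -> list[ModerationResult]:
    """Regress a per-subject stay coefficient on a z-scored ability score.

    Fits coefficient ~ z(ability) [+ z(ability)^2].  When
    ``drop_nonsig_quadratic`` is set and the quadratic term is not significant
    at ``alpha``, the model is refit with the linear term only (mirroring the
    stepwise simplification used for the group analyses).  Returns one
    ModerationResult per ability term; ``p_fdr`` is left for the caller,
    since the correction family spans several such calls.
    """
    import statsmodels.api as sm

    ability = np.asarray(ability, dtype=float)
    if ability.std(ddof=0) == 0:
        raise ValueError("ability score has zero variance")
    idx = STAY_TERMS.index(term)
    y = np.array([c.to_array()[idx] for c in coefs])
    if len(y) != len(ability):
        raise ValueError("coefs and ability must have equal length")
    z = (ability - ability.mean()) / ability.std(ddof=0)

    def _fit(with_quad: bool):
        cols = {"linear": z}
        if with_quad:
            cols["quadratic"] = z**2
        X = sm.add_constant(pd.DataFrame(cols))
        return sm.OLS(y, X).fit(), list(cols)

    res, names = _fit(quadratic)
    if quadratic and drop_nonsig_quadratic and res.pvalues["quadratic"] >= alpha:
        res, names = _fit(False)
    ci = res.conf_int(alpha=1 - level)
    return [
        ModerationResult(
            term=name,
            estimate=float(res.params[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
            p_unc=float(res.pvalues[name]),
        )
        for name in names
    ]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def split_scores(scores, mode: str = "median") -> np.ndarray:
    """Rank-based split into 2 (median) or 3 (tertile) near-equal groups.

    Returns integer labels 0 (low) .. k-1 (high); ties are broken by stable
    input order, so group sizes differ by at most one.
    """
    scores = np.asarray(scores, dtype=float)
    if mode == "median":
        k = 2
    elif mode == "tertile":
        k = 3
        if scores.size < 3:
            raise ValueError("tertile split needs at least 3 scores")
    else:
        raise ValueError(f"unknown split mode: {mode!r}")
    order = np.argsort(scores, kind="stable")
    labels = np.empty(scores.size, dtype=int)
    # group boundaries at the 1/k order statistics
    edges = [round(scores.size * j / k) for j in range(k + 1)]
    for g in range(k):
        labels[order[edges[g]:edges[g + 1]]] = g
    return labels
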