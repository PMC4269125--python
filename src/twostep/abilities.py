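"""Correlation and regression layer linking model parameters to abilities.

Pearson correlations with Fisher-z confidence intervals, partial correlation,
the processing-speed x working-memory interaction model on the model-based
weight, an a-priori Monte-Carlo power computation for a correlation test, and
cohort-level ability summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ABILITY_COLUMNS",
    "AbilityScores",
    "pearson_ci",
    "partial_correlation",
    "interaction_model",
    "power_simulation",
    "summarize_abilities",
]

ABILITY_COLUMNS = ["dsst", "tmt_a_s", "tmt_ratio", "digit_span_bw", "mwt"]


@dataclass(frozen=True)
class AbilityScores:
    """One subject's cognitive test scores.

    dsst: correct symbols in 120 s (processing speed); tmt_a_s: Trail Making
    part A seconds (visual attention / speed); tmt_ratio: TMT B/A ratio
    (executive set-switching); digit_span_bw: backwards digit span (verbal
    working memory); mwt: vocabulary-test correct answers out of 37.
    """

    dsst: float
    tmt_a_s: float
    tmt_ratio: float
    digit_span_bw: float
    mwt: float

    def __post_init__(self) -> None:
        for name in ABILITY_COLUMNS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _fisher_ci(r: float, n_eff: int, level: float) -> tuple[float, float]:
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        return r, r
    zcrit = stats.norm.ppf(0.5 + level / 2)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n_eff - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, float, float, float]:
    """Pearson r with a Fisher-z confidence interval and t-test p-value.

    Returns (r, ci_low, ci_high, p).  The interval is
    tanh(atanh(r) +/- z * / sqrt(n - 3)); perfectly linear data yield the
    degenerate interval [r, r].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    lo, hi = _fisher_ci(float(r), x.size, level)
    return float(r), lo, hi, float(p)


def partial_correlation(
    x, y, control, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Correlation of x and y after removing (OLS) the control variables.

    ``control`` may be one variable or a (n, k) matrix.  The Fisher-z interval
    and the t-test use n - 3 - k and n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(control, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, k = C.shape
    if x.size != n or y.size != n or n < 5:
        raise ValueError("need aligned samples with n >= 5")
    Z = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise ValueError("control variables are collinear")
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ beta_x
    ry = y - Z @ beta_y
    if rx.std() < 1e-12 or ry.std() < 1e-12:
        # a variable fully explained by the controls: partial r defined as 0
        return 0.0, 0.0, 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2 * stats.t.sf(abs(t), df=df))
    if abs(r) >= 1.0:
        return r, r, r, 0.0
    zcrit = stats.norm.ppf(0.5 + level / 2)
    half = zcrit / np.sqrt(n - 3 - k)
    z = np.arctanh(r)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half)), p


def interaction_model(
    omega_unconstrained,
    dsst,
    digit_span,
    controls: pd.DataFrame | None = None,
    robust: bool = False,
) -> dict:
    """Processing-speed x working-memory interaction on the model-based weight.

    Median-splits the digit span, z-scores the DSST, and fits
    omega' ~ z(DSST) * group [+ controls] by OLS (omega' on the unconstrained
    logit scale, where the Gaussian error assumption is reasonable).  Returns
    the interaction coefficient with CI and p, R^2, and the within-group DSST
    slopes with their own CIs/p-values.  ``robust`` switches to HC3
    heteroskedasticity-robust standard errors.
    """
    import statsmodels.api as sm

    from .stay import split_scores

    w = np.asarray(omega_unconstrained, dtype=float)
    d = np.asarray(dsst, dtype=float)
    g = split_scores(np.asarray(digit_span, dtype=float), mode="median")
    if len({0, 1} - set(g.tolist())) > 0:
        raise ValueError("both median-split groups must be non-empty")
    z = (d - d.mean()) / d.std(ddof=0)
    cols = {"z_dsst": z, "group_high": g.astype(float), "z_dsst_x_group": z * g}
    if controls is not None:
        for c in controls.columns:
            v = controls[c].to_numpy(dtype=float)
            cols[f"ctrl_{c}"] = (v - v.mean()) / v.std(ddof=0)
    X = sm.add_constant(pd.DataFrame(cols))
    res = sm.OLS(w, X).fit(cov_type="HC3" if robust else "nonrobust")
    ci = res.conf_int()

    def _term(name):
        return {
            "estimate": float(res.params[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
            "p": float(res.pvalues[name]),
        }

    out = {
        "interaction": _term("z_dsst_x_group"),
        "r_squared": float(res.rsquared),
        "n": int(len(w)),
        "slopes": {},
    }
    # within-group simple slopes from separate regressions
    for label, grp in (("low", 0), ("high", 1)):
        mask = g == grp
        Xg = sm.add_constant(pd.DataFrame({"z_dsst": z[mask]}))
        rg = sm.OLS(w[mask], Xg).fit(cov_type="HC3" if robust else "nonrobust")
        cig = rg.conf_int()
        out["slopes"][label] = {
            "estimate": float(rg.params["z_dsst"]),
            "ci_low": float(cig.loc["z_dsst", 0]),
            "ci_high": float(cig.loc["z_dsst", 1]),
            "p": float(rg.pvalues["z_dsst"]),
        }
    return out


def power_simulation(
    true_r: float,
    n: int,
    n_reps: int = 100_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo power of the two-sided Pearson correlation test.

    Draws ``n_reps`` bivariate-normal samples of size ``n`` with population
    correlation ``true_r`` and returns the fraction whose correlation test
    rejects at ``alpha`` — the a-priori power of a correlational design.
    """
    if not abs(true_r) < 1:
        raise ValueError("|true_r| must be < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    # vectorised: y = r*x + sqrt(1-r^2)*e has population correlation r with x
    batch = max(1, min(n_reps, int(2e7 // n)))
    n_sig = 0
    done = 0
    df = n - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df=df)
    rcrit = tcrit / np.sqrt(df + tcrit**2)  # |r| threshold equivalent to the t-test
    while done < n_reps:
        m = min(batch, n_reps - done)
        x = rng.standard_normal((m, n))
        y = true_r * x + np.sqrt(1 - true_r**2) * rng.standard_normal((m, n))
        x -= x.mean(axis=1, keepdims=True)
        y -= y.mean(axis=1, keepdims=True)
        r = (x * y).sum(axis=1) / np.sqrt((x**2).sum(axis=1) * (y**2).sum(axis=1))
        n_sig += int((np.abs(r) > rcrit).sum())
        done += m
    return n_sig / n_reps


def summarize_abilities(cohort: pd.DataFrame) -> dict:
    """Cohort summary: per-measure mean, SD, range, and the correlation matrix.

    ``cohort`` must contain the five ability columns.  Constant columns are
    reported with SD 0 and flagged; their correlations are NaN.
    """
    missing = [c for c in ABILITY_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing ability columns: {missing}")
    sub = cohort[ABILITY_COLUMNS]
    flagged = [c for c in ABILITY_COLUMNS if sub[c].isna().any() or sub[c].std() == 0]
    summary = pd.DataFrame(
        {
            "mean": sub.mean(),
            "sd": sub.std(ddof=1),
            "min": sub.min(),
            "max": sub.max(),
        }
    )
    return {
        "summary": summary,
        "correlations": sub.corr(),
        "flagged": flagged,
        "n": int(len(sub)),
    }
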