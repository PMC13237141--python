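"""Group-level statistics on fitted parameters, attributions and ratings.

Covers the analyses run on the fitted winning model and the raw trial data:

* the valence learning-bias score (alpha_pos - alpha_neg)/(alpha_pos +
  alpha_neg) and its Wilcoxon / one-sample-t group tests,
* Spearman correlations of bias scores with depression (PHQ-9) and
  self-esteem (SDQ-III), jointly FDR-adjusted (Benjamini-Hochberg),
* trial-level linear(-probability) mixed models for external attributions
  with feedback extremity split into within- and between-subject components,
* the model-agnostic mixed model of expectation ratings, and its repeat on
  model-predicted ratings as a posterior predictive check.

Mixed models are REML fits (statsmodels MixedLM); p-values use a
between-within containment degrees-of-freedom scheme (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

from .belief_models import ModelId, ParameterSet, simulate_trajectory, group_by_condition
from .task_engine import TrialRecord, records_to_frame

__all__ = [
    "TestResult",
    "LmmSummary",
    "learning_bias",
    "wilcoxon_signed",
    "one_sample_t",
    "bh_fdr",
    "spearman_with_fdr",
    "within_between_decompose",
    "external_attribution_model",
    "expectation_lmm",
    "posterior_predictive_check",
]


# ---------------------------------------------------------------------------
# scalar scores and simple tests
# ---------------------------------------------------------------------------

def learning_bias(alpha_pos: float, alpha_neg: float) -> float:
    """Valence bias in learning: (a+ - a-) / (a+ + a-), in [-1, 1].

    Positive values mean faster learning from better-than-expected feedback;
    the reference cohort shows a median-negative bias (negativity bias).
    """
    if alpha_pos < 0 or alpha_neg < 0:
        raise ValueError("learning rates must be non-negative")
    total = alpha_pos + alpha_neg
    if total == 0:
        raise ValueError("bias undefined when both learning rates are 0")
    return (alpha_pos - alpha_neg) / total


@dataclass
class TestResult:
    name: str
    statistic: float
    p_raw: float
    n: int
    effect_name: str = ""
    effect_size: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "test": self.name,
            "statistic": self.statistic,
            "p": self.p_raw,
            "n": self.n,
            self.effect_name or "effect": self.effect_size,
            "ci95": [self.ci_low, self.ci_high],
        }
        if self.p_adjusted is not None:
            out["p_fdr"] = self.p_adjusted
        out.update(self.extra)
        return out


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    d = np.sort(d)
    n = len(d)
    return np.sort([(d[i] + d[j]) / 2.0 for i in range(n) for j in range(i, n)])


def wilcoxon_signed(
    x: np.ndarray, y: np.ndarray, *, exact: bool | None = None
) -> TestResult:
    """Paired Wilcoxon signed-rank test with Hodges-Lehmann estimate.

    Zero differences are dropped.  For n <= 12 (or ``exact=True``) the
    two-sided p-value is computed by full enumeration of the 2^n sign
    assignments of the observed ranks; otherwise a normal approximation with
    continuity and tie corrections is used.  Effect size r = |z| / sqrt(n);
    the Hodges-Lehmann estimate is the median of the Walsh averages of the
    paired differences, with a distribution-free 95% CI.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    if exact is None:
        exact = n <= 12

    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    sd = float(np.sqrt(var))
    # z with continuity correction toward the mean
    delta = w_pos - mu
    z = (delta - 0.5 * np.sign(delta)) / sd if delta != 0 else 0.0

    if exact:
        # enumerate all sign assignments of the observed ranks
        obs_dev = abs(w_pos - mu)
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= obs_dev - 1e-12:
                count += 1
        p = count / 2.0**n
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    p = min(p, 1.0)

    walsh = _walsh_averages(d)
    hl = float(np.median(walsh))
    m = len(walsh)
    k = int(np.floor(mu - 1.959964 * sd))
    k = max(k, 0)
    ci_low = float(walsh[k]) if k < m else float(walsh[0])
    ci_high = float(walsh[m - 1 - k]) if k < m else float(walsh[-1])

    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=z,
        p_raw=float(p),
        n=n,
        effect_name="r",
        effect_size=abs(z) / np.sqrt(n),
        ci_low=ci_low,
        ci_high=ci_high,
        extra={"W_pos": w_pos, "hodges_lehmann": hl, "exact": bool(exact)},
    )


def one_sample_t(values: np.ndarray, mu0: float = 0.0) -> TestResult:
    """One-sample t-test with Cohen's d and a noncentral-t CI for d."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0 or np.all(v == v[0]):
        raise ValueError("zero variance")
    mean = v.mean()
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    d = (mean - mu0) / sd

    # CI for d by inverting the noncentral t distribution
    def _solve(target_prob: float) -> float:
        f = lambda nc: stats.nct.cdf(t, n - 1, nc) - target_prob
        lo, hi = t - 10 - 10 * abs(t), t + 10 + 10 * abs(t)
        try:
            from scipy.optimize import brentq

            return brentq(f, lo, hi, xtol=1e-8) / np.sqrt(n)
        except ValueError:
            return float("nan")

    return TestResult(
        name="one_sample_t",
        statistic=float(t),
        p_raw=float(p),
        n=n,
        effect_name="cohens_d",
        effect_size=float(d),
        ci_low=_solve(0.975),
        ci_high=_solve(0.025),
        extra={"mean": float(mean), "sd": float(sd), "df": n - 1},
    )


def bh_fdr(
    p_values: np.ndarray, grouping: np.ndarray | list | None = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, optionally within joint groups.

    ``grouping`` labels p-values that are corrected together (p-values with
    different labels are adjusted independently).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    groups = np.zeros(len(p)) if grouping is None else np.asarray(grouping)
    for g in np.unique(groups):
        mask = groups == g
        pg = p[mask]
        m = len(pg)
        order = np.argsort(pg, kind="stable")
        adj = pg[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[mask] = res
    return out


def spearman_with_fdr(
    pairs: list[tuple[np.ndarray, np.ndarray, str]]
) -> list[TestResult]:
    """Spearman correlations with Fisher-z CIs, p-values jointly BH-adjusted."""
    results = []
    for xv, yv, label in pairs:
        xv = np.asarray(xv, dtype=float)
        yv = np.asarray(yv, dtype=float)
        n = len(xv)
        if n < 5 or len(yv) != n:
            raise ValueError(f"{label}: need equal-length vectors with n >= 5")
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            raise ValueError(f"{label}: constant vector")
        rho, p = stats.spearmanr(xv, yv)
        # Fisher z interval with the Fieller-Hartley-Pearson variance
        z = np.arctanh(rho)
        se = np.sqrt(1.06 / (n - 3))
        results.append(
            TestResult(
                name=f"spearman[{label}]",
                statistic=float(rho),
                p_raw=float(p),
                n=n,
                effect_name="rho",
                effect_size=float(rho),
                ci_low=float(np.tanh(z - 1.959964 * se)),
                ci_high=float(np.tanh(z + 1.959964 * se)),
            )
        )
    adj = bh_fdr(np.array([r.p_raw for r in results]))
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results


def within_between_decompose(
    values: np.ndarray, subjects: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split observations into within-subject and between-subject components.

    within = value - subject mean (sums to 0 per subject);
    between = subject mean - grand mean.  value = within + between + grand mean.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    df = pd.DataFrame({"v": values, "s": subjects})
    subj_mean = df.groupby("s")["v"].transform("mean").to_numpy()
    grand = values.mean()
    return values - subj_mean, subj_mean - grand


# ---------------------------------------------------------------------------
# linear mixed-effects models
# ---------------------------------------------------------------------------

@dataclass
class LmmSummary:
    formula: str
    effects: pd.DataFrame  # beta, se, ci_low, ci_high, df, t, p, beta_std
    random_variances: dict[str, float]
    n_obs: int
    n_subjects: int
    flags: list[str] = field(default_factory=list)

    def beta(self, effect: str) -> float:
        return float(self.effects.loc[effect, "beta"])

    def p(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])

    def to_json_dict(self) -> dict:
        return {
            "formula": self.formula,
            "effects": self.effects.to_dict(orient="index"),
            "random_variances": self.random_variances,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "flags": self.flags,
        }


def _bw_df(data: pd.DataFrame, exog: pd.DataFrame, groups: str) -> dict[str, float]:
    """Between-within containment degrees of freedom per fixed effect."""
    n_obs = len(data)
    n_sub = data[groups].nunique()
    is_between = {}
    for col in exog.columns:
        per_sub = pd.DataFrame({"g": data[groups].to_numpy(), "x": exog[col].to_numpy()})
        is_between[col] = bool((per_sub.groupby("g")["x"].nunique() <= 1).all())
    n_between = sum(is_between.values())  # includes the intercept
    n_within = len(is_between) - n_between
    df_between = max(n_sub - n_between, 2)
    df_within = max(n_obs - n_sub - n_within, 2)
    return {c: (df_between if b else df_within) for c, b in is_between.items()}


def _fit_mixedlm(
    data: pd.DataFrame,
    formula: str,
    re_formula: str | None,
    groups: str = "subject_id",
) -> tuple:
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
        for method in ("powell", "lbfgs", "bfgs"):
            try:
                fit = model.fit(reml=True, method=method, maxiter=1000)
            except Exception as exc:  # singular fits raise LinAlgError etc.
                last_exc = exc
                continue
            # accept only a converged fit with usable standard errors
            if fit.converged and np.all(np.isfinite(fit.bse_fe)) and np.all(
                fit.bse_fe < 1e4
            ):
                return model, fit
    raise RuntimeError(f"mixed-model fit failed ({last_exc})")


def _lmm(
    data: pd.DataFrame,
    formula: str,
    re_formula: str | None,
    *,
    std_continuous: list[str],
    groups: str = "subject_id",
) -> LmmSummary:
    flags: list[str] = []
    try:
        model, fit = _fit_mixedlm(data, formula, re_formula, groups)
        if not fit.converged:
            raise RuntimeError("non-convergence")
    except Exception:
        if re_formula is not None:
            flags.append("random_slope_dropped")
            model, fit = _fit_mixedlm(data, formula, None, groups)
            re_formula = None
        else:
            raise

    fe_names = list(model.exog_names)
    exog = pd.DataFrame(model.exog, columns=fe_names)
    dfs = _bw_df(data, exog, groups)

    beta = fit.fe_params
    se = fit.bse_fe
    rows = {}
    for name in fe_names:
        df_e = dfs[name]
        t = beta[name] / se[name]
        p = 2.0 * stats.t.sf(abs(t), df=df_e)
        crit = stats.t.ppf(0.975, df=df_e)
        rows[name] = {
            "beta": float(beta[name]),
            "se": float(se[name]),
            "ci_low": float(beta[name] - crit * se[name]),
            "ci_high": float(beta[name] + crit * se[name]),
            "df": float(df_e),
            "t": float(t),
            "p": float(p),
        }

    # standardized betas: z-score outcome and continuous predictors, refit
    data_std = data.copy()
    outcome = formula.split("~")[0].strip()
    for col in [outcome] + std_continuous:
        sd = data_std[col].std(ddof=1)
        if sd > 0:
            data_std[col] = (data_std[col] - data_std[col].mean()) / sd
    try:
        _, fit_std = _fit_mixedlm(data_std, formula, re_formula, groups)
        for name in fe_names:
            rows[name]["beta_std"] = float(fit_std.fe_params[name])
    except Exception:
        flags.append("standardized_fit_failed")
        for name in fe_names:
            rows[name]["beta_std"] = float("nan")

    rv = {k: float(v) for k, v in
          zip(fit.cov_re.index, np.diag(fit.cov_re))} if fit.cov_re.size else {}
    rv["residual"] = float(fit.scale)
    return LmmSummary(
        formula=f"{formula} | re: {re_formula or '~1'}",
        effects=pd.DataFrame(rows).T,
        random_variances=rv,
        n_obs=len(data),
        n_subjects=data[groups].nunique(),
        flags=flags,
    )


def _agent_trials_frame(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials[trials["interference"] == "Agent"].copy()
    if df.empty:
        raise ValueError("no Agent-condition trials")
    df["external"] = (df["attribution"] == "external").astype(float)
    # valence: +0.5 better-than-expected, -0.5 worse-than-expected
    df["valence"] = np.where(df["realized_pe"] > 0, 0.5, -0.5)
    extremity = (df["feedback"] - 50.0).abs().to_numpy()
    within, between = within_between_decompose(extremity, df["subject_id"].to_numpy())
    df["extremity_within"] = within
    df["extremity_between"] = between
    return df


def external_attribution_model(
    trials: pd.DataFrame, trait: pd.Series, trait_name: str = "trait"
) -> LmmSummary:
    """Trial-level linear-probability mixed model of external attributions.

    Fixed effects: PE valence (+-0.5), the mean-centered trait score, their
    interaction, and feedback extremity |FB - 50| decomposed into within- and
    between-subject components.  Random intercept and valence slope per
    subject (slope dropped, and flagged, on a singular fit).

    ``trait`` is indexed by subject_id; it is mean-centered internally.
    """
    df = _agent_trials_frame(trials)
    centered = trait - trait.mean()
    df["trait"] = df["subject_id"].map(centered)
    if df["trait"].isna().any():
        missing = sorted(set(df.loc[df["trait"].isna(), "subject_id"]))
        raise ValueError(f"missing trait scores for subjects {missing}")
    summary = _lmm(
        df,
        "external ~ valence * trait + extremity_within + extremity_between",
        "~valence",
        std_continuous=["trait", "extremity_within", "extremity_between"],
    )
    summary.formula += f" [trait={trait_name}]"
    return summary


def expectation_lmm(trials: pd.DataFrame) -> LmmSummary:
    """Model-agnostic mixed model of expectation ratings.

    expectation ~ trial_c * ability * interference with Trial centered within
    condition, Ability coded High = +0.5 / Low = -0.5, Interference coded
    Agent = +0.5 / NoAgent = -0.5; random intercept and Trial slope per
    subject.
    """
    df = trials.copy()
    df["trial_c"] = df["trial_within"] - df["trial_within"].mean()
    df["ability_c"] = np.where(df["ability"] == "High", 0.5, -0.5)
    df["interference_c"] = np.where(df["interference"] == "Agent", 0.5, -0.5)
    return _lmm(
        df,
        "expectation ~ trial_c * ability_c * interference_c",
        "~trial_c",
        std_continuous=["trial_c"],
    )


def posterior_predictive_check(
    fits: dict[str, ParameterSet],
    sessions: dict[str, list[TrialRecord]],
    model: ModelId = ModelId.M5_attribution_weighting,
) -> dict[str, LmmSummary]:
    """Re-run the model-agnostic analysis on model-predicted expectations.

    For every subject with a fitted parameter set, noise-free expectation
    trajectories are simulated from the (posterior-mean) parameters along the
    recorded feedback/attribution sequence, and `expectation_lmm` is fitted
    to observed and predicted ratings alike.  Subjects without a fit are
    excluded with a warning.
    """
    obs_frames, pred_frames = [], []
    for sid, session in sessions.items():
        if sid not in fits:
            warnings.warn(f"no fit for subject {sid}; excluded", stacklevel=2)
            continue
        frame = records_to_frame(session)
        obs_frames.append(frame)
        trajs = simulate_trajectory(model, fits[sid], session)
        pred = frame.copy()
        by_cond = group_by_condition(session)
        for cid, traj in trajs.items():
            globals_ = [r.trial_global for r in by_cond[cid]]
            pred.loc[pred["trial_global"].isin(globals_), "expectation"] = np.asarray(
                traj.expectations
            )
        pred_frames.append(pred)
    if not obs_frames:
        raise ValueError("no subjects with fits")
    return {
        "observed": expectation_lmm(pd.concat(obs_frames, ignore_index=True)),
        "predicted": expectation_lmm(pd.concat(pred_frames, ignore_index=True)),
    }
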