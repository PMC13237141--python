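"""Model comparison: PSIS-LOO per subject x model, random-effects BMS.

Predictive accuracy of each fitted model is estimated by leave-one-out
cross-validation approximated with Pareto-smoothed importance sampling
(PSIS-LOO) over the posterior draws; the Pareto tail-shape diagnostic k-hat
flags trials whose importance ratios are too heavy-tailed for a reliable
estimate (k-hat > 0.7).

Subject-wise LOO sums then enter random-effects Bayesian model selection:
a Dirichlet prior over population model frequencies is updated by a
variational algorithm, exceedance probabilities are computed by Monte Carlo
over the Dirichlet posterior, and the Bayesian omnibus risk (BOR) — the
posterior probability that all model frequencies are equal — protects the
exceedance probabilities against chance differences:
pxp_k = (1 - BOR) * xp_k + BOR / K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from arviz import psislw
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["LooResult", "BmsResult", "psis_loo", "bms", "KHAT_THRESHOLD"]

KHAT_THRESHOLD = 0.7


@dataclass
class LooResult:
    elpd_pointwise: np.ndarray  # per-trial elpd contributions
    elpd_sum: float
    khat: np.ndarray  # per-trial Pareto shape estimates (NaN = degenerate)
    n_bad: int  # trials with khat > 0.7

    def to_json_dict(self) -> dict:
        return {
            "elpd_sum": float(self.elpd_sum),
            "n_points": int(self.elpd_pointwise.size),
            "n_bad_khat": int(self.n_bad),
            "max_khat": float(np.nanmax(self.khat)) if self.khat.size else float("nan"),
        }


def psis_loo(loglik_matrix: np.ndarray) -> LooResult:
    """PSIS-LOO from a (draws x trials) pointwise log-likelihood matrix.

    Importance ratios for leaving out trial i are the reciprocal likelihoods
    1 / p(y_i | theta^s); their log, -loglik, is Pareto-smoothed per trial
    (generalized Pareto fitted to the largest 20% of ratios, tail ratios
    replaced by expected order statistics, weights truncated).  The smoothed,
    normalized weights give elpd_i = log sum_s w_s p(y_i | theta^s).

    Trials whose likelihood is constant across draws have degenerate
    (uniform) weights; their khat is reported as NaN and elpd equals the
    constant log-likelihood.
    """
    ll = np.asarray(loglik_matrix, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik_matrix must be 2-D (draws x trials)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("loglik_matrix contains non-finite entries")
    n_draws, n_points = ll.shape
    if n_draws < 400:
        warnings.warn(
            f"only {n_draws} draws; PSIS-LOO expects at least a few hundred",
            stacklevel=2,
        )

    elpd = np.empty(n_points)
    khat = np.full(n_points, np.nan)
    spread = ll.max(axis=0) - ll.min(axis=0)
    degenerate = spread < 1e-12
    for i in np.where(degenerate)[0]:
        elpd[i] = ll[0, i]  # uniform weights: elpd is the constant itself

    idx = np.where(~degenerate)[0]
    if idx.size:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lw_smooth, k = psislw(-ll[:, idx].T)
        khat[idx] = np.asarray(k, dtype=float)
        # psislw normalizes along the sample axis: logsumexp(lw) = 0 per point
        elpd[idx] = logsumexp(lw_smooth + ll[:, idx].T, axis=1)

    return LooResult(
        elpd_pointwise=elpd,
        elpd_sum=float(elpd.sum()),
        khat=khat,
        n_bad=int(np.sum(khat[np.isfinite(khat)] > KHAT_THRESHOLD)),
    )


@dataclass
class BmsResult:
    model_names: tuple[str, ...]
    alpha: np.ndarray  # Dirichlet posterior over model frequencies
    expected_frequencies: np.ndarray
    xp: np.ndarray  # unprotected exceedance probabilities
    pxp: np.ndarray  # protected exceedance probabilities
    bor: float
    model_posteriors: np.ndarray  # per-subject model attribution (subjects x models)

    def to_json_dict(self) -> dict:
        return {
            "models": list(self.model_names),
            "alpha": self.alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "xp": self.xp.tolist(),
            "pxp": self.pxp.tolist(),
            "bor": float(self.bor),
        }


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    asum, a0sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(asum)
        - gammaln(alpha).sum()
        - gammaln(a0sum)
        + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(asum)))
    )


def bms(
    elpd_sums: np.ndarray,
    model_names: tuple[str, ...] | None = None,
    *,
    alpha0: float = 1.0,
    n_exceedance_samples: int = 100_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BmsResult:
    """Random-effects Bayesian model selection from per-subject evidence.

    ``elpd_sums`` is a (subjects x models) matrix of log model evidence
    approximations (PSIS-LOO sums).  The variational update alternates
    per-subject model attributions u_nk with the Dirichlet pseudo-counts
    alpha_k until convergence.  Exceedance probabilities are Monte Carlo
    estimates over the Dirichlet posterior; BOR compares the free energy of
    the random-effects model against the equal-frequency null.
    """
    L = np.asarray(elpd_sums, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("elpd_sums must be (subjects >= 2) x (models >= 2)")
    if not np.all(np.isfinite(L)):
        n, k = np.argwhere(~np.isfinite(L))[0]
        raise ValueError(f"non-finite evidence for subject index {n}, model index {k}")
    n_sub, n_mod = L.shape
    names = model_names or tuple(f"model_{k}" for k in range(n_mod))

    a0 = np.full(n_mod, float(alpha0))
    alpha = a0.copy()
    u = np.full((n_sub, n_mod), 1.0 / n_mod)
    for _ in range(max_iter):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = a0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    # free energy of the random-effects model vs the equal-frequency null
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    f_rfx = float(np.sum(u * L) + np.sum(u * e_ln_r) + entropy - _dirichlet_kl(alpha, a0))
    f_null = float(np.sum(logsumexp(L, axis=1) - np.log(n_mod)))
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))

    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_exceedance_samples)
    winners = np.argmax(samples, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / n_exceedance_samples

    pxp = (1.0 - bor) * xp + bor / n_mod
    return BmsResult(
        model_names=names,
        alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        xp=xp,
        pxp=pxp,
        bor=bor,
        model_posteriors=u,
    )
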