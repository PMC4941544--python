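"""Horizontal integration: p-value combination and random-effects meta-analysis.

Per-feature statistics from independent studies are combined in two ways:
the p-values through Fisher's, Stouffer's, or the additive method (exact
Irwin-Hall distribution of the sum of p-values for few studies, its normal
limit for m >= 20 — "add-CLT"), and the effect sizes through a
random-effects model y_i = mu + u_i + e_i with u_i ~ N(0, tau^2),
e_i ~ N(0, v_i), estimated by restricted maximum likelihood (REML).
Benjamini-Hochberg adjustment converts combined p-values to FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

COMBINERS = ("fisher", "stouffer", "add_clt")

#: clamp for p-values of exactly 0 (or 1 where the transform needs p < 1)
P_CLAMP = 1e-300

#: number of studies at which the additive method switches from the exact
#: Irwin-Hall CDF to its central-limit normal approximation
ADD_CLT_SWITCH = 20


@dataclass
class MetaInput:
    """Per-feature inputs to the meta-analysis step.

    y and v are the per-study Hedges' g estimates and their variances
    (SE_g^2); p the per-study two-sided DE p-values; m the number of
    contributing studies (features measured in only a subset of studies are
    combined over that subset).
    """

    feature_id: str
    y: np.ndarray
    v: np.ndarray
    p: np.ndarray
    m: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.m == 0:
            self.m = self.y.size
        if not (self.y.size == self.v.size == self.p.size == self.m >= 1):
            raise ValueError(
                f"feature {self.feature_id}: inconsistent study counts "
                f"(y={self.y.size}, v={self.v.size}, p={self.p.size}, m={self.m})"
            )
        if np.any(self.v <= 0):
            raise ValueError(f"feature {self.feature_id}: variances must be > 0")
        if np.any((self.p <= 0) | (self.p > 1)):
            raise ValueError(f"feature {self.feature_id}: p-values must be in (0,1]")


@dataclass
class MetaFeature:
    """Cross-study summary of one feature."""

    feature_id: str
    mu_hat: float
    tau2_hat: float
    se_mu: float
    p_combined: float
    fdr: float = float("nan")
    is_de: bool = False
    m: int = 0


def _clamp(p: np.ndarray, low: float = P_CLAMP, high: float = 1.0) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < low) or np.any(p > high):
        warnings.warn(f"p-values clamped to [{low}, {high}]")
    return np.clip(p, low, high)


def fisher_combine(p) -> float:
    """Fisher's method: -2*sum(ln p) ~ chi-square with 2m df under the null."""
    p = _clamp(p)
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, 2 * p.size))


def stouffer_combine(p) -> float:
    """Stouffer's method: sum of normal quantiles z_i = Phi^-1(1-p_i) over sqrt(m)."""
    p = _clamp(p, low=P_CLAMP, high=1.0 - 1e-16)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(np.sum(z) / math.sqrt(p.size)))


def irwin_hall_cdf(x: float, m: int) -> float:
    """CDF of the sum of m independent U(0,1) variables.

    Alternating-sum formula F(x) = (1/m!) * sum_k (-1)^k C(m,k) (x-k)^m,
    evaluated with log-domain binomial terms and compensated summation so
    the cancellation stays controlled for m up to a few dozen.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if x <= 0.0:
        return 0.0
    if x >= m:
        return 1.0
    terms = []
    for k in range(int(math.floor(x)) + 1):
        if x - k <= 0.0:  # boundary term (x integral) contributes nothing
            continue
        # log of binom(m,k) * (x-k)^m / m!
        log_t = (
            -special.gammaln(k + 1)
            - special.gammaln(m - k + 1)
            + m * math.log(x - k)
        )
        terms.append((-1.0) ** k * math.exp(log_t))
    return float(min(max(math.fsum(terms), 0.0), 1.0))


def additive_combine(p, switch: int = ADD_CLT_SWITCH) -> float:
    """Additive combination of p-values (add-CLT).

    The statistic is the sum of p-values; small sums are significant.  For
    m < ``switch`` the exact Irwin-Hall left tail is returned; for
    m >= ``switch`` the normal limit Phi((mean(p) - 1/2)/sqrt(1/(12m))).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0,1]")
    m = p.size
    if m < 1:
        raise ValueError("need at least one p-value")
    x = float(np.sum(p))
    if m < switch:
        return irwin_hall_cdf(x, m)
    return float(stats.norm.cdf((x / m - 0.5) / math.sqrt(1.0 / (12.0 * m))))


def _reml_neg_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2))
        + math.log(np.sum(w))
        + float(np.sum(w * (y - mu) ** 2))
    )


def reml_estimate(
    y, v, tol: float = 1e-8, max_iter: int = 200
) -> tuple[float, float, float]:
    """REML estimates (mu_hat, tau2_hat, se_mu) of the random-effects model.

    The restricted log-likelihood is maximized over tau^2 in
    [0, 10*var(y) + max(v)] by bounded scalar optimization; the overall
    effect is the inverse-variance weighted mean with weights
    1/(v_i + tau2_hat).  A single study returns its own estimate with
    tau2 = 0 and a warning.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.size != v.size or y.size < 1:
        raise ValueError("y and v must be equal-length, nonempty")
    if np.any(v <= 0):
        raise ValueError("all variances must be > 0")
    if y.size == 1:
        warnings.warn("single study: tau^2 not estimable, set to 0")
        return float(y[0]), 0.0, float(math.sqrt(v[0]))
    tau2_max = 10.0 * float(np.var(y, ddof=1)) + float(np.max(v))
    if tau2_max <= 0:
        tau2_hat = 0.0
    else:
        res = optimize.minimize_scalar(
            _reml_neg_loglik,
            bounds=(0.0, tau2_max),
            args=(y, v),
            method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        if not res.success:
            raise RuntimeError(
                f"REML did not converge in {max_iter} iterations "
                f"(last tau2 = {res.x:.6g})"
            )
        tau2_hat = float(res.x)
        # the bounded optimizer never returns the boundary exactly; snap to 0
        # when the likelihood at 0 is at least as high
        if _reml_neg_loglik(0.0, y, v) <= _reml_neg_loglik(tau2_hat, y, v):
            tau2_hat = 0.0
    w = 1.0 / (v + tau2_hat)
    mu_hat = float(np.sum(w * y) / np.sum(w))
    se_mu = float(math.sqrt(1.0 / np.sum(w)))
    return mu_hat, tau2_hat, se_mu


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def combine_feature(inputs: MetaInput, method: str = "add_clt") -> MetaFeature:
    """Combine one feature's per-study statistics into a MetaFeature.

    p_combined via the selected combiner, (mu_hat, tau2_hat, se_mu) via
    REML; the DE flag is filled later by the pipeline once FDR and the
    top-|SMD| selection have been applied.
    """
    if method not in COMBINERS:
        raise ValueError(f"method must be one of {COMBINERS}")
    combiner = {
        "fisher": fisher_combine,
        "stouffer": stouffer_combine,
        "add_clt": additive_combine,
    }[method]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu_hat, tau2_hat, se_mu = reml_estimate(inputs.y, inputs.v)
    p_combined = combiner(inputs.p)
    return MetaFeature(
        feature_id=inputs.feature_id,
        mu_hat=mu_hat,
        tau2_hat=tau2_hat,
        se_mu=se_mu,
        p_combined=max(p_combined, P_CLAMP),
        m=inputs.m,
    )
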