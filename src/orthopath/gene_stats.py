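"""Per-study, per-feature effect sizes and differential-expression tests.

For each feature of a two-group study the module computes the standardized
mean difference (Cohen's d), its sampling variance, and the small-sample
corrected Hedges' g, plus a two-sided differential-expression p-value from a
pooled t, Welch t, or an empirical-Bayes moderated t that shrinks per-feature
variances toward a common prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

TEST_METHODS = ("pooled_t", "welch_t", "moderated_t")


class ZeroVarianceError(ValueError):
    """Raised when the pooled standard deviation is zero (effect undefined)."""


@dataclass
class StudyEffect:
    """Effect-size statistics of one feature in one study.

    d is the standardized mean difference (disease - control)/S_pooled, so a
    positive value means up-regulated in disease; g = J(df)*d is the
    bias-corrected Hedges' g with standard error SE_g = J(df)*sqrt(V_d).
    """

    feature_id: str
    study_id: str
    n1: int
    n2: int
    d: float
    v_d: float
    g: float
    se_g: float
    p: float
    df: float


def hedges_correction_factor(n: float) -> float:
    """Small-sample bias correction J(n) for Cohen's d.

    J(n) = Gamma(n/2) / ( sqrt(n/2) * Gamma((n-1)/2) ) with n the degrees of
    freedom of the pooled variance, evaluated through log-gamma for
    numerical stability.  Strictly increasing in n, < 1 for finite n, -> 1
    as n grows.
    """
    n = float(n)
    if n < 2:
        raise ValueError(f"degrees of freedom must be >= 2, got {n}")
    return float(
        np.exp(special.gammaln(n / 2.0) - special.gammaln((n - 1) / 2.0))
        / np.sqrt(n / 2.0)
    )


def compute_study_effect(
    group1_values: np.ndarray, group2_values: np.ndarray
) -> StudyEffect:
    """Cohen's d, its variance, and Hedges' g for disease vs control values.

    Parameters
    ----------
    group1_values : array
        Disease-group observations of one feature (missing values removed).
    group2_values : array
        Control-group observations.

    Returns
    -------
    StudyEffect with statistics fields filled (ids empty, p-value NaN;
    the DE test is a separate step).

    Raises
    ------
    ZeroVarianceError
        If both groups are constant (pooled SD zero).
    """
    x1 = np.asarray(group1_values, dtype=float)
    x2 = np.asarray(group2_values, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >= 2 observations per group, got {n1} and {n2}")
    df = n1 + n2 - 2
    s_pooled_sq = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    if s_pooled_sq <= 0:
        raise ZeroVarianceError("pooled standard deviation is zero")
    d = (x1.mean() - x2.mean()) / np.sqrt(s_pooled_sq)
    v_d = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    j = hedges_correction_factor(df)
    return StudyEffect(
        feature_id="",
        study_id="",
        n1=n1,
        n2=n2,
        d=float(d),
        v_d=float(v_d),
        g=float(j * d),
        se_g=float(j * np.sqrt(v_d)),
        p=float("nan"),
        df=float(df),
    )


def _group_matrices(study) -> tuple[np.ndarray, np.ndarray]:
    cols1 = study.group_columns("disease")
    cols2 = study.group_columns("control")
    return study.values[:, cols1], study.values[:, cols2]


def _masked_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row count, mean and unbiased variance ignoring NaN."""
    n = np.sum(np.isfinite(x), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=1)
        var = np.nanvar(x, axis=1, ddof=1)
    mean = np.where(n > 0, mean, np.nan)
    var = np.where(n > 1, var, np.nan)
    return n, mean, var


def study_effects_table(study) -> pd.DataFrame:
    """Vectorized per-feature effect sizes for a whole study.

    Features with fewer than 2 observed samples in either group, or with
    zero pooled variance, are excluded.  Returns a DataFrame indexed by
    feature id with columns n1, n2, d, v_d, g, se_g, df.
    """
    x1, x2 = _group_matrices(study)
    n1, m1, v1 = _masked_moments(x1)
    n2, m2, v2 = _masked_moments(x2)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        d = (m1 - m2) / np.sqrt(sp2)
        v_d = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
        j = np.exp(special.gammaln(df / 2.0) - special.gammaln((df - 1) / 2.0)) / np.sqrt(
            df / 2.0
        )
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(sp2) & (sp2 > 0)
    out = pd.DataFrame(
        {
            "n1": n1.astype(int),
            "n2": n2.astype(int),
            "d": d,
            "v_d": v_d,
            "g": j * d,
            "se_g": j * np.sqrt(v_d),
            "df": df,
        },
        index=pd.Index(study.features, name="feature_id"),
    )
    return out.loc[ok]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x asymptote
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(
    s2: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for per-feature variances.

    Moment-matching on z = log s^2: with e = z - digamma(df/2) + log(df/2),
    Var(e) = trigamma(df/2) + trigamma(d0/2) and
    E(e) = log s0^2 - digamma(d0/2) + log(d0/2).  If the trigamma equation
    has no positive solution the prior is degenerate (d0 = inf, complete
    pooling toward the common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return float("inf"), float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(
        np.exp(e_mean + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_sq


def de_test_per_study(study, method: str = "moderated_t") -> dict[str, float]:
    """Two-sided differential-expression p-value per feature.

    ``pooled_t`` uses the pooled variance with df = n1+n2-2; ``welch_t``
    uses Welch-Satterthwaite df; ``moderated_t`` (default) replaces each
    feature's variance with the posterior
    s~^2 = (d0*s0^2 + df*s^2)/(d0 + df) under the empirical-Bayes prior of
    :func:`estimate_variance_prior` and tests on d0 + df degrees of freedom.
    Features constant in both groups get p = 1; features with fewer than two
    observed samples in a group are omitted.
    """
    if method not in TEST_METHODS:
        raise ValueError(f"method must be one of {TEST_METHODS}")
    x1, x2 = _group_matrices(study)
    n1, m1, v1 = _masked_moments(x1)
    n2, m2, v2 = _masked_moments(x2)
    measurable = (n1 >= 2) & (n2 >= 2)
    df_pooled = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_pooled
        diff = m1 - m2
        if method == "pooled_t":
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            t = diff / se
            df = df_pooled
        elif method == "welch_t":
            a, b = v1 / n1, v2 / n2
            se = np.sqrt(a + b)
            t = diff / se
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        else:  # moderated_t
            d0, s0_sq = estimate_variance_prior(
                sp2[measurable], df_pooled[measurable]
            )
            if np.isinf(d0):
                s_tilde_sq = np.full_like(sp2, s0_sq)
                df = np.full_like(sp2, np.inf)
            else:
                s_tilde_sq = (d0 * s0_sq + df_pooled * sp2) / (d0 + df_pooled)
                df = d0 + df_pooled
            se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
            t = diff / se
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    out: dict[str, float] = {}
    for i, feat in enumerate(study.features):
        if not measurable[i]:
            continue
        pi = p[i]
        if not np.isfinite(pi):
            pi = 1.0  # constant feature: statistic undefined
        out[feat] = float(min(pi, 1.0))
    return out
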