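"""Empirical-Bayes moderated differential expression for log2 intensity data.

The model is the standard moderated t for two-group microarray contrasts:
per-feature residual variances s2_g (d_g degrees of freedom each) are
shrunk toward a common prior via a scaled inverse-chi-square hierarchy,

    s2_g | sigma2_g ~ sigma2_g * chi2(d_g) / d_g
    1/sigma2_g      ~ chi2(d0) / (d0 * s0_sq)

giving the posterior variance  s~2 = (d0*s0_sq + d_g*s2_g) / (d0 + d_g)
and a t statistic on d0 + d_g degrees of freedom.  Hyperparameters (d0,
s0_sq) are estimated by method of moments on log variances.

A feature is called significant under the joint rule used throughout this
package: linear fold change > 2.0 or < 0.5, AND Benjamini-Hochberg adjusted
p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

FC_HIGH = 2.0
FC_LOW = 0.5
FDR_THRESHOLD = 0.05


class DiffExprError(ValueError):
    pass


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled inverse-chi-square prior on residual variances.

    ``d0`` may be ``math.inf`` (no between-feature variance heterogeneity
    beyond sampling noise: every feature shares variance ``s0_sq``).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is allowed as the no-moderation limit (ordinary pooled t)
        if not (self.d0 >= 0):
            raise DiffExprError(f"prior df must be non-negative: {self.d0}")
        if not (self.s0_sq > 0):
            raise DiffExprError(f"prior variance must be positive: {self.s0_sq}")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return math.inf
    # asymptote trigamma(y) ~ 1/y for large y gives the start value
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_ebayes_prior(s2_values: np.ndarray, d_g: int) -> EBayesPrior:
    """Method-of-moments fit of (d0, s0_sq) from per-feature variances.

    Works on z = log(s2): E[z] and Var[z] have closed forms under the
    hierarchy, so matching the empirical mean and variance of z yields the
    hyperparameters.  Zero/negative variances are excluded from the fit.
    If the empirical spread of z does not exceed the chi-square sampling
    contribution, d0 is unbounded and s0_sq is the geometric-mean-based
    location estimate.
    """
    s2 = np.asarray(s2_values, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        raise DiffExprError(
            f"need >=10 positive residual variances to fit the prior, got {s2.size}"
        )
    if d_g < 1:
        raise DiffExprError(f"residual df must be >=1, got {d_g}")
    z = np.log(s2)
    # z = log(s0_sq) + log(chi2_d0-mixture terms); center by the known
    # chi-square log-moment so the remaining moments isolate (d0, s0_sq)
    e = z - special.digamma(d_g / 2.0) + math.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, d_g / 2.0))
    if excess <= 0:
        # no heterogeneity beyond sampling noise: unbounded prior df, and the
        # geometric mean of the observed variances as the common variance
        return EBayesPrior(d0=math.inf, s0_sq=float(math.exp(z.mean())))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(
        e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    )
    return EBayesPrior(d0=d0, s0_sq=float(s0_sq))


def moderated_t(
    mean1: np.ndarray,
    mean2: np.ndarray,
    n1: int,
    n2: int,
    s2: np.ndarray,
    d_g: int,
    prior: EBayesPrior,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated t statistic, two-sided p, and total df for mean1 - mean2.

    With d0 = 0 this reduces to the ordinary pooled two-sample t; with
    d0 unbounded every feature is tested against the prior variance alone.
    """
    if n1 < 2 or n2 < 2:
        raise DiffExprError(f"need >=2 replicates per group, got {n1} and {n2}")
    mean1 = np.asarray(mean1, dtype=float)
    mean2 = np.asarray(mean2, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d0, s0_sq = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = float("inf")
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    if np.any(s2_post <= 0):
        raise DiffExprError("degenerate posterior variance (s~2 = 0)")
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = (mean1 - mean2) / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    return t_mod, p, df_total


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DiffExprError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def is_significant(fc: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Joint call: |fold change| beyond 2-fold and BH q below 0.05."""
    fc = np.asarray(fc, dtype=float)
    q = np.asarray(q, dtype=float)
    return ((fc > FC_HIGH) | (fc < FC_LOW)) & (q < FDR_THRESHOLD)


def call_de(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    stratum: str,
    case: str,
    control: str,
    prior: EBayesPrior | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t contrast within one stratum.

    ``matrix`` is features x samples of log2 intensities; ``sample_sheet``
    has columns sample, group, stratum.  Fold change is the geometric-mean
    ratio 2**(case mean log2 - control mean log2).  Returns one row per
    feature with columns feature_id, log2fc, fc, s2, t_mod, p, q,
    direction, significant.
    """
    required = {"sample", "group", "stratum"}
    if not required.issubset(sample_sheet.columns):
        raise DiffExprError(f"sample sheet needs columns {sorted(required)}")
    sheet = sample_sheet[sample_sheet["stratum"] == stratum]
    if sheet.empty:
        raise DiffExprError(f"stratum {stratum!r} absent from sample sheet")
    groups = set(sheet["group"])
    for g in (case, control):
        if g not in groups:
            raise DiffExprError(f"group {g!r} absent from stratum {stratum!r}")
    case_samples = sheet.loc[sheet["group"] == case, "sample"].tolist()
    ctrl_samples = sheet.loc[sheet["group"] == control, "sample"].tolist()
    n1, n2 = len(case_samples), len(ctrl_samples)
    if n1 < 2 or n2 < 2:
        raise DiffExprError(
            f"need >=2 replicates per group in stratum {stratum!r}: "
            f"{case}={n1}, {control}={n2}"
        )
    missing = (set(case_samples) | set(ctrl_samples)) - set(matrix.columns)
    if missing:
        raise DiffExprError(f"samples missing from matrix: {sorted(missing)[:5]}")

    x1 = matrix[case_samples].to_numpy(dtype=float)
    x2 = matrix[ctrl_samples].to_numpy(dtype=float)
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    d_g = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + (
        (x2 - mean2[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d_g
    if prior is None:
        prior = fit_ebayes_prior(s2, d_g)
    t_mod, p, _ = moderated_t(mean1, mean2, n1, n2, s2, d_g, prior)
    q = bh_adjust(p)
    log2fc = mean1 - mean2
    fc = np.exp2(log2fc)
    significant = is_significant(fc, q)
    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    return pd.DataFrame(
        {
            "feature_id": matrix.index.astype(str),
            "log2fc": log2fc,
            "fc": fc,
            "s2": s2,
            "t_mod": t_mod,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": significant,
        }
    ).set_index("feature_id", drop=False)
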