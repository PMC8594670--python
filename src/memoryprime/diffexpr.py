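"""Per-transcript one-sample inference on replicate log2 ratios with
empirical-Bayes variance moderation.

Each transcript contributes a handful of replicate log-ratio values per
contrast.  Gene-wise sample variances s2 (residual df d = n - 1) are
shrunk toward a prior variance s0sq with prior degrees of freedom d0,
estimated by moment matching on z = log s2 under the hierarchical model
s2 | sigma2 ~ sigma2 * chi2_d / d,  sigma2 ~ s0sq * d0 / chi2_d0.
The moderated t uses the posterior variance and d0 + d degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

#: smallest representable positive p, used when the posterior variance is zero
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class EBHyperparams:
    """Prior of the variance hierarchy: d0 may be math.inf (no dispersion)."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is the valid no-moderation limit (ordinary t); estimation
        # itself always returns d0 > 0 or the +inf sentinel.
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be non-negative, got {self.d0}")
        if not (self.s0sq > 0):
            raise ValueError(f"s0sq must be positive, got {self.s0sq}")


def fit_gene_stats(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript mean, unbiased variance and residual df.

    ratios: ReplicateRatios rows for ONE contrast (columns transcript_id, M).
    Every transcript must carry >= 2 replicate values.
    """
    grouped = ratios.groupby("transcript_id")["M"]
    n = grouped.size()
    if (n < 2).any():
        bad = n.index[n < 2][0]
        raise ValueError(
            f"transcript {bad!r} has {int(n.loc[bad])} replicate value(s); "
            "need >= 2 for a variance"
        )
    out = pd.DataFrame(
        {
            "mean_M": grouped.mean(),
            "s2": grouped.var(ddof=1),
            "n": n.astype(int),
        }
    )
    out["d"] = out["n"] - 1
    out.index.name = "transcript_id"
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return math.inf
    f = lambda x: special.polygamma(1, x) - y
    lo = 1e-8
    hi = max(10.0, 2.0 / y)
    while f(hi) > 0:
        hi *= 10
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def estimate_eb_hyperparams(s2: np.ndarray, d: int) -> EBHyperparams:
    """Moment-matching estimate of (d0, s0sq) from gene-wise variances.

    Works on z = log s2: var(z) in excess of trigamma(d/2) identifies d0 via
    trigamma(d0/2) = var(z) - trigamma(d/2); the mean of z then identifies
    s0sq after removing the chi-square log-biases of both levels.  When the
    observed dispersion does not exceed the sampling dispersion, d0 is the
    +inf sentinel and s0sq the common variance implied by mean(z).
    """
    s2 = np.asarray(s2, dtype=float)
    if d < 1:
        raise ValueError("residual df must be >= 1")
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all gene variances are zero: degenerate data")
    if not positive.all():
        logger.warning(
            "dropping %d zero variances from hyperparameter estimation",
            int((~positive).sum()),
        )
        s2 = s2[positive]
    if len(s2) < 100:
        logger.warning(
            "only %d transcripts available for hyperparameter estimation; "
            "estimates may be unstable (>= 100 recommended)",
            len(s2),
        )
    z = np.log(s2)
    zbar = float(z.mean())
    # bias of log s2 around log sigma2 at the sampling level
    bias_d = float(special.digamma(d / 2.0) - math.log(d / 2.0))
    excess = float(z.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return EBHyperparams(d0=math.inf, s0sq=math.exp(zbar - bias_d))
    d0 = 2.0 * _trigamma_inverse(excess)
    bias_d0 = float(special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    # E[z] = log s0sq + bias_d - bias_d0
    return EBHyperparams(d0=d0, s0sq=math.exp(zbar - bias_d + bias_d0))


def moderated_t(gene_stats: pd.DataFrame, hyper: EBHyperparams, alpha: float = 0.05) -> pd.DataFrame:
    """ContrastTable: posterior variance, moderated t, p, direction, DE flag.

    Posterior variance s2_post = (d0*s0sq + d*s2)/(d0 + d); t = mean_M /
    sqrt(s2_post/n); two-sided p from the t distribution with d0 + d df
    (standard normal when d0 is infinite).  d0 = 0 reproduces the ordinary
    one-sample t.  Rows with zero posterior variance get the floor p (or 1
    when the mean is also 0) and are flagged in `zero_variance`.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    mean = gene_stats["mean_M"].to_numpy(dtype=float)
    s2 = gene_stats["s2"].to_numpy(dtype=float)
    d = gene_stats["d"].to_numpy(dtype=float)
    n = gene_stats["n"].to_numpy(dtype=float)

    if math.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0sq)
        df_total = np.full_like(s2, math.inf)
    else:
        s2_post = (hyper.d0 * hyper.s0sq + d * s2) / (hyper.d0 + d)
        df_total = hyper.d0 + d

    zero_var = s2_post <= 0.0
    se = np.sqrt(np.where(zero_var, np.nan, s2_post) / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / se
    if math.isinf(hyper.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)
    # zero posterior variance: exact calling on the mean
    t = np.where(zero_var, np.where(mean == 0.0, 0.0, np.sign(mean) * np.inf), t)
    p = np.where(zero_var, np.where(mean == 0.0, 1.0, P_FLOOR), p)
    p = np.where(p == 0.0, P_FLOOR, p)  # keep p in (0, 1]

    out = gene_stats.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["df_total"] = df_total
    out["p"] = p
    out["direction"] = np.where(mean >= 0.0, "up", "down")
    out["is_de"] = out["p"].to_numpy() < alpha
    out["zero_variance"] = zero_var
    return out


def call_dets(contrast_table: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """DET calls at strict p < alpha: transcript_id -> direction."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    de = contrast_table[contrast_table["p"] < alpha]
    return dict(zip(de.index, de["direction"]))


def analyze_contrast(
    ratios: pd.DataFrame,
    alpha: float = 0.05,
    hyper: EBHyperparams | None = None,
    mean_tol: float = 1e-9,
) -> pd.DataFrame:
    """Fit gene stats and run the moderated t for one contrast's ratios.

    If every gene variance is exactly zero (noise-free data) empirical-Bayes
    estimation is impossible; calls then degenerate to exact thresholding on
    |mean_M| > mean_tol.
    """
    gs = fit_gene_stats(ratios)
    if (gs["s2"] <= 0.0).all():
        logger.warning("all variances zero; using exact noise-free calling")
        mean = gs["mean_M"].to_numpy()
        nonzero = np.abs(mean) > mean_tol
        out = gs.copy()
        out["s2_post"] = 0.0
        t = np.zeros(len(mean))
        t[nonzero] = np.sign(mean[nonzero]) * np.inf
        out["t"] = t
        out["df_total"] = math.inf
        out["p"] = np.where(nonzero, P_FLOOR, 1.0)
        out["direction"] = np.where(mean >= 0.0, "up", "down")
        out["is_de"] = nonzero
        out["zero_variance"] = True
        return out
    if hyper is None:
        hyper = estimate_eb_hyperparams(gs["s2"].to_numpy(), int(gs["d"].iloc[0]))
    return moderated_t(gs, hyper, alpha=alpha)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
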