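"""Causal estimators and heterogeneity/pleiotropy diagnostics.

Given a :class:`~summr.instruments.HarmonizedSet` of J instruments with
exposure effects g_j (SE s_gj) and outcome effects G_j (SE s_Gj), the per-SNP
Wald ratio is r_j = G_j / g_j with first-order standard error s_Gj / |g_j|.

* **IVW** combines the ratios with inverse-variance weights
  w_j = g_j² / s_Gj², equivalent to weighted least squares of G on g through
  the origin.  The multiplicative random-effects model (default, the standard
  two-sample MR convention) inflates the fixed-effect SE by
  max(1, sqrt(Q/(J-2))), where Q = sum w_j (r_j - b)² is Cochran's Q with
  J-1 degrees of freedom.
* **MR-Egger** adds an intercept to the weighted regression; the slope is the
  causal estimate and the intercept the average directional-pleiotropy effect
  per SNP.  A nonzero intercept (p < 0.05) flags directional pleiotropy.
* **Weighted median** takes the weight-interpolated median of the ordered
  ratios; it is consistent while instruments carrying at least half the
  weight are valid.  Its SE comes from a seeded parametric bootstrap.

P-values use the normal approximation z = beta/se throughout; 95% CIs use the
two-sided multiplier 1.959964.  For a binary outcome every estimate is also
reported on the odds-ratio scale as exp of the beta-scale quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientInstrumentsError

Z95 = 1.959964  # two-sided 95% normal multiplier

ESTIMATE_COLUMNS = ["method", "nsnp", "beta", "se", "ci_low", "ci_high",
                    "pvalue", "or", "or_ci_low", "or_ci_high"]


@dataclass
class MREstimate:
    """A causal-effect estimate on the per-SD-of-exposure scale.

    ``or_scale`` is ``(OR, OR_ci_low, OR_ci_high)``, present exactly when the
    outcome is binary (beta is then a log odds ratio).
    """

    method: str
    nsnp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    or_scale: tuple[float, float, float] | None = None

    def as_row(self) -> dict:
        row = {"method": self.method, "nsnp": self.nsnp, "beta": self.beta,
               "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
               "pvalue": self.pvalue, "or": np.nan, "or_ci_low": np.nan,
               "or_ci_high": np.nan}
        if self.or_scale is not None:
            row["or"], row["or_ci_low"], row["or_ci_high"] = self.or_scale
        return row


@dataclass
class HeterogeneityResult:
    """Cochran's Q for the per-SNP ratio estimates."""

    q: float
    df: int
    pvalue: float


@dataclass
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropic effect per SNP."""

    intercept: float
    se: float
    pvalue: float

    @property
    def significant(self) -> bool:
        """Directional-pleiotropy flag at the conventional 0.05 level."""
        return self.pvalue < 0.05


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")


def _estimate(method: str, nsnp: int, beta: float, se: float, binary: bool) -> MREstimate:
    lo, hi = beta - Z95 * se, beta + Z95 * se
    or_scale = (float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi))) if binary else None
    return MREstimate(method, int(nsnp), float(beta), float(se), float(lo), float(hi),
                      _normal_p(beta, se), or_scale)


def _get(record, name):
    try:
        return record[name]
    except (TypeError, KeyError, IndexError):
        return getattr(record, name)


def wald_ratio(record, *, binary: bool = False, second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate, ratio of outcome to exposure effects.

    ``record`` is any mapping/object with ``beta_exp``, ``beta_out``,
    ``se_out`` (and ``se_exp`` for second-order SEs).  First-order delta
    method: se = se_out/|beta_exp|.
    """
    be = float(_get(record, "beta_exp"))
    bo = float(_get(record, "beta_out"))
    so = float(_get(record, "se_out"))
    if be == 0.0:
        raise DomainError("wald ratio undefined for beta_exp = 0")
    beta = bo / be
    if second_order:
        sg = float(_get(record, "se_exp"))
        se = np.sqrt(so * so / (be * be) + bo * bo * sg * sg / be ** 4)
    else:
        se = so / abs(be)
    return _estimate("wald_ratio", 1, beta, se, binary)


def _weights(hset, second_order: bool) -> np.ndarray:
    """Inverse-variance weights of the per-SNP ratios."""
    be, so = hset.beta_exp, hset.se_out
    if np.any(be == 0.0):
        raise DomainError("beta_exp = 0 among instruments; wald ratios undefined")
    var = so ** 2 / be ** 2
    if second_order:
        var = var + hset.beta_out ** 2 * hset.se_exp ** 2 / be ** 4
    return 1.0 / var


def ivw(hset, model: str = "multiplicative_random", *, second_order: bool = False,
        ) -> tuple[MREstimate, HeterogeneityResult | None]:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    Returns the pooled estimate and Cochran's Q heterogeneity result (``None``
    when J < 2).  ``model`` is ``"fixed"`` or ``"multiplicative_random"``;
    the latter never deflates the fixed-effects SE.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = hset.nsnp
    if j == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    w = _weights(hset, second_order)
    r = hset.beta_out / hset.beta_exp
    sw = w.sum()
    beta = float((w * r).sum() / sw)
    se = float(1.0 / np.sqrt(sw))

    het = None
    if j >= 2:
        q = float((w * (r - beta) ** 2).sum())
        het = HeterogeneityResult(q, j - 1, float(stats.chi2.sf(q, j - 1)))
        if model == "multiplicative_random" and j >= 3:
            se *= max(1.0, np.sqrt(het.q / (j - 2)))
    return _estimate("ivw", j, beta, se, hset.outcome_binary), het


def egger(hset) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger weighted regression of outcome on exposure effects.

    Requires J >= 3 and the exposure-increasing allele orientation (applied
    defensively here).  SEs are inflated by max(1, sqrt(RSS_w/(J-2)))
    (multiplicative overdispersion); p-values are two-sided normal.
    """
    j = hset.nsnp
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    be, bo, so = hset.beta_exp.copy(), hset.beta_out.copy(), hset.se_out
    neg = be < 0
    be[neg], bo[neg] = -be[neg], -bo[neg]

    w = 1.0 / so ** 2
    x = np.column_stack([np.ones(j), be])
    xtw = x.T * w
    xtwx_inv = np.linalg.inv(xtw @ x)
    coef = xtwx_inv @ (xtw @ bo)
    resid = bo - x @ coef
    rss_w = float((w * resid ** 2).sum())
    scale2 = max(1.0, rss_w / (j - 2))
    ses = np.sqrt(np.diag(xtwx_inv) * scale2)

    slope = _estimate("egger", j, float(coef[1]), float(ses[1]), hset.outcome_binary)
    intercept = EggerIntercept(float(coef[0]), float(ses[0]),
                               _normal_p(float(coef[0]), float(ses[0])))
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median: interpolate ordered values across the
    cumulative-midpoint grid s_j = cum(w')_j - w'_j/2 at probability 0.5."""
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, v))


def weighted_median(hset, n_boot: int = 1000, seed: int | None = None,
                    *, second_order: bool = False) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The bootstrap resamples each exposure and outcome effect from a normal
    with its reported SE, recomputes the weighted median, and takes the SD
    over ``n_boot`` replicates.  ``seed`` is mandatory (determinism contract).
    """
    j = hset.nsnp
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 instruments")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    w = _weights(hset, second_order)
    r = hset.beta_out / hset.beta_exp
    point = _weighted_median(r, w)

    rng = np.random.default_rng(seed)
    be = hset.beta_exp + hset.se_exp * rng.standard_normal((n_boot, j))
    bo = hset.beta_out + hset.se_out * rng.standard_normal((n_boot, j))
    be = np.where(be == 0.0, np.finfo(float).tiny, be)
    rb = bo / be
    wb = be ** 2 / hset.se_out ** 2
    if second_order:
        wb = 1.0 / (1.0 / wb + bo ** 2 * hset.se_exp ** 2 / be ** 4)
    ests = np.empty(n_boot)
    for i in range(n_boot):
        ests[i] = _weighted_median(rb[i], wb[i])
    se = float(ests.std(ddof=1))
    return _estimate("weighted_median", j, point, se, hset.outcome_binary)


def leave_one_out(hset, model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated with each instrument removed in turn.

    Flags any drop that changes the sign of the estimate or moves the 95% CI
    across zero relative to the all-SNP estimate.
    """
    if hset.nsnp < 2:
        raise InsufficientInstrumentsError("leave-one-out requires at least 2 instruments")
    full, _ = ivw(hset, model=model)
    rows = []
    for snp in hset.snp_ids:
        est, _ = ivw(hset.drop([snp]), model=model)
        rows.append({
            "snp_id": snp, "nsnp": est.nsnp, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
            "sign_change": np.sign(est.beta) != np.sign(full.beta),
            "significance_change": (est.ci_low > 0 or est.ci_high < 0)
                                   != (full.ci_low > 0 or full.ci_high < 0),
        })
    return pd.DataFrame(rows)


def funnel_data(hset) -> pd.DataFrame:
    """Per-SNP funnel-plot coordinates: Wald ratio vs precision 1/se(ratio)."""
    if hset.nsnp < 1:
        raise InsufficientInstrumentsError("funnel data requires at least 1 instrument")
    ratio = hset.beta_out / hset.beta_exp
    precision = np.abs(hset.beta_exp) / hset.se_out
    return pd.DataFrame({"snp_id": hset.snp_ids, "ratio": ratio, "precision": precision})


def estimates_table(estimates) -> pd.DataFrame:
    """Serialize a sequence of :class:`MREstimate` to the canonical TSV frame."""
    return pd.DataFrame([e.as_row() for e in estimates], columns=ESTIMATE_COLUMNS)
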