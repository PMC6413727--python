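"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume per-SNP Wald ratios (or harmonized instruments, for
MR-Egger) and return pooled estimates on the log-odds scale; odds ratios are
produced only at the reporting boundary. The suite covers fixed/random
inverse-variance weighting with Cochran's Q and I^2, MR-Egger regression,
the simple/weighted/penalized-weighted median family, and penalized and
robust IVW variants.

Conventions
-----------
* Wald-ratio SE: the full delta-method expansion
  sqrt(se_out^2/b_exp^2 + b_out^2 se_exp^2 / b_exp^4) by default
  (``se_method="second_order"``); the common first-order form
  se_out/|b_exp| is available as ``"first_order"``.
* 95% CIs use a 1.96 multiplier throughout; IVW P-values use the normal
  approximation, Egger P-values a t distribution with k-2 df.
* Penalty weights follow the standard convention: each inverse-variance
  weight is multiplied by min(1, 20 q_j), q_j the upper-tail chi-square(1)
  probability of the SNP's contribution to Cochran's Q. Penalized IVW
  anchors the contributions at the IVW estimate; the penalized weighted
  median anchors them at the weighted-median estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .records import (
    ConvergenceError,
    DegenerateInstrumentError,
    HarmonizedInstrument,
    HeterogeneityResult,
    InsufficientInstrumentsError,
    MREstimate,
    MRError,
    WaldRatio,
)

log = logging.getLogger(__name__)

CI_Z = 1.96  # 95% CI multiplier
PENALTY_SCALE = 20.0  # penalty = min(1, 20 * q_j)

SE_METHODS = ("second_order", "first_order")


def wald_ratio(
    instr: HarmonizedInstrument, se_method: str = "second_order"
) -> WaldRatio:
    """Per-SNP causal-effect ratio beta_outcome/beta_exposure with delta SE."""
    if instr.beta_exposure == 0:
        raise DegenerateInstrumentError(
            f"SNP {instr.snp_id}: zero exposure beta, Wald ratio undefined"
        )
    bx, by = instr.beta_exposure, instr.beta_outcome
    sx, sy = instr.se_exposure, instr.se_outcome
    if se_method == "first_order":
        se = sy / abs(bx)
    elif se_method == "second_order":
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise MRError(f"unknown se_method {se_method!r}; use one of {SE_METHODS}")
    return WaldRatio(snp_id=instr.snp_id, beta_xy=by / bx, se_xy=se)


def wald_ratios(
    instruments: list[HarmonizedInstrument], se_method: str = "second_order"
) -> list[WaldRatio]:
    return [wald_ratio(v, se_method) for v in instruments]


def _arrays(ratios: list[WaldRatio]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    beta = np.array([r.beta_xy for r in ratios], dtype=float)
    se = np.array([r.se_xy for r in ratios], dtype=float)
    w = se**-2
    if not np.all(np.isfinite(w)):
        bad = ratios[int(np.argmax(~np.isfinite(w)))].snp_id
        raise MRError(f"non-finite weight for SNP {bad}")
    return beta, se, w


def _estimate(method: str, beta: float, se: float, n: int, dist: str = "norm",
              df: int | None = None) -> MREstimate:
    if se == 0:  # degenerate exact fit
        pval = 1.0 if beta == 0 else 0.0
    elif dist == "t":
        pval = 2.0 * float(stats.t.sf(abs(beta / se), df))
    else:
        pval = 2.0 * float(stats.norm.sf(abs(beta / se)))
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - CI_Z * se,
        ci_high=beta + CI_Z * se,
        pval=pval,
        n_snps=n,
    )


def heterogeneity(ratios: list[WaldRatio], pooled_beta: float) -> HeterogeneityResult:
    """Cochran's Q about ``pooled_beta`` and I^2 = max(0, (Q-df)/Q) * 100."""
    beta, _, w = _arrays(ratios)
    Q = float(np.sum(w * (beta - pooled_beta) ** 2))
    df = len(ratios) - 1
    pval = float(stats.chi2.sf(Q, df)) if df > 0 else float("nan")
    i2 = max(0.0, (Q - df) / Q * 100.0) if Q > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, pval=pval, i2=i2)


def ivw_estimate(
    ratios: list[WaldRatio], model: str = "auto"
) -> tuple[MREstimate, HeterogeneityResult | None]:
    """Inverse-variance weighted pooling of Wald ratios.

    ``model`` is ``"fixed"``, ``"random"`` (DerSimonian-Laird additive tau^2)
    or ``"auto"``: random effects iff heterogeneity is significant
    (P < 0.01 and I^2 > 50%), otherwise fixed — matching the usual
    meta-analytic model-selection rule. A single ratio is returned as-is with
    heterogeneity undefined.
    """
    if not ratios:
        raise InsufficientInstrumentsError("IVW needs at least one Wald ratio")
    if model not in ("auto", "fixed", "random"):
        raise MRError(f"unknown IVW model {model!r}")
    beta, se, w = _arrays(ratios)
    k = len(ratios)
    if k == 1:
        est = _estimate("IVW-fixed", float(beta[0]), float(se[0]), 1)
        return est, None

    b_fixed = float(np.sum(w * beta) / np.sum(w))
    het = heterogeneity(ratios, b_fixed)

    use_random = model == "random" or (model == "auto" and het.significant)
    if use_random:
        s1, s2 = float(np.sum(w)), float(np.sum(w**2))
        tau2 = max(0.0, (het.Q - het.df) / (s1 - s2 / s1))
        w_re = 1.0 / (se**2 + tau2)
        b = float(np.sum(w_re * beta) / np.sum(w_re))
        s = float(np.sum(w_re)) ** -0.5
        est = _estimate("IVW-random", b, s, k)
    else:
        s = float(np.sum(w)) ** -0.5
        est = _estimate("IVW-fixed", b_fixed, s, k)
    return est, het


def orient_positive(
    instruments: list[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Flip both betas of any instrument with a negative exposure beta.

    The Egger intercept is only interpretable when all instruments point in
    the same exposure direction; this is the conventional orientation.
    """
    out = []
    for v in instruments:
        if v.beta_exposure < 0:
            out.append(
                HarmonizedInstrument(
                    snp_id=v.snp_id,
                    beta_exposure=-v.beta_exposure,
                    se_exposure=v.se_exposure,
                    beta_outcome=-v.beta_outcome,
                    se_outcome=v.se_outcome,
                    pval_exposure=v.pval_exposure,
                    pval_outcome=v.pval_outcome,
                    chrom=v.chrom,
                    pos=v.pos,
                    gene=v.gene,
                    orientation_flipped=not v.orientation_flipped,
                )
            )
        else:
            out.append(v)
    return out


def egger_regression(
    instruments: list[HarmonizedInstrument],
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression of outcome on exposure betas, free intercept.

    Weights are 1/se_outcome^2; instruments are first oriented so all
    exposure betas are non-negative. Standard errors carry a multiplicative
    dispersion floored at 1 (residual SD is never allowed to shrink SEs
    below the fixed-effect ones); P-values use t with k-2 df. Returns
    (slope, intercept) estimates; a nonzero intercept indicates average
    directional pleiotropy and the slope is the pleiotropy-adjusted causal
    effect.
    """
    k = len(instruments)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {k}")
    oriented = orient_positive(instruments)
    bx = np.array([v.beta_exposure for v in oriented])
    by = np.array([v.beta_outcome for v in oriented])
    sy = np.array([v.se_outcome for v in oriented])
    if np.ptp(bx) == 0:
        raise MRError("all exposure betas equal: Egger design matrix is singular")
    fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2).fit()
    # fit.bse is scaled by the residual MSE; refloor the dispersion at 1
    sigma = math.sqrt(fit.scale)
    adj = max(1.0, sigma) / sigma
    se_inter, se_slope = (float(s) * adj for s in fit.bse)
    inter, slope = (float(b) for b in fit.params)
    return (
        _estimate("Egger-slope", slope, se_slope, k, dist="t", df=k - 2),
        _estimate("Egger-intercept", inter, se_inter, k, dist="t", df=k - 2),
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with cumulative-weight linear interpolation.

    Sort by value; standardize weights to sum 1; assign each observation the
    midpoint of its cumulative-weight span; linearly interpolate the value at
    cumulative weight 0.5. With equal weights this reproduces the ordinary
    interpolated median.
    """
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    total = w.sum()
    if total <= 0:
        raise MRError("all-zero weights in weighted median")
    w = w / total
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, v))


def _penalty_weights(
    beta: np.ndarray, w: np.ndarray, anchor: float
) -> np.ndarray:
    """min(1, 20 q_j) penalties from each SNP's Q contribution about ``anchor``."""
    q = stats.chi2.sf(w * (beta - anchor) ** 2, df=1)
    return np.minimum(1.0, PENALTY_SCALE * q)


def median_estimate(
    ratios: list[WaldRatio],
    variant: str = "weighted",
    n_boot: int = 10_000,
    seed: int = 1,
) -> MREstimate:
    """Simple, weighted, or penalized-weighted median of the Wald ratios.

    ``simple`` uses uniform weights; ``weighted`` uses inverse-variance
    weights; ``penalized`` multiplies the inverse-variance weights by
    min(1, 20 q_j), with Q contributions anchored at the weighted-median
    estimate, down-weighting outlying ratios. The SE is a parametric
    bootstrap: each ratio is resampled ~ Normal(beta_j, se_j), the median
    recomputed with fixed weights, and the SD over ``n_boot`` draws taken.
    """
    if len(ratios) < 3:
        raise InsufficientInstrumentsError(
            f"median estimators need >= 3 ratios, got {len(ratios)}"
        )
    if n_boot < 1:
        raise MRError("n_boot must be >= 1")
    beta, se, iv_w = _arrays(ratios)
    if variant == "simple":
        w = np.ones_like(beta)
        method = "SimpleMedian"
    elif variant == "weighted":
        w = iv_w
        method = "WeightedMedian"
    elif variant == "penalized":
        anchor = weighted_median(beta, iv_w)
        w = iv_w * _penalty_weights(beta, iv_w, anchor)
        method = "PenalizedWeightedMedian"
    else:
        raise MRError(f"unknown median variant {variant!r}")
    if w.sum() <= 0:
        raise MRError("all weights zero after penalization")

    point = weighted_median(beta, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=beta, scale=se, size=(n_boot, beta.size))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = weighted_median(draws[i], w)
    se_boot = float(boot.std(ddof=1)) if n_boot > 1 else float("nan")
    return _estimate(method, point, se_boot, len(ratios))


def penalized_ivw(ratios: list[WaldRatio]) -> MREstimate:
    """Fixed-effect IVW with weights penalized by each SNP's Q contribution.

    Contributions are computed about the unpenalized IVW estimate; weights
    are multiplied by min(1, 20 q_j) and the pool recomputed, shrinking the
    influence of heterogeneous outliers. With homogeneous data all penalties
    are 1 and the estimate equals plain IVW.
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("penalized IVW needs >= 2 ratios")
    beta, _, w = _arrays(ratios)
    b0 = float(np.sum(w * beta) / np.sum(w))
    wp = w * _penalty_weights(beta, w, b0)
    if wp.sum() <= 0:
        raise MRError("all weights zero after penalization")
    b = float(np.sum(wp * beta) / np.sum(wp))
    s = float(np.sum(wp)) ** -0.5
    return _estimate("PenalizedIVW", b, s, len(ratios))


@dataclass(slots=True)
class _RobustFit:
    beta: float
    se: float
    iterations: int
    trace: list[float]


def _tukey_weights(u: np.ndarray, c: float = 4.685) -> np.ndarray:
    out = np.zeros_like(u)
    inside = np.abs(u) < c
    out[inside] = (1.0 - (u[inside] / c) ** 2) ** 2
    return out


def _tukey_psi_prime(u: np.ndarray, c: float = 4.685) -> np.ndarray:
    out = np.zeros_like(u)
    inside = np.abs(u) < c
    t = (u[inside] / c) ** 2
    out[inside] = (1.0 - t) * (1.0 - 5.0 * t)
    return out


def _mm_origin_fit(
    y: np.ndarray, x: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> _RobustFit:
    """MM-style robust regression through the origin with Tukey's biweight.

    Start from the >= 50%-breakdown weighted-median slope, fix the residual
    scale at the MAD of the initial residuals, then iterate redescending
    IRLS (c = 4.685). The SE is the heteroskedasticity-robust sandwich.
    """
    b = weighted_median(y / x, x**2)  # high-breakdown start
    resid = y - b * x
    scale = float(np.median(np.abs(resid - np.median(resid)))) * 1.4826
    if scale <= 0:
        # exact fit at the start: no residual scatter to down-weight
        scale = 1.0
    trace = [b]
    for it in range(max_iter):
        u = (y - b * x) / scale
        w = _tukey_weights(u)
        if np.sum(w * x**2) <= 0:
            raise ConvergenceError("robust fit degenerate: all weights zero", trace)
        b_new = float(np.sum(w * x * y) / np.sum(w * x**2))
        trace.append(b_new)
        if abs(b_new - b) <= tol * max(1.0, abs(b)):
            b = b_new
            break
        b = b_new
    else:
        raise ConvergenceError(
            f"robust IVW did not converge in {max_iter} iterations", trace
        )
    # asymptotic M-estimator variance: sigma^2 sum(x^2 psi(u)^2) / (sum(x^2 psi'(u)))^2
    # with an n/(n-1) small-sample inflation
    u = (y - b * x) / scale
    psi = u * _tukey_weights(u)
    denom = float(np.sum(x**2 * _tukey_psi_prime(u)))
    if denom <= 0:
        raise ConvergenceError("robust fit degenerate: non-positive curvature", trace)
    n = len(y)
    # Huber's correction inflates the variance for the variability of psi'
    psi_p = _tukey_psi_prime(u)
    kappa = 1.0 + (1.0 / n) * float(np.var(psi_p)) / float(np.mean(psi_p)) ** 2
    var = (
        kappa**2
        * (n / (n - 1))
        * scale**2
        * float(np.sum(x**2 * psi**2))
        / denom**2
    )
    return _RobustFit(beta=b, se=math.sqrt(var), iterations=len(trace) - 1, trace=trace)


def robust_ivw(ratios: list[WaldRatio], penalized: bool = False) -> MREstimate:
    """Robust IVW: MM regression through the origin of beta/se on 1/se.

    Tukey's biweight (tuning constant 4.685) from a high-breakdown start
    resists gross outlier ratios; ``penalized`` additionally applies the
    min(1, 20 q_j) penalty factors to the working weights first. The CI uses
    the robust sandwich SE with a normal approximation.
    """
    if len(ratios) < 3:
        raise InsufficientInstrumentsError("robust IVW needs >= 3 ratios")
    beta, se, w = _arrays(ratios)
    if penalized:
        b0 = float(np.sum(w * beta) / np.sum(w))
        pen = _penalty_weights(beta, w, b0)
        se_eff = se / np.sqrt(np.maximum(pen, 1e-300))
    else:
        se_eff = se
    fit = _mm_origin_fit(beta / se_eff, 1.0 / se_eff)
    method = "PenalizedRobustIVW" if penalized else "RobustIVW"
    return _estimate(method, fit.beta, fit.se, len(ratios))


@dataclass(slots=True)
class EstimateReport:
    """All estimators' pooled results plus the heterogeneity block."""

    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult | None
    skipped: dict[str, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([e.to_dict() for e in self.estimates])


def estimate_all(
    instruments: list[HarmonizedInstrument],
    model: str = "auto",
    se_method: str = "second_order",
    n_boot: int = 10_000,
    seed: int = 1,
) -> EstimateReport:
    """Run the IVW estimator and the six alternatives on shared inputs.

    Returns a report shaped like the conventional comparison table: IVW
    (fixed/random per ``model``), the three median variants, penalized IVW
    and the two robust IVW variants. Estimators that need more SNPs than
    provided are skipped with a reason rather than raising.
    """
    ratios = wald_ratios(instruments, se_method)
    ivw, het = ivw_estimate(ratios, model=model)
    report = EstimateReport(estimates=[ivw], heterogeneity=het)
    if len(ratios) < 3:
        for name in (
            "SimpleMedian", "WeightedMedian", "PenalizedWeightedMedian",
            "PenalizedIVW", "RobustIVW", "PenalizedRobustIVW",
        ):
            report.skipped[name] = f"needs >= 3 instruments, got {len(ratios)}"
        return report
    for variant in ("simple", "weighted", "penalized"):
        report.estimates.append(
            median_estimate(ratios, variant, n_boot=n_boot, seed=seed)
        )
    report.estimates.append(penalized_ivw(ratios))
    report.estimates.append(robust_ivw(ratios, penalized=False))
    report.estimates.append(robust_ivw(ratios, penalized=True))
    return report
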