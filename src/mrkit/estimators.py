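"""Causal-effect estimators for two-sample MR on summary statistics.

All four estimators operate on the per-SNP Wald ratios r_j = beta_outcome_j /
beta_exposure_j with inverse-variance weights w_j = beta_exposure_j² / se_outcome_j²
(the first-order delta-method precision of the ratio):

* **IVW** — the precision-weighted mean of the ratios, algebraically identical to
  weighted least squares of outcome betas on exposure betas through the origin.
  Consistent when every instrument is valid.
* **MR-Egger** — the same weighted regression with a free intercept; a non-zero
  intercept measures directional (unbalanced horizontal) pleiotropy and the slope
  is a pleiotropy-adjusted causal estimate, valid under the InSIDE condition.
* **Weighted median** — the interpolated 50% point of the weight-ordered ratios;
  consistent when valid instruments carry at least half of the total weight.
* **Weighted mode** — the argmax of a normal-kernel weighted density of the
  ratios; consistent when the largest group of instruments sharing an estimate
  is the valid one.

Estimates are reported per exposure unit and rescaled to odds ratios per one SD
of the exposure using the :class:`~mrkit.summary.ExposureSpec` scaling constant.
Median and mode standard errors come from a parametric bootstrap; IVW and Egger
use their analytic forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, NamedTuple, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientInstrumentsError, UndefinedRatioError, ValidationError
from .summary import InstrumentSet

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

IvwModel = Literal["fixed", "multiplicative_random"]
EggerSeMethod = Literal["multiplicative", "plain"]


@dataclass(frozen=True)
class BootstrapSpec:
    """Parametric-bootstrap controls for the median and mode estimators."""

    n_replicates: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("bootstrap needs at least 2 replicates")


class OrScale(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


class CochranQ(NamedTuple):
    q: float
    df: int
    p_value: float


@dataclass(frozen=True)
class EggerIntercept:
    """Directional-pleiotropy test: average pleiotropic log-odds effect per SNP."""

    value: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class PerSnpEstimate:
    """One SNP's Wald-ratio estimate rescaled to an OR per exposure SD."""

    rsid: str
    ratio: float
    se: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class MrResult:
    """A causal estimate with its per-SD odds-ratio scaling and diagnostics."""

    method: str
    beta_per_unit: float
    se_per_unit: float
    beta_per_sd: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    q_statistic: Optional[float] = None
    q_df: Optional[int] = None
    q_p: Optional[float] = None
    egger_intercept: Optional[EggerIntercept] = None
    per_snp: tuple[PerSnpEstimate, ...] = ()
    note: Optional[str] = None


def scale_to_or(beta_per_unit: float, se_per_unit: float, sd_value: float) -> OrScale:
    """Rescale a per-unit log-odds effect to an OR per one exposure SD.

    The p-value is the two-sided normal tail of beta/SE and is invariant to the
    SD constant; the 95% CI uses the 1.96 normal multiplier.
    """
    if sd_value <= 0:
        raise ValidationError(f"sd_value must be positive, got {sd_value!r}")
    beta_sd = beta_per_unit * sd_value
    half_width = Z_95 * se_per_unit * sd_value
    z = beta_per_unit / se_per_unit
    with np.errstate(over="ignore"):  # an unidentified ratio gets an infinite CI bound
        return OrScale(
            odds_ratio=float(np.exp(beta_sd)),
            ci_low=float(np.exp(beta_sd - half_width)),
            ci_high=float(np.exp(beta_sd + half_width)),
            p_value=float(2.0 * stats.norm.sf(abs(z))),
        )


def _ratio_arrays(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ratios, delta-method SEs, IVW weights); requires non-zero exposure betas."""
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        bad = ", ".join(instruments.rsids[i] for i in zero)
        raise UndefinedRatioError(f"zero exposure beta for: {bad}")
    ratios = by / bx
    ratio_se = sy / np.abs(bx)
    weights = bx**2 / sy**2
    return ratios, ratio_se, weights


def _per_snp_estimates(instruments: InstrumentSet) -> tuple[PerSnpEstimate, ...]:
    ratios, ratio_se, _ = _ratio_arrays(instruments)
    sd = instruments.exposure.sd_value
    out = []
    for rsid, r, s in zip(instruments.rsids, ratios, ratio_se):
        scaled = scale_to_or(r, s, sd)
        out.append(PerSnpEstimate(rsid, float(r), float(s), *scaled))
    return tuple(out)


def cochran_q(instruments: InstrumentSet, beta_ref: float) -> CochranQ:
    """Cochran's heterogeneity statistic of the Wald ratios around ``beta_ref``.

    Q = sum_j w_j (r_j − beta_ref)² with IVW weights; df = n − 1; p from the
    chi-square upper tail. Q is zero exactly when all ratios coincide.
    """
    if len(instruments) < 2:
        raise InsufficientInstrumentsError("heterogeneity needs at least 2 SNPs")
    ratios, _, weights = _ratio_arrays(instruments)
    q = float(np.sum(weights * (ratios - beta_ref) ** 2))
    df = len(instruments) - 1
    return CochranQ(q=q, df=df, p_value=float(stats.chi2.sf(q, df)))


def ivw_estimate(instruments: InstrumentSet, model: IvwModel = "fixed") -> MrResult:
    """Inverse-variance-weighted causal estimate.

    beta = sum(w_j r_j)/sum(w_j) with w_j = beta_x_j²/se_y_j². The fixed-effect
    SE is 1/sqrt(sum w_j); the multiplicative random-effects model inflates it by
    max(1, sqrt(Q/(n−1))), so under-dispersed sets fall back to the fixed SE.
    Cochran's Q is always attached when n >= 2.
    """
    ratios, _, weights = _ratio_arrays(instruments)
    n = len(instruments)
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se = float(1.0 / np.sqrt(np.sum(weights)))

    note = None
    q = df = qp = None
    if n >= 2:
        q, df, qp = cochran_q(instruments, beta)
    if model == "multiplicative_random":
        if n < 2:
            note = "single SNP: multiplicative_random fell back to fixed-effect SE"
        else:
            se *= max(1.0, np.sqrt(q / df))
    elif model != "fixed":
        raise ValidationError(f"unknown IVW model {model!r}")

    sd = instruments.exposure.sd_value
    scaled = scale_to_or(beta, se, sd)
    return MrResult(
        method="ivw",
        beta_per_unit=beta,
        se_per_unit=se,
        beta_per_sd=beta * sd,
        or_per_sd=scaled.odds_ratio,
        ci_low=scaled.ci_low,
        ci_high=scaled.ci_high,
        p_value=scaled.p_value,
        n_snps=n,
        q_statistic=q,
        q_df=df,
        q_p=qp,
        per_snp=_per_snp_estimates(instruments),
        note=note,
    )


def _oriented(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposure betas re-oriented non-negative, outcome betas flipped to match."""
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign, sy


def egger_estimate(
    instruments: InstrumentSet, se_method: EggerSeMethod = "multiplicative"
) -> MrResult:
    """MR-Egger weighted regression with a free intercept.

    Exposure betas are oriented non-negative (flipping the paired outcome betas)
    before fitting outcome betas on exposure betas with weights 1/se_y². The
    intercept, with SE, 95% CI and two-sided p, is the directional-pleiotropy
    test; the slope is the pleiotropy-adjusted causal estimate. The default SE
    convention multiplies the weighted-least-squares SEs by
    max(1, sqrt(Q'/(n−2))) where Q' is the residual heterogeneity, which matches
    how the intervals in the accompanying serum-mineral analysis were computed;
    ``se_method="plain"`` gives the unscaled WLS SEs.
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs at least 3 SNPs, got {n}")
    bx, by, sy = _oriented(instruments)
    if np.ptp(bx) == 0:
        raise ValidationError("degenerate design: all exposure betas identical after orientation")

    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    intercept, slope = (float(v) for v in fit.params)
    # statsmodels' bse already carry sqrt(scale) with scale = Q'/(n-2); undo it
    # for the plain convention, floor it at 1 for the multiplicative one.
    scale = float(fit.scale)
    plain_se = np.asarray(fit.bse) / np.sqrt(scale)
    if se_method == "multiplicative":
        ses = plain_se * max(1.0, np.sqrt(scale))
    elif se_method == "plain":
        ses = plain_se
    else:
        raise ValidationError(f"unknown Egger SE method {se_method!r}")
    intercept_se, slope_se = (float(s) for s in ses)

    sd = instruments.exposure.sd_value
    scaled = scale_to_or(slope, slope_se, sd)
    z0 = intercept / intercept_se
    egger_int = EggerIntercept(
        value=intercept,
        se=intercept_se,
        ci_low=intercept - Z_95 * intercept_se,
        ci_high=intercept + Z_95 * intercept_se,
        p_value=float(2.0 * stats.norm.sf(abs(z0))),
    )
    return MrResult(
        method="egger",
        beta_per_unit=slope,
        se_per_unit=slope_se,
        beta_per_sd=slope * sd,
        or_per_sd=scaled.odds_ratio,
        ci_low=scaled.ci_low,
        ci_high=scaled.ci_high,
        p_value=scaled.p_value,
        n_snps=n,
        egger_intercept=egger_int,
        per_snp=_per_snp_estimates(instruments),
    )


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Interpolated weighted median.

    Values are sorted; with weights normalised to sum 1 and cumulative-midpoint
    positions p_j = cum_j − w_j/2, the estimate is the linear interpolation of
    value against p at p = 0.5. With equal weights this is the ordinary
    interpolated median.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValidationError("weighted_median of empty sequence")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    w = w / w.sum()
    positions = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, positions, v))


def _bootstrap_se(
    instruments: InstrumentSet,
    point_fn: Callable[[np.ndarray, np.ndarray], float],
    bootstrap: BootstrapSpec,
) -> float:
    """Parametric bootstrap: resample betas from N(beta, SE), re-estimate, take the SD."""
    bx = instruments.beta_exposure
    sx = instruments.se_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    rng = np.random.default_rng(bootstrap.seed)
    n_rep = bootstrap.n_replicates
    bx_star = bx + rng.standard_normal((n_rep, bx.size)) * sx
    by_star = by + rng.standard_normal((n_rep, by.size)) * sy
    estimates = np.empty(n_rep)
    for i in range(n_rep):
        bxi = bx_star[i]
        # a resampled exposure beta of exactly zero would make the ratio blow up
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        ratios = by_star[i] / bxi
        weights = bxi**2 / sy**2
        estimates[i] = point_fn(ratios, weights)
    return float(np.std(estimates, ddof=1))


def weighted_median_estimate(
    instruments: InstrumentSet, bootstrap: BootstrapSpec = BootstrapSpec()
) -> MrResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Consistent when instruments carrying at least 50% of the IVW weight are
    valid, so it tolerates up to half the weight coming from pleiotropic SNPs.
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median needs at least 3 SNPs, got {n}")
    ratios, _, weights = _ratio_arrays(instruments)
    beta = weighted_median(ratios, weights)
    se = _bootstrap_se(instruments, lambda r, w: weighted_median(r, w), bootstrap)

    sd = instruments.exposure.sd_value
    scaled = scale_to_or(beta, se, sd)
    return MrResult(
        method="weighted_median",
        beta_per_unit=beta,
        se_per_unit=se,
        beta_per_sd=beta * sd,
        or_per_sd=scaled.odds_ratio,
        ci_low=scaled.ci_low,
        ci_high=scaled.ci_high,
        p_value=scaled.p_value,
        n_snps=n,
        per_snp=_per_snp_estimates(instruments),
    )


MODE_GRID_POINTS = 512


def weighted_mode(values: Sequence[float], weights: Sequence[float], phi: float = 1.0) -> float:
    """Argmax of the normal-kernel weighted density of ``values``.

    The bandwidth is ``phi`` times the modified Silverman rule
    h = 0.9 · min(SD, MAD) · n^(−1/5), with the MAD scaled for normal
    consistency — the convention of the mode-based-estimation literature. The
    density is evaluated on a 512-point grid spanning [min − h, max + h]; exact
    ties in the argmax are broken toward the grid midpoint.
    """
    if phi <= 0:
        raise ValidationError(f"phi must be positive, got {phi!r}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValidationError("weighted_mode of empty sequence")
    if np.ptp(v) == 0:
        return float(v[0])
    w = w / w.sum()
    spread = min(float(np.std(v, ddof=1)), float(stats.median_abs_deviation(v, scale="normal")))
    h = phi * 0.9 * spread * v.size ** (-1.0 / 5.0)
    h = max(h, 1e-8)
    grid = np.linspace(v.min() - h, v.max() + h, MODE_GRID_POINTS)
    density = np.sum(w[:, None] * stats.norm.pdf((grid[None, :] - v[:, None]) / h), axis=0)
    peaks = np.flatnonzero(density == density.max())
    mid = (MODE_GRID_POINTS - 1) / 2.0
    best = peaks[np.argmin(np.abs(peaks - mid))]
    return float(grid[best])


def weighted_mode_estimate(
    instruments: InstrumentSet,
    phi: float = 1.0,
    bootstrap: BootstrapSpec = BootstrapSpec(),
) -> MrResult:
    """Weighted mode-based causal estimate with parametric-bootstrap SE.

    Consistent when the largest group of instruments sharing the same underlying
    ratio is the valid group (the "zero modal pleiotropy" assumption). ``phi``
    scales the kernel bandwidth; smaller values sharpen the density at the cost
    of variance.
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs at least 3 SNPs, got {n}")
    ratios, _, weights = _ratio_arrays(instruments)
    beta = weighted_mode(ratios, weights, phi=phi)
    se = _bootstrap_se(instruments, lambda r, w: weighted_mode(r, w, phi=phi), bootstrap)

    sd = instruments.exposure.sd_value
    scaled = scale_to_or(beta, se, sd)
    return MrResult(
        method="weighted_mode",
        beta_per_unit=beta,
        se_per_unit=se,
        beta_per_sd=beta * sd,
        or_per_sd=scaled.odds_ratio,
        ci_low=scaled.ci_low,
        ci_high=scaled.ci_high,
        p_value=scaled.p_value,
        n_snps=n,
        per_snp=_per_snp_estimates(instruments),
    )
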