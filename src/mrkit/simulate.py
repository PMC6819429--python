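"""Synthetic two-sample summary statistics with known ground truth.

The generator emulates the data-generating process the estimators assume: each
SNP has a true exposure effect drawn uniformly from a stated range; the
*observed* exposure beta adds normal estimation noise at the exposure-GWAS SE;
the outcome beta is

    causal_effect × true exposure beta + pleiotropy + noise,

where the pleiotropic (direct) effect is zero for valid SNPs and, for the
configured invalid fraction, drawn normal — mean zero under balanced
pleiotropy, non-zero mean under directional pleiotropy. By default pleiotropic
effects are drawn independently of instrument strength (the InSIDE condition
MR-Egger requires); a ``correlated`` mode ties them to instrument strength to
demonstrate Egger breakdown. Exposure and outcome samples are treated as
non-overlapping, so the two noise draws are independent.

Defaults mirror the serum-mineral study scale: 50 instruments with per-allele
exposure effects in [0.005, 0.08], exposure SEs of 0.003 and outcome log-odds
SEs of 0.02, and a null causal effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .estimators import MrResult, ivw_estimate
from .summary import ExposureSpec, InstrumentSet, SnpAssociation

PleiotropyMode = Literal["none", "balanced", "directional", "correlated"]

#: Exposure spec attached to simulated sets: unit SD so per-unit == per-SD.
SYNTHETIC_EXPOSURE = ExposureSpec(
    name="synthetic", sd_value=1.0, sd_units="SD", variance_explained=0.01
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one simulated two-sample dataset."""

    n_snps: int = 50
    causal_effect: float = 0.0
    exposure_beta_range: tuple[float, float] = (0.005, 0.08)
    se_exposure_level: float = 0.003
    se_outcome_level: float = 0.02
    pleiotropy_mode: PleiotropyMode = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    invalid_fraction: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be at least 1")
        low, high = self.exposure_beta_range
        if not (0 < low <= high):
            raise ValidationError("exposure_beta_range must be a positive interval")
        if self.se_exposure_level <= 0 or self.se_outcome_level <= 0:
            raise ValidationError("SE levels must be positive")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be non-negative")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValidationError("invalid_fraction must lie in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "correlated"):
            raise ValidationError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


@dataclass(frozen=True)
class SimulatedInstruments:
    """A simulated instrument set together with its generating truth."""

    instruments: InstrumentSet
    causal_effect: float
    true_beta_exposure: np.ndarray
    pleiotropy: np.ndarray
    valid: np.ndarray  # boolean mask, True where the SNP has no direct effect
    config: SyntheticConfig


def simulate_instruments(config: SyntheticConfig) -> SimulatedInstruments:
    """Draw one two-sample summary dataset from the configured truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    low, high = config.exposure_beta_range

    bx_true = rng.uniform(low, high, size=n)
    bx_obs = bx_true + rng.normal(0.0, config.se_exposure_level, size=n)

    n_invalid = int(round(config.invalid_fraction * n))
    valid = np.ones(n, dtype=bool)
    if config.pleiotropy_mode != "none" and n_invalid > 0:
        invalid_idx = rng.choice(n, size=n_invalid, replace=False)
        valid[invalid_idx] = False

    alpha = np.zeros(n)
    if config.pleiotropy_mode == "balanced":
        alpha[~valid] = rng.normal(0.0, config.pleiotropy_sd, size=n_invalid)
    elif config.pleiotropy_mode == "directional":
        alpha[~valid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid)
    elif config.pleiotropy_mode == "correlated":
        # instrument strength drives the direct effect: violates InSIDE
        strength = (bx_true - bx_true.mean()) / max(bx_true.std(), np.finfo(float).tiny)
        alpha[~valid] = (
            config.pleiotropy_mean + config.pleiotropy_sd * strength[~valid]
        )

    by_obs = config.causal_effect * bx_true + alpha + rng.normal(
        0.0, config.se_outcome_level, size=n
    )
    eaf = rng.uniform(0.05, 0.95, size=n)

    snps = []
    for j in range(n):
        z_x = bx_obs[j] / config.se_exposure_level
        z_y = by_obs[j] / config.se_outcome_level
        snps.append(
            SnpAssociation(
                rsid=f"snp{j + 1:04d}",
                effect_allele="A",
                other_allele="G",
                eaf=float(eaf[j]),
                beta_exposure=float(bx_obs[j]),
                se_exposure=config.se_exposure_level,
                p_exposure=float(min(max(2 * stats.norm.sf(abs(z_x)), 1e-300), 1.0)),
                beta_outcome=float(by_obs[j]),
                se_outcome=config.se_outcome_level,
                p_outcome=float(min(max(2 * stats.norm.sf(abs(z_y)), 1e-300), 1.0)),
            )
        )
    instruments = InstrumentSet(
        exposure=SYNTHETIC_EXPOSURE,
        snps=tuple(snps),
        label=f"synthetic(seed={config.seed})",
    )
    return SimulatedInstruments(
        instruments=instruments,
        causal_effect=config.causal_effect,
        true_beta_exposure=bx_true,
        pleiotropy=alpha,
        valid=valid,
        config=config,
    )


Estimator = Callable[[InstrumentSet], MrResult]


@dataclass(frozen=True)
class ReplicationSummary:
    """Monte-Carlo operating characteristics of one estimator."""

    estimates: pd.DataFrame  # one row per replicate
    mean_bias: float
    empirical_se: float
    coverage: float
    rejection_rate: float
    n_replicates: int
    n_failed: int
    alpha: float
    truth: float


def replicate_study(
    config: SyntheticConfig,
    estimator: Estimator = ivw_estimate,
    n_replicates: int = 500,
    seed: int = 2024,
    alpha: float = 0.05,
) -> ReplicationSummary:
    """Repeatedly simulate and estimate; summarise bias, spread, coverage, rejections.

    Each replicate regenerates the dataset under ``config`` with an independent
    child seed, applies ``estimator`` (any callable from an
    :class:`InstrumentSet` to an :class:`MrResult`; estimator exceptions are
    counted, not fatal), and records the per-unit estimate, SE, 95% CI hit on
    the true causal effect, and rejection of the no-effect null at ``alpha``.
    """
    if n_replicates < 2:
        raise ValidationError("replicate_study needs at least 2 replicates")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)

    rows = []
    n_failed = 0
    truth = config.causal_effect
    from .estimators import Z_95

    for i in range(n_replicates):
        cfg = dataclasses.replace(config, seed=int(child_seeds[i]))
        sim = simulate_instruments(cfg)
        try:
            result = estimator(sim.instruments)
        except Exception:  # noqa: BLE001 - estimator failures are data, not bugs
            n_failed += 1
            continue
        lo = result.beta_per_unit - Z_95 * result.se_per_unit
        hi = result.beta_per_unit + Z_95 * result.se_per_unit
        rows.append(
            {
                "replicate": i,
                "seed": int(child_seeds[i]),
                "estimate": result.beta_per_unit,
                "se": result.se_per_unit,
                "covered": bool(lo <= truth <= hi),
                "rejected": bool(result.p_value < alpha),
                "egger_intercept": (
                    result.egger_intercept.value if result.egger_intercept else np.nan
                ),
            }
        )

    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValidationError("every replicate failed; nothing to summarise")
    return ReplicationSummary(
        estimates=frame,
        mean_bias=float(frame["estimate"].mean() - truth),
        empirical_se=float(frame["estimate"].std(ddof=1)),
        coverage=float(frame["covered"].mean()),
        rejection_rate=float(frame["rejected"].mean()),
        n_replicates=n_replicates,
        n_failed=n_failed,
        alpha=alpha,
        truth=truth,
    )
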