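"""Domain types and per-SNP arithmetic for two-sample MR summary statistics.

A two-sample Mendelian randomization analysis starts from per-SNP association
estimates taken from two non-overlapping GWAS samples: the SNP-exposure effect
(beta, SE) and the SNP-outcome effect (log-odds beta, SE for a binary outcome).
This module defines the containers for those records, TSV ingestion/serialization,
allele harmonization of independently sourced exposure/outcome records, and the
per-SNP derived quantities (Wald ratio, approximate F-statistic).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    HarmonizationError,
    ParseError,
    UndefinedRatioError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Allele pairs that read the same on both strands; their orientation cannot be
#: resolved from alleles alone and must lean on the allele frequency.
PALINDROMIC_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})

#: EAF window in which a palindromic SNP's orientation is considered ambiguous.
AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)

REQUIRED_COLUMNS = (
    "rsid",
    "effect_allele",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
)

OPTIONAL_COLUMNS = (
    "chromosome",
    "nearby_gene",
    "other_allele",
    "eaf",
    "f_statistic",
    "p_exposure",
    "p_outcome",
    "proxy_of",
    "proxy_r2",
)

HarmonizePolicy = Literal["flag-keep", "strict-drop"]


def _check_probability(value: Optional[float], name: str, rsid: str) -> None:
    if value is not None and not (0.0 < value <= 1.0):
        raise ValidationError(f"{name} for {rsid} must lie in (0, 1], got {value!r}")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's exposure and outcome effect estimates on a common allele frame.

    ``beta_exposure`` is in exposure units per copy of ``effect_allele``;
    ``beta_outcome`` is the log-odds of the outcome per copy of the same allele.
    ``proxy_of``/``proxy_r2`` record that the outcome association was read off a
    linkage-disequilibrium proxy variant (metadata only; no LD arithmetic is done).
    """

    rsid: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    other_allele: Optional[str] = None
    chromosome: Optional[str] = None
    nearby_gene: Optional[str] = None
    eaf: Optional[float] = None
    f_statistic: Optional[float] = None
    p_exposure: Optional[float] = None
    p_outcome: Optional[float] = None
    proxy_of: Optional[str] = None
    proxy_r2: Optional[float] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.se_exposure <= 0:
            raise ValidationError(
                f"se_exposure for {self.rsid} must be positive, got {self.se_exposure!r}"
            )
        if self.se_outcome <= 0:
            raise ValidationError(
                f"se_outcome for {self.rsid} must be positive, got {self.se_outcome!r}"
            )
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"eaf for {self.rsid} must lie in [0, 1], got {self.eaf!r}")
        if self.f_statistic is not None and self.f_statistic < 0:
            raise ValidationError(f"f_statistic for {self.rsid} must be non-negative")
        _check_probability(self.p_exposure, "p_exposure", self.rsid)
        _check_probability(self.p_outcome, "p_outcome", self.rsid)

    @property
    def alleles(self) -> Optional[frozenset]:
        if self.other_allele is None:
            return None
        return frozenset({self.effect_allele, self.other_allele})

    @property
    def is_palindromic(self) -> Optional[bool]:
        """Whether the allele pair is strand-ambiguous; None if the other allele is unknown."""
        pair = self.alleles
        return None if pair is None else pair in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class ExposureSpec:
    """Name, SD scaling constant and instrument strength of one exposure.

    ``sd_value`` converts per-unit causal effects to per-SD effects (for the
    serum minerals studied here: 0.5 mg/dl for calcium, 0.1 for magnesium, the
    rounded mean SDs of the source GWAS cohorts). ``variance_explained`` is the
    fraction of exposure variance captured by the instrument set, used for power.
    """

    name: str
    sd_value: float
    sd_units: str
    variance_explained: float

    def __post_init__(self) -> None:
        if self.sd_value <= 0:
            raise ValidationError(f"sd_value must be positive, got {self.sd_value!r}")
        if not (0.0 < self.variance_explained < 1.0):
            raise ValidationError(
                f"variance_explained must lie in (0, 1), got {self.variance_explained!r}"
            )


@dataclass(frozen=True)
class InstrumentSet:
    """An ordered collection of instrument SNPs for one exposure."""

    exposure: ExposureSpec
    snps: tuple[SnpAssociation, ...]
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        if len(self.snps) == 0:
            raise ValidationError("no instruments")
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsid(s) in instrument set: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    # Column vectors used by every estimator.
    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([s.beta_exposure for s in self.snps], dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([s.se_exposure for s in self.snps], dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([s.beta_outcome for s in self.snps], dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([s.se_outcome for s in self.snps], dtype=float)

    def get(self, rsid: str) -> SnpAssociation:
        for snp in self.snps:
            if snp.rsid == rsid:
                return snp
        raise ConfigurationError(f"rsid {rsid} not present in instrument set {self.label!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per SNP, in the TSV column layout."""
        columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
        rows = []
        for snp in self.snps:
            d = dataclasses.asdict(snp)
            rows.append({c: d[c] for c in columns})
        return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class ExclusionSet:
    """A named group of SNPs removed in a sensitivity analysis.

    ``pleiotropy_class`` distinguishes horizontal pleiotropy (the SNP may act on
    the outcome through a pathway other than the exposure; grounds for exclusion)
    from vertical pleiotropy (the secondary trait is downstream of the exposure;
    the SNP is retained and the set exists only as documentation).
    """

    name: str
    rsids: tuple[str, ...]
    rationale: str = ""
    pleiotropy_class: Literal["horizontal", "vertical"] = "horizontal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rsids", tuple(self.rsids))
        if self.pleiotropy_class not in ("horizontal", "vertical"):
            raise ValidationError(
                f"pleiotropy_class must be 'horizontal' or 'vertical', got {self.pleiotropy_class!r}"
            )


@dataclass(frozen=True)
class GwasRecord:
    """A single-sample association record, prior to harmonization."""

    rsid: str
    effect_allele: str
    beta: float
    se: float
    other_allele: Optional[str] = None
    eaf: Optional[float] = None
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"se for {self.rsid} must be positive, got {self.se!r}")


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal effect estimate (exposure units in the denominator)."""

    ratio: float
    se: float


def read_instrument_table(path: str | Path, exposure: ExposureSpec, label: str | None = None) -> InstrumentSet:
    """Read a tab-separated summary-statistics table into an :class:`InstrumentSet`.

    The table must carry one header row naming at least the required columns
    (``rsid``, ``effect_allele``, ``beta_exposure``, ``se_exposure``,
    ``beta_outcome``, ``se_outcome``); recognised optional columns are attached
    when present, and empty cells in them become absent fields. Row order is
    preserved.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"rsid": str}, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)} in {path}")
    if len(frame) == 0:
        raise ValidationError("no instruments")

    snps = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
            if col not in frame.columns:
                continue
            value = row[col]
            if pd.isna(value):
                continue
            kwargs[col] = value
        for col in ("chromosome", "nearby_gene", "other_allele", "effect_allele", "proxy_of"):
            if col in kwargs:
                kwargs[col] = str(kwargs[col])
        snps.append(SnpAssociation(**kwargs))
    return InstrumentSet(exposure=exposure, snps=tuple(snps), label=label or exposure.name)


def write_instrument_table(instruments: InstrumentSet, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_instrument_table` (lossless round-trip)."""
    instruments.to_frame().to_csv(path, sep="\t", index=False)


def harmonize_pair(
    exposure_record: GwasRecord,
    outcome_record: GwasRecord,
    policy: HarmonizePolicy = "flag-keep",
) -> Optional[SnpAssociation]:
    """Place an exposure and an outcome record on the exposure's allele frame.

    If the outcome effect allele equals the exposure's *other* allele, the
    outcome beta's sign is flipped (and its EAF reflected). Palindromic SNPs
    (A/T or C/G) whose exposure EAF falls in the ambiguity window are flagged
    ``ambiguous``; under the ``strict-drop`` policy they are excluded
    (returns None, with the reason logged) instead of flagged.
    """
    if exposure_record.rsid != outcome_record.rsid:
        raise HarmonizationError(
            f"records refer to different SNPs: {exposure_record.rsid} vs {outcome_record.rsid}"
        )
    rsid = exposure_record.rsid
    ea_x, oa_x = exposure_record.effect_allele, exposure_record.other_allele
    ea_y, oa_y = outcome_record.effect_allele, outcome_record.other_allele

    if ea_y == ea_x and (oa_x is None or oa_y is None or oa_y == oa_x):
        beta_outcome = outcome_record.beta
    elif oa_x is not None and ea_y == oa_x and (oa_y is None or oa_y == ea_x):
        beta_outcome = -outcome_record.beta
    else:
        raise HarmonizationError(
            f"allele sets for {rsid} cannot be reconciled: "
            f"exposure {ea_x}/{oa_x or '?'} vs outcome {ea_y}/{oa_y or '?'}"
        )

    ambiguous = False
    pair = None if oa_x is None else frozenset({ea_x, oa_x})
    if pair in PALINDROMIC_PAIRS and exposure_record.eaf is not None:
        low, high = AMBIGUOUS_EAF_WINDOW
        if low <= exposure_record.eaf <= high:
            ambiguous = True
            if policy == "strict-drop":
                logger.info(
                    "dropping %s: palindromic alleles %s/%s with eaf %.3f in [%.2f, %.2f]",
                    rsid, ea_x, oa_x, exposure_record.eaf, low, high,
                )
                return None

    return SnpAssociation(
        rsid=rsid,
        effect_allele=ea_x,
        other_allele=oa_x,
        eaf=exposure_record.eaf,
        beta_exposure=exposure_record.beta,
        se_exposure=exposure_record.se,
        p_exposure=exposure_record.p_value,
        beta_outcome=beta_outcome,
        se_outcome=outcome_record.se,
        p_outcome=outcome_record.p_value,
        ambiguous=ambiguous,
    )


def wald_ratio(snp: SnpAssociation) -> WaldRatio:
    """Per-SNP causal estimate: outcome beta over exposure beta.

    The SE is the first-order delta-method approximation se_outcome/|beta_exposure|,
    which treats the exposure beta as fixed — the same approximation the IVW
    weighting relies on.
    """
    if snp.beta_exposure == 0:
        raise UndefinedRatioError(f"beta_exposure is zero for {snp.rsid}; Wald ratio undefined")
    return WaldRatio(
        ratio=snp.beta_outcome / snp.beta_exposure,
        se=snp.se_outcome / abs(snp.beta_exposure),
    )


def f_statistic_from_summary(snp: SnpAssociation) -> float:
    """Approximate instrument-strength F-statistic, (beta/SE)² of the exposure association.

    This is a summary-level approximation; when the source GWAS reports an F
    value (computed upstream from unrounded statistics) that stored value takes
    precedence and is available as ``snp.f_statistic``.
    """
    return (snp.beta_exposure / snp.se_exposure) ** 2


def apply_exclusion(instruments: InstrumentSet, exclusion: ExclusionSet) -> InstrumentSet:
    """Return a new instrument set without the excluded SNPs.

    All excluded rsids must be present; the provenance of the exclusion is
    recorded in the new set's label. An empty exclusion returns an identical set.
    """
    if not exclusion.rsids:
        return dataclasses.replace(instruments)
    present = set(instruments.rsids)
    for rsid in exclusion.rsids:
        if rsid not in present:
            raise ConfigurationError(
                f"exclusion {exclusion.name!r} names rsid {rsid} absent from set {instruments.label!r}"
            )
    kept = tuple(s for s in instruments.snps if s.rsid not in set(exclusion.rsids))
    return InstrumentSet(
        exposure=instruments.exposure,
        snps=kept,
        label=f"{instruments.label} minus {exclusion.name}",
    )
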