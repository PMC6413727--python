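"""Core record types for two-sample Mendelian randomization.

Every analysis stage passes typed records rather than bare arrays so that
per-SNP provenance (identifiers, alleles, removal reasons) survives from the
raw summary-statistics tables through to the final report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class MRError(Exception):
    """Base class for all package errors."""


class ConfigError(MRError):
    """A configuration problem (missing column, bad threshold)."""


class ValidationError(MRError):
    """An input record violates an invariant (e.g. non-positive SE)."""


class EmptyIntersectionError(MRError):
    """Exposure and outcome tables share no SNPs."""


class DegenerateInstrumentError(MRError):
    """An instrument cannot yield a Wald ratio (zero exposure beta)."""


class InsufficientInstrumentsError(MRError):
    """An estimator was given fewer SNPs than it needs."""


class ConvergenceError(MRError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(slots=True)
class VariantAssociation:
    """One SNP's association with one trait from a GWAS summary table.

    ``beta`` is in SD units for a quantitative exposure and log-odds for a
    binary outcome. ``beta_missing`` marks a row whose beta was unreported
    (kept so the record can later be imputed or excluded explicitly).
    """

    snp_id: str
    chrom: str
    pos: int
    beta: float | None
    se: float
    pval: float
    gene: str = ""
    effect_allele: str | None = None
    eaf: float | None = None
    beta_missing: bool = False

    def __post_init__(self) -> None:
        if self.se is not None and not self.se > 0:
            raise ValidationError(
                f"non-positive SE ({self.se}) for SNP {self.snp_id}"
            )
        if not (0 < self.pval <= 1):
            raise ValidationError(
                f"P-value {self.pval} outside (0, 1] for SNP {self.snp_id}"
            )
        if self.pos is not None and not self.pos > 0:
            raise ValidationError(f"non-positive position for SNP {self.snp_id}")
        if self.beta_missing and self.beta is not None:
            raise ValidationError(
                f"SNP {self.snp_id}: beta_missing set but beta present"
            )


@dataclass(slots=True)
class HarmonizedInstrument:
    """A SNP's paired exposure/outcome associations on a common effect allele."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    pval_exposure: float
    pval_outcome: float
    chrom: str = ""
    pos: int = 0
    gene: str = ""
    orientation_flipped: bool = False

    def __post_init__(self) -> None:
        if not self.se_exposure > 0:
            raise ValidationError(f"non-positive exposure SE for {self.snp_id}")
        if not self.se_outcome > 0:
            raise ValidationError(f"non-positive outcome SE for {self.snp_id}")


@dataclass(slots=True)
class WaldRatio:
    """Per-SNP causal-effect ratio beta_outcome/beta_exposure and its SE."""

    snp_id: str
    beta_xy: float
    se_xy: float

    @property
    def weight(self) -> float:
        """Inverse-variance weight, exactly se_xy**-2."""
        return self.se_xy ** -2


@dataclass(slots=True)
class MREstimate:
    """One estimator's pooled result on the log-odds scale.

    ``ci_low``/``ci_high`` are the 95% bounds on the log scale; the
    ``odds_ratio`` properties exponentiate at the reporting boundary.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "n_snps": self.n_snps,
        }


@dataclass(slots=True)
class HeterogeneityResult:
    """Cochran's Q across Wald ratios and the derived I^2 percentage."""

    Q: float
    df: int
    pval: float
    i2: float

    @property
    def significant(self) -> bool:
        """Significant heterogeneity: P < 0.01 and I^2 > 50%."""
        return self.pval < 0.01 and self.i2 > 50.0

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "df": self.df,
            "pval": self.pval,
            "i2": self.i2,
            "significant": self.significant,
        }


@dataclass(slots=True)
class LDPair:
    """Squared correlation between two SNPs; the pair is unordered."""

    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(
                f"r2 {self.r2} outside [0, 1] for pair ({self.snp_a}, {self.snp_b})"
            )


@dataclass(slots=True)
class SelectionReport:
    """Bookkeeping for the instrument-selection pipeline.

    Stage counts are ``None`` for stages that were not run. Every input SNP is
    exactly once either a survivor or listed in ``removed`` with its reason.
    """

    n_input: int = 0
    n_after_significance: int | None = None
    n_after_clump: int | None = None
    n_after_known_outcome_loci: int | None = None
    n_after_outcome_p: int | None = None
    removed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_final(self) -> int:
        return self.n_input - len(self.removed)


@dataclass(slots=True)
class LeaveOneOutRow:
    """IVW re-estimate with one SNP dropped, and its relative OR shift."""

    dropped_snp: str
    estimate: MREstimate
    heterogeneity: HeterogeneityResult | None
    delta_rel: float


@dataclass(slots=True)
class FunnelPoint:
    """One SNP's (ratio estimate, precision) pair for a funnel plot."""

    snp_id: str
    beta_xy: float
    precision: float

    def __post_init__(self) -> None:
        if not self.precision > 0:
            raise ValidationError(f"non-positive precision for {self.snp_id}")
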