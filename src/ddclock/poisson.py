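"""Poisson limiting-dilution statistics for droplet digital PCR.

With N molecules scattered over D droplets, per-droplet occupancy is
Poisson with mean lambda, and the observable positive-droplet fraction p
determines it: lambda = -ln(1 - p). Accurate counting needs limiting
dilution — few enough molecules that a positive droplet almost always
holds exactly one, P(K=1 | K>=1) = lambda e^{-lambda} / (1 - e^{-lambda}).

The assay's working rule of thumb: keep the positive fraction at or below
10% per target, which guarantees at least 95% single-molecule occupancy.
Both gates are inclusive at their boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .droplets import ClusterCounts, NoPositiveDropletsError


class SaturationError(ValueError):
    """All (or effectively all) droplets are positive; occupancy is unidentifiable."""


@dataclass(frozen=True)
class QCRule:
    """Acceptance gates for a single target's droplet counts.

    Defaults encode the recommended operating range: <= 10% positive
    droplets per target and >= 95% single-molecule occupancy, plus a floor
    of at least one positive droplet so empty channels fail QC rather
    than raising.
    """

    max_positive_fraction: float = 0.10
    min_single_fraction: float = 0.95
    min_positive_droplets: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.max_positive_fraction <= 1):
            raise ValueError("max_positive_fraction must be in (0, 1]")
        if not (0 < self.min_single_fraction <= 1):
            raise ValueError("min_single_fraction must be in (0, 1]")
        if self.min_positive_droplets < 0:
            raise ValueError("min_positive_droplets must be >= 0")


@dataclass(frozen=True)
class PoissonQuant:
    """Poisson quantification and QC verdict for one target.

    ``copies`` is the estimated number of target molecules in the whole
    well, lambda * n_total.
    """

    cpg: str
    p_positive: float
    lam: float
    copies: float
    single_fraction: float
    passed: bool


def occupancy(p_positive: float) -> float:
    """Mean molecules per droplet from the positive fraction: -ln(1 - p).

    Raises
    ------
    SaturationError
        If ``p_positive`` >= 1 (a saturated well carries no information
        about concentration).
    """
    if not 0 <= p_positive:
        raise ValueError(f"p_positive must be >= 0, got {p_positive}")
    if p_positive >= 1:
        raise SaturationError(f"saturated well: p_positive = {p_positive} >= 1")
    return -math.log1p(-p_positive)


def positive_fraction(lam: float) -> float:
    """Inverse of :func:`occupancy`: p = 1 - e^{-lambda}."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return -math.expm1(-lam)


def single_molecule_fraction(p_positive: float) -> float:
    """P(exactly one molecule | positive) at the occupancy implied by p.

    Equals lambda e^{-lambda} / (1 - e^{-lambda}); tends to 1 as p -> 0
    (the limiting-dilution regime) and falls as wells load up.

    Raises
    ------
    ValueError
        If ``p_positive`` = 0 (conditioning on an impossible event).
    SaturationError
        If ``p_positive`` >= 1.
    """
    if p_positive == 0:
        raise ValueError("single-molecule fraction undefined at p_positive = 0")
    lam = occupancy(p_positive)
    return lam * math.exp(-lam) / -math.expm1(-lam)


def qc_evaluate(counts: ClusterCounts, rule: QCRule | None = None) -> PoissonQuant:
    """Poisson statistics plus QC verdict for one channel's counts.

    QC failure is a verdict, never an exception: empty and saturated
    channels produce ``passed=False`` with limiting values filled in
    (single_fraction -> 1 as p -> 0; lambda = inf at p = 1).
    """
    rule = rule if rule is not None else QCRule()
    p = counts.n_positive_total / counts.n_total
    if p >= 1.0:
        lam = math.inf
        single = 0.0
    else:
        lam = occupancy(p)
        single = 1.0 if p == 0 else single_molecule_fraction(p)
    passed = (
        p <= rule.max_positive_fraction
        and single >= rule.min_single_fraction
        and counts.n_positive_total >= rule.min_positive_droplets
    )
    return PoissonQuant(
        cpg=counts.cpg,
        p_positive=p,
        lam=lam,
        copies=lam * counts.n_total,
        single_fraction=single,
        passed=passed,
    )


def corrected_methylation(counts: ClusterCounts) -> float:
    """Occupancy-corrected methylation fraction, lambda_M / (lambda_M + lambda_U).

    The plain droplet-count ratio overstates the labeled allele once
    droplets start holding molecules of both alleles (a droplet with both
    sits in the labeled-allele cluster). Treating the two alleles as
    independent Poisson processes, the negative fraction factorizes,
    so lambda_total = lambda_labeled + lambda_other and each occupancy is
    recoverable from the observable fractions:

        lambda_labeled = -ln(1 - n_allele / n_total)
        lambda_other   = -ln(1 - p_total) - lambda_labeled

    At limiting dilution (p << 1) this agrees with the count ratio; at
    high occupancy it removes the co-occupancy bias. Opt-in: the default
    pipeline reports the plain count ratio the assay defines.

    Raises
    ------
    SaturationError
        If either relevant positive fraction reaches 1.
    NoPositiveDropletsError
        If the channel has no positive droplets at all.
    """
    if counts.n_positive_total == 0:
        raise NoPositiveDropletsError(
            f"{counts.cpg}: no positive droplets, methylation undefined"
        )
    p_total = counts.n_positive_total / counts.n_total
    p_allele = counts.n_allele / counts.n_total
    lam_total = occupancy(p_total)  # raises SaturationError at p_total >= 1
    lam_allele = occupancy(p_allele)
    lam_other = max(lam_total - lam_allele, 0.0)
    if counts.labeled_allele == "methylated":
        lam_m, lam_u = lam_allele, lam_other
    else:
        lam_m, lam_u = lam_other, lam_allele
    return lam_m / (lam_m + lam_u)


def beta_confidence_interval(
    n_methylated: int, n_unmethylated: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for beta = M / (M + U).

    An extension beyond the assay's printed analysis: droplet counts are
    treated as a binomial draw of size M + U.
    """
    n = n_methylated + n_unmethylated
    if n == 0:
        raise NoPositiveDropletsError("no positive droplets, interval undefined")
    lo, hi = proportion_confint(n_methylated, n, alpha=1 - confidence, method="wilson")
    return float(lo), float(hi)
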