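"""Two-threshold droplet classification and methylation fractions.

A multiplex ddPCR well partitions a bisulfite-converted DNA sample into
~20,000 droplets. Each fluorescence channel interrogates one CpG with a
single colour and three probes, producing three amplitude clusters:

* negative — no target molecule,
* single-positive — target present, but only the *unlabeled* allele,
* high-positive — at least one molecule of the *labeled* allele.

Which allele carries the label is a fixed property of the assay: the
methylated allele for CCDC102B and ELOVL2, the unmethylated allele for
ASPA, C1orf132, EDARADD and FHL2 (the rarer allele in the population, to
keep 'rain' off the informative cluster). Two per-channel thresholds
separate the clusters: ``t_total`` splits negatives from all positives,
``t_allele`` splits single-positives from the labeled-allele cluster.

The methylation fraction (beta value) is computed directly from droplet
counts, M / (M + U), where M and U are methylated- and
unmethylated-droplet counts; the orientation merely decides which cluster
is which.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .poisson import PoissonQuant

#: The six age-associated CpG targets of the dodecaplex assay.
CPGS: tuple[str, ...] = ("ASPA", "C1orf132", "CCDC102B", "EDARADD", "ELOVL2", "FHL2")

#: Which allele carries the fluorescent label in each channel.
LABELED_ALLELE: dict[str, str] = {
    "ASPA": "unmethylated",
    "C1orf132": "unmethylated",
    "CCDC102B": "methylated",
    "EDARADD": "unmethylated",
    "ELOVL2": "methylated",
    "FHL2": "unmethylated",
}

_ALLELES = frozenset({"methylated", "unmethylated"})


class ChannelError(ValueError):
    """A channel is missing, duplicated, or otherwise unusable."""


class NoPositiveDropletsError(ValueError):
    """Methylation is undefined: the well has no positive droplets (M + U = 0)."""


def default_labeled_allele(cpg: str) -> str:
    """Return the assay's labeled allele for a known CpG.

    Raises
    ------
    ChannelError
        If ``cpg`` is not one of the six assay targets (custom channels
        must state their orientation explicitly).
    """
    try:
        return LABELED_ALLELE[cpg]
    except KeyError:
        raise ChannelError(
            f"unknown CpG {cpg!r}: supply labeled_allele explicitly"
        ) from None


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-channel amplitude thresholds.

    ``t_total`` separates negative droplets from all positives;
    ``t_allele`` separates single-positives from the labeled-allele
    (high) cluster. A droplet strictly above a threshold is above it.
    """

    cpg: str
    t_total: float
    t_allele: float
    labeled_allele: str | None = None

    def __post_init__(self) -> None:
        if not (self.t_total < self.t_allele):
            raise ValueError(
                f"{self.cpg}: t_total ({self.t_total}) must be below "
                f"t_allele ({self.t_allele})"
            )
        allele = self.labeled_allele
        if allele is None:
            allele = default_labeled_allele(self.cpg)
            object.__setattr__(self, "labeled_allele", allele)
        if allele not in _ALLELES:
            raise ValueError(f"labeled_allele must be one of {sorted(_ALLELES)}")


@dataclass
class DropletWell:
    """One well's droplet amplitudes, one array per channel."""

    well_id: str
    channel_amplitudes: dict[str, np.ndarray]
    droplet_count: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.channel_amplitudes:
            raise ValueError(f"well {self.well_id}: no channels")
        counts = set()
        clean: dict[str, np.ndarray] = {}
        for cpg, amps in self.channel_amplitudes.items():
            arr = np.asarray(amps, dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ChannelError(f"well {self.well_id}, channel {cpg}: empty amplitude list")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"well {self.well_id}, channel {cpg}: non-finite amplitudes")
            clean[cpg] = arr
            counts.add(arr.size)
        if len(counts) != 1:
            raise ValueError(
                f"well {self.well_id}: channels disagree on droplet count ({sorted(counts)})"
            )
        self.channel_amplitudes = clean
        self.droplet_count = counts.pop()

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_amplitudes)


@dataclass(frozen=True)
class ClusterCounts:
    """Droplet counts for one CpG channel — the sufficient statistic.

    ``n_allele`` is the high-positive (labeled-allele) cluster;
    the orientation maps the clusters onto methylated (M) and
    unmethylated (U) droplet counts.
    """

    cpg: str
    n_total: int
    n_negative: int
    n_positive_total: int
    n_allele: int
    labeled_allele: str

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"{self.cpg}: n_total must be positive")
        if self.n_negative + self.n_positive_total != self.n_total:
            raise ValueError(f"{self.cpg}: counts do not partition the well")
        if not (0 <= self.n_allele <= self.n_positive_total):
            raise ValueError(f"{self.cpg}: n_allele outside [0, n_positive_total]")
        if self.labeled_allele not in _ALLELES:
            raise ValueError(f"labeled_allele must be one of {sorted(_ALLELES)}")

    @property
    def n_methylated(self) -> int:
        """Methylated-droplet count M under this channel's orientation."""
        if self.labeled_allele == "methylated":
            return self.n_allele
        return self.n_positive_total - self.n_allele

    @property
    def n_unmethylated(self) -> int:
        """Unmethylated-droplet count U under this channel's orientation."""
        return self.n_positive_total - self.n_methylated


@dataclass
class MethylationResult:
    """Per-CpG methylation estimate with its Poisson QC record.

    ``beta`` is NaN and ``error`` is set when the channel could not be
    quantified (e.g. no positive droplets).
    """

    cpg: str
    beta: float
    n_methylated: int
    n_unmethylated: int
    counts: ClusterCounts | None = None
    qc: "PoissonQuant | None" = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def classify_droplets(well: DropletWell, thresholds: ChannelThresholds) -> ClusterCounts:
    """Partition one channel's droplets with the two amplitude thresholds.

    Boundary convention: a droplet is above a threshold when its
    amplitude is *strictly greater*; droplets exactly at a threshold
    stay below.
    """
    cpg = thresholds.cpg
    if cpg not in well.channel_amplitudes:
        raise ChannelError(
            f"well {well.well_id}: channel {cpg!r} not present "
            f"(has {sorted(well.channels)})"
        )
    amps = well.channel_amplitudes[cpg]
    n_total = amps.size
    n_positive = int(np.count_nonzero(amps > thresholds.t_total))
    n_allele = int(np.count_nonzero(amps > thresholds.t_allele))
    return ClusterCounts(
        cpg=cpg,
        n_total=n_total,
        n_negative=n_total - n_positive,
        n_positive_total=n_positive,
        n_allele=n_allele,
        labeled_allele=thresholds.labeled_allele,  # type: ignore[arg-type]
    )


def methylation_fraction(counts: ClusterCounts) -> MethylationResult:
    """Compute the beta value from cluster counts.

    For channels labeling the methylated allele, beta = M / (M + U);
    for channels labeling the unmethylated allele, beta = 1 − U / (M + U).
    The two expressions are the same quantity, so identical (M, U) give
    identical results regardless of orientation.

    Raises
    ------
    NoPositiveDropletsError
        When M + U = 0: the fraction is undefined, never silently 0.
    """
    m, u = counts.n_methylated, counts.n_unmethylated
    if m + u == 0:
        raise NoPositiveDropletsError(
            f"{counts.cpg}: no positive droplets, methylation undefined"
        )
    if counts.labeled_allele == "methylated":
        beta = m / (m + u)
    else:
        beta = 1.0 - u / (m + u)
    return MethylationResult(
        cpg=counts.cpg, beta=beta, n_methylated=m, n_unmethylated=u, counts=counts
    )


def quantify_well(
    well: DropletWell,
    thresholds: Sequence[ChannelThresholds],
    qc_rule: "QCRule | None" = None,
) -> list[MethylationResult]:
    """Quantify every channel of a well: classify, QC, methylation fraction.

    Returns one :class:`MethylationResult` per threshold entry, in input
    order. Channel failures (e.g. an all-negative channel) are reported on
    the corresponding result's ``error`` field rather than aborting the
    well; the QC record is attached either way.
    """
    from .poisson import QCRule, qc_evaluate

    seen: set[str] = set()
    for thr in thresholds:
        if thr.cpg in seen:
            raise ChannelError(f"duplicate thresholds for channel {thr.cpg!r}")
        seen.add(thr.cpg)
    missing = set(well.channels) - seen
    if missing:
        raise ChannelError(f"well {well.well_id}: no thresholds for {sorted(missing)}")

    rule = qc_rule if qc_rule is not None else QCRule()
    results: list[MethylationResult] = []
    for thr in thresholds:
        counts = classify_droplets(well, thr)
        quant = qc_evaluate(counts, rule)
        try:
            res = methylation_fraction(counts)
        except NoPositiveDropletsError as exc:
            res = MethylationResult(
                cpg=thr.cpg,
                beta=math.nan,
                n_methylated=counts.n_methylated,
                n_unmethylated=counts.n_unmethylated,
                counts=counts,
                error=str(exc),
            )
        res.qc = quant
        results.append(res)
    return results
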