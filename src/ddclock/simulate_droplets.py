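"""Synthetic droplet-well generator: the stand-in for QX600 CSV exports.

The generator mimics the physics the quantification stage assumes, with
ground truth recorded for every droplet:

1. For each CpG channel, the methylated-molecule count is
   Binomial(total_molecules, true_beta); the rest are unmethylated.
2. Each molecule lands in one of ``n_droplets`` droplets uniformly at
   random (multinomial placement — per-droplet counts are asymptotically
   Poisson with lambda = total_molecules / n_droplets).
3. Every droplet gets a true cluster label: *high* if it holds any
   labeled-allele molecule, *single-positive* if it holds only unlabeled
   molecules, *negative* otherwise.
4. Amplitudes are drawn from per-cluster Gaussians (defaults well
   separated, gap >= 6 cluster SDs, so midpoint thresholds are
   unambiguous).
5. 'Rain': with probability ``rain_fraction``, a high-cluster droplet's
   amplitude is redrawn uniformly on the inter-threshold gap, dropping it
   into the single-positive region — the artifact where upper positive
   droplets fall into the lower cluster.

Everything is bit-reproducible from (seed, config): wells in a series use
deterministic per-well child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .droplets import (
    CPGS,
    ChannelThresholds,
    ClusterCounts,
    DropletWell,
    default_labeled_allele,
)

#: Mass of one haploid genome equivalent, in nanograms.
PG_PER_HAPLOID_GENOME = 3.3e-3


def ng_to_molecules(ng: float, amplifiable_fraction: float = 0.2) -> int:
    """Convert a DNA input mass to amplifiable target copies per locus.

    ``amplifiable_fraction`` discounts bisulfite degradation and
    partitioning losses; the 0.2 default is a modeling choice placing a
    40 ng input near ~2,400 amplifiable copies, not a measured value.
    """
    if ng < 0:
        raise ValueError("input mass must be >= 0")
    if not (0 < amplifiable_fraction <= 1):
        raise ValueError("amplifiable_fraction must be in (0, 1]")
    return int(round(ng / PG_PER_HAPLOID_GENOME * amplifiable_fraction))


@dataclass(frozen=True)
class ClusterAmplitudes:
    """Gaussian amplitude model for the three droplet clusters."""

    negative: tuple[float, float] = (1000.0, 100.0)
    single: tuple[float, float] = (4000.0, 150.0)
    high: tuple[float, float] = (8000.0, 200.0)

    def __post_init__(self) -> None:
        means = (self.negative[0], self.single[0], self.high[0])
        if not (means[0] < means[1] < means[2]):
            raise ValueError("cluster means must be ordered negative < single < high")
        if any(sd <= 0 for _, sd in (self.negative, self.single, self.high)):
            raise ValueError("cluster SDs must be positive")

    def default_thresholds(self, cpg: str, labeled_allele: str | None = None) -> ChannelThresholds:
        """Midpoint thresholds between adjacent cluster means."""
        return ChannelThresholds(
            cpg=cpg,
            t_total=0.5 * (self.negative[0] + self.single[0]),
            t_allele=0.5 * (self.single[0] + self.high[0]),
            labeled_allele=labeled_allele,
        )


@dataclass(frozen=True)
class CpGSimConfig:
    """Ground-truth state of one channel: methylation level and input copies."""

    true_beta: float
    total_molecules: int
    labeled_allele: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.true_beta <= 1):
            raise ValueError("true_beta must be in [0, 1]")
        if self.total_molecules < 0:
            raise ValueError("total_molecules must be >= 0")


#: Typical mid-adult blood methylation levels, used as generator defaults.
DEFAULT_TRUE_BETAS: dict[str, float] = {
    "ASPA": 0.49,
    "C1orf132": 0.56,
    "CCDC102B": 0.44,
    "EDARADD": 0.30,
    "ELOVL2": 0.57,
    "FHL2": 0.34,
}


@dataclass(frozen=True)
class AssaySimConfig:
    """Full configuration of one simulated multiplex well."""

    seed: int
    n_droplets: int = 20000
    cpgs: Mapping[str, CpGSimConfig] = field(default_factory=dict)
    amplitudes: ClusterAmplitudes = field(default_factory=ClusterAmplitudes)
    rain_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if not (0 <= self.rain_fraction < 0.5):
            raise ValueError("rain_fraction must be in [0, 0.5)")
        if not self.cpgs:
            object.__setattr__(
                self,
                "cpgs",
                {
                    cpg: CpGSimConfig(
                        true_beta=DEFAULT_TRUE_BETAS[cpg],
                        total_molecules=1500,
                        labeled_allele=default_labeled_allele(cpg),
                    )
                    for cpg in CPGS
                },
            )
        else:
            resolved = {
                cpg: (
                    cfg
                    if cfg.labeled_allele is not None
                    else replace(cfg, labeled_allele=default_labeled_allele(cpg))
                )
                for cpg, cfg in self.cpgs.items()
            }
            object.__setattr__(self, "cpgs", resolved)

    def thresholds(self) -> list[ChannelThresholds]:
        """Midpoint thresholds for every configured channel."""
        return [
            self.amplitudes.default_thresholds(cpg, cfg.labeled_allele)
            for cpg, cfg in self.cpgs.items()
        ]


@dataclass
class ChannelTruth:
    """Ground-truth bookkeeping for one simulated channel."""

    cpg: str
    true_beta: float
    labeled_allele: str
    n_methylated_molecules: int
    n_unmethylated_molecules: int
    methylated_per_droplet: np.ndarray
    unmethylated_per_droplet: np.ndarray
    labels: np.ndarray  # 0 negative, 1 single-positive, 2 high
    rain: np.ndarray  # bool, amplitude displaced into the gap

    def cluster_counts(self) -> ClusterCounts:
        """The counts a perfect (threshold-free) classifier would report."""
        n = self.labels.size
        n_pos = int(np.count_nonzero(self.labels > 0))
        return ClusterCounts(
            cpg=self.cpg,
            n_total=n,
            n_negative=n - n_pos,
            n_positive_total=n_pos,
            n_allele=int(np.count_nonzero(self.labels == 2)),
            labeled_allele=self.labeled_allele,
        )


@dataclass
class SimulatedWell:
    """A droplet well plus the ground truth that generated it."""

    well: DropletWell
    truth: dict[str, ChannelTruth]
    config: AssaySimConfig


def _simulate_channel(
    cpg: str,
    cfg: CpGSimConfig,
    n_droplets: int,
    amplitudes: ClusterAmplitudes,
    rain_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ChannelTruth]:
    n_meth = int(rng.binomial(cfg.total_molecules, cfg.true_beta))
    n_unmeth = cfg.total_molecules - n_meth
    p_uniform = np.full(n_droplets, 1.0 / n_droplets)
    meth = rng.multinomial(n_meth, p_uniform)
    unmeth = rng.multinomial(n_unmeth, p_uniform)

    labeled = meth if cfg.labeled_allele == "methylated" else unmeth
    other = unmeth if cfg.labeled_allele == "methylated" else meth
    labels = np.zeros(n_droplets, dtype=np.int8)
    labels[other > 0] = 1
    labels[labeled > 0] = 2

    amps = np.empty(n_droplets)
    for code, (mean, sd) in enumerate(
        (amplitudes.negative, amplitudes.single, amplitudes.high)
    ):
        mask = labels == code
        amps[mask] = rng.normal(mean, sd, size=int(mask.sum()))

    rain = np.zeros(n_droplets, dtype=bool)
    if rain_fraction > 0:
        high = np.flatnonzero(labels == 2)
        hit = high[rng.random(high.size) < rain_fraction]
        thr = amplitudes.default_thresholds(cpg, cfg.labeled_allele)
        amps[hit] = rng.uniform(thr.t_total, thr.t_allele, size=hit.size)
        rain[hit] = True

    truth = ChannelTruth(
        cpg=cpg,
        true_beta=cfg.true_beta,
        labeled_allele=cfg.labeled_allele,  # type: ignore[arg-type]
        n_methylated_molecules=n_meth,
        n_unmethylated_molecules=n_unmeth,
        methylated_per_droplet=meth,
        unmethylated_per_droplet=unmeth,
        labels=labels,
        rain=rain,
    )
    return amps, truth


def simulate_well(config: AssaySimConfig, well_id: str = "A01") -> SimulatedWell:
    """Simulate one multiplex well with full ground truth."""
    rng = np.random.default_rng(config.seed)
    channel_amps: dict[str, np.ndarray] = {}
    truth: dict[str, ChannelTruth] = {}
    for cpg, cfg in config.cpgs.items():
        amps, ch_truth = _simulate_channel(
            cpg, cfg, config.n_droplets, config.amplitudes, config.rain_fraction, rng
        )
        channel_amps[cpg] = amps
        truth[cpg] = ch_truth
    well = DropletWell(well_id=well_id, channel_amplitudes=channel_amps)
    return SimulatedWell(well=well, truth=truth, config=config)


def simulate_dilution_series(
    config: AssaySimConfig,
    dilution_factors: Sequence[float],
    replicates: int = 2,
) -> list[SimulatedWell]:
    """Simulate a dilution series: ``replicates`` wells per factor.

    Factors must be positive and non-increasing (a descending series);
    per-channel molecule counts are scaled by each factor (rounded).
    Wells get deterministic child seeds derived from ``config.seed``, so
    the whole series is reproducible.
    """
    factors = list(dilution_factors)
    if not factors:
        raise ValueError("need at least one dilution factor")
    if any(f <= 0 for f in factors):
        raise ValueError("dilution factors must be positive")
    if any(b > a for a, b in zip(factors, factors[1:])):
        raise ValueError("dilution factors must be descending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    wells: list[SimulatedWell] = []
    for level, factor in enumerate(factors):
        scaled = {
            cpg: replace(cfg, total_molecules=int(round(cfg.total_molecules * factor)))
            for cpg, cfg in config.cpgs.items()
        }
        for rep in range(replicates):
            child_seed = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(level, rep)
            ).generate_state(1)[0]
            sub = replace(config, seed=int(child_seed), cpgs=scaled)
            wells.append(
                simulate_well(sub, well_id=f"D{level:02d}R{rep:02d}")
            )
    return wells
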