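"""Droplet-well generator: conservation, Poisson behavior, rain, dilution."""

import numpy as np
import pytest
from scipy import stats

from ddclock import classify_droplets, methylation_fraction
from ddclock.simulate_droplets import (
    AssaySimConfig,
    ClusterAmplitudes,
    CpGSimConfig,
    ng_to_molecules,
    simulate_dilution_series,
    simulate_well,
)


class TestSimulateWell:
    def test_molecule_conservation_and_label_consistency(self, single_channel_config):
        cfg = single_channel_config(seed=9, true_beta=0.4)
        t = simulate_well(cfg).truth["FHL2"]
        assert t.methylated_per_droplet.sum() == t.n_methylated_molecules
        assert t.unmethylated_per_droplet.sum() == t.n_unmethylated_molecules
        assert t.n_methylated_molecules + t.n_unmethylated_molecules == 1500
        # FHL2 labels the unmethylated allele
        labeled = t.unmethylated_per_droplet
        other = t.methylated_per_droplet
        assert np.all(t.labels[labeled > 0] == 2)
        assert np.all(t.labels[(labeled == 0) & (other > 0)] == 1)
        assert np.all(t.labels[(labeled == 0) & (other == 0)] == 0)

    def test_boundary_beta_zero(self):
        cfg = AssaySimConfig(
            seed=4, cpgs={"ELOVL2": CpGSimConfig(true_beta=0.0, total_molecules=1500)}
        )
        t = simulate_well(cfg).truth["ELOVL2"]
        # ELOVL2 labels the methylated allele, absent at beta = 0
        assert t.n_methylated_molecules == 0
        assert t.cluster_counts().n_allele == 0

    def test_expected_positive_fraction(self, single_channel_config):
        """2,482 molecules over 20,000 droplets -> p ~ 1 - e^{-0.1241} = 11.67%."""
        fractions = []
        for seed in range(20):
            cfg = single_channel_config(seed=seed, total_molecules=2482)
            counts = simulate_well(cfg).truth["FHL2"].cluster_counts()
            fractions.append(counts.n_positive_total / counts.n_total)
        expected = 1 - np.exp(-2482 / 20000)
        se = np.sqrt(expected * (1 - expected) / (20 * 20000))
        assert abs(np.mean(fractions) - expected) < 3 * se

    def test_no_rain_classification_recovers_truth(self, single_channel_config):
        cfg = single_channel_config(seed=21, rain_fraction=0.0)
        sim = simulate_well(cfg)
        counts = classify_droplets(sim.well, cfg.thresholds()[0])
        assert counts == sim.truth["FHL2"].cluster_counts()

    def test_determinism(self, single_channel_config):
        a = simulate_well(single_channel_config(seed=77))
        b = simulate_well(single_channel_config(seed=77))
        np.testing.assert_array_equal(
            a.well.channel_amplitudes["FHL2"], b.well.channel_amplitudes["FHL2"]
        )

    def test_poisson_occupancy_distribution(self):
        """Pooled per-droplet molecule counts fit Poisson(lambda) at lambda<=0.3."""
        lam = 0.1
        pooled = np.zeros(4, dtype=float)  # occupancy 0,1,2,3+
        n_droplets, n_seeds = 5000, 40
        for seed in range(n_seeds):
            cfg = AssaySimConfig(
                seed=seed,
                n_droplets=n_droplets,
                cpgs={"FHL2": CpGSimConfig(true_beta=0.3, total_molecules=int(lam * n_droplets))},
            )
            t = simulate_well(cfg).truth["FHL2"]
            k = t.methylated_per_droplet + t.unmethylated_per_droplet
            pooled += [np.sum(k == 0), np.sum(k == 1), np.sum(k == 2), np.sum(k >= 3)]
        n = n_droplets * n_seeds
        pmf = stats.poisson.pmf([0, 1, 2], lam)
        expected = np.append(pmf, 1 - pmf.sum()) * n
        p_value = stats.chisquare(pooled, expected).pvalue
        assert p_value > 0.01

    def test_rain_biases_toward_common_allele(self):
        """With the rarer allele labeled, rain pushes beta toward the common
        allele (here: labeled methylated at true beta 0.2 -> downward bias)."""
        errs = []
        for seed in range(40):
            cfg = AssaySimConfig(
                seed=seed,
                n_droplets=10000,
                rain_fraction=0.15,
                cpgs={"CCDC102B": CpGSimConfig(true_beta=0.2, total_molecules=800)},
            )
            sim = simulate_well(cfg)
            counts = classify_droplets(sim.well, cfg.thresholds()[0])
            errs.append(methylation_fraction(counts).beta - 0.2)
        # sign test: overwhelmingly negative deviations
        assert np.median(errs) < 0
        assert np.mean(np.array(errs) < 0) > 0.9

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            AssaySimConfig(seed=0, n_droplets=0)
        with pytest.raises(ValueError):
            CpGSimConfig(true_beta=1.2, total_molecules=10)
        with pytest.raises(ValueError):
            CpGSimConfig(true_beta=0.5, total_molecules=-1)
        with pytest.raises(ValueError):
            ClusterAmplitudes(negative=(5000, 100), single=(4000, 100))


class TestDilutionSeries:
    def test_construction_and_monotone_counts(self, single_channel_config):
        cfg = single_channel_config(seed=1, total_molecules=12000)
        factors = [2.0**-i for i in range(7)]
        wells = simulate_dilution_series(cfg, factors, replicates=2)
        assert len(wells) == 14
        means = []
        for level in range(7):
            fr = [
                w.truth["FHL2"].cluster_counts().n_positive_total
                for w in wells[2 * level : 2 * level + 2]
            ]
            means.append(np.mean(fr))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_replicate_spread_grows_at_low_input(self, single_channel_config):
        """Beta SD across replicates at the lowest input exceeds the SD at the
        highest (binomial variance shrinks with the positive count)."""
        sd_low, sd_high = [], []
        for seed in range(30):
            cfg = single_channel_config(seed=seed, true_beta=0.4, total_molecules=6000)
            wells = simulate_dilution_series(cfg, [1.0, 1 / 64], replicates=4)
            betas = {0: [], 1: []}
            for i, w in enumerate(wells):
                counts = classify_droplets(w.well, cfg.thresholds()[0])
                betas[i // 4].append(methylation_fraction(counts).beta)
            sd_high.append(np.std(betas[0]))
            sd_low.append(np.std(betas[1]))
        assert np.mean(sd_low) > np.mean(sd_high)

    def test_degenerate_series_and_validation(self, single_channel_config):
        cfg = single_channel_config(seed=2)
        assert len(simulate_dilution_series(cfg, [1.0], replicates=3)) == 3
        with pytest.raises(ValueError):
            simulate_dilution_series(cfg, [0.5, 1.0])  # ascending
        with pytest.raises(ValueError):
            simulate_dilution_series(cfg, [])

    def test_zero_molecule_level_allowed(self, single_channel_config):
        cfg = single_channel_config(seed=3, total_molecules=10)
        wells = simulate_dilution_series(cfg, [1.0, 0.001], replicates=1)
        counts = wells[-1].truth["FHL2"].cluster_counts()
        assert counts.n_positive_total == 0

    def test_determinism_of_sub_seeds(self, single_channel_config):
        cfg = single_channel_config(seed=5, total_molecules=2000)
        a = simulate_dilution_series(cfg, [1.0, 0.5], replicates=2)
        b = simulate_dilution_series(cfg, [1.0, 0.5], replicates=2)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(
                wa.well.channel_amplitudes["FHL2"], wb.well.channel_amplitudes["FHL2"]
            )


def test_ng_to_molecules():
    # 40 ng at the default amplifiable fraction lands near 2,400 copies
    assert 2000 < ng_to_molecules(40) < 2900
    assert ng_to_molecules(0) == 0
    with pytest.raises(ValueError):
        ng_to_molecules(-1)
    with pytest.raises(ValueError):
        ng_to_molecules(10, amplifiable_fraction=0)
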