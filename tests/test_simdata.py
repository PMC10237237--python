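"""Generator behaviour: Balding–Nichols limits, HWE purebreds, crossbred
mosaics, dataset bookkeeping and the divergence calibration."""

import numpy as np
import pandas as pd
import pytest

from breedcomp.divergence import pairwise_fst
from breedcomp.simdata import (
    BREEDS,
    TABLE_POP_SIZES,
    AlleleFrequencyTable,
    CrossDesign,
    SimulationConfig,
    UnsupportedDesignError,
    assemble_study_dataset,
    simulate_breed_frequencies,
    simulate_crossbreds,
    simulate_purebreds,
    write_dataset,
)
from breedcomp.genotype_io import read_plink


def two_breed_config(F, n_snps=10_000, seed=0):
    return SimulationConfig.scaled(
        n_breeds=2,
        n_snps=n_snps,
        n_chromosomes=2,
        n_training=1,
        n_validation=1,
        n_snp_selection=1,
        drift_F=F,
        seed=seed,
    )


class TestBreedFrequencies:
    def test_zero_drift_limit_reproduces_ancestral(self):
        cfg = two_breed_config(F=1e-9, n_snps=2000)
        tab = simulate_breed_frequencies(cfg)
        assert np.abs(tab.freqs - tab.ancestral).max() < 1e-3

    def test_mean_frequency_is_ancestral(self):
        cfg = two_breed_config(F=0.2, n_snps=20_000, seed=3)
        tab = simulate_breed_frequencies(cfg)
        # Beta mean equals the ancestral p: per-breed average deviation vanishes
        for k in range(2):
            assert abs((tab.freqs[k] - tab.ancestral).mean()) < 0.01

    def test_realized_fst_matches_monte_carlo_oracle(self):
        """Two breeds at F=0.1: realized mean per-SNP Fst agrees with an
        independent Monte-Carlo estimate of E[s^2/(pbar(1-pbar))] computed
        directly from the Beta model (10 seeds)."""
        rng = np.random.default_rng(99)
        mc = []
        for _ in range(10):  # independent oracle: raw Beta draws, no simulator
            p = rng.uniform(0.05, 0.95, size=10_000)
            scale = (1 - 0.1) / 0.1
            f1 = rng.beta(p * scale, (1 - p) * scale)
            f2 = rng.beta(p * scale, (1 - p) * scale)
            s2 = ((f1 - f2) / 2.0) ** 2
            pb = (f1 + f2) / 2.0
            ok = (pb > 0) & (pb < 1)
            mc.append((s2[ok] / (pb[ok] * (1 - pb[ok]))).mean())
        expected = np.mean(mc)
        tab = simulate_breed_frequencies(two_breed_config(F=0.1, seed=5))
        realized = pairwise_fst(tab)[0, 1]
        assert abs(realized - expected) < 0.03

    def test_default_drift_spans_observed_cattle_envelope(self):
        """The calibrated default drifts realize pairwise Fst inside the
        0.039-0.146 envelope reported between European cattle breeds."""
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig.scaled(
                n_breeds=13, n_snps=5000, n_chromosomes=3,
                n_training=1, n_validation=1, n_snp_selection=1, seed=seed,
            )
            pw = pairwise_fst(simulate_breed_frequencies(cfg))
            vals = pw[np.triu_indices(13, 1)]
            if vals.min() >= 0.035 and vals.max() <= 0.155:
                hits += 1
        assert hits >= 4

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError, match="drift_F"):
            two_breed_config(F=1.5)

    def test_deterministic_given_seed(self):
        a = simulate_breed_frequencies(two_breed_config(F=0.1, n_snps=500, seed=7))
        b = simulate_breed_frequencies(two_breed_config(F=0.1, n_snps=500, seed=7))
        np.testing.assert_array_equal(a.freqs, b.freqs)
        assert a.markers.equals(b.markers)


class TestPurebreds:
    def _table(self, f_row, n=200):
        m = len(f_row)
        markers = pd.DataFrame(
            {"chrom": np.ones(m, dtype=int), "pos": np.arange(1, m + 1)},
            index=pd.Index([f"m{j}" for j in range(m)], name="snp_id"),
        )
        return AlleleFrequencyTable(np.array([f_row]), ["X"], markers)

    def test_fixed_alleles(self):
        tab = self._table([1.0, 0.0, 1.0])
        gm = simulate_purebreds(tab, [5], seed=0)
        np.testing.assert_array_equal(gm.genotypes, [[2, 0, 2]] * 5)

    def test_intermediate_frequency_binomial(self):
        """f=0.5, n=500: allele frequency and het fraction near 0.5 within
        exact-binomial bounds (4 sigma on 1000 draws: +/-0.063 per SNP;
        averaged over 50 SNPs the tolerance 0.05 is conservative)."""
        tab = self._table([0.5] * 50)
        gm = simulate_purebreds(tab, [500], seed=1)
        assert abs(gm.genotypes.mean() / 2.0 - 0.5) < 0.05
        assert abs((gm.genotypes == 1).mean() - 0.5) < 0.05

    def test_genotype_values_and_no_missing(self, small_dataset):
        g = small_dataset.training.genotypes
        assert set(np.unique(g)).issubset({0, 1, 2})


class TestCrossbreds:
    def test_pedigree_expected_fractions(self):
        f1 = CrossDesign("AxB", (0, 1), 1)
        np.testing.assert_allclose(f1.expected_fractions(3), [0.5, 0.5, 0])
        tw = CrossDesign("Ax(BxC)", (0, (1, 2)), 1)
        np.testing.assert_allclose(tw.expected_fractions(3), [0.5, 0.25, 0.25])
        bc = CrossDesign("Ax(AxB)", (0, (0, 1)), 1)
        np.testing.assert_allclose(bc.expected_fractions(2), [0.75, 0.25])

    def test_deep_pedigree_rejected(self):
        with pytest.raises(UnsupportedDesignError):
            CrossDesign("too deep", (0, (1, (2, 3))), 1)

    def test_f1_realized_fraction_exact(self):
        """Purebred x purebred: every transmitted locus is fixed for its
        parent's breed, so the realized fraction is exactly one half."""
        cfg = two_breed_config(F=0.2, n_snps=400, seed=2)
        tab = simulate_breed_frequencies(cfg)
        gm = simulate_crossbreds(tab, [CrossDesign("f1", (0, 1), 20)], cfg)
        np.testing.assert_allclose(gm.samples["frac_AA"], 0.5)
        np.testing.assert_allclose(gm.samples["frac_AU"], 0.5)

    def test_three_way_realized_fraction_lln(self):
        """A x (BxC): the F1 dam's gamete is a recombination mosaic, so
        realized B/C fractions vary around 0.25 with positive spread, while
        the sire's breed stays exactly 0.5.  Oracle: independent
        re-simulation of Haldane crossover counts gives the same mean."""
        cfg = SimulationConfig.scaled(
            n_breeds=3, n_snps=3000, n_chromosomes=3,
            n_training=1, n_validation=1, n_snp_selection=1,
            drift_F=0.1, seed=4,
            cross_designs=[CrossDesign("3way", (0, (1, 2)), 300)],
        )
        tab = simulate_breed_frequencies(cfg)
        gm = simulate_crossbreds(tab, cfg.cross_designs, cfg, seed=9)
        fb = gm.samples["frac_AU"].to_numpy()
        np.testing.assert_allclose(gm.samples["frac_AA"], 0.5)
        assert abs(fb.mean() - 0.25) < 0.02
        assert fb.std() > 0

        # oracle: simulate the mosaic process alone (no genotypes)
        rng = np.random.default_rng(1234)
        gpos = [tab.markers.loc[tab.markers.chrom == c, "pos"].to_numpy() * 1e-8
                for c in (1, 2, 3)]
        sims = []
        for _ in range(300):
            tot = 0
            for gp in gpos:
                L = gp[-1]
                xo = np.sort(rng.uniform(0, L, rng.poisson(L)))
                par = (rng.integers(2) + np.searchsorted(xo, gp)) % 2
                tot += (par == 0).sum()
            sims.append(tot / sum(len(gp) for gp in gpos) / 2.0)
        assert abs(np.mean(sims) - fb.mean()) < 0.02

    def test_independent_locus_mode(self):
        cfg = two_breed_config(F=0.2, n_snps=1000, seed=2)
        tab = simulate_breed_frequencies(cfg)
        gm = simulate_crossbreds(
            tab, [CrossDesign("bc", (0, (0, 1)), 100)], cfg, model="independent"
        )
        frac = gm.samples["frac_AA"]
        assert abs(frac.mean() - 0.75) < 0.02
        assert frac.std() > 0

    def test_empty_designs_rejected(self):
        cfg = two_breed_config(F=0.2, n_snps=100)
        tab = simulate_breed_frequencies(cfg)
        with pytest.raises(ValueError):
            simulate_crossbreds(tab, [], cfg)


class TestStudyDataset:
    def test_population_sizes_match_config(self, small_dataset):
        cfg = small_dataset.config
        assert small_dataset.training.n_samples == sum(cfg.pop_sizes["training"])
        assert small_dataset.purebred_validation.n_samples == sum(
            cfg.pop_sizes["validation"]
        )
        assert small_dataset.snp_selection.n_samples == sum(
            cfg.pop_sizes["snp_selection"]
        )
        assert small_dataset.crossbred_validation.n_samples == sum(
            d.n_animals for d in cfg.cross_designs
        )

    def test_populations_disjoint(self, small_dataset):
        pops = list(small_dataset.populations.values())
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                assert not (set(pops[i].sample_ids) & set(pops[j].sample_ids))

    def test_full_scale_defaults_mirror_study_design(self):
        cfg = SimulationConfig()
        assert cfg.n_snps == 49_213
        assert len(cfg.chromosomes) == 29
        angus = cfg.breed_labels.index("AA")
        assert cfg.pop_sizes["training"][angus] == 500
        assert cfg.pop_sizes["validation"][angus] == 250
        assert cfg.pop_sizes["snp_selection"][angus] == 1000
        assert cfg.breed_labels == BREEDS
        assert cfg.pop_sizes["validation"] == TABLE_POP_SIZES["validation"]

    def test_determinism_bit_identical(self):
        kw = dict(n_breeds=3, n_snps=300, n_chromosomes=2,
                  n_training=5, n_validation=3, n_snp_selection=4, seed=11)
        a = assemble_study_dataset(SimulationConfig.scaled(**kw))
        b = assemble_study_dataset(SimulationConfig.scaled(**kw))
        for pop in a.populations:
            np.testing.assert_array_equal(
                a.populations[pop].genotypes, b.populations[pop].genotypes
            )

    def test_write_dataset_round_trips(self, tmp_path):
        cfg = SimulationConfig.scaled(
            n_breeds=2, n_snps=60, n_chromosomes=2,
            n_training=4, n_validation=2, n_snp_selection=3, seed=5,
        )
        ds = assemble_study_dataset(cfg)
        write_dataset(ds, tmp_path)
        back = read_plink(tmp_path / "training")
        np.testing.assert_array_equal(back.genotypes, ds.training.genotypes)
        sidecar = pd.read_csv(tmp_path / "samples.tsv", sep="\t")
        assert len(sidecar) == sum(p.n_samples for p in ds.populations.values())
        assert {"sample_id", "population", "breed", "frac_AA"} <= set(sidecar.columns)
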