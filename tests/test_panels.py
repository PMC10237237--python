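"""Allocation, position clustering, SNP scoring and panel assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedcomp.panels import (
    DEFAULT_STRATEGIES,
    SizingError,
    allocate_per_chromosome,
    build_all_panels,
    pam_position_clusters,
    score_snps,
    score_table,
    select_panel,
)

from conftest import make_genotypes


class TestAllocation:
    def test_exact_proportions(self):
        np.testing.assert_array_equal(
            allocate_per_chromosome(8, [100e6, 50e6, 50e6]), [4, 2, 2]
        )

    def test_largest_remainder_rule(self):
        # quotas (3.5, 1.75, 1.75): floors (3,1,1), remainders (.5,.75,.75)
        np.testing.assert_array_equal(
            allocate_per_chromosome(7, [100, 50, 50]), [3, 2, 2]
        )

    def test_remainder_tie_breaks_to_earlier_chromosome(self):
        # quotas (1.5, 1.5): one leftover unit goes to the first chromosome
        np.testing.assert_array_equal(allocate_per_chromosome(3, [50, 50]), [2, 1])

    @settings(max_examples=100, deadline=None)
    @given(
        density=st.integers(0, 500),
        lengths=st.lists(st.integers(1, 10_000), min_size=1, max_size=30),
    )
    def test_conservation(self, density, lengths):
        counts = allocate_per_chromosome(density, lengths)
        assert counts.sum() == density
        assert (counts >= 0).all()

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            allocate_per_chromosome(5, [0, 0])


def exhaustive_kmedoids(positions, k):
    """Brute-force oracle: best medoid subset over all combinations."""
    x = np.asarray(positions, float)
    best, best_meds = np.inf, None
    for meds in itertools.combinations(range(len(x)), k):
        cost = sum(min(abs(xi - x[m]) for m in meds) for xi in x)
        if cost < best - 1e-12:
            best, best_meds = cost, meds
    return best, best_meds


class TestPamPositionClusters:
    def test_two_well_separated_groups(self):
        pos = [1, 2, 3, 100, 101, 102]
        labels, medoids = pam_position_clusters(pos, 2)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]
        assert [pos[m] for m in medoids] == [2, 101]

    def test_k_equals_n_every_snp_its_own_medoid(self):
        labels, medoids = pam_position_clusters([5, 10, 20], 3)
        assert sorted(medoids.tolist()) == [0, 1, 2]

    def test_k_one_lower_median(self):
        _, medoids = pam_position_clusters([1, 4, 9, 30], 1)
        assert medoids.tolist() == [1]  # lower median of 4 points
        _, medoids = pam_position_clusters([1, 4, 9], 1)
        assert medoids.tolist() == [1]

    @settings(max_examples=30, deadline=None)
    @given(data=st.data())
    def test_matches_exhaustive_search(self, data):
        """On <=8-point instances the DP cost equals the brute-force optimum
        over all medoid subsets."""
        n = data.draw(st.integers(2, 8))
        k = data.draw(st.integers(1, n))
        pos = sorted(
            data.draw(
                st.lists(
                    st.integers(0, 1000), min_size=n, max_size=n, unique=True
                )
            )
        )
        labels, medoids = pam_position_clusters(pos, k)
        cost = sum(
            abs(pos[i] - pos[medoids[labels[i]]]) for i in range(n)
        )
        best, _ = exhaustive_kmedoids(pos, k)
        assert cost == pytest.approx(best)

    def test_k_exceeds_n_rejected(self):
        with pytest.raises(SizingError):
            pam_position_clusters([1, 2], 3)


class TestScoring:
    @staticmethod
    @pytest.fixture(scope="class")
    def scored(small_dataset):
        g = small_dataset.snp_selection
        return g, score_table(g, seed=3, n_trees=50)

    def test_monomorphic_snp_scores_zero(self):
        geno = np.array([[0, 1, 2, 2], [0, 2, 1, 0], [0, 0, 1, 2], [0, 1, 0, 1]])
        gm = make_genotypes(geno, breed=["a", "a", "b", "b"])
        for method in ("fst", "pca_weight", "snpblup_sd", "plsda_weight"):
            s = score_snps(method, gm, seed=0, pls_components=1)
            assert s[0] == pytest.approx(0.0, abs=1e-12), method
            assert (s >= 0).all()

    def test_breed_diagnostic_snp_tops_fst_ranking(self, small_dataset):
        """A SNP fixed opposite in one breed vs all others must land in the
        top Fst decile (constructed marker check)."""
        g = small_dataset.snp_selection
        geno = g.genotypes.copy()
        is_aa = (g.samples["breed"] == "AA").to_numpy()
        geno[:, 0] = np.where(is_aa, 2, 0)
        gm = make_genotypes(geno, chrom=g.markers["chrom"], pos=g.markers["pos"],
                            breed=g.samples["breed"], ids=g.sample_ids)
        s = score_snps("fst", gm)
        assert s[0] >= np.quantile(s, 0.9)

    def test_equal_effects_give_zero_sd(self):
        # snpblup_sd of a monomorphic SNP: every per-breed fit estimates 0
        geno = np.array([[1, 1, 2], [1, 0, 2], [1, 2, 0], [1, 1, 0]] * 3)
        gm = make_genotypes(geno, breed=["a", "b", "c", "a"] * 3)
        s = score_snps("snpblup_sd", gm, seed=0)
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_rf_vim_deterministic_given_seed(self, small_dataset):
        g = small_dataset.snp_selection.subset(
            markers=small_dataset.snp_selection.marker_ids[:100]
        )
        a = score_snps("rf_vim", g, seed=5, n_trees=25)
        b = score_snps("rf_vim", g, seed=5, n_trees=25)
        np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            score_snps("chi2", small_dataset.snp_selection)

    def test_scores_finite_nonnegative(self, scored):
        _, tab = scored
        for col in ("fst", "pca_weight", "snpblup_sd", "rf_vim", "plsda_weight"):
            assert np.isfinite(tab[col]).all()
            assert (tab[col] >= 0).all()


class TestSelectPanel:
    def test_full_density_returns_all_snps(self, small_dataset):
        mk = small_dataset.snp_selection.markers
        panel = select_panel("random", len(mk), mk, seed=0)
        assert sorted(panel.marker_ids) == sorted(mk.index)

    def test_block_method_picks_max_per_block(self):
        # 10 SNPs on one chromosome, scores 1..10, 2 blocks -> SNPs 5 and 10
        mk = pd.DataFrame(
            {"chrom": 1, "pos": np.arange(1, 11) * 100},
            index=pd.Index([f"m{j}" for j in range(10)], name="snp_id"),
        )
        scores = pd.DataFrame({"fst": np.arange(1, 11)}, index=mk.index)
        panel = select_panel("fst_block", 2, mk, scores=scores)
        assert panel.marker_ids == ["m4", "m9"]

    def test_highest_ties_break_to_lower_position(self):
        mk = pd.DataFrame(
            {"chrom": 1, "pos": [100, 200, 300]},
            index=pd.Index(["a", "b", "c"], name="snp_id"),
        )
        scores = pd.DataFrame({"fst": [1.0, 1.0, 1.0]}, index=mk.index)
        panel = select_panel("fst_highest", 2, mk, scores=scores)
        assert panel.marker_ids == ["a", "b"]

    def test_random_is_seeded(self, small_dataset):
        mk = small_dataset.snp_selection.markers
        a = select_panel("random", 50, mk, seed=1)
        b = select_panel("random", 50, mk, seed=1)
        c = select_panel("random", 50, mk, seed=2)
        assert a.marker_ids == b.marker_ids
        assert a.marker_ids != c.marker_ids

    def test_density_exceeding_total_rejected(self, small_dataset):
        mk = small_dataset.snp_selection.markers
        with pytest.raises(SizingError):
            select_panel("random", len(mk) + 1, mk)

    def test_unknown_strategy_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            select_panel("best_guess", 10, small_dataset.snp_selection.markers)


class TestBuildAllPanels:
    def test_seven_by_seven_grid(self, small_dataset):
        g = small_dataset.snp_selection
        densities = [50, 100, 200]
        panels = build_all_panels(
            g, densities=densities, seed=0,
            strategies=DEFAULT_STRATEGIES,
            scores=score_table(g, seed=0, n_trees=25),
        )
        assert len(panels) == 7 * len(densities)
        # identical per-chromosome allocation across strategies per density
        for d in densities:
            allocs = {
                tuple(sorted(p.per_chromosome.items()))
                for p in panels
                if p.density == d
            }
            assert len(allocs) == 1
        for p in panels:
            assert len(set(p.marker_ids)) == p.density
            assert sum(p.per_chromosome.values()) == p.density

    def test_informative_and_random_panels_overlap_little(self, small_dataset):
        g = small_dataset.snp_selection
        scores = score_table(g, methods=["fst"], seed=0)
        a = select_panel("fst_highest", 100, g.markers, scores=scores)
        b = select_panel("random", 100, g.markers, scores=scores, seed=9)
        overlap = len(set(a.marker_ids) & set(b.marker_ids)) / 100
        assert overlap < 0.5


class TestPanelInformativeness:
    """End-to-end panel quality on a 5-breed simulation: deviation from the
    full-panel gold standard shrinks with density, and Fst-ranked panels
    beat random panels at low density."""

    def test_density_trend_and_fst_vs_random(self):
        import breedcomp as bc
        from breedcomp.evaluation import main_breed_deviation
        from breedcomp.genotype_io import GenotypeMatrix
        from breedcomp.pipeline import predict_snp_blup

        cfg = bc.SimulationConfig.scaled(
            n_breeds=5, n_snps=4000, n_chromosomes=3,
            n_training=100, n_validation=5, n_snp_selection=150,
            drift_F=0.2, seed=9,
            cross_designs=[bc.CrossDesign("AAxCH F1", (0, 4), 40)],
        )
        ds = bc.assemble_study_dataset(cfg)
        val = ds.crossbred_validation
        gold = predict_snp_blup(ds.training, val)
        scores = score_table(ds.snp_selection, methods=["fst"], seed=1)
        lengths = dict(cfg.chromosomes)

        def deviation(strategy, density):
            panel = select_panel(
                strategy, density, ds.snp_selection.markers,
                scores=scores, chrom_lengths=lengths, seed=2,
            )
            pred = predict_snp_blup(ds.training, val, panel=panel)
            return main_breed_deviation(pred, gold).mean()

        devs = [deviation("fst_highest", d) for d in (200, 800, 2000)]
        assert devs[0] > devs[1] > devs[2]
        assert deviation("fst_highest", 200) < deviation("random", 200)
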