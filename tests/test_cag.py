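import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from enterocag.abundance_io import GenusAbundanceTable, ValidationError, to_relative
from enterocag.cag import (
    CAGPartition,
    cag_abundance,
    compare_cag_abundance,
    correlation_matrix,
    define_cags,
    select_training_combination,
)
from enterocag.synthetic import SyntheticCohortConfig, default_config, generate_cohort

from .conftest import random_count_table


class TestCorrelationMatrix:
    def test_duplicated_genus_perfect_correlation(self, rng):
        base = rng.random(10)
        df = pd.DataFrame(
            {"g1": base, "g2": base, "g3": rng.random(10)},
            index=[f"s{i}" for i in range(10)],
        )
        corr = correlation_matrix(GenusAbundanceTable(df, "counts"))
        assert corr.loc["g1", "g2"] == pytest.approx(1.0)

    def test_monotone_reversal(self, rng):
        g1 = rng.random(10)
        df = pd.DataFrame({"g1": g1, "g2": -g1 + 5.0}, index=[f"s{i}" for i in range(10)])
        corr = correlation_matrix(GenusAbundanceTable(df, "counts"))
        assert corr.loc["g1", "g2"] == pytest.approx(-1.0)

    def test_matches_scipy_pairwise_oracle(self, rng):
        table = random_count_table(rng, n_samples=15, n_genera=10)
        corr = correlation_matrix(table)
        for a in table.genus_names:
            for b in table.genus_names:
                expected = spearmanr(table.data[a], table.data[b]).statistic
                assert corr.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_constant_genus_rejected(self):
        df = pd.DataFrame(
            {"g1": [1, 2, 3], "g2": [4, 4, 4]}, index=["a", "b", "c"]
        )
        with pytest.raises(ValidationError, match="g2"):
            correlation_matrix(GenusAbundanceTable(df, "counts"))

    def test_spearman_rank_invariance_counts_vs_relative(self, rng):
        # equal depths: relative abundance is a positive rescale per sample
        counts = rng.integers(1, 50, size=(12, 6)).astype(float)
        counts = counts / counts.sum(axis=1, keepdims=True) * 1000
        df = pd.DataFrame(
            counts, index=[f"s{i}" for i in range(12)], columns=[f"g{j}" for j in range(6)]
        )
        t_counts = GenusAbundanceTable(df, "counts")
        t_rel = to_relative(t_counts)
        c1 = correlation_matrix(t_counts)
        c2 = correlation_matrix(t_rel)
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-12)


class TestDefineCags:
    def _block_corr(self):
        genera = [f"g{i}" for i in range(6)]
        mat = np.zeros((6, 6))
        mat[:3, :3] = 1.0
        mat[3:, 3:] = 1.0
        return pd.DataFrame(mat, index=genera, columns=genera)

    def test_perfect_blocks_recovered(self):
        part = define_cags(self._block_corr(), k=2)
        assert part.members(1) == ("g0", "g1", "g2")
        assert part.members(2) == ("g3", "g4", "g5")

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            define_cags(self._block_corr(), k=7)

    def test_degenerate_matrix_warns_k2(self):
        genera = [f"g{i}" for i in range(5)]
        mat = np.full((5, 5), 0.3)
        np.fill_diagonal(mat, 1.0)
        corr = pd.DataFrame(mat, index=genera, columns=genera)
        with pytest.warns(UserWarning, match="degenerate"):
            part = define_cags(corr)
        assert part.k == 2

    def test_permutation_invariance(self, medium_cohort):
        _, rel, _, truth = medium_cohort
        genera = [g for ms in truth.blocks.values() for g in ms]
        corr = correlation_matrix(rel, genus_subset=genera)
        part1 = define_cags(corr, k=7)
        order = list(corr.index[::-1])
        part2 = define_cags(corr.loc[order, order], k=7)
        lab1 = [part1.assignments[g] for g in genera]
        lab2 = [part2.assignments[g] for g in genera]
        assert adjusted_rand_score(lab1, lab2) == pytest.approx(1.0)

    def test_silhouette_scan_recovers_planted_blocks(self):
        cfg = default_config()
        cfg.n_per_cell = 23  # 207 samples
        table, _, truth = generate_cohort(cfg, seed=42)
        rel = to_relative(table)
        genera = [g for ms in truth.blocks.values() for g in ms]
        part = define_cags(correlation_matrix(rel, genus_subset=genera))
        true_labels = {
            g: i for i, ms in enumerate(truth.blocks.values()) for g in ms
        }
        ari = adjusted_rand_score(
            [true_labels[g] for g in genera], [part.assignments[g] for g in genera]
        )
        assert part.k == 7
        assert ari >= 0.9

    def test_contiguous_ids_enforced(self):
        with pytest.raises(ValidationError):
            CAGPartition(
                assignments={"a": 1, "b": 3},
                correlation_method="spearman",
                linkage="average",
                distance="1 - r",
                k=2,
            )


class TestCagAbundance:
    def _partition(self):
        return CAGPartition(
            assignments={"g1": 1, "g2": 1, "g3": 2},
            correlation_method="spearman",
            linkage="average",
            distance="1 - r",
            k=2,
        )

    def test_additivity(self):
        df = pd.DataFrame([[0.2, 0.3, 0.5]], index=["s1"], columns=["g1", "g2", "g3"])
        prof = cag_abundance(GenusAbundanceTable(df, "relative"), self._partition())
        assert prof.loc["s1", "CAG1"] == pytest.approx(0.5)
        assert prof.loc["s1", "CAG2"] == pytest.approx(0.5)

    def test_all_in_one_cag_conserves_mass(self, rng):
        rel = to_relative(random_count_table(rng, n_genera=4))
        part = CAGPartition(
            assignments={g: 1 for g in rel.genus_names},
            correlation_method="spearman",
            linkage="average",
            distance="1 - r",
            k=1,
        )
        prof = cag_abundance(rel, part)
        np.testing.assert_allclose(prof["CAG1"], 1.0, atol=1e-9)

    def test_mass_conservation_exact(self, medium_cohort):
        _, rel, _, truth = medium_cohort
        genera = [g for ms in truth.blocks.values() for g in ms]
        part = define_cags(correlation_matrix(rel, genus_subset=genera), k=7)
        prof = cag_abundance(rel, part)
        np.testing.assert_allclose(
            prof.sum(axis=1).to_numpy(),
            rel.data[genera].sum(axis=1).to_numpy(),
            atol=1e-12,
        )

    def test_missing_genus_rejected(self):
        df = pd.DataFrame([[1.0]], index=["s1"], columns=["g1"])
        with pytest.raises(ValidationError):
            cag_abundance(GenusAbundanceTable(df, "relative"), self._partition())


class TestCompareCagAbundance:
    def test_planted_blocks_flagged_with_direction(self, medium_cohort):
        _, rel, meta, truth = medium_cohort
        genera = [g for ms in truth.blocks.values() for g in ms]
        part = define_cags(correlation_matrix(rel, genus_subset=genera), k=7)
        prof = cag_abundance(rel, part)
        res = compare_cag_abundance(prof, meta, comparisons=[("normal", "cancer")])
        # map planted blocks to CAG columns via majority membership
        cag_of = {}
        for name, members in truth.blocks.items():
            ids = [part.assignments[g] for g in members]
            cag_of[name] = f"CAG{max(set(ids), key=ids.count)}"
        by_cag = {r.genus: r for r in res}
        assert by_cag[cag_of["pathogen"]].significant
        assert by_cag[cag_of["pathogen"]].direction == "up_in_second"
        assert by_cag[cag_of["butyrate"]].significant
        assert by_cag[cag_of["butyrate"]].direction == "down_in_second"

    def test_null_false_positive_rate(self):
        flags = trials = 0
        for seed in range(20):
            cfg = default_config()
            cfg.n_per_cell = 10
            cfg.group_effects = {}
            cfg.stage_effects = {}
            table, meta, truth = generate_cohort(cfg, seed=500 + seed)
            rel = to_relative(table)
            genera = [g for ms in truth.blocks.values() for g in ms]
            part = define_cags(correlation_matrix(rel, genus_subset=genera), k=7)
            prof = cag_abundance(rel, part)
            res = compare_cag_abundance(prof, meta, comparisons=[("normal", "cancer")])
            flags += sum(r.significant for r in res)
            trials += len(res)
        assert flags / trials <= 0.03


def _planted_selection_cfg(seed):
    cfg = default_config()
    cfg.enterotype_profiles = {}  # flat: no dominant-genus closure effects
    cfg.n_per_cell = 20
    cfg.block_group_loadings = {
        "pathogen": {"adenoma": 0.0},
        "butyrate": {"adenoma": 0.0},
    }
    cfg.anchor_trackers = {
        g: {"adenoma": 0.9} for g in cfg.blocks["pathogen"] + cfg.blocks["butyrate"]
    }
    cfg.seed = seed
    return cfg


class TestSelectTrainingCombination:
    COMBOS = [
        ("normal", "cancer"),
        ("normal", "adenoma"),
        ("adenoma", "cancer"),
        ("normal", "adenoma", "cancer"),
    ]

    def test_single_combination_trivial_winner(self, medium_cohort):
        _, rel, meta, _ = medium_cohort
        ranking, winner = select_training_combination(
            rel, meta, [("normal", "cancer")]
        )
        assert len(ranking) == 1
        assert winner.source_groups == ("normal", "cancer")

    def test_empty_combination_list_rejected(self, medium_cohort):
        _, rel, meta, _ = medium_cohort
        with pytest.raises(ValidationError):
            select_training_combination(rel, meta, [])

    def test_planted_design_nc_beats_na(self):
        # the combination with intact block structure in both its groups
        # dominates the one whose second group has corrupted structure
        wins = 0
        n_seeds = 15
        for seed in range(n_seeds):
            cfg = _planted_selection_cfg(seed)
            table, meta, _ = generate_cohort(cfg, seed=seed)
            rel = to_relative(table)
            ranking, _ = select_training_combination(rel, meta, self.COMBOS)
            scores = dict(zip(ranking["combination"], ranking["score"]))
            wins += scores["normal+cancer"] > scores["normal+adenoma"]
        assert wins >= 0.8 * n_seeds

    def test_null_cohort_scores_near_chance(self):
        # flat profiles: with dominant-genus regimes the high-variance
        # enterotype CAGs amplify the LOO nearest-centroid's negative bias
        cfg = default_config()
        cfg.enterotype_profiles = {}
        cfg.n_per_cell = 20
        cfg.group_effects = {}
        cfg.stage_effects = {}
        table, meta, _ = generate_cohort(cfg, seed=77)
        rel = to_relative(table)
        ranking, _ = select_training_combination(rel, meta, self.COMBOS)
        assert ((ranking["score"] - 0.5).abs() <= 0.12).all()

    def test_deterministic_tie_break_order(self, medium_cohort):
        _, rel, meta, _ = medium_cohort
        r1, _ = select_training_combination(rel, meta, self.COMBOS, k=5)
        r2, _ = select_training_combination(rel, meta, self.COMBOS, k=5)
        assert list(r1["combination"]) == list(r2["combination"])
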