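import numpy as np
import pandas as pd
import pytest

from enterocag.abundance_io import GenusAbundanceTable, ValidationError, to_relative
from enterocag.cag import CAGPartition, correlation_matrix, define_cags
from enterocag.network import (
    anchor_correlation_profile,
    find_stable_cag,
    network_to_edgelist,
    pearson_network,
    variable_genera,
)
from enterocag.synthetic import default_config, generate_cohort


def _part(clusters, **kwargs):
    assignments = {}
    for cid, members in enumerate(clusters, start=1):
        for g in members:
            assignments[g] = cid
    return CAGPartition(
        assignments=assignments,
        correlation_method="spearman",
        linkage="average",
        distance="1 - r",
        k=len(clusters),
        **kwargs,
    )


class TestPearsonNetwork:
    def test_duplicated_genus_edge(self, rng):
        base = rng.random(20)
        df = pd.DataFrame(
            {"g1": base, "g2": base, "g3": rng.random(20)},
            index=[f"s{i}" for i in range(20)],
        )
        net = pearson_network(GenusAbundanceTable(df, "counts"))
        assert net.has_edge("g1", "g2")
        assert net["g1"]["g2"]["r"] == pytest.approx(1.0)

    def test_zero_threshold_complete_graph(self, rng):
        df = pd.DataFrame(
            rng.random((10, 4)) + 0.01,
            index=[f"s{i}" for i in range(10)],
            columns=list("abcd"),
        )
        net = pearson_network(GenusAbundanceTable(df, "counts"), edge_threshold=0.0)
        assert net.number_of_edges() == 6

    def test_independent_noise_rarely_connected(self):
        # n=100 independent genera: no |r| >= 0.5 edge in >= 95% of seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                rng.random((100, 8)) + 0.01,
                index=[f"s{i}" for i in range(100)],
                columns=[f"g{j}" for j in range(8)],
            )
            net = pearson_network(GenusAbundanceTable(df, "counts"))
            hits += net.number_of_edges() == 0
        assert hits >= 0.95 * n_seeds

    def test_constant_genus_excluded_with_warning(self, rng):
        df = pd.DataFrame(
            {"g1": rng.random(10), "g2": rng.random(10), "g3": np.ones(10)},
            index=[f"s{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning, match="constant"):
            net = pearson_network(GenusAbundanceTable(df, "counts"))
        assert "g3" not in net.nodes

    def test_edgelist_columns(self, rng):
        base = rng.random(15)
        df = pd.DataFrame(
            {"g1": base, "g2": base + rng.normal(0, 0.01, 15)},
            index=[f"s{i}" for i in range(15)],
        )
        net = pearson_network(GenusAbundanceTable(df, "counts"), group="cancer")
        frame = network_to_edgelist(net)
        assert list(frame.columns) == ["genus_a", "genus_b", "r", "group", "stratum"]
        assert (frame["group"] == "cancer").all()


class TestFindStableCag:
    def test_identical_partitions_return_largest(self):
        p = _part([("a", "b", "c"), ("d", "e")])
        assert find_stable_cag([p, p]) == ("a", "b", "c")

    def test_shared_block_only(self):
        block = ("p", "q", "r", "s", "t", "u", "v", "w", "x", "y")
        p1 = _part([block, ("a", "b"), ("c", "d")])
        p2 = _part([block, ("a", "c"), ("b", "d")])
        p3 = _part([("a", "d"), block, ("b", "c")])
        assert find_stable_cag([p1, p2, p3]) == tuple(sorted(block))

    def test_no_repeated_cluster(self):
        p1 = _part([("a", "b"), ("c", "d")])
        p2 = _part([("a", "c"), ("b", "d")])
        assert find_stable_cag([p1, p2]) == ()

    def test_order_invariance(self):
        block = ("p", "q", "r")
        p1 = _part([block, ("a", "b")])
        p2 = _part([("a",), block, ("b",)])
        assert find_stable_cag([p1, p2]) == find_stable_cag([p2, p1])

    def test_disjoint_universes_rejected(self):
        p1 = _part([("a", "b")])
        p2 = _part([("c", "d")])
        with pytest.raises(ValidationError):
            find_stable_cag([p1, p2])

    def test_relaxed_mode_accepts_jaccard_match(self):
        ten = tuple("abcdefghij")
        nine_plus = tuple("abcdefghik")  # Jaccard 9/11 = 0.818
        p1 = _part([ten, ("x", "y"), ("k",)])
        p2 = _part([nine_plus, ("x", "j"), ("y",)])
        assert find_stable_cag([p1, p2]) == ()
        assert find_stable_cag([p1, p2], relaxed=True) == tuple(sorted(ten))

    def test_planted_anchor_recovered_per_group(self):
        cfg = default_config()
        cfg.n_per_cell = 40  # 120 per group
        table, meta, truth = generate_cohort(cfg, seed=13)
        rel = to_relative(table)
        genera = [g for ms in truth.blocks.values() for g in ms]
        parts = [
            define_cags(
                correlation_matrix(rel, meta.samples_in_group(g), genera),
                source_groups=(g,),
            )
            for g in ("normal", "adenoma", "cancer")
        ]
        assert find_stable_cag(parts) == tuple(sorted(truth.blocks["anchor"]))


def _switch_cohort(seed):
    """Flat-profile cohort with one genus tracking the anchor factor only in
    the normal group."""
    cfg = default_config()
    cfg.enterotype_profiles = {}
    cfg.n_per_cell = 34  # ~100 per group
    cfg.block_loadings = dict(cfg.block_loadings)
    cfg.block_loadings["anchor"] = 0.9
    cfg.genus_noise_sd = {g: 0.5 for g in cfg.blocks["anchor"]}
    cfg.genus_noise_sd["Citrobacter"] = 0.5
    cfg.anchor_trackers = {"Citrobacter": {"normal": 0.9}}
    table, meta, truth = generate_cohort(cfg, seed=seed)
    return to_relative(table), meta, cfg


class TestAnchorCorrelationProfile:
    def test_single_member_anchor_self_correlation(self, rng):
        base = rng.random(30)
        df = pd.DataFrame(
            {"anchor1": base, "probe": base},
            index=[f"s{i}" for i in range(30)],
        )
        stages = ["normal"] * 10 + ["advanced_adenoma"] * 10 + ["crc_early"] * 10
        from enterocag.abundance_io import CohortMetadata

        meta = CohortMetadata(pd.DataFrame({"stage6": stages}, index=df.index))
        prof = anchor_correlation_profile(
            GenusAbundanceTable(df, "counts"), meta, ["anchor1"], "probe"
        )
        for v in prof.values():
            assert v == pytest.approx(1.0)

    def test_genus_in_anchor_rejected(self, medium_cohort):
        _, rel, meta, truth = medium_cohort
        anchor = truth.blocks["anchor"]
        with pytest.raises(ValidationError):
            anchor_correlation_profile(rel, meta, anchor, anchor[0])

    def test_independent_genus_near_zero(self):
        rel, meta, cfg = _switch_cohort(seed=3)
        prof = anchor_correlation_profile(rel, meta, cfg.blocks["anchor"], "Sutterella")
        for v in prof.values():
            assert abs(v) <= 0.2

    def test_planted_switch_profile_recovered(self):
        rel, meta, cfg = _switch_cohort(seed=9)
        prof = anchor_correlation_profile(rel, meta, cfg.blocks["anchor"], "Citrobacter")
        assert prof["normal"] == pytest.approx(0.8, abs=0.15)
        assert abs(prof["cancer"]) <= 0.15

    def test_affine_invariance(self):
        rel, meta, cfg = _switch_cohort(seed=4)
        anchor = cfg.blocks["anchor"]
        prof1 = anchor_correlation_profile(rel, meta, anchor, "Dorea")
        shifted = rel.data.copy()
        shifted["Dorea"] = shifted["Dorea"] * 3.5 + 0.2
        t2 = GenusAbundanceTable(shifted, "counts")
        prof2 = anchor_correlation_profile(t2, meta, anchor, "Dorea")
        for g in prof1:
            assert prof1[g] == pytest.approx(prof2[g], abs=1e-9)


class TestVariableGenera:
    def test_rule_application(self):
        profiles = pd.DataFrame(
            {"normal": [0.8, 0.5], "adenoma": [0.5, 0.45], "cancer": [0.0, 0.55]},
            index=["switchy", "steady"],
        )
        out = variable_genera(profiles)
        flags = dict(zip(out["genus"], out["flagged"]))
        assert flags["switchy"] and not flags["steady"]
        assert list(out["genus"]) == ["switchy", "steady"]  # sorted by score

    def test_empty_input(self):
        out = variable_genera(pd.DataFrame())
        assert len(out) == 0

    def test_single_defined_group_skipped(self):
        profiles = pd.DataFrame(
            {"normal": [0.9], "adenoma": [np.nan], "cancer": [np.nan]},
            index=["lonely"],
        )
        assert len(variable_genera(profiles)) == 0

    def test_planted_switch_flagged_independents_not(self):
        hits_switch = hits_indep = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rel, meta, cfg = _switch_cohort(seed=seed)
            anchor = cfg.blocks["anchor"]
            profs = {
                g: anchor_correlation_profile(rel, meta, anchor, g)
                for g in ("Citrobacter", "Sutterella", "Dorea")
            }
            out = variable_genera(pd.DataFrame(profs).T)
            flags = dict(zip(out["genus"], out["flagged"]))
            hits_switch += flags.get("Citrobacter", False)
            hits_indep += not flags.get("Sutterella", False) and not flags.get(
                "Dorea", False
            )
        assert hits_switch >= 0.9 * n_seeds
        assert hits_indep >= 0.9 * n_seeds
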