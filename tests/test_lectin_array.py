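import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from glycoserum import io, lectin_array, synthetic
from tests.conftest import make_spot_frame


class TestFilterEffectiveSpots:
    def test_background_cutoff(self, single_block):
        # backgrounds {85, 90, 95}: mean 90, sample SD 5, cutoff 100
        effective, rejected = lectin_array.filter_effective_spots(single_block)
        assert set(effective) == {"B", "C"}
        assert effective["B"] == pytest.approx([10.0])
        assert effective["C"] == pytest.approx([210.0])
        assert list(rejected["probe"]) == ["A"]
        assert rejected["cutoff"].iloc[0] == pytest.approx(100.0)

    def test_all_rejected(self):
        block = make_spot_frame([("s1", "b1", p, 1, 10.0, bg)
                                 for p, bg in [("A", 85.0), ("B", 90.0), ("C", 95.0)]])
        effective, rejected = lectin_array.filter_effective_spots(block)
        assert effective == {}
        assert len(rejected) == 3

    def test_zero_background_keeps_everything(self):
        block = make_spot_frame([("s1", "b1", "A", r, fg, 0.0)
                                 for r, fg in [(1, 5.0), (2, 50.0), (3, 500.0)]])
        effective, rejected = lectin_array.filter_effective_spots(block)
        assert rejected.empty
        assert effective["A"] == pytest.approx([5.0, 50.0, 500.0])

    def test_empty_block_rejected(self):
        with pytest.raises(io.ValidationError):
            lectin_array.filter_effective_spots(make_spot_frame([]).iloc[:0])

    @pytest.mark.parametrize("spread", [1.0, 2.0, 5.0])
    def test_widening_background_never_adds_spots(self, rng, spread):
        base = rng.uniform(50, 150, 30)
        fg = rng.uniform(100, 400, 30)
        kept = []
        for s in (1.0, spread):
            bg = 100 + (base - 100) * s  # same mean, scaled SD
            block = make_spot_frame([("s1", "b1", f"L{i}", 1, fg[i], bg[i])
                                     for i in range(30)])
            eff, _ = lectin_array.filter_effective_spots(block)
            kept.append(sum(len(v) for v in eff.values()))
        assert kept[1] <= kept[0]


class TestNormalizeBlock:
    def test_single_lectin_is_identity(self):
        prof = lectin_array.normalize_block({"A": np.array([123.0])}, "b1")
        assert prof.nfi == {"A": 1.0}

    def test_two_lectin_medians(self):
        prof = lectin_array.normalize_block(
            {"A": np.array([30.0]), "B": np.array([70.0])}, "b1")
        assert prof.nfi["A"] == pytest.approx(0.3)
        assert prof.nfi["B"] == pytest.approx(0.7)

    def test_median_of_multiple_spots(self):
        prof = lectin_array.normalize_block(
            {"A": np.array([10.0, 20.0, 30.0]), "B": np.array([80.0])}, "b1")
        assert prof.nfi == pytest.approx({"A": 0.2, "B": 0.8})

    def test_controls_excluded_from_denominator(self):
        prof = lectin_array.normalize_block(
            {"A": np.array([30.0]), "B": np.array([70.0]), "BSA": np.array([900.0])})
        assert prof.nfi == pytest.approx({"A": 0.3, "B": 0.7})

    def test_degenerate_block(self):
        with pytest.raises(io.DegenerateBlockError):
            lectin_array.normalize_block({"A": np.array([0.0])}, "b1")

    def test_nfi_sums_to_one_on_synthetic(self):
        spots, _, _ = synthetic.simulate_lectin_arrays(synthetic.SimulationConfig(seed=7))
        table = lectin_array.nfi_table(spots)
        sums = table.groupby(["sample_id", "block_id"])["nfi"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_scale_invariance(self):
        spots, _, _ = synthetic.simulate_lectin_arrays(
            synthetic.SimulationConfig(seed=3, n_subgroups_per_group=1, blocks_per_sample=2))
        scaled = spots.copy()
        scaled[["foreground", "background"]] *= 7.5
        a = lectin_array.nfi_table(spots)
        b = lectin_array.nfi_table(scaled)
        assert np.allclose(a["nfi"], b["nfi"], rtol=1e-12)

    def test_vectorized_path_matches_per_block_path(self, rng):
        spots, _, _ = synthetic.simulate_lectin_arrays(
            synthetic.SimulationConfig(seed=11, n_subgroups_per_group=1,
                                       blocks_per_sample=2, n_lectins=6))
        table = lectin_array.nfi_table(spots)
        for (s, b), block in spots.groupby(["sample_id", "block_id"]):
            eff, _ = lectin_array.filter_effective_spots(block)
            prof = lectin_array.normalize_block(eff, b)
            sub = table[(table.sample_id == s) & (table.block_id == b)]
            assert dict(zip(sub["probe"], sub["nfi"])) == pytest.approx(prof.nfi)


class TestAggregateSample:
    def test_identical_blocks(self):
        blocks = [lectin_array.BlockNFIProfile(f"b{i}", {"A": 0.25, "B": 0.75})
                  for i in range(9)]
        prof = lectin_array.aggregate_sample(blocks, "s1")
        assert prof.n_blocks == 9
        assert prof.mean_nfi == pytest.approx({"A": 0.25, "B": 0.75})
        assert prof.sd_nfi == pytest.approx({"A": 0.0, "B": 0.0})

    def test_two_block_mean_and_sd(self):
        blocks = [lectin_array.BlockNFIProfile("b1", {"A": 0.2}),
                  lectin_array.BlockNFIProfile("b2", {"A": 0.4})]
        prof = lectin_array.aggregate_sample(blocks)
        assert prof.mean_nfi["A"] == pytest.approx(0.3)
        # sample SD convention (ddof=1)
        assert prof.sd_nfi["A"] == pytest.approx(np.sqrt(0.02))

    def test_partial_coverage(self):
        blocks = [lectin_array.BlockNFIProfile(f"b{i}", {"A": 0.5, "B": 0.5})
                  for i in range(6)]
        blocks += [lectin_array.BlockNFIProfile(f"b{i+6}", {"A": 0.5, "B": 0.3, "C": 0.2})
                   for i in range(3)]
        prof = lectin_array.aggregate_sample(blocks)
        assert prof.n_blocks == 9
        assert prof.coverage["C"] == 3
        assert prof.mean_nfi["C"] == pytest.approx(0.2)


def make_profiles(case_over_control: dict, n_pairs=5, noise=0.0, seed=0):
    """Build NFI matrices with exact group means per lectin."""
    rng = np.random.default_rng(seed)
    lectins = list(case_over_control)
    rows, meta = [], []
    for g, scale in (("TD", False), ("ASD", True)):
        for k in range(1, n_pairs + 1):
            base = {l: (v[1] if scale else v[0]) for l, v in case_over_control.items()}
            jitter = rng.normal(0, noise, len(lectins))
            rows.append({l: base[l] + jitter[i] for i, l in enumerate(lectins)})
            meta.append({"sample_id": f"{g}-{k}", "group": g, "subgroup_index": k})
    return (pd.DataFrame(rows, index=[m["sample_id"] for m in meta]),
            pd.DataFrame(meta))


class TestDifferentialLectins:
    def test_planted_up_and_down(self):
        nfi, meta = make_profiles({"MALII": (0.1, 0.333), "STL": (0.2, 0.108),
                                   "flat": (0.3, 0.3)}, noise=0.002, seed=1)
        out = lectin_array.differential_lectins(nfi, meta).set_index("lectin")
        assert out.loc["MALII", "fold_change"] == pytest.approx(3.33, rel=0.05)
        assert out.loc["MALII", "direction"] == "up"
        assert out.loc["STL", "direction"] == "down"
        assert out.loc["flat", "direction"] == "unchanged"

    def test_identical_groups_unchanged(self):
        nfi, meta = make_profiles({"A": (0.4, 0.4), "B": (0.6, 0.6)})
        out = lectin_array.differential_lectins(nfi, meta)
        assert (out["fold_change"] == 1.0).all()
        assert (out["direction"] == "unchanged").all()

    def test_control_mean_zero_flagged_infinite(self):
        nfi, meta = make_profiles({"A": (0.0, 0.5), "B": (1.0, 0.5)})
        out = lectin_array.differential_lectins(nfi, meta).set_index("lectin")
        assert np.isinf(out.loc["A", "fold_change"])
        assert out.loc["A", "control_mean_zero"]

    def test_insufficient_pairs(self):
        nfi, meta = make_profiles({"A": (0.5, 0.5)}, n_pairs=1)
        with pytest.raises(io.InsufficientReplicatesError):
            lectin_array.differential_lectins(nfi, meta)

    def test_bh_option_adds_q_values(self):
        nfi, meta = make_profiles({f"L{i}": (0.1, 0.1) for i in range(5)}, noise=0.01)
        out = lectin_array.differential_lectins(nfi, meta, bh_correct=True)
        assert "q_value" in out.columns
        assert (out["q_value"].fillna(1) >= out["p_value"].fillna(1) - 1e-12).all()


def cophenetic_from_dendrogram(dend):
    """Pairwise cophenetic distances implied by the merge list."""
    n = len(dend.labels)
    members = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    for i, j, h, new in dend.merges:
        for a in members[i]:
            for b in members[j]:
                coph[a, b] = coph[b, a] = h
        members[new] = members.pop(i) | members.pop(j)
    return coph


class TestHierarchicalCluster:
    def test_identical_profiles_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], index=["a", "b"])
        dend = lectin_array.hierarchical_cluster(m)
        assert dend.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_merges_first(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [1.1, 2.1, 3.1], [3.0, 2.0, 1.0]],
                         index=["a", "b", "c"])
        dend = lectin_array.hierarchical_cluster(m)
        assert set(dend.merges[0][:2]) == {0, 1}

    def test_matches_scipy_average_linkage(self, rng):
        x = rng.normal(size=(6, 8))
        m = pd.DataFrame(x, index=[f"s{i}" for i in range(6)])
        dend = lectin_array.hierarchical_cluster(m)
        link = hierarchy.linkage(x, method="average", metric="correlation")
        coph = cophenetic_from_dendrogram(dend)
        iu = np.triu_indices(6, 1)
        expected = hierarchy.cophenet(link)
        got = coph[iu]
        # scipy condensed order matches triu order
        assert np.allclose(np.sort(got), np.sort(expected), atol=1e-10)
        assert np.allclose(got, expected, atol=1e-10)

    def test_newick_is_well_formed(self):
        from io import StringIO
        from Bio import Phylo
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)),
                         index=[f"s{i}" for i in range(5)])
        nwk = lectin_array.hierarchical_cluster(m).to_newick()
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(m.index)

    def test_constant_profile_warns(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        with pytest.warns(UserWarning, match="constant"):
            lectin_array.hierarchical_cluster(m)
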