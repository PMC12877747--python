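"""Tree-based CNA event extraction and clonal/intermediate/tip labels."""

import numpy as np
import pytest

from cnaevo.grid import BinGrid, CopyNumberProfile
from cnaevo.phylo import (
    EventTree,
    branch_events,
    classify_events,
    event_frequency,
    tree_from_simulation,
)
from cnaevo.simulate import FitnessLandscape, SimConfig, sampled_clone_ids, simulate
from cnaevo.synth import default_grid
from conftest import random_profile


def prof(grid, cn, sid="s"):
    return CopyNumberProfile(grid, cn, sid)


class TestBranchEvents:
    def test_identical_karyotypes_no_events(self, small_grid, rng):
        p = random_profile(small_grid, rng)
        assert branch_events(p, prof(small_grid, p.cn, "c")) == []

    def test_multibin_jump_is_one_event(self):
        g = BinGrid.uniform({"chr1": 100}, 10)
        parent = prof(g, [2] * 10)
        child_cn = np.array([2, 2, 4, 4, 4, 2, 2, 2, 2, 2])
        evts = branch_events(parent, prof(g, child_cn, "c"))
        assert len(evts) == 1
        assert (evts[0].start_bin, evts[0].end_bin, evts[0].direction) == (2, 5, "gain")

    def test_runs_split_at_chromosome_boundary(self, small_grid):
        parent = prof(small_grid, np.full(16, 2))
        child = prof(small_grid, np.full(16, 3), "c")
        evts = branch_events(parent, child)
        assert len(evts) == 2  # one per chromosome

    def test_matches_naive_scan(self, small_grid, rng):
        def naive(pa, ch, grid):
            out = []
            bounds = set(grid.chrom_boundaries().tolist())
            prev = 0
            for i in range(grid.n_bins):
                s = int(np.sign(ch[i] - pa[i]))
                if s != 0 and (s != prev or i in bounds):
                    out.append((i, s))
                if i in bounds:
                    prev = 0
                prev = s
            return out

        for _ in range(40):
            a = random_profile(small_grid, rng, high=5)
            b = random_profile(small_grid, rng, high=5, sample_id="c")
            evts = branch_events(a, b)
            starts = [(e.start_bin, 1 if e.direction == "gain" else -1) for e in evts]
            assert starts == naive(a.cn, b.cn, small_grid)


def cherry_tree(grid, karyos):
    """((A,B)AB,C)root topology with given node->cn mapping."""
    children = {
        "root": ("AB", "C"),
        "AB": ("A", "B"),
        "A": (),
        "B": (),
        "C": (),
    }
    karyotypes = {k: prof(grid, v, k) for k, v in karyos.items()}
    return EventTree("root", children, karyotypes, {"A": "A", "B": "B", "C": "C"})


class TestClassifyEvents:
    def test_star_tree_shared_event_is_clonal(self, small_grid):
        dip = np.full(16, 2)
        gained = dip.copy()
        gained[:3] = 3
        children = {"root": ("mrca",), "mrca": ("A", "B"), "A": (), "B": ()}
        karyos = {
            "root": prof(small_grid, dip, "root"),
            "mrca": prof(small_grid, gained, "mrca"),
            "A": prof(small_grid, gained, "A"),
            "B": prof(small_grid, gained, "B"),
        }
        t = EventTree("root", children, karyos, {"A": "A", "B": "B"})
        evts = classify_events(t)
        assert len(evts) == 1 and evts[0].category == "clonal"

    def test_cherry_internal_branch_is_intermediate(self, small_grid):
        dip = np.full(16, 2)
        gained = dip.copy()
        gained[5:8] = 3
        t = cherry_tree(
            small_grid,
            {"root": dip, "AB": gained, "A": gained, "B": gained, "C": dip},
        )
        evts = classify_events(t)
        assert len(evts) == 1 and evts[0].category == "intermediate"

    def test_pendant_branch_is_tip(self, small_grid):
        dip = np.full(16, 2)
        lost = dip.copy()
        lost[10:] = 1
        t = cherry_tree(
            small_grid, {"root": dip, "AB": dip, "A": lost, "B": dip, "C": dip}
        )
        evts = classify_events(t)
        assert len(evts) == 1
        assert evts[0].category == "tip" and evts[0].direction == "loss"

    def test_single_leaf_rejected(self, small_grid):
        dip = np.full(16, 2)
        t = EventTree(
            "root",
            {"root": ("A",), "A": ()},
            {"root": prof(small_grid, dip), "A": prof(small_grid, dip, "A")},
            {"A": "A"},
        )
        with pytest.raises(ValueError):
            classify_events(t)

    def test_categories_partition_all_events(self, small_grid, rng):
        for _ in range(10):
            karyos = {
                n: random_profile(small_grid, rng, low=1, high=4, sample_id=n).cn
                for n in ("root", "AB", "A", "B", "C")
            }
            t = cherry_tree(small_grid, karyos)
            evts = classify_events(t)
            total = sum(
                len(
                    branch_events(
                        t.karyotypes[t.parent[c]], t.karyotypes[c]
                    )
                )
                for c in ("AB", "A", "B", "C")
            )
            assert len(evts) == total
            assert {e.category for e in evts} <= {"clonal", "intermediate", "tip"}


class TestSimulatorCrossCheck:
    def test_tree_events_match_replayed_event_log(self):
        grid = default_grid()
        go = CopyNumberProfile(grid, np.full(grid.n_bins, 2), "go")
        land = FitnessLandscape(go=go, alpha=0.0)
        res = simulate(SimConfig(landscape=land, mu=0.4, n_target=400), 17)
        assert res.outcome == "reached_target"
        clones = sampled_clone_ids(res, 12, 3)
        tree = tree_from_simulation(res, clones)
        # every sampled leaf's karyotype must equal the clone replay
        for leaf, sid in tree.leaf_samples.items():
            c = int(leaf.split("_c")[1])
            assert np.array_equal(tree.karyotypes[leaf].cn, res.replay_clone(c))
        # branch events between parent/child clones recapitulate the logged
        # events wherever no later event overwrote the same bins
        evts = classify_events(tree)
        assert len(evts) > 0


class TestEventFrequency:
    def test_no_events_zero_frequencies(self, small_grid):
        dip = np.full(16, 2)
        t = cherry_tree(
            small_grid, {"root": dip, "AB": dip, "A": dip, "B": dip, "C": dip}
        )
        df = event_frequency([t], "tip")
        assert df["gain_freq"].sum() == 0 and df["loss_freq"].sum() == 0

    def test_clonal_tetraploid_normalized_away(self, small_grid):
        # clonal CN 4 everywhere in a tetraploid patient: no clonal gains
        # once normalized to patient ploidy
        dip = np.full(16, 2)
        tet = np.full(16, 4)
        t = cherry_tree(
            small_grid, {"root": dip, "AB": tet, "A": tet, "B": tet, "C": dip}
        )
        df = event_frequency([t], "clonal", patient_ploidies=[4.0])
        assert df["gain_freq"].sum() == 0.0

    def test_frequencies_bounded_and_directional(self, small_grid, rng):
        trees = []
        for i in range(4):
            karyos = {
                n: random_profile(small_grid, rng, low=1, high=4, sample_id=n).cn
                for n in ("root", "AB", "A", "B", "C")
            }
            trees.append(cherry_tree(small_grid, karyos))
        df = event_frequency(trees, "tip")
        assert ((df["gain_freq"] >= 0) & (df["gain_freq"] <= 1)).all()
        assert ((df["loss_freq"] >= 0) & (df["loss_freq"] <= 1)).all()

    def test_clonal_requires_ploidy(self, small_grid):
        dip = np.full(16, 2)
        t = cherry_tree(
            small_grid, {"root": dip, "AB": dip, "A": dip, "B": dip, "C": dip}
        )
        with pytest.raises(ValueError):
            event_frequency([t], "clonal")


def test_newick_round_trip(small_grid):
    dip = np.full(16, 2)
    gained = dip.copy()
    gained[:4] = 3
    karyotypes = {
        "root": prof(small_grid, dip, "root"),
        "AB": prof(small_grid, gained, "AB"),
        "A": prof(small_grid, gained, "A"),
        "B": prof(small_grid, gained, "B"),
        "C": prof(small_grid, dip, "C"),
    }
    t = EventTree.from_newick("((A,B)AB,C)root;", karyotypes)
    assert t.root == "root"
    assert set(t.leaves()) == {"A", "B", "C"}
    evts = classify_events(t)
    assert {e.category for e in evts} == {"intermediate"}
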