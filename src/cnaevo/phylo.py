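"""Phylogenetic classification of copy-number events.

A rooted tree whose nodes carry karyotypes (e.g. observed leaves plus
ancestral states reconstructed by MEDICC2, or a simulated clone genealogy)
is scanned branch by branch: each maximal contiguous run of bins in which
the child differs from its parent in the same direction is one event
(counted once regardless of the magnitude of the copy-number change).

Events are placed into three tree-positional categories relative to the
most recent common ancestor (MRCA) of the tumor-sample leaves:

* clonal -- events on the root-to-MRCA path (shared by every sample);
* intermediate -- events on internal branches below the MRCA (shared by
  some but not all samples);
* tip -- events on pendant branches (private to one sample).

For cross-patient clonal frequencies, gains and losses are defined
relative to the rounded patient ploidy rather than the diploid root, so a
tetraploid tumor is not scored as having gained the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .grid import CopyNumberProfile

__all__ = [
    "EventTree",
    "CNAEventRecord",
    "branch_events",
    "classify_events",
    "event_frequency",
    "tree_from_simulation",
]


@dataclass(frozen=True)
class CNAEventRecord:
    chrom: str
    start_bin: int
    end_bin: int  # half-open bin-index range
    direction: str  # "gain" | "loss"
    branch: tuple  # (parent node id, child node id)
    category: str | None = None  # clonal | intermediate | tip


@dataclass
class EventTree:
    """Rooted tree with a karyotype at every node.

    ``children`` maps node id -> tuple of child ids; ``karyotypes`` maps
    node id -> CopyNumberProfile on a shared grid; ``leaf_samples`` maps
    leaf node id -> sample id (leaves without an entry, e.g. a normal
    outgroup, are excluded from the MRCA computation).
    """

    root: str
    children: dict
    karyotypes: dict
    leaf_samples: dict

    def __post_init__(self):
        self.parent = {}
        for u, kids in self.children.items():
            for v in kids:
                self.parent[v] = u
        missing = [n for n in self.nodes() if n not in self.karyotypes]
        if missing:
            raise ValueError(f"nodes without karyotypes: {missing[:5]}")

    def nodes(self) -> list:
        out, stack = [], [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children.get(u, ()))
        return out

    def leaves(self) -> list:
        return [n for n in self.nodes() if not self.children.get(n)]

    def path_to_root(self, node: str) -> list:
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def mrca(self, nodes: Sequence[str]) -> str:
        nodes = list(nodes)
        if not nodes:
            raise ValueError("empty node set")
        common = None
        for n in nodes:
            anc = set(self.path_to_root(n))
            common = anc if common is None else common & anc
        # deepest common ancestor = the one with the longest path to root
        return max(common, key=lambda u: len(self.path_to_root(u)))

    @classmethod
    def from_newick(
        cls,
        newick: str,
        karyotypes: dict,
        leaf_samples: dict | None = None,
    ) -> "EventTree":
        """Build from a Newick string with internal node labels and a
        node-label -> CopyNumberProfile mapping."""
        tree = dendropy.Tree.get(data=newick, schema="newick")
        children: dict = {}

        def label(nd):
            return nd.taxon.label if nd.taxon is not None else nd.label

        root = label(tree.seed_node)
        for nd in tree.preorder_node_iter():
            children[label(nd)] = tuple(label(c) for c in nd.child_nodes())
        if leaf_samples is None:
            leaf_samples = {
                label(nd): label(nd) for nd in tree.leaf_node_iter()
            }
        return cls(root, children, karyotypes, leaf_samples)


def branch_events(
    parent: CopyNumberProfile,
    child: CopyNumberProfile,
    branch: tuple = ("parent", "child"),
) -> list:
    """Maximal same-direction runs of changed bins between parent and child
    karyotypes; one event per run, never crossing a chromosome boundary."""
    if parent.grid.n_bins != child.grid.n_bins or parent.grid.chroms != child.grid.chroms:
        raise ValueError("parent and child are on different grids")
    sign = np.sign(child.cn - parent.cn)
    events = []
    grid = parent.grid
    for chrom, sl in grid.chrom_slices().items():
        s = sign[sl]
        i = 0
        n = len(s)
        while i < n:
            if s[i] == 0:
                i += 1
                continue
            j = i
            while j < n and s[j] == s[i]:
                j += 1
            events.append(
                CNAEventRecord(
                    chrom=chrom,
                    start_bin=sl.start + i,
                    end_bin=sl.start + j,
                    direction="gain" if s[i] > 0 else "loss",
                    branch=branch,
                )
            )
            i = j
    return events


def classify_events(tree: EventTree) -> list:
    """All branch events of a tree, labelled clonal / intermediate / tip.

    The MRCA is the most recent common ancestor of the leaves listed in
    ``leaf_samples`` (outgroup leaves excluded).  Requires >= 2 such
    leaves.
    """
    sample_leaves = [n for n in tree.leaves() if n in tree.leaf_samples]
    if len(sample_leaves) < 2:
        raise ValueError("MRCA undefined: need >= 2 sample leaves")
    mrca = tree.mrca(sample_leaves)
    clonal_path = set(tree.path_to_root(mrca))  # nodes from MRCA up to root
    below = set()
    stack = list(tree.children.get(mrca, ()))
    while stack:
        u = stack.pop()
        below.add(u)
        stack.extend(tree.children.get(u, ()))

    out = []
    for child in tree.nodes():
        if child == tree.root:
            continue
        parent = tree.parent[child]
        events = branch_events(
            tree.karyotypes[parent], tree.karyotypes[child], (parent, child)
        )
        if not events:
            continue
        if child in clonal_path:
            cat = "clonal"
        elif child in below:
            cat = "tip" if not tree.children.get(child) else "intermediate"
        else:
            continue  # outgroup lineage
        out.extend(
            CNAEventRecord(e.chrom, e.start_bin, e.end_bin, e.direction, e.branch, cat)
            for e in events
        )
    return out


def _clonal_events_vs_ploidy(tree: EventTree, patient_ploidy: float) -> list:
    """Clonal gains/losses relative to the rounded patient ploidy: runs
    where the MRCA karyotype deviates from round(ploidy)."""
    sample_leaves = [n for n in tree.leaves() if n in tree.leaf_samples]
    mrca = tree.mrca(sample_leaves)
    base = int(np.floor(patient_ploidy + 0.5))  # round half up
    mrca_prof = tree.karyotypes[mrca]
    ref = CopyNumberProfile(
        mrca_prof.grid, np.full(mrca_prof.grid.n_bins, base), "ploidy_ref"
    )
    evts = branch_events(ref, mrca_prof, ("ploidy_ref", mrca))
    return [
        CNAEventRecord(e.chrom, e.start_bin, e.end_bin, e.direction, e.branch, "clonal")
        for e in evts
    ]


def event_frequency(
    trees: Sequence[EventTree],
    category: str,
    patient_ploidies: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-bin gain and loss frequencies across patients for one category.

    The frequency at a bin is the fraction of patients with at least one
    event of that direction overlapping the bin.  For ``clonal``,
    per-patient ploidies are required and events are taken relative to the
    rounded patient ploidy.
    """
    trees = list(trees)
    if category not in ("clonal", "intermediate", "tip"):
        raise ValueError("category must be clonal, intermediate or tip")
    if category == "clonal":
        if patient_ploidies is None:
            raise ValueError("clonal frequencies require patient ploidies")
        per_patient = [
            _clonal_events_vs_ploidy(t, p) for t, p in zip(trees, patient_ploidies)
        ]
    else:
        per_patient = [
            [e for e in classify_events(t) if e.category == category] for t in trees
        ]
    grid = trees[0].karyotypes[trees[0].root].grid
    n = grid.n_bins
    gain = np.zeros(n)
    loss = np.zeros(n)
    for events in per_patient:
        g = np.zeros(n, dtype=bool)
        l = np.zeros(n, dtype=bool)
        for e in events:
            (g if e.direction == "gain" else l)[e.start_bin : e.end_bin] = True
        gain += g
        loss += l
    k = len(trees)
    df = grid.to_frame()
    df["gain_freq"] = gain / k
    df["loss_freq"] = loss / k
    return df


def tree_from_simulation(result, clone_ids: Sequence[int]) -> EventTree:
    """Clone-ancestry tree of a sampled set of simulator clones.

    Builds the induced genealogy of the sampled clones (their ancestor
    clones back to the founder), with each node carrying the clone
    karyotype; duplicate sampled clones become distinct leaves attached to
    their clone node.
    """
    needed = set()
    for c in clone_ids:
        cc = int(c)
        while cc != -1 and cc not in needed:
            needed.add(cc)
            cc = int(result.parents[cc])
    children: dict = {f"c{c}": [] for c in needed}
    for c in sorted(needed):
        p = int(result.parents[c])
        if p != -1:
            children[f"c{p}"].append(f"c{c}")
    karyotypes = {
        f"c{c}": CopyNumberProfile(result.grid, result.clone_cn[c], f"c{c}")
        for c in needed
    }
    leaf_samples = {}
    for i, c in enumerate(clone_ids):
        leaf = f"s{i}_c{int(c)}"
        children[f"c{int(c)}"].append(leaf)
        children[leaf] = []
        karyotypes[leaf] = CopyNumberProfile(
            result.grid, result.clone_cn[int(c)], leaf
        )
        leaf_samples[leaf] = f"gland{i:05d}"
    # founder is the unique clone with parent -1 among needed
    roots = [c for c in needed if int(result.parents[c]) == -1]
    if len(roots) != 1:
        raise ValueError("sampled clones do not share a single founder")
    children = {k: tuple(v) for k, v in children.items()}
    return EventTree(f"c{roots[0]}", children, karyotypes, leaf_samples)
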