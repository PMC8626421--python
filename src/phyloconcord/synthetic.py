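"""Synthetic-data generators with known ground truth.

Every pipeline input — species trees with matched mutation/coalescent
branch lengths, copy-labelled collinear gene trees under independent- or
shared-WGD scenarios, Ks samples from known Gaussian mixtures — can be
generated here, so every analysis stage is testable without any external
dataset.  All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .tree import (
    UNIT_COALESCENT,
    UNIT_MUTATION,
    Node,
    PhyloTree,
    parse_newick,
)
from .wgd import CopyLabeledGeneTree

__all__ = [
    "ScenarioSpec",
    "gen_species_tree",
    "gen_wgd_copy_trees",
    "gen_ks_mixture_sample",
]

SCENARIOS = ("msc", "independent_wgd", "shared_wgd", "ks_mixture")


@dataclass
class ScenarioSpec:
    """Declarative description of a synthetic scenario, echoed as metadata."""

    scenario: str
    n: int
    seed: int
    parameters: dict

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _random_topology(labels: Sequence[str], rng: np.random.Generator) -> Node:
    """Random binary rooted topology by uniform coalescent-style joins."""
    pool = [Node(label=lab) for lab in labels]
    while len(pool) > 1:
        i = int(rng.integers(len(pool)))
        j = int(rng.integers(len(pool) - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        parent = Node()
        parent.add_child(pool[i])
        parent.add_child(pool[j])
        pool[j] = pool[-1]
        pool.pop()
        pool[i] = parent
    return pool[0]


def gen_species_tree(
    n_taxa: int,
    cu_range: tuple[float, float],
    mu_theta: float,
    seed: int = 0,
) -> tuple[PhyloTree, PhyloTree]:
    """A random species tree in both unit systems with a known, constant theta.

    Returns ``(coalescent_tree, mutation_tree)`` sharing one random binary
    topology.  Internal coalescent lengths are uniform on ``cu_range``,
    terminals are 1; the mutation tree's lengths equal ``mu_theta`` times
    the coalescent lengths, so theta estimation must recover ``mu_theta``
    exactly on every internal branch.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    lo, hi = cu_range
    if not (0 <= lo <= hi):
        raise ValueError("cu_range must satisfy 0 <= lo <= hi")
    if mu_theta <= 0:
        raise ValueError("mu_theta must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    root = _random_topology(labels, rng)
    for node in root.postorder():
        if node.parent is None:
            node.length = None
        elif node.is_leaf:
            node.length = 1.0
        else:
            node.length = float(rng.uniform(lo, hi))
    cu_tree = PhyloTree(root, unit_tag=UNIT_COALESCENT)
    mu_root = root.copy()
    for node in mu_root.postorder():
        if node.length is not None:
            node.length = node.length * mu_theta
    mu_tree = PhyloTree(mu_root, unit_tag=UNIT_MUTATION)
    return cu_tree, mu_tree


_WGD_BACKBONES = {
    "independent_wgd": "((A1:1,A2:1):1,(B1:1,B2:1):1);",
    "shared_wgd": "((A1:1,B1:1):1,(A2:1,B2:1):1);",
}


def _nni_once(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    """One random nearest-neighbour interchange on a random internal edge.

    On the rooted representation an internal edge (child ``u`` internal,
    parent ``v``) admits two exchanges: swap one child of ``u`` with the
    subtree across the edge.  One of the available (edge, exchange) moves
    is chosen uniformly.
    """
    out = tree.copy()
    internal_edges = [
        n
        for n in out.root.postorder()
        if n.parent is not None and not n.is_leaf and n.parent.parent is not None
    ]
    # edges incident to a binary root: exchanging across them is equivalent
    # to an exchange at the sibling, so include root children once
    if len(out.root.children) == 2:
        left, right = out.root.children
        if not left.is_leaf:
            internal_edges.append(left)
    if not internal_edges:
        return out
    u = internal_edges[int(rng.integers(len(internal_edges)))]
    v = u.parent
    if v.parent is None:  # root edge: exchange with a child of the sibling
        sib = [c for c in v.children if c is not u][0]
        if sib.is_leaf:
            return out
        across = sib.children[int(rng.integers(len(sib.children)))]
        holder = sib
    else:
        across = [c for c in v.children if c is not u][0]
        holder = v
    child = u.children[int(rng.integers(len(u.children)))]
    ui = u.children.index(child)
    hi = holder.children.index(across)
    u.children[ui], holder.children[hi] = across, child
    across.parent, child.parent = u, holder
    return PhyloTree(out.root, unit_tag=out.unit_tag)


def gen_wgd_copy_trees(
    scenario: str,
    n: int,
    noise: float = 0.0,
    seed: int = 0,
) -> list[CopyLabeledGeneTree]:
    """Copy-labelled 2+2 gene trees under a known WGD scenario.

    ``independent_wgd`` emits ((A1,A2),(B1,B2)) backbones, ``shared_wgd``
    emits ((A1,B1),(A2,B2)); each tree is independently perturbed by one
    random NNI with probability ``noise``.
    """
    if scenario not in _WGD_BACKBONES:
        raise ValueError(f"scenario must be one of {sorted(_WGD_BACKBONES)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    backbone = parse_newick(_WGD_BACKBONES[scenario])
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    trees = []
    for _ in range(n):
        tree = backbone.copy()
        if rng.random() < noise:
            tree = _nni_once(tree, rng)
        trees.append(CopyLabeledGeneTree.from_suffix_labels(tree))
    return trees


def gen_ks_mixture_sample(
    components: Sequence[tuple[float, float, float]],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """i.i.d. draws from a Gaussian mixture of (weight, mean, sd) components.

    Negative draws are rejected and redrawn, keeping the sample a valid
    set of Ks values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    comps = [(float(w), float(m), float(s)) for w, m, s in components]
    if not comps:
        raise ValueError("at least one mixture component required")
    weights = np.array([w for w, _, _ in comps])
    if (weights <= 0).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must be positive and sum to 1")
    if any(s <= 0 for _, _, s in comps):
        raise ValueError("component sds must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    means = np.array([m for _, m, _ in comps])
    sds = np.array([s for _, _, s in comps])
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        which = rng.choice(len(comps), size=m, p=weights)
        draws = rng.normal(means[which], sds[which])
        good = draws[draws >= 0]
        out[filled : filled + good.size] = good
        filled += good.size
    return out
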