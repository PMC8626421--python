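"""Multispecies-coalescent gene-tree simulation.

The species tree carries internal branch lengths in coalescent units;
terminal branches are conventionally set to 1 (with one allele per species
they cannot affect the gene-tree topology).  Within each species-tree
branch of duration ``t``, the ``k`` lineages present coalesce with
exponential waiting times at rate ``k(k-1)/2``; lineages surviving the
branch pass to the parent, and everything left at the root coalesces in an
unbounded root branch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tree import (
    UNIT_COALESCENT,
    UNIT_MUTATION,
    GeneTreeSet,
    Node,
    PhyloTree,
)

__all__ = [
    "SimulationConfig",
    "coalescent_scale",
    "as_species_tree_cu",
    "simulate_gene_tree",
    "simulate_gene_trees",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Replication settings for :func:`simulate_gene_trees`.

    ``n_trees`` independent gene trees are produced; replicate *i* draws its
    randomness from the *i*-th spawn of a seed sequence built from ``seed``,
    so increasing ``n_trees`` never changes earlier replicates.
    """

    n_trees: int
    seed: int = 0
    alleles_per_species: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.alleles_per_species < 1:
            raise ValueError("alleles_per_species must be >= 1")


def _check_species_tree(species_tree: PhyloTree) -> None:
    if not species_tree.is_binary():
        raise ValueError("species tree must be rooted and binary")
    if len(species_tree.root.children) != 2:
        raise ValueError("species tree must be rooted (root of degree 2)")
    for node in species_tree.root.postorder():
        if node.parent is not None and node.length is None:
            raise ValueError("species tree branch without a length")


def coalescent_scale(mutation_tree: PhyloTree, theta: float) -> PhyloTree:
    """Rescale a mutation-unit species tree into coalescent units.

    Internal branch lengths are divided by ``theta`` (theta being the ratio
    of mutation-unit to coalescent-unit length); terminal branches are set
    to 1.  A tiny ``theta`` (e.g. 0.001) therefore produces very long
    internal branches — the no-ILS baseline.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    out = mutation_tree.copy(unit_tag=UNIT_COALESCENT)
    for node in out.root.postorder():
        if node.parent is None:
            node.length = None
            continue
        if node.is_leaf:
            node.length = 1.0
        else:
            if node.length is None:
                raise ValueError("internal branch without a mutation-unit length")
            node.length = node.length / theta
    return out


def as_species_tree_cu(tree: PhyloTree) -> PhyloTree:
    """Normalise a coalescent-unit tree for simulation: terminals set to 1."""
    out = tree.copy(unit_tag=UNIT_COALESCENT)
    for node in out.root.postorder():
        if node.parent is None:
            node.length = None
        elif node.is_leaf:
            node.length = 1.0
        elif node.length is None:
            raise ValueError("internal branch without a coalescent-unit length")
    return out


def _evolve_branch(
    lineages: list[tuple[Node, float]],
    duration: float,
    rng: np.random.Generator,
) -> list[tuple[Node, float]]:
    """Coalesce lineages within a branch of the given duration (inf allowed).

    Each lineage is ``(gene_node, age)`` where ``age`` is the elapsed time on
    that lineage's own clock; branch lengths of new gene-tree nodes are set
    from those clocks.
    """
    elapsed = 0.0
    pool = list(lineages)
    while len(pool) > 1:
        k = len(pool)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if elapsed + wait > duration:
            break
        elapsed += wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        node_i, age_i = pool[i]
        node_j, age_j = pool[j]
        node_i.length = age_i + wait
        node_j.length = age_j + wait
        parent = Node()
        parent.add_child(node_i)
        parent.add_child(node_j)
        # ages advance for all lineages
        pool = [(n, a + wait) for n, a in pool]
        pool[j] = pool[-1]
        pool.pop()
        pool[i] = (parent, 0.0)
    if duration != np.inf:
        remaining = duration - elapsed
        pool = [(n, a + remaining) for n, a in pool]
    return pool


def simulate_gene_tree(
    species_tree: PhyloTree, rng: np.random.Generator, alleles_per_species: int = 1
) -> PhyloTree:
    """Draw one gene tree under the MSC within ``species_tree``.

    Gene-tree branch lengths are in coalescent units on each lineage's own
    clock (exact for ultrametric species trees).
    """
    _check_species_tree(species_tree)
    pools: dict[int, list[tuple[Node, float]]] = {}
    for sp_node in species_tree.root.postorder():
        if sp_node.is_leaf:
            if alleles_per_species == 1:
                entering = [(Node(label=sp_node.label), 0.0)]
            else:
                entering = [
                    (Node(label=f"{sp_node.label}_{i + 1}"), 0.0)
                    for i in range(alleles_per_species)
                ]
        else:
            entering = []
            for ch in sp_node.children:
                entering.extend(pools.pop(id(ch)))
        duration = np.inf if sp_node.parent is None else float(sp_node.length)
        pools[id(sp_node)] = _evolve_branch(entering, duration, rng)
    (root_node, _age), = pools[id(species_tree.root)]
    # carry the per-lineage age into the pending branch length bookkeeping
    root_node.length = None
    return PhyloTree(root_node, unit_tag=UNIT_COALESCENT)


def simulate_gene_trees(
    species_tree: PhyloTree, config: SimulationConfig
) -> GeneTreeSet:
    """Simulate ``config.n_trees`` independent MSC gene trees (reproducible)."""
    _check_species_tree(species_tree)
    base = np.random.PCG64(np.random.SeedSequence(config.seed))
    trees = [
        simulate_gene_tree(
            species_tree,
            np.random.Generator(base.jumped(i)),
            alleles_per_species=config.alleles_per_species,
        )
        for i in range(config.n_trees)
    ]
    return GeneTreeSet(trees, taxa=trees[0].taxa)
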