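"""Polyploidy evidence: collinear gene-tree WGD tests, Ks mixture fitting
and LTR insertion-time dating.

For two species A and B that each retained duplicate collinear copies
(A1, A2, B1, B2), the unrooted quartet topology of a collinear gene tree
decides whether the duplication happened independently in each lineage
(within-species copies sister: ((A1,A2),(B1,B2))) or once in their common
ancestor (either cross-species pairing).  Triplicated copies (A1..A3,
B1..B3) generalise the test: independent iff each species' copy set forms
a clade on the induced subtree.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .tree import GeneTreeSet, PhyloTree, Split, bipartitions, induced_quartet_topology

__all__ = [
    "CopyLabeledGeneTree",
    "WGDClassification",
    "KsBlock",
    "KsMixtureFit",
    "classify_copy_tree",
    "independent_wgd_proportion",
    "block_median_ks",
    "load_ks_blocks",
    "fit_ks_mixture",
    "ltr_insertion_time",
    "CODING_RATE",
    "REPEAT_RATE",
]

#: synonymous substitution rate in coding regions (per site per year)
CODING_RATE = 1.9e-9
#: mutation rate of repeat sequences, taken as twice the coding rate
REPEAT_RATE = 3.8e-9


# ---------------------------------------------------------------------------
# copy-labelled gene trees
# ---------------------------------------------------------------------------


@dataclass
class CopyLabeledGeneTree:
    """A gene tree whose tips are duplicate copies, mapped back to species."""

    tree: PhyloTree
    copies: dict[str, list[str]]  # species -> copy tip labels

    def __post_init__(self) -> None:
        tips = set(self.tree.taxa)
        seen: set[str] = set()
        for species, labels in self.copies.items():
            if not labels:
                raise ValueError(f"species {species!r} has no copies")
            for label in labels:
                if label in seen:
                    raise ValueError(f"copy label {label!r} mapped twice")
                seen.add(label)
                if label not in tips:
                    raise ValueError(
                        f"copy label {label!r} of species {species!r} absent from tree"
                    )

    @classmethod
    def from_suffix_labels(cls, tree: PhyloTree) -> "CopyLabeledGeneTree":
        """Build the copy map from tip labels of the form ``<species><index>``
        (e.g. A1, A2, B1), the naming convention for extracted collinear copies.
        """
        copies: dict[str, list[str]] = {}
        for label in tree.taxa:
            species = label.rstrip("0123456789")
            if not species or species == label:
                raise ValueError(f"tip {label!r} has no trailing copy index")
            copies.setdefault(species, []).append(label)
        for labels in copies.values():
            labels.sort()
        return cls(tree=tree, copies=copies)


@dataclass
class WGDClassification:
    """Aggregate verdicts for one species pair over a set of collinear trees."""

    species_a: str
    species_b: str
    counts: Counter
    proportion_independent: float

    @property
    def n_trees(self) -> int:
        return sum(self.counts.values())


def _copy_split(tree: CopyLabeledGeneTree, species_a: str, species_b: str) -> Split:
    for sp in (species_a, species_b):
        if sp not in tree.copies:
            raise ValueError(f"species {sp!r} not in the copy map")
        for label in tree.copies[sp]:
            if label not in tree.tree.taxa:
                raise ValueError(f"missing copy {label!r}")
    return Split(tree.copies[species_a], tree.copies[species_b])


def classify_copy_tree(
    tree: CopyLabeledGeneTree, species_a: str, species_b: str
) -> str:
    """Verdict for one collinear gene tree: independent / shared / other.

    The tree is restricted to the copies of the two species (outgroup
    copies, if present, are ignored).  The duplication is ``independent``
    iff the split separating A's copies from B's copies is induced by an
    edge of the restricted tree; ``shared`` if that split conflicts with
    an induced edge (copies pair across species); ``other`` when the
    restriction is too unresolved to decide.
    """
    ca = tree.copies[species_a] if species_a in tree.copies else None
    cb = tree.copies[species_b] if species_b in tree.copies else None
    target = _copy_split(tree, species_a, species_b)
    na, nb = len(ca), len(cb)
    if na != nb or na not in (2, 3):
        raise ValueError(
            f"expected 2+2 (WGD) or 3+3 (WGT) copies, got {na}+{nb} for "
            f"{species_a!r}/{species_b!r}"
        )
    relevant = target.taxa
    if na == 2:
        topo = induced_quartet_topology(tree.tree, sorted(relevant))
        if isinstance(topo, Split):
            return "independent" if topo == target else "shared"
        return "other"
    induced = set()
    for edge_split in bipartitions(tree.tree):
        r = edge_split.restrict(relevant)
        if r is not None and not r.is_trivial():
            induced.add(r)
    if target in induced:
        return "independent"
    if any(target.conflicts_with(r) for r in induced):
        return "shared"
    return "other"


def independent_wgd_proportion(
    trees: Sequence[CopyLabeledGeneTree], species_a: str, species_b: str
) -> WGDClassification:
    """Proportion of collinear gene trees supporting an independent WGD.

    The denominator is independent + shared; 'other' verdicts are reported
    separately in the counts.
    """
    if not trees:
        raise ValueError("empty tree list")
    counts: Counter = Counter()
    for tree in trees:
        counts[classify_copy_tree(tree, species_a, species_b)] += 1
    decided = counts["independent"] + counts["shared"]
    if decided == 0:
        raise ValueError("no classifiable (independent/shared) trees")
    return WGDClassification(
        species_a=species_a,
        species_b=species_b,
        counts=counts,
        proportion_independent=counts["independent"] / decided,
    )


# ---------------------------------------------------------------------------
# Ks blocks and mixture fitting
# ---------------------------------------------------------------------------


@dataclass
class KsBlock:
    """Ks values of one collinear block's gene pairs."""

    block_id: str
    values: list[float]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"block {self.block_id!r} is empty")
        if any(v < 0 for v in self.values):
            raise ValueError(f"block {self.block_id!r} contains negative Ks")

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def block_median_ks(blocks: Iterable[KsBlock]) -> dict[str, float]:
    """Empirical median Ks per block (midpoint rule for even counts)."""
    medians = {}
    for block in blocks:
        medians[block.block_id] = block.median
    if not medians:
        raise ValueError("no blocks supplied")
    return medians


def load_ks_blocks(path) -> list[KsBlock]:
    """Read a Ks TSV with columns block_id, gene1, gene2, ks."""
    df = pd.read_csv(path, sep="\t")
    required = {"block_id", "ks"}
    if not required <= set(df.columns):
        raise ValueError(f"Ks table must have columns {sorted(required)}")
    return [
        KsBlock(block_id=str(bid), values=sub["ks"].astype(float).tolist())
        for bid, sub in df.groupby("block_id", sort=True)
    ]


@dataclass
class KsMixtureFit:
    """A fitted k-component Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    n_obs: int
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def peak(self) -> float:
        """Mean of the heaviest component — the fitted Ks peak."""
        return float(self.means[int(np.argmax(self.weights))])

    def bic(self) -> float:
        n_params = 3 * self.k - 1
        return n_params * math.log(self.n_obs) - 2.0 * self.log_likelihood

    def components(self) -> list[tuple[float, float, float]]:
        return [
            (float(w), float(m), float(s))
            for w, m, s in zip(self.weights, self.means, self.sds)
        ]


def fit_ks_mixture(
    values: Sequence[float],
    k: int,
    max_ks: float = 5.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> KsMixtureFit:
    """EM fit of a k-component Gaussian mixture to Ks values in (0, max_ks].

    Initialisation is deterministic (component means at sample quantiles),
    so repeated fits of the same data are identical.  The EM log-likelihood
    is monotone non-decreasing; convergence is declared when the
    per-observation log-likelihood improves by less than ``tol`` between
    iterations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(values, dtype=float)
    x = x[(x > 0) & (x <= max_ks)]
    if x.size < 10 * k:
        raise ValueError(
            f"insufficient data: {x.size} values in (0, {max_ks}] for k={k} "
            f"(need >= {10 * k})"
        )
    n = x.size
    # quantile-spread initialisation
    means = np.quantile(x, (np.arange(k) + 0.5) / k)
    sds = np.full(k, max(x.std() / k, 1e-3))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        log_comp = np.log(weights)[:, None] + norm.logpdf(
            x[None, :], means[:, None], sds[:, None]
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[None, :])
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - means**2
        sds = np.sqrt(np.maximum(var, 1e-12))
        if trace and (ll - trace[-1]) / n < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    order = np.argsort(means)
    return KsMixtureFit(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        log_likelihood=trace[-1],
        converged=converged,
        n_iter=it,
        n_obs=n,
        log_likelihood_trace=trace,
    )


# ---------------------------------------------------------------------------
# LTR dating
# ---------------------------------------------------------------------------


def ltr_insertion_time(K: float, r: float = REPEAT_RATE) -> float:
    """LTR insertion age in years: T = K / (2 r)."""
    if r <= 0:
        raise ValueError("mutation rate r must be positive")
    if K < 0:
        raise ValueError("divergence K must be non-negative")
    return K / (2.0 * r)
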