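"""Quartet-frequency concordance statistics.

Tabulates the three unrooted resolutions of every four-taxon subset across
a gene-tree collection, derives per-branch quartet supports (q1, q2, q3),
converts supports to coalescent-unit branch lengths, and provides the
regression and chi-square agreement tests plus split-support
classification used to compare empirical against simulated gene trees.

Resolved-only frequency semantics: unresolved and missing quartets are
tallied but excluded from frequency denominators, matching the coalescent
expectation that f1+f2+f3 = 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import (
    GeneTreeSet,
    PhyloTree,
    Split,
    bipartitions,
    topological_distance_matrix,
)

__all__ = [
    "QuartetTable",
    "BranchQuartetSupport",
    "SplitSupportSummary",
    "count_quartet_topologies",
    "all_quartet_frequencies",
    "branch_quartet_support",
    "coalescent_length_from_support",
    "correlate_quartet_tables",
    "minor_topology_chisq",
    "classify_split_support",
]

SUPPORT_CATEGORIES = (
    "strongly_supported",
    "weakly_supported",
    "weakly_rejected",
    "strongly_rejected",
)


# ---------------------------------------------------------------------------
# quartet tabulation
# ---------------------------------------------------------------------------


def _quartet_codes(
    gene_trees: GeneTreeSet,
    taxa: Sequence[str],
    quartets: np.ndarray,
) -> np.ndarray:
    """Per (tree, quartet) topology code.

    Codes: 1/2/3 = the canonical resolution index (the pairing of the
    subset's smallest-index taxon with the 2nd/3rd/4th), 0 = unresolved,
    -1 = some tip missing.  Quartet index columns must be sorted ascending.
    """
    index = {t: i for i, t in enumerate(taxa)}
    a, b, c, d = quartets[:, 0], quartets[:, 1], quartets[:, 2], quartets[:, 3]
    codes = np.empty((len(gene_trees), len(quartets)), dtype=np.int8)
    for ti, tree in enumerate(gene_trees):
        D = topological_distance_matrix(tree, index)
        s = np.stack(
            (
                D[a, b] + D[c, d],
                D[a, c] + D[b, d],
                D[a, d] + D[b, c],
            )
        )
        s_filled = np.where(np.isnan(s), np.inf, s)
        smin = s_filled.min(axis=0)
        ties = (s_filled == smin).sum(axis=0)
        code = np.argmin(s_filled, axis=0).astype(np.int8) + 1
        code[ties != 1] = 0
        missing = (
            np.isnan(D[a, a]) | np.isnan(D[b, b]) | np.isnan(D[c, c]) | np.isnan(D[d, d])
        )
        code[missing] = -1
        codes[ti] = code
    return codes


def _counts_from_codes(codes: np.ndarray) -> np.ndarray:
    """(nq, 5) array of [n1, n2, n3, unresolved, missing] per quartet."""
    counts = np.empty((codes.shape[1], 5), dtype=np.int64)
    for col, val in enumerate((1, 2, 3, 0, -1)):
        counts[:, col] = (codes == val).sum(axis=0)
    return counts


@dataclass
class QuartetTable:
    """Counts of the three resolutions for every four-taxon subset.

    Rows are the ``C(n, 4)`` subsets in lexicographic order; the three
    canonical resolutions are ordered by the sister pair containing the
    subset's alphabetically smallest taxon.
    """

    taxa: tuple[str, ...]
    subsets: np.ndarray  # (nq, 4) int indices into taxa, rows sorted
    counts: np.ndarray  # (nq, 5) int: n1, n2, n3, unresolved, missing
    n_trees: int

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.subsets = np.asarray(self.subsets, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n_quartets(self) -> int:
        return len(self.subsets)

    def resolved_totals(self) -> np.ndarray:
        return self.counts[:, :3].sum(axis=1)

    def frequencies(self) -> np.ndarray:
        """(nq, 3) resolved-only frequencies; NaN rows where nothing resolved."""
        totals = self.resolved_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = self.counts[:, :3] / totals[:, None]
        freq[totals == 0] = np.nan
        return freq

    def to_frame(self) -> pd.DataFrame:
        labels = np.asarray(self.taxa)
        df = pd.DataFrame(
            {
                "subset": ["|".join(labels[row]) for row in self.subsets],
                "n1": self.counts[:, 0],
                "n2": self.counts[:, 1],
                "n3": self.counts[:, 2],
                "unresolved": self.counts[:, 3],
                "missing": self.counts[:, 4],
            }
        )
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "QuartetTable":
        df = pd.read_csv(path, sep="\t")
        subsets_labels = [s.split("|") for s in df["subset"]]
        taxa = tuple(sorted({t for row in subsets_labels for t in row}))
        index = {t: i for i, t in enumerate(taxa)}
        subsets = np.array(
            [sorted(index[t] for t in row) for row in subsets_labels], dtype=np.int64
        )
        counts = df[["n1", "n2", "n3", "unresolved", "missing"]].to_numpy(np.int64)
        n_trees = int(counts[0].sum()) if len(counts) else 0
        return cls(taxa=taxa, subsets=subsets, counts=counts, n_trees=n_trees)


def count_quartet_topologies(
    gene_trees: GeneTreeSet, quartet: Sequence[str]
) -> tuple[int, int, int, int, int]:
    """Tally the induced resolutions of one quartet across all gene trees.

    Returns ``(n1, n2, n3, unresolved, missing)`` with resolutions in
    canonical order (sister pair containing the alphabetically smallest
    taxon: ab|cd, ac|bd, ad|bc for sorted taxa a<b<c<d).
    """
    q = sorted(quartet)
    if len(q) != 4 or len(set(q)) != 4:
        raise ValueError("quartet must contain 4 distinct taxon labels")
    missing_ref = set(q) - set(gene_trees.taxa)
    if missing_ref:
        raise ValueError(f"quartet taxa not in reference set: {sorted(missing_ref)}")
    subsets = np.array([[0, 1, 2, 3]])
    codes = _quartet_codes(gene_trees, q, subsets)
    counts = _counts_from_codes(codes)[0]
    return tuple(int(x) for x in counts)


def all_quartet_frequencies(gene_trees: GeneTreeSet) -> QuartetTable:
    """One row of resolution counts per four-taxon subset of the reference taxa."""
    taxa = gene_trees.taxa
    if len(taxa) < 4:
        raise ValueError("need at least 4 reference taxa")
    subsets = np.array(
        list(itertools.combinations(range(len(taxa)), 4)), dtype=np.int64
    )
    codes = _quartet_codes(gene_trees, taxa, subsets)
    return QuartetTable(
        taxa=taxa,
        subsets=subsets,
        counts=_counts_from_codes(codes),
        n_trees=len(gene_trees),
    )


# ---------------------------------------------------------------------------
# branch quartet support
# ---------------------------------------------------------------------------


@dataclass
class BranchQuartetSupport:
    """Pooled quartet support around one internal species-tree branch.

    ``q1`` is the frequency of the species-tree resolution; ``q2`` and
    ``q3`` the two alternatives (q2 groups the first child clade with the
    sibling side).  ``counts`` are the pooled resolved tallies behind the
    frequencies.
    """

    split: Split
    q1: float
    q2: float
    q3: float
    counts: tuple[int, int, int]
    unresolved: int = 0
    missing: int = 0
    n_quartets: int = 0

    def minor_counts(self) -> tuple[int, int]:
        """The two non-species-tree resolution counts, largest first."""
        c2, c3 = self.counts[1], self.counts[2]
        return (c2, c3) if c2 >= c3 else (c3, c2)


def _branch_groups(
    species_tree: PhyloTree, branch: Split
) -> tuple[list[str], list[str], list[str], list[str]]:
    """The four taxon groups adjacent to an internal edge of the species tree.

    The two child clades sit on one side; the sibling clade and the
    remainder of the taxon set on the other (for an edge incident to a
    binary root, the far side is split by the sibling's children).
    """
    taxa = frozenset(species_tree.taxa)
    clades: dict[int, frozenset] = {}
    target: Optional = None
    for node in species_tree.root.postorder():
        if node.is_leaf:
            clades[id(node)] = frozenset((node.label,))
            continue
        clade = frozenset().union(*(clades[id(ch)] for ch in node.children))
        clades[id(node)] = clade
        if node.parent is not None and (
            Split(clade, taxa - clade) == branch if len(taxa - clade) else False
        ):
            target = node
    if target is None:
        raise ValueError(f"branch {branch!r} is not an internal edge of the species tree")
    if len(target.children) != 2:
        raise ValueError("species tree must be binary at the focal branch")
    g1 = sorted(clades[id(target.children[0])])
    g2 = sorted(clades[id(target.children[1])])
    parent = target.parent
    siblings = [ch for ch in parent.children if ch is not target]
    if parent.parent is not None:
        if len(siblings) != 1:
            raise ValueError("species tree must be binary at the focal branch")
        g3 = sorted(clades[id(siblings[0])])
        g4 = sorted(taxa - clades[id(parent)])
    else:
        # edge incident to the root: the far side is the sibling subtree
        if len(siblings) != 1 or siblings[0].is_leaf:
            raise ValueError(
                f"branch {branch!r} has no four adjacent groups (root edge to a leaf)"
            )
        sib = siblings[0]
        if len(sib.children) != 2:
            raise ValueError("species tree must be binary at the focal branch")
        g3 = sorted(clades[id(sib.children[0])])
        g4 = sorted(clades[id(sib.children[1])])
    return g1, g2, g3, g4


def branch_quartet_support(
    gene_trees: GeneTreeSet, species_tree: PhyloTree, branch: Split
) -> BranchQuartetSupport:
    """Pooled q1/q2/q3 for one internal branch of the species tree.

    Enumerates every quartet taking one taxon from each of the branch's
    four adjacent groups, pools raw resolved counts over all (gene tree,
    quartet) pairs with equal weight, and reports pooled frequencies.
    """
    g1, g2, g3, g4 = _branch_groups(species_tree, branch)
    taxa = gene_trees.taxa
    index = {t: i for i, t in enumerate(taxa)}
    combos = np.array(
        [
            (index[w], index[x], index[y], index[z])
            for w in g1
            for x in g2
            for y in g3
            for z in g4
        ],
        dtype=np.int64,
    )
    i1, i2, i3, i4 = combos[:, 0], combos[:, 1], combos[:, 2], combos[:, 3]
    tallies = np.zeros(3, dtype=np.int64)
    unresolved = 0
    missing = 0
    for tree in gene_trees:
        D = topological_distance_matrix(tree, index)
        # s1: species-tree resolution (child clades together)
        s = np.stack(
            (
                D[i1, i2] + D[i3, i4],
                D[i1, i3] + D[i2, i4],
                D[i1, i4] + D[i2, i3],
            )
        )
        s_filled = np.where(np.isnan(s), np.inf, s)
        smin = s_filled.min(axis=0)
        ties = (s_filled == smin).sum(axis=0)
        code = np.argmin(s_filled, axis=0)
        nan_any = (
            np.isnan(D[i1, i1]) | np.isnan(D[i2, i2])
            | np.isnan(D[i3, i3]) | np.isnan(D[i4, i4])
        )
        valid = ~nan_any & (ties == 1)
        for topo in range(3):
            tallies[topo] += int((valid & (code == topo)).sum())
        unresolved += int((~valid & ~nan_any).sum())
        missing += int(nan_any.sum())
    total = int(tallies.sum())
    if total == 0:
        raise ValueError("no resolved quartets around the focal branch")
    q = tallies / total
    return BranchQuartetSupport(
        split=branch,
        q1=float(q[0]),
        q2=float(q[1]),
        q3=float(q[2]),
        counts=(int(tallies[0]), int(tallies[1]), int(tallies[2])),
        unresolved=unresolved,
        missing=missing,
        n_quartets=len(combos),
    )


def coalescent_length_from_support(q1: float, ceiling: float = 10.0) -> float:
    """Invert the MSC concordance formula q1 = 1 - (2/3)e^(-t).

    Returns ``max(0, -ln((3/2)(1 - q1)))``, clipped to 0 below the
    star-tree limit q1 = 1/3 and capped at ``ceiling`` as q1 approaches 1.
    """
    if not 0 <= q1 <= 1:
        raise ValueError("q1 must be in [0, 1]")
    if q1 >= 1.0:
        return float(ceiling)
    t = -np.log(1.5 * (1.0 - q1))
    return float(min(max(t, 0.0), ceiling))


# ---------------------------------------------------------------------------
# agreement tests
# ---------------------------------------------------------------------------


def correlate_quartet_tables(
    table_a: QuartetTable, table_b: QuartetTable
) -> tuple[float, float, float, float]:
    """OLS of table B's quartet frequencies on table A's.

    The per-subset resolved frequencies (three values per subset) are
    flattened; subsets unresolved in either table are dropped.  Returns
    ``(r_squared, slope, intercept, p_value)`` with a two-sided p for a
    non-zero slope.
    """
    if table_a.taxa != table_b.taxa:
        raise ValueError("quartet tables are over different taxon sets")
    if not np.array_equal(table_a.subsets, table_b.subsets):
        raise ValueError("quartet tables have different subset orderings")
    fa = table_a.frequencies()
    fb = table_b.frequencies()
    keep = ~(np.isnan(fa).any(axis=1) | np.isnan(fb).any(axis=1))
    x = fa[keep].ravel()
    y = fb[keep].ravel()
    if x.size < 3:
        raise ValueError("too few resolved subsets for regression")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor frequencies")
    if np.array_equal(x, y):
        # exact self-correlation short-circuits floating-point noise
        return 1.0, 1.0, 0.0, 0.0
    res = stats.linregress(x, y)
    return (
        float(res.rvalue**2),
        float(res.slope),
        float(res.intercept),
        float(res.pvalue),
    )


def minor_topology_chisq(
    empirical: tuple[int, int], simulated: tuple[int, int]
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 minor-topology count table.

    Rows are the two datasets, columns the two minor resolutions; df = 1,
    no continuity correction.  Returns ``(chi2, df, p)``.
    """
    table = np.array([empirical, simulated], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    row_tot = table.sum(axis=1)
    if (row_tot == 0).any():
        raise ValueError("each dataset must contribute at least one minor-topology count")
    col_tot = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(row_tot, col_tot) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    chi2 = float(np.nansum(terms))  # zero-total columns contribute nothing
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p


# ---------------------------------------------------------------------------
# split support classification
# ---------------------------------------------------------------------------


@dataclass
class SplitSupportSummary:
    """Per-gene-tree verdicts on a focal split, with aggregate proportions."""

    split: Split
    threshold: float
    categories: list[str] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def n_categorized(self) -> int:
        return len(self.categories)

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n_categorized
        if n == 0:
            return {c: float("nan") for c in SUPPORT_CATEGORIES}
        return {c: self.categories.count(c) / n for c in SUPPORT_CATEGORIES}


def classify_split_support(
    gene_trees: GeneTreeSet,
    split: Split,
    threshold: float = 75.0,
    missing_support: str = "error",
) -> SplitSupportSummary:
    """Classify each gene tree's stance on a focal split.

    Per tree (restricted to the split's taxa present in it):

    * ``strongly_supported`` — the split is an edge with support >= threshold;
    * ``weakly_supported`` — an edge, but only with support < threshold;
    * ``weakly_rejected`` — absent, yet compatible once all edges with
      support < threshold are contracted;
    * ``strongly_rejected`` — absent and in conflict with a high-support edge.

    ``missing_support`` controls edges without a support value: ``"error"``
    (default) raises, ``"high"`` treats them as maximally supported.
    """
    if missing_support not in ("error", "high"):
        raise ValueError("missing_support must be 'error' or 'high'")
    summary = SplitSupportSummary(split=split, threshold=threshold)
    for tree in gene_trees:
        common = split.taxa & frozenset(tree.taxa)
        restricted = split.restrict(common)
        if restricted is None or restricted.is_trivial():
            summary.n_skipped += 1
            continue
        # restricted splits induced by the tree's internal edges, keeping
        # the best support among edges inducing the same restriction
        induced: dict[Split, float] = {}
        for edge_split in bipartitions(tree):
            r = edge_split.restrict(common)
            if r is None or r.is_trivial():
                continue
            sup = _edge_support(tree, edge_split, missing_support)
            if r not in induced or sup > induced[r]:
                induced[r] = sup
        if restricted in induced:
            cat = (
                "strongly_supported"
                if induced[restricted] >= threshold
                else "weakly_supported"
            )
        else:
            conflict = any(
                sup >= threshold and restricted.conflicts_with(r)
                for r, sup in induced.items()
            )
            cat = "strongly_rejected" if conflict else "weakly_rejected"
        summary.categories.append(cat)
    return summary


def _edge_support(tree: PhyloTree, edge_split: Split, missing_support: str) -> float:
    # locate the internal node whose clade (or its complement) equals a block
    taxa = frozenset(tree.taxa)
    best: Optional[float] = None
    clades: dict[int, frozenset] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            clades[id(node)] = frozenset((node.label,))
            continue
        clade = frozenset().union(*(clades[id(ch)] for ch in node.children))
        clades[id(node)] = clade
        if node.parent is None:
            continue
        if clade == edge_split.block1 or clade == edge_split.block2:
            sup = node.support
            if sup is None:
                if missing_support == "error":
                    raise ValueError(
                        "gene tree has an internal edge without a support value"
                    )
                sup = 100.0
            if best is None or sup > best:
                best = sup
    if best is None:  # pragma: no cover - caller guarantees the edge exists
        raise ValueError("edge not found in tree")
    return best
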