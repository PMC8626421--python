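"""Per-branch theta estimation and the end-to-end ILS assessment.

Theta for an internal branch is its length in mutation units divided by
its length in coalescent units; a larger theta means a larger ancestral
population and hence more incomplete lineage sorting.  The assessment
pipeline simulates gene trees with ILS (from the coalescent-unit tree)
and essentially without ILS (mutation tree rescaled by theta = 0.001),
tabulates quartet frequencies, and compares both simulations against the
empirical gene trees with linear regression and per-branch chi-square
tests on the two minor topologies.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    BranchQuartetSupport,
    QuartetTable,
    all_quartet_frequencies,
    branch_quartet_support,
    correlate_quartet_tables,
    minor_topology_chisq,
)
from .msc import SimulationConfig, as_species_tree_cu, coalescent_scale, simulate_gene_trees
from .tree import GeneTreeSet, PhyloTree, Split, internal_edge_lengths

__all__ = ["ThetaEstimate", "IlsReport", "estimate_theta", "run_ils_assessment"]

DEFAULT_THETA_NO_ILS = 0.001


@dataclass
class ThetaEstimate:
    """Per-branch mutation-unit length, coalescent-unit length and their ratio."""

    rows: dict[Split, tuple[float, float, float]]  # split -> (mu, cu, theta)
    unmatched_mutation: set[Split] = field(default_factory=set)
    unmatched_coalescent: set[Split] = field(default_factory=set)

    def theta_values(self) -> list[float]:
        return [theta for _, _, theta in self.rows.values()]

    def to_frame(self) -> pd.DataFrame:
        splits = sorted(self.rows, key=Split.sort_key)
        return pd.DataFrame(
            {
                "split": [repr(s) for s in splits],
                "mutation_length": [self.rows[s][0] for s in splits],
                "coalescent_length": [self.rows[s][1] for s in splits],
                "theta": [self.rows[s][2] for s in splits],
            }
        )


def estimate_theta(
    mutation_tree: PhyloTree, coalescent_tree: PhyloTree
) -> ThetaEstimate:
    """Theta per internal branch shared (by bipartition) between the two trees.

    Terminal branches are excluded — a terminal branch has no quartet
    signal from which a coalescent-unit length could be estimated.
    Branches present in only one tree are reported as unmatched rather
    than silently dropped.  A zero coalescent length yields ``inf`` with a
    warning.
    """
    mu = internal_edge_lengths(mutation_tree)
    cu = internal_edge_lengths(coalescent_tree)
    shared = set(mu) & set(cu)
    if not shared:
        raise ValueError("no shared internal branch between the two trees")
    rows: dict[Split, tuple[float, float, float]] = {}
    for split in shared:
        m, c = mu[split], cu[split]
        if c == 0:
            warnings.warn(f"zero coalescent length on {split!r}; theta set to inf")
            theta = math.inf
        else:
            theta = m / c
        rows[split] = (m, c, theta)
    return ThetaEstimate(
        rows=rows,
        unmatched_mutation=set(mu) - shared,
        unmatched_coalescent=set(cu) - shared,
    )


@dataclass
class ChiSquareResult:
    split: Split
    empirical_minor: tuple[int, int]
    simulated_minor: tuple[int, int]
    chi2: float
    df: int
    p: float
    p_adjusted: float = float("nan")


@dataclass
class IlsReport:
    """Everything the ILS assessment produces, ready for serialisation."""

    empirical_table: QuartetTable
    with_ils_table: QuartetTable
    no_ils_table: QuartetTable
    r2_with_ils: float
    r2_no_ils: float
    regression_with_ils: tuple[float, float, float, float]
    regression_no_ils: tuple[float, float, float, float]
    chisq_results: list[ChiSquareResult]
    theta: ThetaEstimate
    config: SimulationConfig
    theta_no_ils: float

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_trees": self.config.n_trees,
                "seed": self.config.seed,
                "theta_no_ils": self.theta_no_ils,
            },
            "r2_with_ils": self.r2_with_ils,
            "r2_no_ils": self.r2_no_ils,
            "regression_with_ils": dict(
                zip(("r2", "slope", "intercept", "p"), self.regression_with_ils)
            ),
            "regression_no_ils": dict(
                zip(("r2", "slope", "intercept", "p"), self.regression_no_ils)
            ),
            "chisq": [
                {
                    "split": repr(r.split),
                    "empirical_minor": list(r.empirical_minor),
                    "simulated_minor": list(r.simulated_minor),
                    "chi2": r.chi2,
                    "df": r.df,
                    "p": r.p,
                    "p_adjusted": r.p_adjusted,
                }
                for r in self.chisq_results
            ],
            "theta": {
                repr(s): {
                    "mutation_length": m,
                    "coalescent_length": c,
                    "theta": (None if math.isinf(t) else t),
                }
                for s, (m, c, t) in sorted(
                    self.theta.rows.items(), key=lambda kv: kv[0].sort_key()
                )
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.empirical_table.to_tsv(os.path.join(outdir, "quartets_empirical.tsv"))
        self.with_ils_table.to_tsv(os.path.join(outdir, "quartets_with_ils.tsv"))
        self.no_ils_table.to_tsv(os.path.join(outdir, "quartets_no_ils.tsv"))
        self.theta.to_frame().to_csv(
            os.path.join(outdir, "theta.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                {
                    "split": repr(r.split),
                    "chi2": r.chi2,
                    "df": r.df,
                    "p": r.p,
                    "p_adjusted": r.p_adjusted,
                }
                for r in self.chisq_results
            ]
        ).to_csv(os.path.join(outdir, "chisq.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "ils_report.json"), "w") as fh:
            fh.write(self.to_json() + "\n")


def _benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return adjusted.tolist()


def run_ils_assessment(
    empirical: GeneTreeSet,
    mutation_tree: PhyloTree,
    coalescent_tree: PhyloTree,
    config: SimulationConfig,
    theta_no_ils: float = DEFAULT_THETA_NO_ILS,
    focal_branches: Optional[Sequence[Split]] = None,
) -> IlsReport:
    """Run the full empirical-vs-simulated concordance assessment.

    Simulates a with-ILS gene-tree set from the coalescent-unit species
    tree and a no-ILS set from the mutation tree rescaled with
    ``theta_no_ils``, builds the three quartet tables, regresses each
    simulated table on the empirical one, and runs per-focal-branch
    chi-square tests comparing minor-topology counts (ranked by the
    empirical counts) between the empirical and with-ILS sets.
    """
    if config.n_trees < 100:
        warnings.warn("n_trees < 100: quartet frequencies will be unstable")
    if set(empirical.taxa) != set(coalescent_tree.taxa):
        raise ValueError("empirical gene trees and coalescent tree differ in taxa")
    cu_species = as_species_tree_cu(coalescent_tree)
    with_ils = simulate_gene_trees(cu_species, config)
    no_ils_species = coalescent_scale(mutation_tree, theta_no_ils)
    no_ils = simulate_gene_trees(no_ils_species, replace(config, seed=config.seed + 1))

    t_emp = all_quartet_frequencies(empirical)
    t_ils = all_quartet_frequencies(with_ils)
    t_no = all_quartet_frequencies(no_ils)

    reg_ils = correlate_quartet_tables(t_emp, t_ils)
    reg_no = correlate_quartet_tables(t_emp, t_no)

    theta = estimate_theta(mutation_tree, coalescent_tree)

    if focal_branches is None:
        focal_branches = sorted(
            internal_edge_lengths(cu_species), key=Split.sort_key
        )
    chisq_results: list[ChiSquareResult] = []
    for branch in focal_branches:
        bs_emp = branch_quartet_support(empirical, cu_species, branch)
        bs_sim = branch_quartet_support(with_ils, cu_species, branch)
        # minor columns fixed by the empirical ranking, applied to both
        if bs_emp.counts[1] >= bs_emp.counts[2]:
            cols = (1, 2)
        else:
            cols = (2, 1)
        emp_minor = (bs_emp.counts[cols[0]], bs_emp.counts[cols[1]])
        sim_minor = (bs_sim.counts[cols[0]], bs_sim.counts[cols[1]])
        chi2, df, p = minor_topology_chisq(emp_minor, sim_minor)
        chisq_results.append(
            ChiSquareResult(
                split=branch,
                empirical_minor=emp_minor,
                simulated_minor=sim_minor,
                chi2=chi2,
                df=df,
                p=p,
            )
        )
    if chisq_results:
        adjusted = _benjamini_hochberg([r.p for r in chisq_results])
        for r, pa in zip(chisq_results, adjusted):
            r.p_adjusted = pa

    return IlsReport(
        empirical_table=t_emp,
        with_ils_table=t_ils,
        no_ils_table=t_no,
        r2_with_ils=reg_ils[0],
        r2_no_ils=reg_no[0],
        regression_with_ils=reg_ils,
        regression_no_ils=reg_no,
        chisq_results=chisq_results,
        theta=theta,
        config=config,
        theta_no_ils=theta_no_ils,
    )
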