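"""Clade scoring across gene-tree sets, support-based branch collapsing,
gene concordance factors, and the branch-length/support regression.

Trees are treated as unrooted throughout: a clade is monophyletic in a
tree when its members (restricted to the tree's leaves) form one side
of a bipartition.  Clades with fewer than two members present, or fewer
than two non-members, are not evaluable and are excluded from all
denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .phyio import GeneTreeRecord


@dataclass(frozen=True)
class CladeDefinition:
    name: str
    members: frozenset[str]
    outgroup: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"clade {self.name!r} has no members")
        if self.members & self.outgroup:
            raise ValueError(f"clade {self.name!r}: outgroup overlaps members")


@dataclass(frozen=True)
class CladeSupportReport:
    clade: str
    n_evaluable: int
    prop_monophyletic: float  # NaN when n_evaluable == 0
    prop_strong: float
    support_threshold: int


def read_clade_definitions(path) -> list[CladeDefinition]:
    """Read clade definitions from TSV (columns: name, member[, role])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "role" not in df.columns:
        df["role"] = ""
    df["role"] = df["role"].fillna("")
    out = []
    for name, group in df.groupby("name", sort=False):
        members = frozenset(group.loc[group["role"] != "outgroup", "member"])
        outgroup = frozenset(group.loc[group["role"] == "outgroup", "member"])
        out.append(CladeDefinition(name, members, outgroup))
    return out


def _splits_with_support(
    record: GeneTreeRecord,
) -> dict[frozenset[str], int | None]:
    """Map each non-trivial split (canonical side) to its edge support."""
    tree = record.tree
    leaves = frozenset(record.leaf_labels())
    out: dict[frozenset[str], int | None] = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        canon = _canonical(below, leaves)
        support = getattr(edge, "support", None)
        # a split may appear twice via the root's two child edges; keep
        # the labelled copy
        if canon not in out or out[canon] is None:
            out[canon] = support
    return out


def _canonical(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    other = leaves - side
    if (len(side), sorted(side)) <= (len(other), sorted(other)):
        return frozenset(side)
    return frozenset(other)


def is_monophyletic(tree: GeneTreeRecord, clade: CladeDefinition) -> str:
    """'yes' | 'no' | 'not_evaluable' for an unrooted bipartition test."""
    leaves = frozenset(tree.leaf_labels())
    members = clade.members & leaves
    others = leaves - members
    if len(members) < 2 or len(others) < 2:
        return "not_evaluable"
    splits = _splits_with_support(tree)
    canon = _canonical(members, leaves)
    return "yes" if canon in splits else "no"


def clade_support(
    trees: list[GeneTreeRecord],
    clade: CladeDefinition,
    support_threshold: int = 90,
) -> CladeSupportReport:
    """Proportions of evaluable trees that are monophyletic / strongly so.

    A tree counts toward ``prop_strong`` when the clade's bipartition
    exists and its edge support is present and at or above the
    threshold.
    """
    if not trees:
        raise ValueError("need at least one tree")
    n_eval = 0
    n_mono = 0
    n_strong = 0
    for rec in trees:
        leaves = frozenset(rec.leaf_labels())
        members = clade.members & leaves
        others = leaves - members
        if len(members) < 2 or len(others) < 2:
            continue
        n_eval += 1
        splits = _splits_with_support(rec)
        canon = _canonical(members, leaves)
        if canon in splits:
            n_mono += 1
            support = splits[canon]
            if support is not None and support >= support_threshold:
                n_strong += 1
    if n_eval == 0:
        return CladeSupportReport(clade.name, 0, math.nan, math.nan,
                                  support_threshold)
    return CladeSupportReport(
        clade.name, n_eval, n_mono / n_eval, n_strong / n_eval,
        support_threshold,
    )


def collapse_low_support(
    record: GeneTreeRecord, threshold: int = 10
) -> GeneTreeRecord:
    """Contract internal edges with support strictly below ``threshold``.

    Leaf edges and unlabeled internal edges are never contracted; branch
    lengths of contracted edges are discarded.
    """
    out = record.clone()
    to_collapse = []
    for edge in out.tree.preorder_edge_iter():
        node = edge.head_node
        if node is out.tree.seed_node or node.is_leaf():
            continue
        support = getattr(edge, "support", None)
        if support is not None and support < threshold:
            to_collapse.append(edge)
    for edge in to_collapse:
        edge.collapse()
    return out


def n_internal_edges(record: GeneTreeRecord) -> int:
    """Internal edges of the unrooted tree (splits with >= 2 leaves a side)."""
    return len(_splits_with_support(record))


def gene_concordance(
    species_tree: GeneTreeRecord, trees: list[GeneTreeRecord]
) -> pd.DataFrame:
    """Gene concordance factor for each internal species-tree branch.

    A gene tree is decisive for a branch when, after restriction to the
    taxa it shares with the species tree's split, both sides retain at
    least two leaves; it is concordant when the restricted split occurs
    in the gene tree.  gCF is reported in percent; NaN when no tree is
    decisive.
    """
    sp_leaves = frozenset(species_tree.leaf_labels())
    sp_splits = _splits_with_support(species_tree)
    if not sp_splits:
        raise ValueError("species tree has no internal branches")

    gene_splits = []
    gene_leaves = []
    for rec in trees:
        gene_leaves.append(frozenset(rec.leaf_labels()))
        gene_splits.append(set(_splits_with_support(rec)))

    rows = []
    for split in sorted(sp_splits, key=lambda s: (len(s), sorted(s))):
        other = sp_leaves - split
        n_dec = 0
        n_con = 0
        for splits, leaves in zip(gene_splits, gene_leaves):
            p = split & leaves
            q = other & leaves
            if len(p) < 2 or len(q) < 2:
                continue
            n_dec += 1
            # restrict to leaves shared with the species tree's split
            shared = p | q
            restricted = {
                _canonical(frozenset(s & shared), frozenset(shared))
                for s in splits
                if len(s & shared) >= 2 and len(shared - s) >= 2
            }
            if _canonical(frozenset(p), frozenset(shared)) in restricted:
                n_con += 1
        rows.append({
            "bipartition": "|".join(sorted(split)),
            "gcf_percent": 100.0 * n_con / n_dec if n_dec else math.nan,
            "n_concordant": n_con,
            "n_decisive": n_dec,
        })
    return pd.DataFrame(rows)


def ols_support_regression(
    x: "list[float] | np.ndarray", y: "list[float] | np.ndarray"
) -> tuple[float, float, float, float]:
    """OLS of ``y`` on ``x``: (slope, intercept, r_squared, p_value).

    The p-value is the two-sided t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need matched x/y with at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return res.slope, res.intercept, res.rvalue ** 2, res.pvalue
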