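"""Synthetic marker sets for exercising the filtration workflow.

Generates a random species tree, per-marker gene trees whose
topological error grows as alignment length shrinks, and JC69 sequence
alignments, so that every downstream stage (statistics, filtration,
jackknife, concordance) can run end to end without real data.

Gene tree estimation error is modeled phenomenologically: each gene
tree is the species tree perturbed by ``K ~ Poisson(c * ref_len /
length)`` random NNI moves, rather than by re-estimating trees from
simulated sequences.  Bipartitions that survive perturbation keep
support 100; edges touched by an NNI get a low support drawn uniformly
from 0-70.  An optional length-independent mode (``ils_like=True``)
applies NNI noise at a fixed rate to emulate ILS-style discordance that
length filtering cannot remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phyio import (
    Alignment,
    GeneTreeRecord,
    edge_length,
    parse_newick,
    write_alignment,
    write_tree,
)

BASES = "ACGT"


@dataclass
class SimConfig:
    n_taxa: int = 12
    n_markers: int = 100
    min_bp: int = 100
    max_bp: int = 5000
    error_rate_scale: float = 1.0   # expected NNIs = c * ref_len / length
    ref_len: int = 1000
    substitution_scale: float = 0.05
    occupancy_dropout: float = 0.0  # per-taxon dropout probability
    ils_like: bool = False          # NNI rate independent of length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not 0.0 <= self.occupancy_dropout <= 1.0:
            raise ValueError("occupancy_dropout must be in [0,1]")
        if self.error_rate_scale < 0:
            raise ValueError("error_rate_scale must be >= 0")
        if self.min_bp < 1 or self.max_bp < self.min_bp:
            raise ValueError("bad length range")


def _taxon_names(n: int) -> list[str]:
    return [f"T{i:03d}" for i in range(1, n + 1)]


def simulate_species_tree(cfg: SimConfig) -> GeneTreeRecord:
    """Random binary unrooted species tree with exponential branch lengths."""
    rng = np.random.default_rng(cfg.seed)
    names = _taxon_names(cfg.n_taxa)
    # sequential random joining yields a uniform-ish random binary topology
    taxon_ns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = []
    for name in names[:3]:
        leaf = dendropy.Node(taxon=taxon_ns.get_taxon(name))
        tree.seed_node.add_child(leaf)
        nodes.append(leaf)
    for name in names[3:]:
        target = nodes[rng.integers(len(nodes))]
        parent = target.parent_node
        new_internal = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(new_internal)
        new_internal.add_child(target)
        leaf = dendropy.Node(taxon=taxon_ns.get_taxon(name))
        new_internal.add_child(leaf)
        nodes.append(leaf)
        nodes.append(new_internal)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        node.edge.length = float(
            rng.exponential(cfg.substitution_scale)
        ) + 1e-6
        node.edge.support = None if node.is_leaf() else 100
    tree.update_bipartitions(suppress_unifurcations=False)
    return GeneTreeRecord("species_tree", tree)


def _random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> bool:
    """Apply one random NNI move in place; returns False if no internal
    edge is eligible."""
    candidates = []
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.seed_node or head.is_leaf():
            continue
        if head.parent_node is None:
            continue
        # need >= 2 children at head and a sibling or extra child at tail
        if len(head.child_nodes()) >= 2:
            candidates.append(edge)
    if not candidates:
        return False
    edge = candidates[rng.integers(len(candidates))]
    head, tail = edge.head_node, edge.tail_node
    head_children = head.child_nodes()
    tail_others = [c for c in tail.child_nodes() if c is not head]
    if tail is tree.seed_node and len(tail_others) < 1:
        return False
    if not tail_others:
        return False
    a = head_children[rng.integers(len(head_children))]
    b = tail_others[rng.integers(len(tail_others))]
    # swap subtrees a and b across the edge
    head.remove_child(a)
    tail.remove_child(b)
    head.add_child(b)
    tail.add_child(a)
    # edges adjacent to the move lose their original bipartition
    edge.support = 0
    return True


def simulate_gene_trees(
    sp: GeneTreeRecord, lengths: list[int], cfg: SimConfig
) -> list[GeneTreeRecord]:
    """Perturbed copies of the species tree, one per marker length.

    The number of NNI moves per tree is Poisson with mean
    ``c * ref_len / length`` (or ``c`` itself in ``ils_like`` mode).
    Bipartitions shared with the species tree keep support 100; novel
    bipartitions get uniform support in 0-70.  Taxa are dropped
    independently with probability ``occupancy_dropout`` (never below 4
    retained taxa).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sp_splits = _splits(sp.tree)
    out = []
    for i, length in enumerate(lengths):
        if length <= 0:
            raise ValueError("lengths must be positive")
        tree = sp.tree.clone(depth=1)
        k = int(rng.poisson(expected_nni_count(length, cfg)))
        for _ in range(k):
            _random_nni(tree, rng)
        # dropout
        if cfg.occupancy_dropout > 0:
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            keep = [
                t for t in leaves if rng.random() >= cfg.occupancy_dropout
            ]
            if len(keep) < 4:
                keep = list(rng.choice(leaves, size=4, replace=False))
            if len(keep) < len(leaves):
                tree.retain_taxa_with_labels(keep)
        _assign_supports(tree, sp_splits, rng)
        rec = GeneTreeRecord(f"marker{i:04d}", tree)
        rec.nni_count = k  # truth bookkeeping for tests/manifest
        out.append(rec)
    return out


def expected_nni_count(length: int, cfg: SimConfig) -> float:
    """Mean of the Poisson NNI count for a marker of ``length`` bp."""
    if cfg.ils_like:
        return cfg.error_rate_scale
    return cfg.error_rate_scale * cfg.ref_len / length


def _splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in head.leaf_iter())
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        other = leaves - below
        canon = below if (len(below), sorted(below)) <= (len(other), sorted(other)) else other
        splits.add(canon)
    return splits


def _assign_supports(
    tree: dendropy.Tree,
    sp_splits: set[frozenset[str]],
    rng: np.random.Generator,
) -> None:
    """Support 100 on species-tree bipartitions, uniform 0-70 otherwise."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        edge.support = None
        if head is tree.seed_node or head.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in head.leaf_iter())
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        other = leaves - below
        canon = below if (len(below), sorted(below)) <= (len(other), sorted(other)) else other
        # compare against species-tree splits restricted to this leaf set
        matched = any(
            _restrict(s, leaves) == canon for s in sp_splits
        ) or canon in sp_splits
        edge.support = 100 if matched else int(rng.integers(0, 71))


def _restrict(split: frozenset[str], leaves: frozenset[str]) -> frozenset[str] | None:
    side = frozenset(split & leaves)
    if len(side) < 2 or len(leaves - side) < 2:
        return None
    other = leaves - side
    return side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other


def marker_lengths(cfg: SimConfig) -> list[int]:
    """Log-uniform marker lengths over [min_bp, max_bp]."""
    rng = np.random.default_rng(cfg.seed + 2)
    lo, hi = np.log(cfg.min_bp), np.log(cfg.max_bp)
    return [int(round(np.exp(v))) for v in rng.uniform(lo, hi, cfg.n_markers)]


def simulate_sequences(
    tree: GeneTreeRecord, length: int, seed: int = 0,
    marker_class: str = "unified",
) -> Alignment:
    """Evolve JC69 sequences along ``tree`` from a uniform root state.

    Per branch of length ``d`` each site changes to a uniformly chosen
    different base with probability ``(3/4)(1 - exp(-4d/3))``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate(BASES)}
    root_seq = rng.integers(0, 4, size=length)
    seqs: dict[str, np.ndarray] = {}

    def _evolve(parent_seq: np.ndarray, node: dendropy.Node) -> None:
        for child in node.child_nodes():
            d = edge_length(child.edge)
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            seq = parent_seq.copy()
            hits = rng.random(length) < p_change
            n_hits = int(hits.sum())
            if n_hits:
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=n_hits)
                seq[hits] = (seq[hits] + shift) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = seq
            else:
                _evolve(seq, child)

    _evolve(root_seq, tree.tree.seed_node)
    rows = {
        name: "".join(BASES[i] for i in seqs[name])
        for name in sorted(seqs)
    }
    return Alignment(tree.marker_id, marker_class, rows)


def generate_study(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full synthetic study to ``outdir``.

    Produces ``alignments/<marker>.fasta``, ``gene_trees/<marker>.nwk``
    (matching stems), ``species_tree.nwk``, and ``manifest.tsv`` with
    per-marker truth (length, NNI count proxy via distinct splits,
    dropped taxa).
    """
    outdir = Path(outdir)
    aln_dir = outdir / "alignments"
    tree_dir = outdir / "gene_trees"
    aln_dir.mkdir(parents=True, exist_ok=True)
    tree_dir.mkdir(parents=True, exist_ok=True)

    sp = simulate_species_tree(cfg)
    lengths = marker_lengths(cfg)
    gene_trees = simulate_gene_trees(sp, lengths, cfg)
    sp_splits = _splits(sp.tree)

    manifest_rows = []
    all_taxa = set(sp.leaf_labels())
    for i, (rec, length) in enumerate(zip(gene_trees, lengths)):
        aln = simulate_sequences(rec, length, seed=cfg.seed + 10 + i)
        write_alignment(aln, aln_dir / f"{rec.marker_id}.fasta")
        write_tree(rec, tree_dir / f"{rec.marker_id}.nwk")
        leaves = frozenset(rec.leaf_labels())
        discordant = sum(
            1 for s in _splits(rec.tree)
            if s not in {_restrict(t, leaves) for t in sp_splits}
        )
        manifest_rows.append({
            "marker_id": rec.marker_id,
            "length_bp": length,
            "n_nni": getattr(rec, "nni_count", 0),
            "n_discordant_splits": discordant,
            "dropped_taxa": ",".join(sorted(all_taxa - leaves)),
        })

    sp_path = outdir / "species_tree.nwk"
    write_tree(sp, sp_path)
    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
    return {
        "alignments": aln_dir,
        "gene_trees": tree_dir,
        "species_tree": sp_path,
        "manifest": manifest_path,
    }
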