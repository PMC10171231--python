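"""Supermatrix concatenation, gene jackknifing, and clade frequencies.

Concatenation lays markers left to right in input order, gap-filling
('-') every roster taxon absent from a marker.  Exon-class markers with
a verified reading frame receive three codon partitions; all other
markers get one partition each.

The gene jackknife draws markers without replacement (fresh seeded
permutation per replicate) until the cumulative length first reaches the
base-pair target, so replicate matrices slightly overshoot the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aln_stats import TaxonRoster
from .phyio import Alignment, GeneTreeRecord, PartitionScheme

logger = logging.getLogger(__name__)


@dataclass
class Supermatrix:
    alignment: Alignment
    scheme: PartitionScheme
    source_ids: list[str]


@dataclass(frozen=True)
class JackknifeReplicate:
    replicate_index: int
    marker_ids: tuple[str, ...]
    total_bp: int
    seed: int


def concatenate(
    alns: list[Alignment],
    roster: TaxonRoster,
    frames: dict[str, int] | None = None,
) -> Supermatrix:
    """Concatenate markers into one gap-filled, partitioned matrix.

    ``frames`` maps exon marker ids to a verified reading-frame offset
    (1/2/3); exon markers are assumed already trimmed to whole codons of
    that frame, so their codon partitions start at offsets 1/2/3 within
    the marker's span.  Exons without a verified frame fall back to a
    single per-marker partition, with a warning.
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    ids = [a.marker_id for a in alns]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate marker ids {dupes}")
    roster_set = set(roster.taxa)
    for a in alns:
        extra = set(a.taxa) - roster_set
        if extra:
            raise ValueError(
                f"marker {a.marker_id!r} has taxa outside roster: {sorted(extra)}"
            )
    frames = frames or {}

    pieces: dict[str, list[str]] = {t: [] for t in roster.taxa}
    entries: list[tuple[str, list[tuple[int, int]], int | None]] = []
    pos = 0  # 0-based running offset
    for a in alns:
        span = (pos + 1, pos + a.length)  # 1-based inclusive
        if a.marker_class == "exon":
            if a.marker_id in frames:
                for codon_pos in (1, 2, 3):
                    entries.append(
                        (f"{a.marker_id}_pos{codon_pos}", [span], codon_pos)
                    )
            else:
                logger.warning(
                    "exon %s has no verified reading frame; using a single "
                    "per-marker partition", a.marker_id,
                )
                entries.append((a.marker_id, [span], None))
        else:
            entries.append((a.marker_id, [span], None))
        for taxon in roster.taxa:
            pieces[taxon].append(a.rows.get(taxon, "-" * a.length))
        pos += a.length

    rows = {t: "".join(chunks) for t, chunks in pieces.items()}
    aln = Alignment("supermatrix", "unified", rows)
    scheme = PartitionScheme(entries)
    scheme.validate(total_length=pos)
    return Supermatrix(aln, scheme, ids)


def gene_jackknife(
    alns: list[Alignment],
    target_bp: int = 200_000,
    n_replicates: int = 1,
    seed: int = 0,
    roster: TaxonRoster | None = None,
    materialize: bool = False,
) -> list[JackknifeReplicate] | list[tuple[JackknifeReplicate, Supermatrix]]:
    """Draw seeded jackknife replicates of whole markers.

    Each replicate permutes the markers and takes them in order until
    the cumulative length first reaches ``target_bp`` (minimum one
    marker).  With ``materialize=True`` each replicate is also
    concatenated into a :class:`Supermatrix` (requires ``roster``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    total_available = sum(a.length for a in alns)
    if total_available < target_bp:
        raise ValueError(
            f"only {total_available} bp available, target is {target_bp}"
        )
    if materialize and roster is None:
        raise ValueError("materialize=True requires a roster")

    by_id = {a.marker_id: a for a in alns}
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_replicates):
        order = rng.permutation(len(alns))
        chosen: list[str] = []
        total = 0
        for idx in order:
            a = alns[idx]
            chosen.append(a.marker_id)
            total += a.length
            if total >= target_bp:
                break
        replicate = JackknifeReplicate(rep, tuple(chosen), total, seed)
        if materialize:
            sm = concatenate([by_id[m] for m in chosen], roster)
            out.append((replicate, sm))
        else:
            out.append(replicate)
    return out


def _nontrivial_bipartitions(record: GeneTreeRecord) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, each as the smaller-or-
    lexicographically-first side normalized against the full leaf set."""
    leaves = frozenset(record.leaf_labels())
    splits: set[frozenset[str]] = set()
    tree = record.tree
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        below = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        splits.add(_canonical_split(below, leaves))
    return splits


def _canonical_split(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    other = leaves - side
    if (len(side), sorted(side)) <= (len(other), sorted(other)):
        return side
    return other


def clade_frequencies(trees: list[GeneTreeRecord]) -> pd.DataFrame:
    """Frequency of each observed non-trivial bipartition across trees.

    Trees may have different leaf sets; the denominator for a split is
    the number of trees in which it is observable (>= 2 leaves on each
    side after restriction to that tree's leaves).
    """
    if not trees:
        raise ValueError("need at least one tree")
    tree_splits: list[set[frozenset[str]]] = []
    tree_leaves: list[frozenset[str]] = []
    for rec in trees:
        tree_leaves.append(frozenset(rec.leaf_labels()))
        tree_splits.append(_nontrivial_bipartitions(rec))

    all_splits: set[frozenset[str]] = set()
    for splits in tree_splits:
        all_splits |= splits

    rows = []
    for split in sorted(all_splits, key=lambda s: (len(s), sorted(s))):
        observable = 0
        count = 0
        for splits, leaves in zip(tree_splits, tree_leaves):
            side = frozenset(split & leaves)
            if len(side) < 2 or len(leaves - side) < 2:
                continue
            observable += 1
            if _canonical_split(side, leaves) in splits:
                count += 1
        rows.append({
            "bipartition": "|".join(sorted(split)),
            "frequency": count / observable if observable else float("nan"),
            "n_present": count,
            "n_observable": observable,
        })
    return pd.DataFrame(rows)
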