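"""Threshold-series generation and alignment/gene-tree filtration.

Each sweep filters on one statistic at a time with a keep-if-at-least
(``>=``) comparator, so survivor sets are nested across an ascending
threshold series.  Gene trees are paired to alignments by marker id
(file stem).

The built-in series reproduce the published sweeps.  Two of the printed
set sizes are internally inconsistent with their own range definitions
(the summary-tree PIS-count range yields 16 distinct values, and the
concatenation PIS-count list enumerates 9); the literal ranges/lists are
used, not padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aln_stats import STATISTICS
from .phyio import GeneTreeRecord

MODES = ("summary_tree", "concatenation")

_SERIES: dict[tuple[str, str], list[float]] = {
    # summary-tree sweeps (ASTRAL / SVDquartets inputs)
    ("sampling_prop", "summary_tree"): [round(0.05 * i, 2) for i in range(1, 21)],
    ("prop_pis", "summary_tree"): [round(0.05 * i, 2) for i in range(1, 21)],
    ("n_pis", "summary_tree"): (
        list(range(10, 101, 10)) + list(range(200, 701, 100))
    ),
    ("length_bp", "summary_tree"): list(range(100, 3001, 100)),
    # concatenation sweeps (fewer thresholds)
    ("sampling_prop", "concatenation"): [round(0.1 * i, 1) for i in range(1, 11)],
    ("prop_pis", "concatenation"): [round(0.1 * i, 1) for i in range(1, 11)],
    ("n_pis", "concatenation"): [10, 30, 50, 70, 100, 200, 500, 700, 1000],
    ("length_bp", "concatenation"): [200, 500, 700, 1000, 1200, 1500, 1700,
                                     2000, 2200, 2500],
}


@dataclass(frozen=True)
class FilterScheme:
    statistic: str
    thresholds: tuple[float, ...]
    mode: str

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(t < 0 for t in self.thresholds):
            raise ValueError("thresholds must be >= 0")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly ascending")


def make_threshold_series(statistic: str, mode: str) -> FilterScheme:
    """Return the built-in threshold series for one statistic and mode."""
    key = (statistic, mode)
    if key not in _SERIES:
        raise ValueError(f"no built-in series for {statistic!r} / {mode!r}")
    return FilterScheme(statistic, tuple(_SERIES[key]), mode)


def filter_alignments(
    stats: pd.DataFrame, statistic: str, threshold: float
) -> set[str]:
    """Marker ids whose ``statistic`` is at or above ``threshold``."""
    if statistic not in stats.columns:
        raise ValueError(f"statistic {statistic!r} not in stats table")
    mask = stats[statistic] >= threshold
    return set(stats.loc[mask, "marker_id"])


def filter_gene_trees(
    trees: list[GeneTreeRecord],
    stats: pd.DataFrame,
    statistic: str,
    threshold: float,
    strict: bool = True,
) -> list[GeneTreeRecord]:
    """Keep trees whose paired alignment passes the filter, in order.

    In strict mode a tree with no stats row is an error; in lenient
    mode it is dropped with a warning.
    """
    known = set(stats["marker_id"])
    orphans = [t.marker_id for t in trees if t.marker_id not in known]
    if orphans:
        if strict:
            raise ValueError(f"gene trees without stats rows: {sorted(orphans)}")
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d gene trees without stats rows", len(orphans)
        )
    survivors = filter_alignments(stats, statistic, threshold)
    return [t for t in trees if t.marker_id in survivors]


def sweep(
    trees: list[GeneTreeRecord],
    stats: pd.DataFrame,
    scheme: FilterScheme,
    strict: bool = True,
) -> pd.DataFrame:
    """Run the full threshold series; one report row per threshold.

    Columns: threshold, n_survivors, survivor marker ids
    (comma-joined), total_bp, total_pis.
    """
    indexed = stats.set_index("marker_id")
    rows = []
    for threshold in scheme.thresholds:
        kept = filter_gene_trees(trees, stats, scheme.statistic, threshold,
                                 strict=strict)
        ids = [t.marker_id for t in kept]
        rows.append({
            "threshold": threshold,
            "n_survivors": len(ids),
            "marker_ids": ",".join(ids),
            "total_bp": int(indexed.loc[ids, "length_bp"].sum()) if ids else 0,
            "total_pis": int(indexed.loc[ids, "n_pis"].sum()) if ids else 0,
        })
    return pd.DataFrame(rows)
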