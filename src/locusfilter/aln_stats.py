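"""Per-alignment summary statistics used by the filtration sweeps.

The four filtration statistics are: taxon sampling proportion, number of
parsimony-informative sites (PIS), proportion of PIS, and alignment
length.  A PIS is a column with at least two unambiguous states
(A/C/G/T) each present in at least two rows; gaps, N and '?' never count
as states.  Missing-data proportion is also tracked per alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .phyio import Alignment, MISSING, UNAMBIGUOUS

STATISTICS = ("sampling_prop", "prop_pis", "n_pis", "length_bp")


@dataclass(frozen=True)
class TaxonRoster:
    """The fixed study-wide sample list (denominator of sampling_prop)."""

    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("roster must be non-empty")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("roster taxa must be unique")

    def __len__(self) -> int:
        return len(self.taxa)

    def __contains__(self, name: str) -> bool:
        return name in set(self.taxa)

    @classmethod
    def from_file(cls, path) -> "TaxonRoster":
        names = [ln.strip() for ln in open(path) if ln.strip()]
        return cls(tuple(names))


@dataclass(frozen=True)
class AlignmentStats:
    marker_id: str
    length_bp: int
    n_samples: int
    sampling_prop: float
    n_pis: int
    prop_pis: float
    missing_bp_prop: float


def count_pis(aln: Alignment) -> int:
    """Count parsimony-informative columns (two states, each twice)."""
    n = 0
    for col in aln.columns():
        counts = Counter(c for c in col if c in UNAMBIGUOUS)
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n


def summarize_alignment(aln: Alignment, roster: TaxonRoster) -> AlignmentStats:
    """Compute the filtration statistics for one alignment."""
    roster_set = set(roster.taxa)
    for name in aln.taxa:
        if name not in roster_set:
            raise ValueError(f"alignment taxon {name!r} not in roster")
    length = aln.length
    n_samples = aln.n_taxa
    n_pis = count_pis(aln)
    missing = sum(seq.count(ch) for seq in aln.rows.values() for ch in MISSING)
    return AlignmentStats(
        marker_id=aln.marker_id,
        length_bp=length,
        n_samples=n_samples,
        sampling_prop=n_samples / len(roster),
        n_pis=n_pis,
        prop_pis=n_pis / length,
        missing_bp_prop=missing / (n_samples * length),
    )


def summarize_set(
    alns: list[Alignment], roster: TaxonRoster
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize a set of alignments.

    Returns ``(per_marker, aggregates)``: one row per alignment, plus a
    set-level table with mean, sd, min, max per statistic and totals for
    length and PIS.
    """
    ids = [a.marker_id for a in alns]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate marker ids {dupes}")
    rows = [summarize_alignment(a, roster).__dict__ for a in alns]
    table = pd.DataFrame(
        rows,
        columns=[
            "marker_id", "length_bp", "n_samples", "sampling_prop",
            "n_pis", "prop_pis", "missing_bp_prop",
        ],
    )
    stat_cols = ["length_bp", "n_samples", "sampling_prop", "n_pis",
                 "prop_pis", "missing_bp_prop"]
    if table.empty:
        agg = pd.DataFrame(
            index=stat_cols, columns=["mean", "sd", "min", "max", "total"],
            dtype=float,
        )
    else:
        agg = pd.DataFrame({
            "mean": table[stat_cols].mean(),
            "sd": table[stat_cols].std(ddof=1),
            "min": table[stat_cols].min(),
            "max": table[stat_cols].max(),
        })
        agg["total"] = float("nan")
        agg.loc["length_bp", "total"] = table["length_bp"].sum()
        agg.loc["n_pis", "total"] = table["n_pis"].sum()
    return table, agg
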