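"""Post-alignment quality-control operators.

Five screens applied after alignment: reference-divergence removal,
minimum taxa/length keep rule, external end trimming to a coverage
floor, window-based masking of locally misaligned sequence, and
reading-frame selection for coding markers.

Comparisons against the divergence and size thresholds are strict
(``>``), and the end-coverage floor is inclusive (``>=``); the keep rule
requires strictly more taxa/bp than the configured minima.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .phyio import Alignment, MISSING, UNAMBIGUOUS

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class QCConfig:
    ref_divergence_max: float = 0.40
    min_taxa_exclusive: int = 3
    min_len_exclusive: int = 100
    end_coverage_min: float = 0.50
    window_len: int = 100
    window_divergence_max: float = 0.40
    orf_inclusion_min: float = 0.90

    def __post_init__(self) -> None:
        for name in ("ref_divergence_max", "end_coverage_min",
                     "window_divergence_max", "orf_inclusion_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.window_len < 1 or self.min_len_exclusive < 1:
            raise ValueError("lengths must be >= 1")


@dataclass
class QCLogEntry:
    """One removal/mask action, serializable to the QC log TSV."""

    marker_id: str
    taxon: str
    action: str
    detail: str


class FrameSelectionError(ValueError):
    """No reading frame includes enough stop-free sequences."""


def pdistance(s1: str, s2: str) -> float | None:
    """Proportion of mismatches over sites unambiguous in both sequences.

    Returns ``None`` when no site is comparable.
    """
    if len(s1) != len(s2):
        raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
    compared = 0
    mismatches = 0
    for a, b in zip(s1, s2):
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS:
            compared += 1
            if a != b:
                mismatches += 1
    if compared == 0:
        return None
    return mismatches / compared


def screen_reference_divergence(
    aln: Alignment,
    ref_taxon: str,
    cfg: QCConfig | None = None,
    log: list[QCLogEntry] | None = None,
) -> Alignment:
    """Drop rows too divergent from the reference; drop the reference too.

    A row is removed when its p-distance to the reference row exceeds
    ``cfg.ref_divergence_max`` (strictly).  Rows with no comparable
    sites are kept.
    """
    cfg = cfg or QCConfig()
    if ref_taxon not in aln.rows:
        raise ValueError(f"reference taxon {ref_taxon!r} not in alignment "
                         f"{aln.marker_id!r}")
    ref = aln.rows[ref_taxon]
    kept: dict[str, str] = {}
    for name, seq in aln.rows.items():
        if name == ref_taxon:
            continue
        d = pdistance(seq, ref)
        if d is not None and d > cfg.ref_divergence_max:
            if log is not None:
                log.append(QCLogEntry(aln.marker_id, name, "removed_divergent",
                                      f"pdist={d:.4f}"))
            continue
        kept[name] = seq
    if not kept:
        raise ValueError(
            f"alignment {aln.marker_id!r}: no rows survive reference screen"
        )
    return aln.replace_rows(kept)


def qc_keep(aln: Alignment, cfg: QCConfig | None = None) -> bool:
    """Keep rule: strictly more taxa and more bp than the minima."""
    cfg = cfg or QCConfig()
    return aln.n_taxa > cfg.min_taxa_exclusive and aln.length > cfg.min_len_exclusive


def _column_coverage(aln: Alignment, i: int) -> float:
    col = aln.column(i)
    return sum(1 for c in col if c in UNAMBIGUOUS) / len(col)


def trim_external(aln: Alignment, cfg: QCConfig | None = None) -> Alignment:
    """Trim leading/trailing columns until end coverage >= the floor.

    Coverage counts rows with an unambiguous nucleotide; interior
    columns are never touched.
    """
    cfg = cfg or QCConfig()
    left = 0
    while left < aln.length and _column_coverage(aln, left) < cfg.end_coverage_min:
        left += 1
    if left == aln.length:
        raise ValueError(
            f"alignment {aln.marker_id!r}: no column meets end coverage "
            f"{cfg.end_coverage_min}"
        )
    right = aln.length - 1
    while _column_coverage(aln, right) < cfg.end_coverage_min:
        right -= 1
    if left == 0 and right == aln.length - 1:
        return aln
    return aln.replace_rows(
        {name: seq[left:right + 1] for name, seq in aln.rows.items()}
    )


def _consensus(aln: Alignment) -> str:
    """Majority-rule consensus over unambiguous states, ties alphabetical.

    Columns with no unambiguous state yield 'N' (never comparable).
    """
    out = []
    for col in aln.columns():
        counts: dict[str, int] = {}
        for c in col:
            if c in UNAMBIGUOUS:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("N")
            continue
        best = max(counts.values())
        winners = sorted(c for c, v in counts.items() if v == best)
        if len(winners) > 1:
            logger.debug("consensus tie %s at column %d", winners, len(out))
        out.append(winners[0])
    return "".join(out)


def _windows(length: int, window_len: int) -> list[tuple[int, int]]:
    """Non-overlapping [start, end) windows; a final partial window is
    kept if >= half a window long, else merged into the previous one."""
    if length <= window_len:
        return [(0, length)]
    bounds = list(range(0, length, window_len))
    windows = [(b, min(b + window_len, length)) for b in bounds]
    last_start, last_end = windows[-1]
    if last_end - last_start < math.ceil(window_len / 2) and len(windows) > 1:
        prev_start, _ = windows[-2]
        windows = windows[:-2] + [(prev_start, last_end)]
    return windows


def mask_divergent_windows(
    aln: Alignment,
    cfg: QCConfig | None = None,
    log: list[QCLogEntry] | None = None,
) -> Alignment:
    """Replace windows > the divergence threshold from consensus with Ns.

    The consensus is the per-column majority state; each row is compared
    to it over non-overlapping windows of ``cfg.window_len`` columns.
    Dimensions never change.
    """
    cfg = cfg or QCConfig()
    consensus = _consensus(aln)
    windows = _windows(aln.length, cfg.window_len)
    new_rows: dict[str, str] = {}
    for name, seq in aln.rows.items():
        pieces = []
        pos = 0
        for start, end in windows:
            segment = seq[start:end]
            d = pdistance(segment, consensus[start:end])
            if d is not None and d > cfg.window_divergence_max:
                pieces.append("N" * (end - start))
                if log is not None:
                    log.append(QCLogEntry(
                        aln.marker_id, name, "masked_window",
                        f"cols={start + 1}-{end} pdist={d:.4f}"))
            else:
                pieces.append(segment)
            pos = end
        new_rows[name] = "".join(pieces)
        assert len(new_rows[name]) == aln.length
    return aln.replace_rows(new_rows)


def _has_internal_stop(seq: str, offset: int) -> bool:
    """Stop-codon scan of ``seq`` read in frame ``offset`` (1-based).

    Codons containing gap/missing characters are skipped; only full
    codons are read.
    """
    start = offset - 1
    end = start + ((len(seq) - start) // 3) * 3
    for i in range(start, end, 3):
        codon = seq[i:i + 3]
        if any(c in MISSING for c in codon):
            continue
        if codon in STOP_CODONS:
            return True
    return False


def select_reading_frame(
    aln: Alignment, cfg: QCConfig | None = None
) -> tuple[int, Alignment]:
    """Pick the reading frame including the most stop-free rows.

    Ties break toward the smaller offset.  The alignment is trimmed to
    whole codons of the chosen frame.  Raises
    :class:`FrameSelectionError` when the best frame's inclusion is not
    strictly above ``cfg.orf_inclusion_min``.
    """
    cfg = cfg or QCConfig()
    inclusion: dict[int, int] = {}
    for offset in (1, 2, 3):
        inclusion[offset] = sum(
            0 if _has_internal_stop(seq, offset) else 1
            for seq in aln.rows.values()
        )
    best_offset = max((1, 2, 3), key=lambda o: (inclusion[o], -o))
    frac = inclusion[best_offset] / aln.n_taxa
    if frac <= cfg.orf_inclusion_min:
        raise FrameSelectionError(
            f"alignment {aln.marker_id!r}: best frame {best_offset} includes "
            f"only {frac:.2%} of sequences (need > {cfg.orf_inclusion_min:.0%})"
        )
    start = best_offset - 1
    n_codons = (aln.length - start) // 3
    end = start + n_codons * 3
    if n_codons == 0:
        raise FrameSelectionError(
            f"alignment {aln.marker_id!r}: too short for a codon in frame "
            f"{best_offset}"
        )
    if start == 0 and end == aln.length:
        return best_offset, aln
    return best_offset, aln.replace_rows(
        {name: seq[start:end] for name, seq in aln.rows.items()}
    )
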