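"""Reading and writing of alignments, trees, and partition schemes.

Alignments are stored as ordered taxon -> sequence maps over the DNA
alphabet ``{A, C, G, T, N, -, ?}``; input is normalized (upper-cased,
``U`` -> ``T``) on read.  Trees are parsed with :mod:`dendropy`; integer
internal-node labels are interpreted as bootstrap support values in
``[0, 100]`` (the IQ-Tree convention), while non-integer labels are kept
as plain labels and ignored by support-aware operations.

All partition/interval coordinates written to disk are 1-based inclusive
(RAxML/NEXUS convention); in-memory interval arithmetic is 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-?")
UNAMBIGUOUS = frozenset("ACGT")
#: characters that denote a missing/unknown base ('?' is equivalent to 'N')
MISSING = frozenset("N-?")

MARKER_CLASSES = ("exon", "intron", "uce", "gene", "unified")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


def _normalize(seq: str, *, context: str = "") -> str:
    out = seq.upper().replace("U", "T")
    bad = set(out) - ALPHABET
    if bad:
        raise FormatError(
            f"illegal characters {sorted(bad)} in sequence {context!r}"
        )
    return out


@dataclass
class Alignment:
    """One per-marker multiple sequence alignment.

    Parameters
    ----------
    marker_id:
        Identifier of the marker (typically the source file stem).
    marker_class:
        One of ``exon``, ``intron``, ``uce``, ``gene``, ``unified``.
    rows:
        Ordered mapping of taxon name to aligned sequence.  All
        sequences must have identical, nonzero length.
    """

    marker_id: str
    marker_class: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {self.marker_class!r}")
        if not self.rows:
            raise ValueError(f"alignment {self.marker_id!r} has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            for name, seq in self.rows.items():
                if len(seq) != len(next(iter(self.rows.values()))):
                    raise FormatError(
                        f"ragged alignment {self.marker_id!r}: row {name!r} "
                        f"has length {len(seq)}"
                    )
        if lengths == {0}:
            raise ValueError(f"alignment {self.marker_id!r} has zero length")
        for name, seq in self.rows.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise FormatError(
                    f"illegal characters {sorted(bad)} in row {name!r} "
                    f"of {self.marker_id!r}"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, i: int) -> str:
        """Return column ``i`` (0-based) as a string, one char per row."""
        return "".join(seq[i] for seq in self.rows.values())

    def columns(self) -> Iterator[str]:
        for i in range(self.length):
            yield self.column(i)

    def replace_rows(self, rows: dict[str, str]) -> "Alignment":
        return Alignment(self.marker_id, self.marker_class, rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.marker_id == other.marker_id
            and self.marker_class == other.marker_class
            and list(self.rows.items()) == list(other.rows.items())
        )


@dataclass
class GeneTreeRecord:
    """A marker id paired with its (unrooted) gene tree.

    The tree is a :class:`dendropy.Tree`; internal-node labels that are
    fully numeric integers are stored as edge support values in
    ``node.edge.support`` (int, 0-100).
    """

    marker_id: str
    tree: dendropy.Tree

    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def clone(self) -> "GeneTreeRecord":
        return GeneTreeRecord(self.marker_id, self.tree.clone(depth=1))

    def as_newick(self) -> str:
        return tree_to_newick(self.tree)


@dataclass
class PartitionScheme:
    """Named character sets tiling a supermatrix.

    ``entries`` holds ``(name, intervals, codon_offset)`` triples where
    intervals are 1-based inclusive ``(start, end)`` pairs and
    ``codon_offset`` is 1, 2, 3, or ``None`` for non-codon partitions.
    """

    entries: list[tuple[str, list[tuple[int, int]], int | None]] = field(
        default_factory=list
    )

    def total_length(self) -> int:
        return max((end for _, ivs, _ in self.entries for _, end in ivs), default=0)

    def validate(self, total_length: int | None = None) -> None:
        """Check that intervals tile ``1..total_length`` exactly once.

        Codon partitions (offset with step 3) are expanded to their
        member sites before coverage is checked.
        """
        covered: set[int] = set()
        for name, intervals, offset in self.entries:
            for start, end in intervals:
                if not 1 <= start <= end:
                    raise ValueError(f"bad interval {start}-{end} in {name!r}")
                if offset is None:
                    sites = range(start, end + 1)
                else:
                    sites = range(start + offset - 1, end + 1, 3)
                for s in sites:
                    if s in covered:
                        raise ValueError(f"site {s} covered twice ({name!r})")
                    covered.add(s)
        total = total_length if total_length is not None else self.total_length()
        expected = set(range(1, total + 1))
        if covered != expected:
            missing = sorted(expected - covered)[:5]
            raise ValueError(f"partition scheme does not tile matrix; "
                             f"first uncovered sites: {missing}")

    def to_raxml(self) -> str:
        """RAxML-style partition file: ``DNA, name = start-end[\\3]``."""
        lines = []
        for name, intervals, offset in self.entries:
            parts = []
            for start, end in intervals:
                if offset is None:
                    parts.append(f"{start}-{end}")
                else:
                    parts.append(f"{start + offset - 1}-{end}\\3")
            lines.append(f"DNA, {name} = {', '.join(parts)}")
        return "\n".join(lines) + "\n"

    def to_nexus_sets(self) -> str:
        """NEXUS ``sets`` block with one charset per entry."""
        lines = ["begin sets;"]
        for name, intervals, offset in self.entries:
            parts = []
            for start, end in intervals:
                if offset is None:
                    parts.append(f"{start}-{end}")
                else:
                    parts.append(f"{start + offset - 1}-{end}\\3")
            lines.append(f"    charset {name} = {' '.join(parts)};")
        lines.append("end;")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# alignment I/O


def _parse_fasta(text: str, path: Path) -> dict[str, str]:
    rows: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                rows[name] = _normalize("".join(chunks), context=name)
            name = line[1:].split()[0] if line[1:].split() else ""
            if not name:
                raise FormatError(f"{path}: empty FASTA header")
            if name in rows:
                raise FormatError(f"{path}: duplicate taxon name {name!r}")
            chunks = []
        else:
            if name is None:
                raise FormatError(f"{path}: sequence data before first header")
            chunks.append(line)
    if name is not None:
        if name in rows:
            raise FormatError(f"{path}: duplicate taxon name {name!r}")
        rows[name] = _normalize("".join(chunks), context=name)
    if not rows:
        raise FormatError(f"{path}: no FASTA records")
    return rows


def _parse_phylip(text: str, path: Path) -> dict[str, str]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) != 2 or not all(tok.isdigit() for tok in header):
        raise FormatError(f"{path}: malformed phylip header {lines[0]!r}")
    ntaxa, length = int(header[0]), int(header[1])
    rows: dict[str, str] = {}
    for ln in lines[1:]:
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed phylip row {ln!r}")
        name, seq = parts[0], parts[1].replace(" ", "")
        if name in rows:
            raise FormatError(f"{path}: duplicate taxon name {name!r}")
        rows[name] = _normalize(seq, context=name)
    if len(rows) != ntaxa:
        raise FormatError(
            f"{path}: header declares {ntaxa} taxa, found {len(rows)}"
        )
    for name, seq in rows.items():
        if len(seq) != length:
            raise FormatError(
                f"{path}: row {name!r} has length {len(seq)}, header says {length}"
            )
    return rows


def read_alignment(path: str | Path, marker_class: str = "unified") -> Alignment:
    """Read a FASTA or relaxed-Phylip alignment.

    Format is auto-detected from the first non-blank character ('>' for
    FASTA, a digit for Phylip).  The marker id is the file stem.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise FormatError(f"{path}: empty file")
    if stripped[0] == ">":
        rows = _parse_fasta(text, path)
    elif stripped[0].isdigit():
        rows = _parse_phylip(text, path)
    else:
        raise FormatError(f"{path}: cannot detect format (starts with "
                          f"{stripped[0]!r})")
    aln = Alignment(path.stem, marker_class, rows)
    return aln


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write ``aln`` to ``path`` as FASTA or relaxed Phylip.

    Round-trip property: ``read_alignment(write_alignment(aln))`` equals
    ``aln`` in names, order, and sequences.
    """
    if aln.length == 0:
        raise ValueError("refusing to write zero-length alignment")
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for name, seq in aln.rows.items():
                fh.write(f">{name}\n{seq}\n")
    elif format == "phylip":
        with path.open("w") as fh:
            fh.write(f"{aln.n_taxa} {aln.length}\n")
            for name, seq in aln.rows.items():
                fh.write(f"{name}  {seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# tree I/O

def _annotate_support(tree: dendropy.Tree) -> None:
    """Move integer internal-node labels onto edges as ``edge.support``."""
    for node in tree.preorder_node_iter():
        node.edge.support = None
        if node.is_leaf() or node.label is None:
            continue
        label = node.label.strip()
        if label.lstrip("+-").isdigit():
            val = int(label)
            if 0 <= val <= 100:
                node.edge.support = val
                node.label = None
                continue
        logger.debug("non-integer internal label %r kept as plain label", label)


def edge_length(edge: dendropy.Edge) -> float:
    """Branch length of ``edge``, with absent lengths read as 0."""
    return edge.length if edge.length is not None else 0.0


def parse_newick(newick: str, marker_id: str = "tree") -> GeneTreeRecord:
    """Parse one Newick string into a :class:`GeneTreeRecord`."""
    if newick.count("(") != newick.count(")"):
        opens = 0
        offset = len(newick)
        for i, ch in enumerate(newick):
            if ch == "(":
                opens += 1
            elif ch == ")":
                opens -= 1
                if opens < 0:
                    offset = i
                    break
        raise FormatError(
            f"unbalanced parentheses in newick near character {offset}"
        )
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    _annotate_support(tree)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels {dupes}")
    return GeneTreeRecord(marker_id, tree)


def read_tree(path: str | Path) -> GeneTreeRecord:
    """Read a single-tree Newick file; marker id is the file stem."""
    path = Path(path)
    return parse_newick(path.read_text().strip(), marker_id=path.stem)


def read_tree_list(path: str | Path) -> list[GeneTreeRecord]:
    """Read a multi-tree Newick file (one tree per line)."""
    path = Path(path)
    records = []
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if line:
            records.append(parse_newick(line, marker_id=f"{path.stem}_{i}"))
    return records


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree, writing edge support back as internal labels."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        sup = getattr(node.edge, "support", None)
        if sup is not None and not node.is_leaf():
            node.label = str(sup)
    return clone.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def write_tree(record: GeneTreeRecord, path: str | Path) -> None:
    Path(path).write_text(record.as_newick() + "\n")


def write_tree_list(records: Iterable[GeneTreeRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(rec.as_newick() + "\n")
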