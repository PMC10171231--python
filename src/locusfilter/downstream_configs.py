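"""Writers for the external species-tree programs' input files.

Three dialects are emitted: BPP v4 A01 (species-tree estimation)
control/sequence/imap files, SVDquartets-ready NEXUS with a PAUP block,
and collapsed multi-tree Newick for quartet-based summary methods.
Output is deterministic: fixed ordering, no timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .phyio import Alignment, GeneTreeRecord
from .supermatrix import Supermatrix
from .treemetrics import collapse_low_support


@dataclass
class BPPControlSettings:
    """MCMC settings for a BPP A01 run.

    Defaults mirror a long species-tree-search run: burnin 10000,
    sample frequency 2, 100000 samples, gamma(3, 0.004) priors on both
    theta and tau.  ``species_map`` maps each sample to its population;
    by default every sample is its own population.
    """

    burnin: int = 10_000
    sampfreq: int = 2
    nsample: int = 100_000
    theta_prior: tuple[float, float] = (3, 0.004)
    tau_prior: tuple[float, float] = (3, 0.004)
    species_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("burnin", "sampfreq", "nsample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def write_bpp(
    alns: list[Alignment],
    settings: BPPControlSettings,
    outdir: str | Path,
    stem: str = "bpp",
) -> tuple[Path, Path, Path]:
    """Write BPP A01 control, sequence, and imap files.

    Returns the three paths (control, sequence, imap).  The sequence
    file holds one Phylip-like block per alignment with taxon labels
    carrying the ``^sample`` suffix BPP expects; nloci equals the number
    of alignments.
    """
    if not alns:
        raise ValueError("need at least one alignment")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_taxa: list[str] = []
    for a in alns:
        for t in a.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    species_map = settings.species_map or {t: t for t in all_taxa}
    missing = [t for t in all_taxa if t not in species_map]
    if missing:
        raise ValueError(f"taxa missing from species_map: {missing}")
    populations = sorted(set(species_map.values()))

    seq_path = outdir / f"{stem}.seq.txt"
    with seq_path.open("w") as fh:
        for a in alns:
            fh.write(f"{a.n_taxa} {a.length}\n")
            for name, seq in a.rows.items():
                fh.write(f"{name}^{name}  {seq}\n")
            fh.write("\n")

    imap_path = outdir / f"{stem}.imap.txt"
    with imap_path.open("w") as fh:
        for taxon in all_taxa:
            fh.write(f"{taxon} {species_map[taxon]}\n")

    ctl_path = outdir / f"{stem}.ctl"
    ta, tb = settings.theta_prior
    ua, ub = settings.tau_prior
    pop_line = " ".join(populations)
    # one sample per population by default; counts follow imap
    counts = {p: 0 for p in populations}
    for t in all_taxa:
        counts[species_map[t]] += 1
    count_line = " ".join(str(counts[p]) for p in populations)
    star_tree = "(" + ",".join(populations) + ");"
    lines = [
        f"seed = 1",
        f"seqfile = {seq_path.name}",
        f"Imapfile = {imap_path.name}",
        f"outfile = {stem}.out.txt",
        f"mcmcfile = {stem}.mcmc.txt",
        "",
        "* A01: species tree estimation, fixed assignments",
        "speciesdelimitation = 0",
        "speciestree = 1",
        "",
        f"species&tree = {len(populations)} {pop_line}",
        f"                {count_line}",
        f"                {star_tree}",
        "",
        "* documented defaults, stated for auditability",
        "usedata = 1",
        "cleandata = 0",
        "",
        f"nloci = {len(alns)}",
        "",
        f"thetaprior = gamma {ta:g} {tb:g}",
        f"tauprior = gamma {ua:g} {ub:g}",
        "",
        "finetune = 1",
        "print = 1 0 0 0",
        f"burnin = {settings.burnin}",
        f"sampfreq = {settings.sampfreq}",
        f"nsample = {settings.nsample}",
    ]
    ctl_path.write_text("\n".join(lines) + "\n")
    return ctl_path, seq_path, imap_path


def write_svdq_nexus(
    supermatrix: Supermatrix, outpath: str | Path, nreps: int = 1000
) -> Path:
    """Write a NEXUS file with DATA, SETS, and PAUP blocks for SVDquartets.

    The PAUP block evaluates quartets exhaustively with multilocus
    bootstrapping.
    """
    outpath = Path(outpath)
    aln = supermatrix.alignment
    lines = [
        "#NEXUS",
        "",
        "begin data;",
        f"    dimensions ntax={aln.n_taxa} nchar={aln.length};",
        "    format datatype=dna missing=? gap=-;",
        "    matrix",
    ]
    width = max(len(t) for t in aln.taxa) + 2
    for name, seq in aln.rows.items():
        lines.append(f"    {name:<{width}}{seq}")
    lines += ["    ;", "end;", ""]
    lines.append(supermatrix.scheme.to_nexus_sets().rstrip("\n"))
    lines += [
        "",
        "begin paup;",
        f"    svdquartets evalq=all bootstrap=multilocus nreps={nreps};",
        "    savetrees file=svdq.tre;",
        "end;",
    ]
    outpath.write_text("\n".join(lines) + "\n")
    return outpath


def prepare_astral_input(
    trees: list[GeneTreeRecord],
    outpath: str | Path,
    collapse_threshold: int = 10,
) -> Path:
    """Collapse low-support branches and write one Newick per line."""
    if not trees:
        raise ValueError("need at least one tree")
    outpath = Path(outpath)
    with outpath.open("w") as fh:
        for rec in trees:
            collapsed = collapse_low_support(rec, threshold=collapse_threshold)
            fh.write(collapsed.as_newick() + "\n")
    return outpath
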