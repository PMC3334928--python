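"""Supermatrix assembly from per-gene codon alignments.

Concatenates gene regions over a shared taxon set, records gene-boundary
coordinates and a taxon x gene presence design (deliberately incomplete
sampling leaves whole gene blocks missing for some taxa), subsets to gene
lists such as a "core-gene complete" matrix, and computes matrix statistics.

Missing cells are filled with ``?`` (the NEXUS/PHYLIP missing symbol); FASTA
export can substitute ``N`` for consumers that require it.  Whole-gene
absence is tracked in the presence matrix, distinct from present-but-gappy
sequences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon_recoding import CodonAlignment, ExclusionMask, InvalidArgumentError

MISSING = "?"


@dataclass
class SuperMatrix:
    """Concatenated gene regions with block coordinates and presence design.

    ``gene_blocks`` maps gene label -> half-open 0-based column interval;
    the intervals tile ``[0, total_sites)`` in order.  ``presence[i][g]`` is
    True when taxon ``i`` was sampled for gene ``g`` (absence means the
    whole block is ``?`` for that taxon).
    """

    taxa: list[str]
    sequences: list[str]
    gene_blocks: dict[str, tuple[int, int]]
    presence: np.ndarray  # bool, taxa x genes
    mask_note: str = ""

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        n = self.total_sites
        pos = 0
        for g, (a, b) in self.gene_blocks.items():
            if (a, b) != (pos, b) or b < a:
                raise InvalidArgumentError(f"gene blocks must tile columns; bad {g}")
            pos = b
        if pos != n:
            raise InvalidArgumentError("gene blocks do not cover the matrix")
        for s in self.sequences:
            if len(s) != n:
                raise InvalidArgumentError("sequence length != total_sites")
        if self.presence.shape != (len(self.taxa), len(self.gene_blocks)):
            raise InvalidArgumentError("presence matrix has wrong shape")

    # -- basic accessors ----------------------------------------------------

    @property
    def total_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def genes(self) -> list[str]:
        return list(self.gene_blocks)

    def gene_alignment(self, gene: str) -> CodonAlignment:
        try:
            a, b = self.gene_blocks[gene]
        except KeyError:
            raise InvalidArgumentError(f"unknown gene {gene!r}")
        return CodonAlignment(list(self.taxa),
                              [s[a:b] for s in self.sequences], gene)

    def drop_columns(self, columns: set[int]) -> "SuperMatrix":
        """Return a copy with the given 0-based columns removed and gene
        boundaries remapped."""
        n = self.total_sites
        keep = np.ones(n, dtype=bool)
        for c in columns:
            if not 0 <= c < n:
                raise InvalidArgumentError(f"column {c} out of bounds (0..{n - 1})")
            keep[c] = False
        kept_idx = np.flatnonzero(keep)
        new_seqs = ["".join(s[i] for i in kept_idx) for s in self.sequences]
        new_blocks: dict[str, tuple[int, int]] = {}
        pos = 0
        for g, (a, b) in self.gene_blocks.items():
            width = int(keep[a:b].sum())
            new_blocks[g] = (pos, pos + width)
            pos += width
        return SuperMatrix(list(self.taxa), new_seqs, new_blocks,
                           self.presence.copy(),
                           mask_note=f"{len(columns)} columns removed")


@dataclass
class MatrixStats:
    n_taxa: int
    n_genes: int
    total_sites: int
    sites_per_gene: dict[str, int] = field(default_factory=dict)
    percent_missing_cells: float = 0.0
    percent_missing_characters: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_taxa": self.n_taxa,
            "n_genes": self.n_genes,
            "total_sites": self.total_sites,
            "sites_per_gene": dict(self.sites_per_gene),
            "percent_missing_cells": self.percent_missing_cells,
            "percent_missing_characters": self.percent_missing_characters,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def concatenate(alignments: list[CodonAlignment],
                taxa: list[str] | None = None) -> SuperMatrix:
    """Concatenate per-gene alignments into a supermatrix.

    Gene order is preserved; a taxon absent from a gene's alignment gets a
    block of ``?`` and a False presence cell.  ``taxa`` fixes the row order
    (default: order of first appearance across genes).
    """
    labels = [a.gene_label or f"gene{k + 1}" for k, a in enumerate(alignments)]
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError(f"duplicate gene labels: {labels}")
    if taxa is None:
        taxa = []
        for a in alignments:
            for t in a.taxa:
                if t not in taxa:
                    taxa.append(t)
    else:
        for a in alignments:
            missing = set(a.taxa) - set(taxa)
            if missing:
                raise InvalidArgumentError(
                    f"gene {a.gene_label!r} has taxa outside the supplied set: "
                    f"{sorted(missing)}")
    blocks: dict[str, tuple[int, int]] = {}
    presence = np.zeros((len(taxa), len(alignments)), dtype=bool)
    rows = ["" for _ in taxa]
    pos = 0
    for g, (label, aln) in enumerate(zip(labels, alignments)):
        blocks[label] = (pos, pos + aln.n_sites)
        pos += aln.n_sites
        index = {t: i for i, t in enumerate(aln.taxa)}
        for i, t in enumerate(taxa):
            if t in index:
                rows[i] += aln.sequences[index[t]]
                presence[i, g] = True
            else:
                rows[i] += MISSING * aln.n_sites
    return SuperMatrix(list(taxa), rows, blocks, presence)


def subset_matrix(matrix: SuperMatrix, genes) -> SuperMatrix:
    """Retain only the requested gene blocks, remapping coordinates."""
    genes = list(genes)
    unknown = set(genes) - set(matrix.gene_blocks)
    if unknown:
        raise InvalidArgumentError(f"unknown gene label(s): {sorted(unknown)}")
    order = [g for g in matrix.gene_blocks if g in set(genes)]
    blocks: dict[str, tuple[int, int]] = {}
    pos = 0
    pieces = {g: matrix.gene_blocks[g] for g in order}
    rows = ["" for _ in matrix.taxa]
    for g in order:
        a, b = pieces[g]
        blocks[g] = (pos, pos + (b - a))
        pos += b - a
        for i in range(len(matrix.taxa)):
            rows[i] += matrix.sequences[i][a:b]
    gidx = [matrix.genes.index(g) for g in order]
    presence = matrix.presence[:, gidx] if order else np.zeros(
        (len(matrix.taxa), 0), dtype=bool)
    return SuperMatrix(list(matrix.taxa), rows, blocks, presence)


def matrix_stats(matrix: SuperMatrix) -> MatrixStats:
    """Deterministic tallies: dimensions, per-gene widths, missingness.

    ``percent_missing_cells`` is over the taxon x gene presence design;
    ``percent_missing_characters`` counts ``?`` characters over the full
    taxon x site grid.  Both are plain percentages (not rounded).
    """
    n_taxa, n_genes = len(matrix.taxa), len(matrix.gene_blocks)
    total = matrix.total_sites
    spg = {g: b - a for g, (a, b) in matrix.gene_blocks.items()}
    n_cells = n_taxa * n_genes
    pm_cells = (100.0 * (n_cells - int(matrix.presence.sum())) / n_cells
                if n_cells else 0.0)
    n_chars = n_taxa * total
    n_missing = sum(s.count(MISSING) for s in matrix.sequences)
    pm_chars = 100.0 * n_missing / n_chars if n_chars else 0.0
    return MatrixStats(n_taxa, n_genes, total, spg, pm_cells, pm_chars)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_fasta(alignment: CodonAlignment, handle, missing_as_n: bool = False) -> None:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        records = []
        for t, s in zip(alignment.taxa, alignment.sequences):
            if missing_as_n:
                s = s.replace(MISSING, "N")
            records.append(SeqRecord(Seq(s), id=t, description=""))
        SeqIO.write(records, handle, "fasta")
    finally:
        if close:
            handle.close()


def read_fasta(handle, gene_label: str = "") -> CodonAlignment:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle), True
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    return CodonAlignment([r.id for r in records],
                          [str(r.seq) for r in records], gene_label)


def write_phylip(alignment: CodonAlignment, handle) -> None:
    """Relaxed PHYLIP: full names, single space, one sequence per line."""
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        handle.write(f"{len(alignment.taxa)} {alignment.n_sites}\n")
        width = max((len(t) for t in alignment.taxa), default=0)
        for t, s in zip(alignment.taxa, alignment.sequences):
            handle.write(f"{t:<{width}} {s}\n")
    finally:
        if close:
            handle.close()


def read_phylip(handle, gene_label: str = "") -> CodonAlignment:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle), True
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if close:
            handle.close()
    n, _ = lines[0].split()
    taxa, seqs = [], []
    for ln in lines[1:1 + int(n)]:
        name, seq = ln.split(None, 1)
        taxa.append(name)
        seqs.append(seq.replace(" ", ""))
    return CodonAlignment(taxa, seqs, gene_label)


def write_nexus(matrix: SuperMatrix, handle, scheme=None) -> None:
    """NEXUS DATA block plus a SETS block with per-gene charsets (and the
    partition scheme's charsets when given)."""
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        handle.write("#NEXUS\nbegin data;\n")
        handle.write(f"    dimensions ntax={len(matrix.taxa)} "
                     f"nchar={matrix.total_sites};\n")
        handle.write("    format datatype=dna missing=? gap=-;\n    matrix\n")
        width = max((len(t) for t in matrix.taxa), default=0)
        for t, s in zip(matrix.taxa, matrix.sequences):
            handle.write(f"    {t:<{width}} {s}\n")
        handle.write("    ;\nend;\nbegin sets;\n")
        for g, (a, b) in matrix.gene_blocks.items():
            handle.write(f"    charset {g} = {a + 1}-{b};\n")
        if scheme is not None:
            for name, sites in scheme.sites.items():
                from .codon_recoding import _ranges_1based
                handle.write(f"    charset {name} = {_ranges_1based(sites)};\n")
        handle.write("end;\n")
    finally:
        if close:
            handle.close()


def write_supermatrix_fasta(matrix: SuperMatrix, handle, blocks_handle=None) -> None:
    """FASTA export; optional TSV sidecar with gene block coordinates."""
    aln = CodonAlignment(list(matrix.taxa), list(matrix.sequences))
    write_fasta(aln, handle)
    if blocks_handle is not None:
        close = False
        if isinstance(blocks_handle, str):
            blocks_handle, close = open(blocks_handle, "w"), True
        try:
            blocks_handle.write("gene\tstart\tend\n")
            for g, (a, b) in matrix.gene_blocks.items():
                blocks_handle.write(f"{g}\t{a}\t{b}\n")
        finally:
            if close:
                blocks_handle.close()


def read_supermatrix_fasta(handle, blocks_handle) -> SuperMatrix:
    """Rebuild a supermatrix from FASTA plus the gene-blocks TSV sidecar.

    Presence is inferred: a block that is entirely ``?`` for a taxon is
    recorded as absent.
    """
    aln = read_fasta(handle)
    close = False
    if isinstance(blocks_handle, str):
        blocks_handle, close = open(blocks_handle), True
    try:
        lines = [ln.strip() for ln in blocks_handle if ln.strip()]
    finally:
        if close:
            blocks_handle.close()
    blocks: dict[str, tuple[int, int]] = {}
    for ln in lines[1:]:
        g, a, b = ln.split("\t")
        blocks[g] = (int(a), int(b))
    presence = np.ones((len(aln.taxa), len(blocks)), dtype=bool)
    for gi, (g, (a, b)) in enumerate(blocks.items()):
        for i, s in enumerate(aln.sequences):
            if b > a and set(s[a:b]) == {MISSING}:
                presence[i, gi] = False
    return SuperMatrix(aln.taxa, aln.sequences, blocks, presence)


def write_presence_tsv(matrix: SuperMatrix, handle) -> None:
    close = False
    if isinstance(handle, str):
        handle, close = open(handle, "w"), True
    try:
        handle.write("taxon\t" + "\t".join(matrix.genes) + "\n")
        for i, t in enumerate(matrix.taxa):
            cells = "\t".join(str(int(x)) for x in matrix.presence[i])
            handle.write(f"{t}\t{cells}\n")
    finally:
        if close:
            handle.close()
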