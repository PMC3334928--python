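"""Degeneracy-aware codon recoding and codon-position partitioning.

This module implements "degen1" recoding — every codon position that can
undergo synonymous change within its amino-acid family is replaced by the
IUPAC ambiguity code spanning that family's states at the position, making
synonymous differences invisible to downstream inference — together with the
leucine/arginine-aware construction of the two-partition scheme used for
partitioned likelihood analyses:

* ``nonsyn_nt1_nt2`` — first-position sites in columns where no taxon encodes
  Leu or Arg (the only amino acids with first-position synonymous
  degeneracy), plus all second positions.  Changes here are essentially all
  non-synonymous.
* ``potsyn_nt1_nt3`` — the remaining first positions plus all third
  positions, where the great majority of change is synonymous.

Synonymous families are the transitive closure of single-nucleotide
synonymous steps over the sense codons of the (standard nuclear) genetic
code.  Under this closure serine falls into two families (four-fold TCN and
two-fold AGY, not connected by any single-nucleotide synonymous step), so
their degen1 images stay distinct and Ser1<->Ser2 differences remain visible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .matrix_builder import SuperMatrix

logger = logging.getLogger("degenphylo")

NUCLEOTIDES = "ACGT"

#: IUPAC single-letter code -> set of nucleotides it denotes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

GAP_CHARS = frozenset("-?")
VALID_CHARS = frozenset(IUPAC_CODES) | GAP_CHARS

STOP = "*"


class InvalidArgumentError(ValueError):
    """Raised when an operation receives arguments violating its contract."""


class StopCodonError(ValueError):
    """Raised in strict mode when an in-frame stop codon is encountered."""


# ---------------------------------------------------------------------------
# Genetic code table
# ---------------------------------------------------------------------------

def load_code_table(path=None) -> dict[str, str]:
    """Load a codon -> amino-acid table (one-letter codes, ``*`` = stop).

    By default the packaged standard nuclear genetic code is used; pass a
    path to a two-column TSV (codon, amino acid; ``#`` comments allowed) to
    override, e.g. for mitochondrial data.
    """
    if path is None:
        text = (
            resources.files("degenphylo")
            .joinpath("data/standard_nuclear_code.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split("\t")
        codon = codon.upper().replace("U", "T")
        if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
            raise InvalidArgumentError(f"malformed codon in code table: {codon!r}")
        table[codon] = aa
    if len(table) != 64:
        raise InvalidArgumentError(
            f"code table must define all 64 codons, got {len(table)}"
        )
    return table


@lru_cache(maxsize=None)
def _standard_code() -> Mapping[str, str]:
    return load_code_table()


def synonymous_families(code: Mapping[str, str] | None = None) -> list[frozenset[str]]:
    """Partition sense codons into synonymous families.

    A family is a connected component of the graph whose vertices are sense
    codons and whose edges join codons differing at exactly one position and
    encoding the same amino acid.  Stops are excluded.
    """
    code = code or _standard_code()
    sense = [c for c, aa in code.items() if aa != STOP]
    adj: dict[str, list[str]] = {c: [] for c in sense}
    for c in sense:
        for pos in range(3):
            for b in NUCLEOTIDES:
                if b == c[pos]:
                    continue
                d = c[:pos] + b + c[pos + 1:]
                if code.get(d) == code[c]:
                    adj[c].append(d)
    families: list[frozenset[str]] = []
    seen: set[str] = set()
    for c in sense:
        if c in seen:
            continue
        comp, stack = set(), [c]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x])
        seen |= comp
        families.append(frozenset(comp))
    return families


def _iupac_union(bases: Iterable[str]) -> str:
    return _SET_TO_CODE[frozenset(bases)]


@lru_cache(maxsize=4)
def _degen1_table_cached(code_items: tuple) -> dict[str, str]:
    code = dict(code_items)
    table: dict[str, str] = {}
    for fam in synonymous_families(code):
        image = "".join(
            _iupac_union({c[pos] for c in fam}) for pos in range(3)
        )
        for c in fam:
            table[c] = image
    for c, aa in code.items():
        if aa == STOP:
            table[c] = "NNN"  # lenient stop policy entry
    return table


def degen1_table(code: Mapping[str, str] | None = None) -> dict[str, str]:
    """Complete degen1 map over all 64 codons.

    Each sense codon maps to the codon whose positions are the IUPAC unions
    over its synonymous family (e.g. CAT -> CAY, CTA -> YTN, ATG -> ATG);
    stop codons carry the lenient policy image ``NNN``.
    """
    code = code or _standard_code()
    return dict(_degen1_table_cached(tuple(sorted(code.items()))))


def expand_codon(codon: str) -> list[str]:
    """All plain-nucleotide codons an IUPAC-ambiguous codon denotes."""
    out = [""]
    for ch in codon:
        try:
            bases = IUPAC_CODES[ch]
        except KeyError:
            raise InvalidArgumentError(f"not an IUPAC nucleotide code: {ch!r}")
        out = [p + b for p in out for b in sorted(bases)]
    return out


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """An in-frame aligned codon matrix for one gene region.

    ``sequences[i]`` belongs to ``taxa[i]``; all sequences share the same
    length, which must be a multiple of three.  Characters are DNA bases,
    IUPAC ambiguity codes, ``-`` (gap) or ``?`` (missing).
    """

    taxa: list[str]
    sequences: list[str]
    gene_label: str = ""

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise InvalidArgumentError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise InvalidArgumentError("taxon labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InvalidArgumentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.sequences and len(self.sequences[0]) % 3:
            raise InvalidArgumentError("alignment length is not a multiple of 3")
        self.sequences = [s.upper() for s in self.sequences]
        for s in self.sequences:
            bad = set(s) - VALID_CHARS
            if bad:
                raise InvalidArgumentError(f"invalid characters: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3

    def codon(self, taxon_index: int, codon_index: int) -> str:
        return self.sequences[taxon_index][3 * codon_index: 3 * codon_index + 3]

    def codon_column(self, codon_index: int) -> list[str]:
        return [self.codon(i, codon_index) for i in range(len(self.taxa))]


# ---------------------------------------------------------------------------
# degen1 recoding
# ---------------------------------------------------------------------------

def _recode_codon(codon: str, table: Mapping[str, str], code: Mapping[str, str],
                  strict: bool, gene: str, where: str) -> str:
    if all(ch in GAP_CHARS for ch in codon):
        return codon                       # gap / missing pass-through
    if any(ch in GAP_CHARS for ch in codon):
        return codon                       # partial codon: untranslatable, keep
    if codon in table:                     # plain sense or stop codon
        if code[codon] == STOP:
            if strict:
                raise StopCodonError(f"in-frame stop codon {codon} at {where}")
            logger.warning("stop codon %s at %s in %s recoded as NNN",
                           codon, where, gene or "<alignment>")
        return table[codon]
    # ambiguous codon: IUPAC union of the degen1 images of all expansions;
    # stop expansions contribute the stop-policy image (NNN) in lenient mode
    images = []
    for exp in expand_codon(codon):
        if code[exp] == STOP:
            if strict:
                raise StopCodonError(
                    f"ambiguous codon {codon} at {where} expands to stop {exp}")
            images.append("NNN")
        else:
            images.append(table[exp])
    result = "".join(
        _iupac_union(set().union(*(IUPAC_CODES[img[pos]] for img in images)))
        for pos in range(3)
    )
    return result


def degen1_recode(alignment: CodonAlignment, *, strict: bool = False,
                  code: Mapping[str, str] | None = None) -> CodonAlignment:
    """Apply degen1 recoding codon-by-codon to an in-frame alignment.

    Stop codons follow the lenient policy by default (replaced with NNN and
    logged); ``strict=True`` raises :class:`StopCodonError` instead.  The
    operation is idempotent.
    """
    code = code or _standard_code()
    table = degen1_table(code)
    cache: dict[str, str] = {}
    out_seqs = []
    for ti, seq in enumerate(alignment.sequences):
        chunks = []
        for j in range(0, len(seq), 3):
            codon = seq[j:j + 3]
            hit = cache.get(codon)
            if hit is None:
                hit = _recode_codon(codon, table, code, strict,
                                    alignment.gene_label,
                                    f"{alignment.taxa[ti]}:codon{j // 3}")
                # stop codons are logged per occurrence, so only cache others
                if codon in table and code.get(codon) == STOP:
                    chunks.append(hit)
                    continue
                cache[codon] = hit
            chunks.append(hit)
        out_seqs.append("".join(chunks))
    return CodonAlignment(list(alignment.taxa), out_seqs, alignment.gene_label)


# ---------------------------------------------------------------------------
# noLR first-position site detection
# ---------------------------------------------------------------------------

_LR = frozenset("LR")


def _codon_could_be_LR(codon: str, code: Mapping[str, str]) -> bool:
    """True if any IUPAC expansion of the codon translates to Leu or Arg.

    Codons containing gap/missing characters cannot be translated and do not
    count (the conservative rule applies only to attested residues).
    """
    if any(ch in GAP_CHARS for ch in codon):
        return False
    return any(code[exp] in _LR for exp in expand_codon(codon))


def find_noLR_nt1_sites(alignment: CodonAlignment,
                        code: Mapping[str, str] | None = None) -> set[int]:
    """First-position site indices of columns encoding no Leu/Arg in any taxon.

    Only leucine and arginine codons can vary synonymously at the first
    position, so at the returned (0-based, absolute-column) nt1 sites
    synonymous change is undetectable in every pairwise comparison.  A codon
    counts as Leu/Arg if *any* of its IUPAC expansions translates to Leu or
    Arg (conservative exclusion).
    """
    code = code or _standard_code()
    verdict: dict[str, bool] = {}
    included: set[int] = set()
    for j in range(alignment.n_codons):
        ok = True
        for i in range(len(alignment.taxa)):
            codon = alignment.codon(i, j)
            v = verdict.get(codon)
            if v is None:
                v = verdict[codon] = _codon_could_be_LR(codon, code)
            if v:
                ok = False
                break
        if ok:
            included.add(3 * j)
    return included


# ---------------------------------------------------------------------------
# Exclusion masks
# ---------------------------------------------------------------------------

@dataclass
class ExclusionMask:
    """Ordered, non-overlapping half-open 0-based column intervals to exclude."""

    intervals: list[tuple[int, int]] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        ivs = [(int(a), int(b)) for a, b in self.intervals]
        ivs.sort()
        prev_end = -1
        for a, b in ivs:
            if a < 0 or b < a:
                raise InvalidArgumentError(f"malformed interval ({a}, {b})")
            if a < prev_end:
                raise InvalidArgumentError("mask intervals overlap")
            prev_end = b
        self.intervals = ivs

    @property
    def n_excluded(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def columns(self) -> set[int]:
        return {c for a, b in self.intervals for c in range(a, b)}

    @classmethod
    def from_ranges_text(cls, text: str, note: str = "") -> "ExclusionMask":
        """Parse plain-text 1-based inclusive ranges, one per line (``12-40``
        or single columns ``7``); ``#`` comments allowed."""
        ivs = []
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            for token in line.replace(",", " ").split():
                if "-" in token:
                    a, b = token.split("-")
                    ivs.append((int(a) - 1, int(b)))
                else:
                    ivs.append((int(token) - 1, int(token)))
        return cls(ivs, note)

    @classmethod
    def from_nexus_exset(cls, text: str, note: str = "") -> "ExclusionMask":
        """Parse a NEXUS ``EXSET`` dialect statement, e.g.
        ``EXSET * untrusted = 12-40 77 120-155;`` (1-based inclusive)."""
        body = text
        if "=" in text:
            body = text.split("=", 1)[1]
        body = body.rstrip().rstrip(";")
        return cls.from_ranges_text(body.replace("\n", " "), note)

    def to_nexus_exset(self, name: str = "mask") -> str:
        parts = []
        for a, b in self.intervals:
            parts.append(str(a + 1) if b == a + 1 else f"{a + 1}-{b}")
        return f"EXSET * {name} = {' '.join(parts)};"


@dataclass
class MaskStats:
    """Bookkeeping for an applied exclusion mask."""

    n_excluded: int
    n_total: int

    @property
    def percent_excluded(self) -> float:
        """Excluded fraction as a percentage rounded to one decimal."""
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_excluded / self.n_total, 1)


def apply_mask(matrix: "SuperMatrix", mask: ExclusionMask) -> tuple["SuperMatrix", MaskStats]:
    """Remove masked columns from a supermatrix, remapping gene boundaries.

    Returns the masked matrix and a :class:`MaskStats` with the excluded
    count, total and percentage (e.g. 1440 of 20373 -> 7.1%).  Raises if any
    interval extends beyond the matrix.
    """
    total = matrix.total_sites
    if mask.intervals and mask.intervals[-1][1] > total:
        raise InvalidArgumentError(
            f"mask interval {mask.intervals[-1]} exceeds matrix length {total}")
    cols = mask.columns()
    masked = matrix.drop_columns(cols)
    return masked, MaskStats(n_excluded=len(cols), n_total=total)


# ---------------------------------------------------------------------------
# Partition scheme
# ---------------------------------------------------------------------------

NONSYN = "nonsyn_nt1_nt2"
POTSYN = "potsyn_nt1_nt3"


@dataclass
class PartitionScheme:
    """Two named, disjoint site sets covering all unmasked supermatrix sites."""

    sites: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        self.sites = {k: frozenset(v) for k, v in self.sites.items()}

    def __getitem__(self, name: str) -> frozenset[int]:
        return self.sites[name]

    @property
    def names(self) -> list[str]:
        return list(self.sites)

    def validate_covers(self, n_sites: int) -> None:
        all_sites: set[int] = set()
        n_assigned = 0
        for s in self.sites.values():
            all_sites |= s
            n_assigned += len(s)
        if n_assigned != len(all_sites) or all_sites != set(range(n_sites)):
            raise RuntimeError("partition leak: sets must disjointly tile all sites")

    def to_nexus_charsets(self) -> str:
        lines = ["begin sets;"]
        for name, s in self.sites.items():
            lines.append(f"    charset {name} = {_ranges_1based(s)};")
        lines.append("end;")
        return "\n".join(lines)

    def to_raxml(self) -> str:
        return "\n".join(
            f"DNA, {name} = {_ranges_1based(s, sep=', ')}"
            for name, s in self.sites.items()
        )


def _ranges_1based(sites: frozenset[int], sep: str = " ") -> str:
    """Render a 0-based site set as 1-based inclusive ranges with /3 strides."""
    out = []
    run_start = run_prev = run_step = None
    for x in sorted(sites):
        if run_start is None:
            run_start = run_prev = x
            run_step = None
        elif run_step is None:
            run_step = x - run_prev
            run_prev = x
        elif x - run_prev == run_step:
            run_prev = x
        else:
            out.append(_fmt_run(run_start, run_prev, run_step))
            run_start, run_prev, run_step = x, x, None
    if run_start is not None:
        out.append(_fmt_run(run_start, run_prev, run_step))
    return sep.join(out)


def _fmt_run(start: int, end: int, step: int | None) -> str:
    if start == end:
        return str(start + 1)
    if step in (None, 1):
        return f"{start + 1}-{end + 1}"
    return f"{start + 1}-{end + 1}\\{step}"


def build_partitions(matrix: "SuperMatrix",
                     code: Mapping[str, str] | None = None) -> PartitionScheme:
    """Build the two-partition scheme from a (masked) supermatrix.

    Per gene block, first-position sites in codon columns where no taxon
    encodes Leu/Arg join all second positions in ``nonsyn_nt1_nt2``; the
    remaining first positions join all third positions in
    ``potsyn_nt1_nt3``.  Every gene block must still be in frame (length a
    multiple of three), i.e. any exclusion mask must remove whole codons.
    """
    nonsyn: set[int] = set()
    potsyn: set[int] = set()
    for gene, (start, stop) in matrix.gene_blocks.items():
        if (stop - start) % 3:
            raise InvalidArgumentError(
                f"gene block {gene!r} is out of frame after masking "
                f"({stop - start} columns); masks must remove whole codons")
        sub = matrix.gene_alignment(gene)
        nolr_local = find_noLR_nt1_sites(sub, code)
        for j in range(sub.n_codons):
            nt1 = start + 3 * j
            if 3 * j in nolr_local:
                nonsyn.add(nt1)
            else:
                potsyn.add(nt1)
            nonsyn.add(nt1 + 1)
            potsyn.add(nt1 + 2)
    scheme = PartitionScheme({NONSYN: frozenset(nonsyn), POTSYN: frozenset(potsyn)})
    scheme.validate_covers(matrix.total_sites)
    return scheme
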