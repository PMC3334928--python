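"""Synthetic data with known truth for every pipeline stage.

Generators here emulate the structure of a multi-gene, codon-based
phylogenetic study without requiring any sequence downloads:

* Yule (pure-birth) trees with rescaled branch lengths;
* in-frame codon alignments evolved under a two-layer process — a slow
  amino-acid (synonymous-family) chain and a fast within-family synonymous
  chain whose stationary base composition can be switched on selected
  terminal branches, concentrating among-lineage compositional
  heterogeneity at synonymous sites;
* block-missing taxon x gene presence designs (a subset of taxa sequenced
  for all genes, the rest for a core subset);
* host-association record tables with hidden per-species diet-breadth
  labels;
* plain nucleotide GTR+gamma+I alignments for model-matched likelihood
  checks.

All generators are bit-reproducible for fixed seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .codon_recoding import (
    NUCLEOTIDES,
    CodonAlignment,
    InvalidArgumentError,
    synonymous_families,
)
from .ml_inference import SubstitutionModel, discrete_gamma_rates

PLANT_ORDERS = [
    "Rosales", "Fagales", "Pinales", "Malpighiales", "Sapindales",
    "Myrtales", "Fabales", "Solanales", "Lamiales", "Asterales",
    "Ericales", "Poales", "Malvales", "Gentianales", "Caryophyllales",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-level simulation settings.

    ``branch_length_scale`` is the expected number of substitutions per
    site corresponding to one unit of (relative) tree branch length;
    ``synonymous_rate_multiplier`` is the rate of synonymous state change
    relative to non-synonymous change; ``composition_shift_taxa`` name the
    taxa whose terminal branches use ``composition_shift_frequencies`` as
    the synonymous-site stationary composition.
    """

    n_taxa: int = 12
    n_codons_per_gene: list = field(default_factory=lambda: [200])
    tree_shape_seed: int = 1
    sequence_seed: int = 2
    branch_length_scale: float = 0.1
    gamma_shape: float = 0.8
    p_invariant: float = 0.1
    gtr_exchangeabilities: tuple = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0)
    base_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)
    synonymous_rate_multiplier: float = 5.0
    composition_shift_taxa: frozenset = frozenset()
    composition_shift_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise InvalidArgumentError("n_taxa must be >= 3")
        if any(n <= 0 for n in self.n_codons_per_gene):
            raise InvalidArgumentError("n_codons_per_gene must be positive")
        for name in ("base_frequencies", "composition_shift_frequencies"):
            f = np.asarray(getattr(self, name), dtype=float)
            if f.shape != (4,) or abs(f.sum() - 1.0) > 1e-9 or np.any(f <= 0):
                raise InvalidArgumentError(f"{name} must be 4 positive reals summing to 1")
        if np.any(np.asarray(self.gtr_exchangeabilities) <= 0):
            raise InvalidArgumentError("exchangeabilities must be positive")
        if self.branch_length_scale < 0:
            raise InvalidArgumentError("branch_length_scale must be >= 0")
        if self.gamma_shape <= 0:
            raise InvalidArgumentError("gamma_shape must be positive")
        if not 0.0 <= self.p_invariant < 1.0:
            raise InvalidArgumentError("p_invariant must lie in [0, 1)")
        if self.synonymous_rate_multiplier < 0:
            raise InvalidArgumentError("synonymous_rate_multiplier must be >= 0")
        self.composition_shift_taxa = frozenset(self.composition_shift_taxa)

    def substitution_model(self) -> SubstitutionModel:
        """The GTR+gamma+I model implied by the config's nucleotide-level
        parameters (used for model-matched simulation and as an inference
        starting point)."""
        return SubstitutionModel(self.gtr_exchangeabilities,
                                 self.base_frequencies,
                                 self.gamma_shape, self.p_invariant)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int,
                  branch_length_scale: float = 1.0) -> dendropy.Tree:
    """Yule (pure-birth, unit rate) rooted binary tree with ``n_taxa``
    uniquely labelled leaves; branch lengths rescaled so the mean edge
    length equals ``branch_length_scale``."""
    if n_taxa < 3:
        raise InvalidArgumentError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)

    class _T:
        __slots__ = ("children", "length", "name")

        def __init__(self):
            self.children, self.length, self.name = [], 0.0, None

    root = _T()
    active: list[tuple[_T, float]] = []
    for _ in range(2):
        c = _T()
        root.children.append(c)
        active.append((c, 0.0))
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length = t - birth
        for _ in range(2):
            c = _T()
            node.children.append(c)
            active.append((c, t))
    t_end = t + rng.exponential(1.0 / n_taxa)
    for node, birth in active:
        node.length = t_end - birth

    lengths = []

    def collect(n):
        for c in n.children:
            lengths.append(c.length)
            collect(c)
    collect(root)
    mean = sum(lengths) / len(lengths)
    factor = branch_length_scale / mean if mean > 0 else 1.0

    counter = [0]
    width = len(str(n_taxa))

    def name_and_scale(n):
        n.length *= factor
        if not n.children:
            counter[0] += 1
            n.name = f"t{counter[0]:0{width}d}"
        for c in n.children:
            name_and_scale(c)
    for c in root.children:
        name_and_scale(c)

    def newick(n):
        if not n.children:
            return f"{n.name}:{n.length:.10g}"
        inner = ",".join(newick(c) for c in n.children)
        return (f"({inner}):{n.length:.10g}" if n.length else f"({inner})")
    return dendropy.Tree.get(data=newick(root) + ";", schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# Two-layer codon simulation
# ---------------------------------------------------------------------------

class _CodonProcess:
    """Precomputed family structure and within-family stationary weights."""

    def __init__(self, config: SimulationConfig):
        self.families = synonymous_families()
        self.codons = sorted(c for fam in self.families for c in fam)
        self.codon_index = {c: i for i, c in enumerate(self.codons)}
        self.fam_of = np.empty(len(self.codons), dtype=int)
        self.fam_members: list[np.ndarray] = []
        for fi, fam in enumerate(self.families):
            members = np.array(sorted(self.codon_index[c] for c in fam))
            self.fam_members.append(members)
            self.fam_of[members] = fi
        self.weights = {
            "base": self._weights(config.base_frequencies),
            "shift": self._weights(config.composition_shift_frequencies),
        }
        # single-nucleotide non-synonymous neighbours (stops excluded):
        # the slow layer moves along these edges, so synonymous positions
        # change only through the fast within-family layer
        self.nonsyn_neighbors: list[np.ndarray] = []
        for c in self.codons:
            nbrs = []
            for pos in range(3):
                for b in NUCLEOTIDES:
                    if b == c[pos]:
                        continue
                    d = c[:pos] + b + c[pos + 1:]
                    j = self.codon_index.get(d)
                    if j is not None and self.fam_of[j] != self.fam_of[self.codon_index[c]]:
                        nbrs.append(j)
            self.nonsyn_neighbors.append(np.array(nbrs))

    def _weights(self, freqs) -> list[np.ndarray]:
        f = {b: float(x) for b, x in zip(NUCLEOTIDES, freqs)}
        per_fam = []
        for members in self.fam_members:
            w = np.array([
                f[self.codons[m][0]] * f[self.codons[m][1]] * f[self.codons[m][2]]
                for m in members])
            per_fam.append(w / w.sum())
        return per_fam

    def root_distribution(self, freqs) -> np.ndarray:
        f = {b: float(x) for b, x in zip(NUCLEOTIDES, freqs)}
        w = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in self.codons])
        return w / w.sum()


def simulate_codon_alignment(tree: dendropy.Tree, config: SimulationConfig,
                             gene_index: int) -> CodonAlignment:
    """Evolve an in-frame codon alignment along ``tree``.

    Amino-acid state moves by a slow chain over synonymous families
    (serine's TCN and AGY count as two families); within the current family
    the codon moves by a fast chain whose stationary composition switches
    to ``composition_shift_frequencies`` on the terminal branches of
    ``composition_shift_taxa``.  Site rate multipliers come from a
    4-category discrete gamma (category means) plus an invariant-site mass.
    Branch lengths are multiplied by ``branch_length_scale``; no stop codon
    can ever be produced.
    """
    if not 0 <= gene_index < len(config.n_codons_per_gene):
        raise InvalidArgumentError(f"gene_index {gene_index} out of range")
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    stray = config.composition_shift_taxa - leaf_labels
    if stray:
        raise InvalidArgumentError(
            f"composition_shift_taxa not on the tree: {sorted(stray)}")

    n_codons = config.n_codons_per_gene[gene_index]
    rng = np.random.default_rng(
        np.random.SeedSequence((config.sequence_seed, gene_index)))
    proc = _CodonProcess(config)
    n_fams = len(proc.families)

    # per-site rate multipliers
    cat_rates = discrete_gamma_rates(config.gamma_shape, 4)
    rates = np.where(
        rng.random(n_codons) < config.p_invariant, 0.0,
        cat_rates[rng.integers(0, 4, size=n_codons)])

    m = config.synonymous_rate_multiplier
    p_syn = m / (1.0 + m) if np.isfinite(m) else 1.0

    root_p = proc.root_distribution(config.base_frequencies)
    root_state = rng.choice(len(proc.codons), size=n_codons, p=root_p)

    def evolve(state: np.ndarray, t: float, comp: str) -> np.ndarray:
        state = state.copy()
        if t <= 0:
            return state
        weights = proc.weights[comp]
        n_events = rng.poisson(3.0 * t * rates)
        for site in np.flatnonzero(n_events):
            s = state[site]
            for _ in range(n_events[site]):
                if rng.random() < p_syn:
                    fi = proc.fam_of[s]
                    members = proc.fam_members[fi]
                    if len(members) > 1:
                        s = int(rng.choice(members, p=weights[fi]))
                else:
                    nbrs = proc.nonsyn_neighbors[s]
                    s = int(nbrs[rng.integers(len(nbrs))])
            state[site] = s
        return state

    scale = config.branch_length_scale
    shift_taxa = config.composition_shift_taxa
    results: dict[str, np.ndarray] = {}

    def walk(node, state):
        for child in node.child_nodes():
            t = float(child.edge.length or 0.0) * scale
            if child.is_leaf():
                label = child.taxon.label
                comp = "shift" if label in shift_taxa else "base"
                results[label] = evolve(state, t, comp)
            else:
                walk(child, evolve(state, t, "base"))

    walk(tree.seed_node, root_state)
    taxa = sorted(results)
    seqs = ["".join(proc.codons[s] for s in results[t]) for t in taxa]
    aln = CodonAlignment(taxa, seqs, gene_label=f"gene{gene_index + 1:02d}")
    _assert_no_stops(aln)
    return aln


def _assert_no_stops(aln: CodonAlignment) -> None:
    from .codon_recoding import _standard_code
    code = _standard_code()
    for i in range(len(aln.taxa)):
        for j in range(aln.n_codons):
            if code.get(aln.codon(i, j)) == "*":  # pragma: no cover
                raise RuntimeError("internal error: simulated stop codon")


# ---------------------------------------------------------------------------
# Presence designs
# ---------------------------------------------------------------------------

@dataclass
class PresenceDesign:
    """Taxon x gene sampling design (True = sequenced)."""

    taxa: list[str]
    genes: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.taxa), len(self.genes)):
            raise InvalidArgumentError("presence matrix has wrong shape")
        if self.presence.size:
            if not self.presence.any(axis=1).all():
                raise InvalidArgumentError("every taxon must be present for >= 1 gene")
            if not (self.presence.sum(axis=0) >= 4).all():
                raise InvalidArgumentError(
                    "every gene needs >= 4 taxa (minimum informative quartet)")

    @classmethod
    def block(cls, taxa: list[str], genes: list[str], n_full: int,
              n_core_genes: int) -> "PresenceDesign":
        """Deliberately incomplete design: the first ``n_full`` taxa are
        sequenced for all genes, the rest only for the first
        ``n_core_genes`` (the core set)."""
        presence = np.zeros((len(taxa), len(genes)), dtype=bool)
        presence[:n_full, :] = True
        presence[n_full:, :n_core_genes] = True
        return cls(list(taxa), list(genes), presence)

    def percent_fully_sampled(self) -> int:
        """Percent of taxa sequenced for every gene, rounded to integer
        (e.g. 29 of 52 -> 56)."""
        full = int(self.presence.all(axis=1).sum())
        return round(100.0 * full / len(self.taxa))

    def to_tsv(self, handle) -> None:
        close = False
        if isinstance(handle, str):
            handle, close = open(handle, "w"), True
        try:
            handle.write("taxon\t" + "\t".join(self.genes) + "\n")
            for i, t in enumerate(self.taxa):
                handle.write(t + "\t" +
                             "\t".join(str(int(x)) for x in self.presence[i]) + "\n")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_tsv(cls, handle) -> "PresenceDesign":
        df = pd.read_csv(handle, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns),
                   df.to_numpy(dtype=int).astype(bool))


def apply_presence_design(alignments: list[CodonAlignment],
                          design: PresenceDesign) -> list[CodonAlignment]:
    """Blank out absent taxon x gene cells with the missing symbol ``?``.

    Each alignment's gene label must appear in the design, and all its taxa
    must be covered; present cells pass through unchanged.
    """
    gene_pos = {g: j for j, g in enumerate(design.genes)}
    taxon_pos = {t: i for i, t in enumerate(design.taxa)}
    out = []
    for aln in alignments:
        if aln.gene_label not in gene_pos:
            raise InvalidArgumentError(f"gene {aln.gene_label!r} not in design")
        j = gene_pos[aln.gene_label]
        seqs = []
        for t, s in zip(aln.taxa, aln.sequences):
            if t not in taxon_pos:
                raise InvalidArgumentError(f"taxon {t!r} not in design")
            seqs.append(s if design.presence[taxon_pos[t], j] else "?" * len(s))
        out.append(CodonAlignment(list(aln.taxa), seqs, aln.gene_label))
    return out


# ---------------------------------------------------------------------------
# Nucleotide-level GTR+gamma+I simulation
# ---------------------------------------------------------------------------

def simulate_gtr_alignment(tree: dendropy.Tree, model: SubstitutionModel,
                           n_sites: int, seed: int) -> CodonAlignment:
    """Simulate plain nucleotides under the inference model itself
    (model-matched data for likelihood and search checks).  ``n_sites``
    must be a multiple of 3 so the result is a valid codon container."""
    if n_sites % 3:
        raise InvalidArgumentError("n_sites must be a multiple of 3")
    rng = np.random.default_rng(seed)
    rates, weights = model.mixture()
    lam, U, Uinv = model.eigensystem()
    pi = np.asarray(model.base_frequencies)
    site_cat = rng.choice(len(rates), size=n_sites, p=weights)

    def pmat(t: float) -> np.ndarray:
        E = np.exp(np.outer(rates * t, lam))
        P = np.einsum("ij,cj,jk->cik", U, E, Uinv)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)

    root_state = rng.choice(4, size=n_sites, p=pi)
    results: dict[str, np.ndarray] = {}

    def walk(node, state):
        for child in node.child_nodes():
            P = pmat(float(child.edge.length or 0.0))
            new = np.empty(n_sites, dtype=int)
            u = rng.random(n_sites)
            for c in range(len(rates)):
                mask = site_cat == c
                if not mask.any():
                    continue
                cum = P[c].cumsum(axis=1)[state[mask]]
                new[mask] = (u[mask, None] > cum).sum(axis=1)
            if child.is_leaf():
                results[child.taxon.label] = new
            else:
                walk(child, new)

    walk(tree.seed_node, root_state)
    taxa = sorted(results)
    seqs = ["".join("ACGT"[s] for s in results[t]) for t in taxa]
    return CodonAlignment(taxa, seqs, gene_label="gtr_sim")


# ---------------------------------------------------------------------------
# Host-record simulation
# ---------------------------------------------------------------------------

def simulate_host_records(n_species: int, p_polyphagous: float,
                          entries_per_species_law=None, seed: int = 0,
                          n_tribes: int = 6) -> tuple[pd.DataFrame, pd.Series]:
    """Entry-level host-association table with hidden diet-breadth truth.

    Oligophagous species draw >= 95% of entries from one plant order;
    polyphagous species spread entries over >= 2 orders with no order
    exceeding 70%.  Returns (table, truth) where ``truth`` maps species to
    its hidden label.  ``entries_per_species_law`` may be an int (constant),
    a callable ``rng -> int``, or None (default: 2 + Poisson(6)).
    """
    if not 0.0 <= p_polyphagous <= 1.0:
        raise InvalidArgumentError("p_polyphagous must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if entries_per_species_law is None:
        def law(r):
            return 2 + int(r.poisson(6))
    elif isinstance(entries_per_species_law, int):
        def law(r, k=entries_per_species_law):
            return k
    else:
        law = entries_per_species_law

    rows, labels = [], {}
    width = len(str(max(n_species, 1)))
    for s in range(n_species):
        name = f"species{s + 1:0{width}d}"
        tribe = f"tribe{s % n_tribes + 1:02d}"
        n = max(1, law(rng))
        poly = bool(rng.random() < p_polyphagous)
        labels[name] = "polyphagous" if poly else "oligophagous"
        if not poly:
            primary = PLANT_ORDERS[int(rng.integers(len(PLANT_ORDERS)))]
            cap = int(np.floor(0.05 * n))
            n_off = min(int(rng.binomial(n, 0.02)), cap)
            orders = [primary] * (n - n_off)
            others = [o for o in PLANT_ORDERS if o != primary]
            orders += [others[int(rng.integers(len(others)))] for _ in range(n_off)]
        else:
            k = int(rng.integers(2, 5))
            chosen = list(rng.choice(PLANT_ORDERS, size=k, replace=False))
            counts = rng.multinomial(n, rng.dirichlet(np.full(k, 2.0)))
            cap = max(1, int(np.floor(0.7 * n)))
            while counts.max() > cap:
                counts[counts.argmax()] -= 1
                counts[counts.argmin()] += 1
            orders = [o for o, c in zip(chosen, counts) for _ in range(c)]
        rng.shuffle(orders)
        for o in orders:
            plant = f"{o}_plant{int(rng.integers(1, 7)):02d}"
            rows.append((name, tribe, plant, o))
    table = pd.DataFrame(rows, columns=["tortricid_species", "tribe",
                                        "plant_species", "plant_order"])
    truth = pd.Series(labels, name="true_label")
    return table, truth


# ---------------------------------------------------------------------------
# Run manifests and dataset convenience
# ---------------------------------------------------------------------------

def write_run_manifest(path: str, **entries) -> None:
    """JSON manifest recording seeds and settings of a simulation run."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=str)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[dendropy.Tree, list[CodonAlignment]]:
    """Tree plus per-gene codon alignments under one config (tree branch
    lengths are relative with mean 1; the substitutions/site scale is
    ``config.branch_length_scale``)."""
    tree = simulate_tree(config.n_taxa, config.tree_shape_seed,
                         branch_length_scale=1.0)
    alignments = [
        simulate_codon_alignment(tree, config, g)
        for g in range(len(config.n_codons_per_gene))
    ]
    return tree, alignments
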