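"""Cross-analysis comparison of bootstrap node support.

Analyses differing in character treatment (all-sites vs degen1-recoded vs
two-partition) or gene sampling (complete core matrix vs deliberately
incomplete full matrix) are compared bipartition-by-bipartition: threshold
fractions (shares of nodes with support >= 70/80/90%), side-by-side support
tables with a "-" marker for nodes absent from an analysis's best tree, and
the missing-data artifact check — strongly supported groups in the
incomplete-matrix tree that do not occur in the complete-matrix tree.

Bipartitions are unordered leaf-label splits (canonicalized to the side not
containing the smallest label), so comparisons are invariant to leaf order,
tree rotation and rooting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .codon_recoding import InvalidArgumentError
from .ml_inference import BootstrapResult, canonical_bipartition


def tree_leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label if l.taxon else l.label
                     for l in tree.leaf_node_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of a tree as canonical frozensets of leaf labels."""
    all_taxa = tree_leaf_labels(tree)
    n = len(all_taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label if l.taxon else l.label
                          for l in node.leaf_iter())
        if 2 <= len(below) <= n - 2:
            out.add(canonical_bipartition(below, all_taxa))
    return out


@dataclass
class SupportProfile:
    """One analysis's reference tree plus bipartition -> support (percent)."""

    label: str
    tree: dendropy.Tree
    supports: dict = field(default_factory=dict)
    clade_root_taxa: frozenset | None = None  # leaf labels whose MRCA is the clade

    @classmethod
    def from_bootstrap(cls, label: str, tree: dendropy.Tree,
                       result: BootstrapResult,
                       clade_root_taxa=None) -> "SupportProfile":
        return cls(label, tree, dict(result.frequencies),
                   frozenset(clade_root_taxa) if clade_root_taxa else None)

    def taxa(self) -> frozenset[str]:
        return tree_leaf_labels(self.tree)

    def clade_node(self):
        if self.clade_root_taxa is None:
            return self.tree.seed_node
        node = self.tree.mrca(taxon_labels=sorted(self.clade_root_taxa))
        if node is None:
            raise InvalidArgumentError("clade_root_taxa have no MRCA in tree")
        return node


@dataclass
class ThresholdReport:
    """Fractions of clade internal nodes meeting support thresholds."""

    thresholds: list
    fractions_percent: dict  # threshold -> rounded percent
    n_nodes: int

    def to_dict(self) -> dict:
        return {"thresholds": list(self.thresholds),
                "fractions_percent": dict(self.fractions_percent),
                "n_nodes": self.n_nodes}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def count_internal_nodes(tree: dendropy.Tree, clade_root=None) -> int:
    """Internal nodes of the rooted subtree at ``clade_root`` (default: the
    whole tree), including the subtree root itself.

    A fully bifurcating rooted subtree with n leaves has n-1 internal
    nodes (52 leaves -> 51).  Polytomies are counted as-is with a warning.
    """
    node = clade_root if clade_root is not None else tree.seed_node
    count, leaves = 0, 0
    for nd in node.preorder_iter():
        k = len(nd.child_nodes())
        if k == 0:
            leaves += 1
        else:
            count += 1
            if k > 2:
                warnings.warn(f"polytomy of degree {k} counted as one node")
    return count


def threshold_fractions(profile: SupportProfile,
                        thresholds=(70, 80, 90)) -> ThresholdReport:
    """Per threshold t, the rounded percent of clade internal nodes with
    support >= t.

    Each internal node of the clade subtree is scored by the support of the
    bipartition its parent edge induces; a subtree root with no such
    bipartition (the global root) is left out of the count.
    """
    all_taxa = profile.taxa()
    n = len(all_taxa)
    clade = profile.clade_node()
    supports = []
    for nd in clade.preorder_iter():
        if nd.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if not 2 <= len(below) <= n - 2:
            continue
        split = canonical_bipartition(below, all_taxa)
        supports.append(float(profile.supports.get(split, 0.0)))
    n_nodes = len(supports)
    fractions = {}
    for t in thresholds:
        hits = sum(1 for s in supports if s >= t)
        fractions[t] = round(100.0 * hits / n_nodes) if n_nodes else 0
    return ThresholdReport(list(thresholds), fractions, n_nodes)


def detect_missing_data_artifacts(full: SupportProfile,
                                  reduced: SupportProfile,
                                  strong_threshold: float = 80.0
                                  ) -> list[frozenset[str]]:
    """Strongly supported groups in the full (deliberately incomplete)
    analysis that are absent from the reduced (complete-matrix) best tree.

    An empty list is the expected outcome when large missing-data blocks do
    not mislead inference; any returned bipartition is a candidate artifact.
    """
    if full.taxa() != reduced.taxa():
        raise InvalidArgumentError("profiles cover different taxon sets")
    reduced_splits = tree_bipartitions(reduced.tree)
    return sorted(
        (s for s, v in full.supports.items()
         if v >= strong_threshold and s not in reduced_splits),
        key=sorted)


def compare_codings(profiles: list[SupportProfile]) -> pd.DataFrame:
    """Side-by-side support table over the first profile's tree nodes.

    One row per internal bipartition of the reference tree (preorder); one
    column per analysis, holding that analysis's support percentage or
    ``"-"`` when the bipartition is absent from its best tree.
    """
    if not profiles:
        raise InvalidArgumentError("need at least one profile")
    ref = profiles[0]
    taxa = ref.taxa()
    for p in profiles[1:]:
        if p.taxa() != taxa:
            raise InvalidArgumentError("profiles cover different taxon sets")
    n = len(taxa)
    rows, index = [], []
    present = {p.label: tree_bipartitions(p.tree) for p in profiles}
    k = 0
    for nd in ref.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if not 2 <= len(below) <= n - 2:
            continue
        split = canonical_bipartition(below, taxa)
        k += 1
        index.append(f"node{k:03d}|{'+'.join(sorted(split))}")
        row = {}
        for p in profiles:
            if split in present[p.label]:
                row[p.label] = float(p.supports.get(split, 0.0))
            else:
                row[p.label] = "-"
        rows.append(row)
    return pd.DataFrame(rows, index=index,
                        columns=[p.label for p in profiles])
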