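"""Diet-breadth (host-range) scoring from entry-level host records.

Each table row records one association of a tortricid species with a plant
species (repeat entries allowed for independent observations).  After
mapping plant species to orders (an editable APG-style lookup ships with
the package) and dropping species with a single entry — one observation
cannot distinguish oligophagy from under-sampling — a species is scored
oligophagous when at least 80% of its entries fall in one plant order, and
polyphagous otherwise.  Tribe-level synopses report
``n_polyphagous/n_scorable = percent`` per tribe.

The taxonomic rank used for scoring defaults to plant order but is
configurable (``rank_column``), since coarser or finer ranks change modal
fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .codon_recoding import InvalidArgumentError

logger = logging.getLogger("degenphylo")

OLIGOPHAGY_THRESHOLD = 0.8  # inclusive
UNRESOLVED = "unresolved"

SPECIES_COL = "tortricid_species"
TRIBE_COL = "tribe"
PLANT_COL = "plant_species"
ORDER_COL = "plant_order"


@dataclass
class DietScore:
    """Per-species diet-breadth verdict.

    ``modal_fraction`` is the share of entries in the most frequent plant
    order; ``label`` is ``oligophagous`` when ``n_entries >= 2`` and the
    modal fraction is >= 0.8, ``polyphagous`` otherwise, and ``unscorable``
    for single-entry species.
    """

    species: str
    n_entries: int
    modal_order: str
    modal_fraction: float
    label: str


@dataclass
class TribeSummary:
    tribe: str
    n_polyphagous: int
    n_scorable: int

    @property
    def percent_polyphagous(self) -> float:
        return 100.0 * self.n_polyphagous / self.n_scorable

    def __str__(self) -> str:
        return (f"{self.n_polyphagous}/{self.n_scorable} = "
                f"{round(self.percent_polyphagous)}%")


# ---------------------------------------------------------------------------
# Lookup and filtering
# ---------------------------------------------------------------------------

def load_order_lookup(path=None) -> dict[str, str]:
    """Plant taxon -> order map from a two-column TSV.  Species rows
    ("Genus epithet") take precedence; genus rows act as a fallback."""
    if path is None:
        text = (resources.files("degenphylo")
                .joinpath("data/plant_order_lookup.tsv").read_text())
    else:
        with open(path) as fh:
            text = fh.read()
    lookup = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        taxon, order = line.split("\t")
        lookup[taxon] = order
    return lookup


def map_plant_orders(table: pd.DataFrame,
                     lookup: dict[str, str] | None = None) -> pd.DataFrame:
    """Fill unresolved ``plant_order`` cells from the lookup (species first,
    then genus); rows still unresolved are flagged and later excluded from
    scoring.  Idempotent."""
    lookup = lookup if lookup is not None else load_order_lookup()
    out = table.copy()
    if ORDER_COL not in out.columns:
        out[ORDER_COL] = UNRESOLVED
    out[ORDER_COL] = out[ORDER_COL].fillna(UNRESOLVED)

    def resolve(row):
        order = row[ORDER_COL]
        if order and order != UNRESOLVED:
            return order
        plant = str(row[PLANT_COL])
        if plant in lookup:
            return lookup[plant]
        genus = plant.split()[0] if plant else ""
        return lookup.get(genus, UNRESOLVED)

    out[ORDER_COL] = out.apply(resolve, axis=1)
    n_unresolved = int((out[ORDER_COL] == UNRESOLVED).sum())
    if n_unresolved:
        logger.info("%d entries remain unresolved and are excluded from scoring",
                    n_unresolved)
    return out


def filter_single_entry_species(table: pd.DataFrame) -> pd.DataFrame:
    """Drop species represented by exactly one entry (a single observation
    would artificially inflate apparent oligophagy)."""
    counts = table[SPECIES_COL].value_counts()
    singles = set(counts[counts == 1].index)
    if singles:
        logger.info("removed %d single-entry species", len(singles))
    return table[~table[SPECIES_COL].isin(singles)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def classify_species(table: pd.DataFrame,
                     rank_column: str = ORDER_COL) -> list[DietScore]:
    """Score each species by its modal plant-order fraction.

    Entries with unresolved rank are excluded first.  A species with >= 2
    (resolved) entries is oligophagous when the modal fraction is >= 0.8
    (inclusive) and polyphagous otherwise; modal ties resolve to any
    maximal order (the fraction, hence the label, is identical).
    """
    resolved = table[table[rank_column] != UNRESOLVED]
    scores = []
    for species, group in resolved.groupby(SPECIES_COL, sort=True):
        counts = group[rank_column].value_counts()
        n = int(counts.sum())
        modal_order = counts.index[0]
        modal_fraction = float(counts.iloc[0]) / n
        if n < 2:
            label = "unscorable"
        elif modal_fraction >= OLIGOPHAGY_THRESHOLD:
            label = "oligophagous"
        else:
            label = "polyphagous"
        scores.append(DietScore(species, n, modal_order, modal_fraction, label))
    return scores


def summarize_tribes(scores: list[DietScore],
                     tribe_of: dict[str, str]) -> tuple[list[TribeSummary], list[str]]:
    """Per-tribe polyphagy synopsis over scorable species.

    Returns (summaries, unmapped_species); species without a tribe mapping
    are listed separately and excluded from tribe rows.
    """
    per_tribe: dict[str, list[DietScore]] = {}
    unmapped = []
    for sc in scores:
        if sc.label == "unscorable":
            continue
        tribe = tribe_of.get(sc.species)
        if tribe is None:
            unmapped.append(sc.species)
            continue
        per_tribe.setdefault(tribe, []).append(sc)
    summaries = [
        TribeSummary(tribe,
                     sum(1 for sc in group if sc.label == "polyphagous"),
                     len(group))
        for tribe, group in sorted(per_tribe.items())
    ]
    return summaries, unmapped


def scores_to_frame(scores: list[DietScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.species, s.n_entries, s.modal_order, s.modal_fraction, s.label)
         for s in scores],
        columns=["species", "n_entries", "modal_order", "modal_fraction", "label"],
    )
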