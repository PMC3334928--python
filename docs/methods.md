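# Methods

`degenphylo` re-implements, at desk scale and on synthetic data with known
truth, the computational chain of a multi-gene (nuclear protein-coding)
phylogenetic study of leaf-roller moths (Tortricidae): codon-aware character
recoding and partitioning, supermatrix construction under deliberately
incomplete gene sampling, partitioned GTR+Γ+I maximum-likelihood inference
with nonparametric bootstrap, cross-analysis node-support comparison, and
diet-breadth (oligophagy/polyphagy) scoring from host-association records.
This note documents the models, conventions, numerical choices and
limitations.

## Degeneracy-aware recoding (degen1)

Synonymous substitutions are prone to among-lineage base-compositional
heterogeneity that can mislead inference. degen1 coding removes their
contribution: every codon position that can undergo synonymous change within
its codon's amino-acid family is replaced by the IUPAC code spanning the
family's states at that position (CAT → CAY for His; all six Leu codons →
YTN; Arg → MGN).

*Families* are connected components of the graph joining sense codons that
differ at one position and encode the same amino acid. Under this
single-step closure serine splits into two families (TCN and AGY; no
single-nucleotide synonymous path joins them), so Ser1↔Ser2 differences
remain visible — a deliberate convention. Note that the per-position IUPAC
unions can jointly over-cover a family: YTN also spans Phe codons (TTT/TTC)
and MGN spans AGY-serine. This over-coverage is inherent to the coding
scheme; the invariant the implementation guarantees (and tests verify
against an independent closure oracle) is that each image position is
exactly the union of its family's states and the image's expansion covers
the family.

Conventions for non-plain codons:

* gap (`---`) and missing (`???`) codons pass through unchanged, as do
  partial codons containing any `-`/`?` (they cannot be translated);
* a codon with ambiguity codes is recoded as the position-wise IUPAC union
  of the degen1 images of its sense expansions;
* stop codons follow a lenient policy by default — replaced by `NNN` with a
  logged warning (real alignments contain artifacts); `strict=True` raises.
  An ambiguous codon with a stop expansion receives `NNN` from that
  expansion, which makes the union `NNN`;
* the recoding is idempotent.

The genetic code ships as an editable TSV (standard nuclear code by
default) and can be overridden per call.

## noLR sites and the two-partition scheme

Only leucine and arginine codons can change synonymously at the first codon
position. First-position sites of columns in which *no* taxon encodes Leu
or Arg therefore carry no detectable synonymous signal. A codon counts as
Leu/Arg-encoding if **any** of its IUPAC expansions translates to Leu or
Arg (conservative exclusion; gap/missing codons do not count). These "noLR"
nt1 sites joined with all nt2 sites form the `nonsyn_nt1_nt2` partition;
the excluded nt1 sites joined with all nt3 sites form `potsyn_nt1_nt3`.
The two sets are disjoint and tile all unmasked sites (validated; a leak is
an internal error).

Exclusion masks are applied **before** noLR detection and partition
building. Masks are half-open 0-based column intervals internally and
1-based inclusive in text/NEXUS form. A mask may remove arbitrary columns
(mask statistics are still exact), but partition building requires every
gene block to remain in frame — masks used upstream of partitioning must
remove whole codons.

## Supermatrices and deliberately incomplete designs

Per-gene alignments concatenate over a shared taxon list; a taxon absent
from a gene receives a block of `?` and a False cell in the taxon×gene
presence matrix, keeping whole-gene absence distinct from
present-but-gappy sequence. Subsetting to a gene list (e.g. the
"core-gene complete" matrix) remaps coordinates and retains the presence
submatrix. Matrix statistics report per-gene widths, the percentage of
absent design cells and the percentage of `?` characters. `?` is the
missing symbol in PHYLIP/NEXUS exports; FASTA export can substitute `N`.

## Likelihood model

GTR+Γ+I per partition. The rate matrix is built from six exchangeabilities
(AC, AG, AT, CG, CT, GT; normalized so GT = 1) and stationary frequencies,
scaled to one expected substitution per unit time. Among-site rate
variation uses a discrete gamma with four categories by default, *category
means* (computed from regularized incomplete gamma functions, not medians);
invariant sites form an extra zero-rate mixture component with weight
`p_invariant`, and the gamma rates are divided by `1 − p_invariant` so the
mixture mean rate is exactly 1.

Likelihoods use Felsenstein pruning with per-node, per-pattern rescaling
(log scalers accumulated), alignment-pattern compression, and transition
matrices from the π-symmetrized eigendecomposition of the reversible rate
matrix. Leaf partials for IUPAC codes are indicators over compatible
states (`Y` sums over C and T), so degen1-recoded matrices are handled
natively; `?`/`-` are fully ambiguous. Partitions share the topology and
one set of branch lengths (no per-partition rate multipliers — a
simplification relative to linked-branch-length schemes with rate
scalers). All-zero partials or non-positive site likelihoods raise a
`NumericalError` with the offending partition named.

## Optimization and tree search

Branch lengths are optimized one edge at a time by bounded Brent search
(bounds 1e-8 … 20 substitutions/site) against cached "inner" and "outer"
conditional likelihood vectors, making each candidate length an O(1)
evaluation; passes repeat until no edge improves. Model parameters are
optimized per partition by bounded L-BFGS-B on transformed coordinates
(log exchangeabilities relative to GT, log frequency ratios, log α with
α ∈ [0.02, 100], a scaled logit for p_inv ∈ [0, 0.95] to limit ridge
behaviour between α and p_inv). Coordinate ascent alternates branch and
model updates; a candidate update is accepted only if the log-likelihood
improves, so the trace is non-decreasing by construction.

Tree search is deliberately modest (the original analyses ran a genetic
algorithm at cluster scale; this module targets desk-scale correctness):
random-order stepwise addition (each insertion point scored by full
log-likelihood; ties keep the first in a deterministic edge enumeration),
followed by NNI hill-climbing in which each candidate swap is scored after
Brent-optimizing the focal edge, taking the best improving neighbour per
round, with a final multi-pass branch-length refinement. The best tree
over `n_starts` random starts is returned; results are bit-reproducible
for a fixed seed.

The nonparametric bootstrap resamples alignment *columns* with replacement
within each partition (nucleotide columns, not codons — the characters the
model sees), preserving partition sizes; each pseudo-replicate reweights
the compressed patterns (no matrix rebuild) and runs a full search.
Bipartition frequencies are reported in percent; trivial splits are
excluded. Bipartitions are canonicalized as the leaf-label side not
containing the lexicographically smallest taxon, making all comparisons
invariant to leaf order, rotation and rooting.

## Support comparison conventions

Node counts are over rooted (sub)trees and include the subtree root (a
fully bifurcating rooted subtree with 52 leaves has 51 internal nodes).
Threshold fractions score each internal node by the support of the
bipartition its parent edge induces and report rounded percentages at
70/80/90 by default (70–79% "moderate", ≥80% "strong"); a global root
without an associated bipartition is excluded from numerator and
denominator. The missing-data artifact check lists bipartitions with
support ≥ threshold in the full (deliberately incomplete) analysis that
are absent from the reduced (complete-matrix) best tree; an empty list is
the expected negative finding. Cross-analysis tables mark a bipartition
absent from an analysis's best tree with `-`.

## Synthetic data generators

**Trees.** Yule (pure birth, unit rate): exponential waiting times with a
uniformly chosen splitting lineage, a final Exp(n) hold, branch lengths
rescaled so the mean edge length equals `branch_length_scale` (1.0 —
relative units — in the dataset pipeline, with the substitutions/site
scale applied at simulation time).

**Codon alignments.** A two-layer process rather than a full 61×61 codon
model — simpler, and sufficient to create the synonymous/non-synonymous
signal contrast the partitioning targets. The slow layer moves along
single-nucleotide *non-synonymous* neighbour edges between codons (stops
excluded, uniform over neighbours), so synonymous positions change only
through the fast layer; the fast layer resamples the codon within the
current family from a stationary distribution proportional to the product
of per-position base frequencies. Per-site rate multipliers come from a
4-category discrete gamma (category means) plus an invariant-site mass.
Events are Poisson with mean 3·t·r per codon per branch (so roughly one
nucleotide substitution per site per unit branch length);
`synonymous_rate_multiplier` m splits events syn : non-syn as m : 1. On
the terminal branches of `composition_shift_taxa` the fast layer's
stationary composition switches to `composition_shift_frequencies`,
concentrating among-lineage compositional heterogeneity at synonymous
sites — the phenomenon degen1 and the two-partition scheme are designed to
neutralize. Stop codons are unreachable by construction and asserted
against. Because non-synonymous multi-step paths can alter a degenerate
position while passing through other families, "no synonymous events"
(m = 0) leaves columns family-pure only to first order; the exact
invariants are zero-divergence identity and degen1-erasure at m ≫ 1.

A model-matched plain-nucleotide GTR+Γ+I simulator
(`simulate_gtr_alignment`) supports likelihood parameter-recovery and
strong-signal search/bootstrap checks where the inference model must be
exactly the generating model.

**Presence designs.** `PresenceDesign.block` reproduces the deliberately
incomplete structure: the first `n_full` taxa sequenced for all genes, the
rest for a leading core subset. Invariants: every taxon has ≥1 gene, every
gene ≥4 taxa.

**Host records.** Entry-level tables (species, tribe, plant species, plant
order over a pool of real angiosperm/conifer order names) with hidden
truth: oligophagous species draw ≥95% of entries from one order (enforced
by capping off-order draws at ⌊0.05 n⌋); polyphagous species spread
entries over ≥2 orders with no order exceeding 70% (enforced by count
rebalancing). Default entries per species: 2 + Poisson(6).

What the generators do **not** emulate: indels (alignments are gap-free
unless a design introduces missing blocks), alignment error, within-gene
rate heterogeneity beyond gamma+I, selection, and the real study's branch
lengths or 66-taxon topology. Passing tests therefore demonstrate
correctness of the computational chain under its own assumptions, not
reproduction of the real-data results.

## Host-range scoring

Plant orders are resolved from an editable TSV lookup (species rows first,
genus fallback); still-unresolved entries are flagged and excluded.
Species with a single entry are unscorable and removed before tallying. A
species is **oligophagous** when ≥80% (inclusive) of its resolved entries
share one plant order, else **polyphagous**; modal ties resolve to any
maximal order (the fraction, hence the label, is identical). Tribe
synopses print `n_polyphagous/n_scorable = percent`. Scoring granularity
is the *entry* (observation row), not the distinct plant species — repeat
entries for one association are independent observations and deliberately
weigh the modal fraction. The taxonomic rank is order by default and
configurable, since coarser/finer ranks change modal fractions.

## Problem sizes used in the checks

Chosen once as realistic desk-scale analogues of the study design:

* likelihood oracle: random trees with ≤5 leaves, 9 sites, ambiguity and
  gaps included, 100 randomized cases;
* parameter recovery: 8 taxa, 6000 sites, α = 0.5 recovered within ±30%;
* search/bootstrap recovery: 12 taxa on a fixed strong-signal tree
  (internal branches 0.15, terminals 0.1), 900 sites, 100 bootstrap
  replicates, all true bipartitions expected ≥95%;
* missing-data artifact check: 14 taxa, five genes of 120/100/70/90/60
  codons, 8 taxa with all genes and 6 with the two core genes only
  (mirroring the study's ~56% fully sampled and ~45% core-site fraction),
  50 bootstrap replicates, artifact threshold 80%;
* host-range recovery: 250 species, ≥10 entries each, p(polyphagous) 0.5.

## Known limitations

* NNI-only topology moves can be trapped by local optima that SPR/TBR
  would escape; multiple random starts mitigate but do not eliminate this.
* Shared branch lengths across partitions bias partitioned fits when
  partition rates differ greatly; the two-partition scheme used here keeps
  the distortion modest at desk scale.
* The bootstrap resamples columns independently, ignoring within-codon
  dependence.
* The codon simulator's event count is approximate in substitutions/site
  units (non-synonymous family jumps change one nucleotide by
  construction, but path lengths within families vary).
* Host-record truth labels for species whose entry count is too small to
  express their regime (e.g. a polyphagous species with one entry) are
  unrecoverable by any scorer; such species are excluded by the
  single-entry filter.
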