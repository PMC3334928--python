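"""Desk-scale partitioned maximum-likelihood phylogenetics under GTR+gamma+I.

The engine computes Felsenstein-pruning log-likelihoods with per-node
rescaling, supports IUPAC-ambiguous characters (a ``Y`` leaf sums over C and
T), discrete-gamma among-site rate variation (category means, 4 categories
by default) with an invariant-site class implemented as an extra zero-rate
mixture component, and partitioned models sharing one topology and one set
of branch lengths.

Tree search is deliberately modest: random-order stepwise addition followed
by NNI hill-climbing with per-edge Brent branch-length optimization, the
best tree over ``n_starts`` random starts.  Nonparametric bootstrap
resamples alignment columns with replacement within each partition and
reports bipartition frequencies in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .codon_recoding import IUPAC_CODES, InvalidArgumentError

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0

_CHARS = "ACGTRYSWKMBDHVN-?"
_CHAR_INDEX = {c: i for i, c in enumerate(_CHARS)}
_PARTIALS = np.zeros((len(_CHARS), 4))
for _c, _i in _CHAR_INDEX.items():
    if _c in IUPAC_CODES:
        for _b in IUPAC_CODES[_c]:
            _PARTIALS[_i, "ACGT".index(_b)] = 1.0
    else:  # gap / missing: fully ambiguous
        _PARTIALS[_i, :] = 1.0
_BYTE_TO_ROW = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CHAR_INDEX.items():
    _BYTE_TO_ROW[ord(_c)] = _i


class NumericalError(ArithmeticError):
    """All-zero partial likelihoods or non-finite site likelihoods."""


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete-gamma categories
    (shape ``alpha``, mean 1)."""
    if k == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * edges), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * edges)])
    return k * (upper - lower)


@dataclass
class SubstitutionModel:
    """GTR+gamma+I.  Exchangeabilities in order AC, AG, AT, CG, CT, GT;
    frequencies in order A, C, G, T.  The rate matrix is normalized to one
    expected substitution per unit time at rate 1, and the gamma+I mixture
    has mean rate 1 (gamma rates divided by ``1 - p_invariant``)."""

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    p_invariant: float = 0.0
    n_gamma_categories: int = 4

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_frequencies, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise InvalidArgumentError("need 6 positive exchangeabilities")
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi <= 0):
            raise InvalidArgumentError("base frequencies must be 4 positive reals summing to 1")
        if self.gamma_shape <= 0:
            raise InvalidArgumentError("gamma_shape must be positive")
        if not 0.0 <= self.p_invariant < 1.0:
            raise InvalidArgumentError("p_invariant must lie in [0, 1)")
        self.exchangeabilities = tuple(float(x) for x in ex / ex[-1])
        self.base_frequencies = tuple(float(x) for x in pi)

    @classmethod
    def jc(cls, **kw) -> "SubstitutionModel":
        """Jukes-Cantor-like: equal frequencies and exchangeabilities."""
        return cls(**kw)

    def rate_matrix(self) -> np.ndarray:
        ex = self.exchangeabilities
        pi = np.asarray(self.base_frequencies)
        R = np.zeros((4, 4))
        for (i, j), s in zip(((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)), ex):
            R[i, j] = R[j, i] = s
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, U, U^-1) with P(t) = U diag(exp(lam t)) U^-1,
        via the pi-symmetrized form of the reversible rate matrix."""
        pi = np.asarray(self.base_frequencies)
        sq = np.sqrt(pi)
        Q = self.rate_matrix()
        S = (sq[:, None] * Q) / sq[None, :]
        S = 0.5 * (S + S.T)
        lam, V = np.linalg.eigh(S)
        U = V / sq[:, None]
        Uinv = V.T * sq[None, :]
        return lam, U, Uinv

    def mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the gamma+I mixture, mean rate 1."""
        g = discrete_gamma_rates(self.gamma_shape, self.n_gamma_categories)
        p = self.p_invariant
        if p > 0:
            rates = np.concatenate([[0.0], g / (1.0 - p)])
            weights = np.concatenate([[p], np.full(len(g), (1.0 - p) / len(g))])
        else:
            rates, weights = g, np.full(len(g), 1.0 / len(g))
        return rates, weights


# ---------------------------------------------------------------------------
# Internal tree representation (rooted view of an unrooted tree)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "parent", "length", "name", "leaf_ix")

    def __init__(self, name=None, leaf_ix=None, length=0.1):
        self.children: list["_Node"] = []
        self.parent: "_Node" | None = None
        self.length = length
        self.name = name
        self.leaf_ix = leaf_ix

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)


def _postorder(root: _Node) -> list[_Node]:
    out, stack = [], [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            out.append(node)
        else:
            stack.append((node, True))
            for c in node.children:
                stack.append((c, False))
    return out


def _copy_tree(root: _Node) -> _Node:
    new = _Node(root.name, root.leaf_ix, root.length)
    for c in root.children:
        new.add(_copy_tree(c))
    return new


def _newick(node: _Node, with_lengths: bool = True) -> str:
    def rec(n: _Node) -> str:
        if n.is_leaf:
            s = n.name or ""
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
        if with_lengths and n.parent is not None:
            s += f":{n.length:.10g}"
        return s
    return rec(node) + ";"


def _from_dendropy(tree: dendropy.Tree, taxa: list[str]) -> _Node:
    index = {t: i for i, t in enumerate(taxa)}

    def rec(dnode) -> _Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label not in index:
                raise InvalidArgumentError(f"tree leaf {label!r} not among taxa")
            n = _Node(label, index[label])
        else:
            n = _Node()
            for c in dnode.child_nodes():
                n.add(rec(c))
        n.length = float(dnode.edge.length or 0.0)
        return n

    return rec(tree.seed_node)


def _to_dendropy(root: _Node) -> dendropy.Tree:
    return dendropy.Tree.get(data=_newick(root), schema="newick",
                             preserve_underscores=True)


def _leafset_below(node: _Node) -> frozenset[str]:
    return frozenset(n.name for n in _postorder(node) if n.is_leaf)


def canonical_bipartition(side, all_taxa) -> frozenset[str]:
    """Canonical split representation: the side *not* containing the
    lexicographically smallest taxon label."""
    all_taxa = frozenset(all_taxa)
    side = frozenset(side)
    ref = min(all_taxa)
    return all_taxa - side if ref in side else side


def _tree_bipartitions(root: _Node, all_taxa) -> set[frozenset[str]]:
    n = len(all_taxa)
    out = set()
    for node in _postorder(root):
        if node.parent is None or node.is_leaf:
            continue
        below = _leafset_below(node)
        if 2 <= len(below) <= n - 2:
            out.add(canonical_bipartition(below, all_taxa))
    return out


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class _Part:
    """Per-partition state: compressed patterns plus model spectral data."""

    def __init__(self, codes: np.ndarray, model: SubstitutionModel, name: str):
        # codes: (n_taxa, n_part_sites) uint8 rows into _PARTIALS
        self.name = name
        self.model = model
        self.n_sites = codes.shape[1]
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns            # (n_pat, n_taxa)
        self.pattern_of_site = inverse.ravel()
        self.pat_weights = counts.astype(float)
        self.leaf_partials = [
            _PARTIALS[patterns[:, i]] for i in range(codes.shape[0])
        ]                                   # each (n_pat, 4)
        self.set_model(model)

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self.rates, self.weights = model.mixture()
        self.eigvals, self.U, self.Uinv = model.eigensystem()
        self.pi = np.asarray(model.base_frequencies)

    @property
    def n_cat(self) -> int:
        return len(self.rates)

    def pmats(self, t: float) -> np.ndarray:
        E = np.exp(np.outer(self.rates * t, self.eigvals))        # (ncat, 4)
        P = np.einsum("ij,cj,jk->cik", self.U, E, self.Uinv)
        np.clip(P, 0.0, None, out=P)
        return P


class _Cache:
    __slots__ = ("down", "logsc", "msgs", "H", "logscH")

    def __init__(self):
        self.down, self.logsc, self.msgs = {}, {}, {}
        self.H, self.logscH = {}, {}


class LikelihoodEngine:
    """Pruning likelihoods, branch-length optimization, stepwise addition
    and NNI search over a list of partitions sharing topology and branch
    lengths."""

    def __init__(self, taxa: list[str], parts: list[_Part]):
        self.taxa = list(taxa)
        self.parts = parts

    # -- construction -------------------------------------------------------

    @classmethod
    def from_matrix(cls, matrix, models, scheme=None) -> "LikelihoodEngine":
        arr = np.vstack([
            _BYTE_TO_ROW[np.frombuffer(s.encode(), dtype=np.uint8)]
            for s in matrix.sequences
        ])
        if np.any(arr == 255):
            raise InvalidArgumentError("matrix contains non-IUPAC characters")
        parts = []
        if scheme is None:
            model = models if isinstance(models, SubstitutionModel) else next(iter(models.values()))
            parts.append(_Part(arr, model, "all"))
        else:
            for name in scheme.names:
                sites = np.asarray(sorted(scheme[name]), dtype=int)
                parts.append(_Part(arr[:, sites], models[name], name))
        return cls(list(matrix.taxa), parts)

    def clone_with_weights(self, weight_arrays: list[np.ndarray]) -> "LikelihoodEngine":
        clone = LikelihoodEngine(self.taxa, [])
        for p, w in zip(self.parts, weight_arrays):
            q = _Part.__new__(_Part)
            q.__dict__ = dict(p.__dict__)
            q.pat_weights = np.asarray(w, dtype=float)
            clone.parts.append(q)
        return clone

    # -- core pruning -------------------------------------------------------

    def _down_pass(self, root: _Node, p: _Part, cache: _Cache) -> None:
        npat, ncat = p.patterns.shape[0], p.n_cat
        for node in _postorder(root):
            if node.is_leaf:
                lp = p.leaf_partials[node.leaf_ix]
                cache.down[node] = np.broadcast_to(lp[:, None, :], (npat, ncat, 4))
                cache.logsc[node] = np.zeros(npat)
            else:
                prod = None
                logsc = np.zeros(npat)
                for c in node.children:
                    P = p.pmats(c.length)
                    msg = np.einsum("cij,pcj->pci", P, cache.down[c])
                    cache.msgs[c] = msg
                    logsc += cache.logsc[c]
                    prod = msg if prod is None else prod * msg
                m = prod.max(axis=(1, 2))
                if np.any(m <= 0.0) or not np.all(np.isfinite(m)):
                    raise NumericalError(
                        f"all-zero partials at an internal node "
                        f"(partition {p.name!r}); check data/branch lengths")
                prod = prod / m[:, None, None]
                cache.down[node] = prod
                cache.logsc[node] = logsc + np.log(m)

    def _part_loglik(self, root: _Node, p: _Part) -> float:
        cache = _Cache()
        self._down_pass(root, p, cache)
        sitel = np.einsum("pci,c,i->p", cache.down[root], p.weights, p.pi)
        if np.any(sitel <= 0.0) or not np.all(np.isfinite(sitel)):
            raise NumericalError(f"non-positive site likelihood in {p.name!r}")
        return float(np.dot(p.pat_weights, np.log(sitel) + cache.logsc[root]))

    def loglik(self, root: _Node) -> float:
        return sum(self._part_loglik(root, p) for p in self.parts)

    # -- up/down caches for per-edge work -----------------------------------

    def _edge_caches(self, root: _Node) -> list[_Cache]:
        caches = []
        for p in self.parts:
            cache = _Cache()
            self._down_pass(root, p, cache)
            npat, ncat = p.patterns.shape[0], p.n_cat
            cache.H[root] = None
            G = {root: np.broadcast_to(p.pi[None, None, :], (npat, ncat, 4))}
            Gsc = {root: np.zeros(npat)}
            stack = [root]
            while stack:
                u = stack.pop()
                if u.is_leaf:
                    continue
                for v in u.children:
                    H = G[u].copy()
                    hsc = Gsc[u].copy()
                    for s in u.children:
                        if s is v:
                            continue
                        H = H * cache.msgs[s]
                        hsc += cache.logsc[s]
                    m = H.max(axis=(1, 2))
                    if np.any(m <= 0.0):
                        raise NumericalError("all-zero outer partial")
                    H /= m[:, None, None]
                    hsc += np.log(m)
                    cache.H[v] = H
                    cache.logscH[v] = hsc
                    if not v.is_leaf:
                        P = p.pmats(v.length)
                        G[v] = np.einsum("cij,pci->pcj", P, H)
                        Gsc[v] = hsc
                        stack.append(v)
            caches.append(cache)
        return caches

    def _edge_loglik(self, caches: list[_Cache], v: _Node, t: float) -> float:
        total = 0.0
        for p, cache in zip(self.parts, caches):
            P = p.pmats(t)
            M = np.einsum("pci,cij,pcj->pc", cache.H[v], P, cache.down[v])
            sitel = M @ p.weights
            if np.any(sitel <= 0.0):
                raise NumericalError("non-positive edge site likelihood")
            total += float(np.dot(
                p.pat_weights,
                np.log(sitel) + cache.logscH[v] + cache.logsc[v]))
        return total

    # -- branch-length optimization -----------------------------------------

    def optimize_branch_lengths(self, root: _Node, passes: int = 2,
                                xtol: float = 1e-7) -> float:
        """Edge-by-edge Brent optimization, one exact pre-order sweep per
        pass: partials are refreshed incrementally after each subtree, so
        every edge is scored against up-to-date inner/outer vectors at
        O(1) node updates per edge."""
        cur = self.loglik(root)
        for _ in range(passes):
            self._branch_pass(root, xtol)
            new = self.loglik(root)
            if new <= cur + 1e-8:
                cur = max(cur, new)
                break
            cur = new
        return cur

    def _branch_pass(self, root: _Node, xtol: float) -> None:
        parts = self.parts
        downs, msgs, logscs = [], [], []
        for p in parts:
            c = _Cache()
            self._down_pass(root, p, c)
            downs.append(c.down)
            msgs.append(c.msgs)
            logscs.append(c.logsc)

        def edge_ll(v, Hs, Hscs, t):
            total = 0.0
            for p, H, hsc, down, logsc in zip(parts, Hs, Hscs, downs, logscs):
                P = p.pmats(t)
                M = np.einsum("pci,cij,pcj->pc", H, P, down[v])
                sitel = M @ p.weights
                if np.any(sitel <= 0.0):
                    raise NumericalError("non-positive edge site likelihood")
                total += float(np.dot(p.pat_weights,
                                      np.log(sitel) + hsc + logsc[v]))
            return total

        def refresh(v):
            # down[v] and the message across v's edge, with current lengths
            for k, p in enumerate(parts):
                if not v.is_leaf:
                    prod, sc = None, np.zeros_like(logscs[k][v])
                    for c in v.children:
                        prod = msgs[k][c] if prod is None else prod * msgs[k][c]
                        sc = sc + logscs[k][c]
                    m = prod.max(axis=(1, 2))
                    if np.any(m <= 0.0):
                        raise NumericalError("all-zero partials during branch pass")
                    downs[k][v] = prod / m[:, None, None]
                    logscs[k][v] = sc + np.log(m)
                msgs[k][v] = np.einsum("cij,pcj->pci", p.pmats(v.length),
                                       downs[k][v])

        def visit(u, Gs, Gscs):
            for v in u.children:
                Hs, Hscs = [], []
                for k in range(len(parts)):
                    H, hsc = Gs[k], Gscs[k]
                    for s in u.children:
                        if s is v:
                            continue
                        H = H * msgs[k][s]
                        hsc = hsc + logscs[k][s]
                    if H is Gs[k]:
                        H = H.copy()
                    m = H.max(axis=(1, 2))
                    H = H / m[:, None, None]
                    hsc = hsc + np.log(m)
                    Hs.append(H)
                    Hscs.append(hsc)
                f_cur = edge_ll(v, Hs, Hscs, v.length)
                res = minimize_scalar(
                    lambda t: -edge_ll(v, Hs, Hscs, t),
                    bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                    method="bounded", options={"xatol": xtol})
                if -res.fun > f_cur + 1e-12:
                    v.length = float(res.x)
                if not v.is_leaf:
                    Gv = [np.einsum("cij,pci->pcj", p.pmats(v.length), Hs[k])
                          for k, p in enumerate(parts)]
                    visit(v, Gv, Hscs)
                refresh(v)

        npats = [p.patterns.shape[0] for p in parts]
        G0 = [np.broadcast_to(p.pi[None, None, :], (n, p.n_cat, 4))
              for p, n in zip(parts, npats)]
        Gsc0 = [np.zeros(n) for n in npats]
        visit(root, G0, Gsc0)

    # -- stepwise addition ---------------------------------------------------

    def stepwise_addition(self, order: list[int],
                          init_length: float = 0.1) -> _Node:
        if len(order) < 3:
            raise InvalidArgumentError("need at least 3 taxa")
        root = _Node()
        for ix in order[:3]:
            root.add(_Node(self.taxa[ix], ix, init_length))
        for ix in order[3:]:
            leaf = _Node(self.taxa[ix], ix, init_length)
            best_ll, best_v = -np.inf, None
            for v in _postorder(root):
                if v.parent is None:
                    continue
                orig = v.length
                mid = _insert_on_edge(v, leaf)
                ll = self.loglik(root)
                _remove_insertion(mid, v, orig)
                if ll > best_ll + 1e-10:
                    best_ll, best_v = ll, v
            _insert_on_edge(best_v, leaf)
        return root

    # -- NNI hill climbing ---------------------------------------------------

    def nni_search(self, root: _Node, max_rounds: int | None = None,
                   bl_passes: int = 1) -> float:
        cur = self.optimize_branch_lengths(root, passes=bl_passes)
        rounds = 0
        max_rounds = max_rounds or 4 * len(self.taxa)
        while rounds < max_rounds:
            rounds += 1
            best = (cur, None)
            for v, s, x in _nni_candidates(root):
                orig = v.length
                _swap_subtrees(s, x)
                try:
                    caches = self._edge_caches(root)
                    res = minimize_scalar(
                        lambda t: -self._edge_loglik(caches, v, t),
                        bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                        method="bounded", options={"xatol": 1e-7})
                    cand = -res.fun
                    cand_t = float(res.x)
                finally:
                    _swap_subtrees(s, x)
                    v.length = orig
                if cand > best[0] + 1e-6:
                    best = (cand, (v, s, x, cand_t))
            if best[1] is None:
                break
            v, s, x, t = best[1]
            _swap_subtrees(s, x)
            v.length = t
            cur = self.optimize_branch_lengths(root, passes=bl_passes)
        return cur


def _insert_on_edge(v: _Node, leaf: _Node) -> _Node:
    p = v.parent
    mid = _Node(length=v.length / 2.0)
    v.length /= 2.0
    p.children[p.children.index(v)] = mid
    mid.parent = p
    mid.add(v)
    mid.add(leaf)
    return mid


def _remove_insertion(mid: _Node, v: _Node, orig_length: float) -> None:
    p = mid.parent
    p.children[p.children.index(mid)] = v
    v.parent = p
    v.length = orig_length


def _nni_candidates(root: _Node):
    """Yield (v, s, x): internal edge above v, u-side subtree s, v-side
    subtree x; swapping s and x realizes one of the two NNI neighbours."""
    for v in _postorder(root):
        if v.parent is None or v.is_leaf:
            continue
        u = v.parent
        sibs = [c for c in u.children if c is not v]
        if not sibs:
            continue
        s = sibs[0]
        for x in list(v.children):
            yield v, s, x


def _swap_subtrees(a: _Node, b: _Node) -> None:
    pa, pb = a.parent, b.parent
    pa.children[pa.children.index(a)] = b
    pb.children[pb.children.index(b)] = a
    a.parent, b.parent = pb, pa


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def log_likelihood(tree: dendropy.Tree, matrix, models, scheme=None) -> float:
    """Partitioned GTR+gamma+I log-likelihood of a supermatrix on a tree.

    ``models`` is a single :class:`SubstitutionModel` (unpartitioned) or a
    mapping from partition name to model matching ``scheme``.  ``?``/``-``
    and IUPAC ambiguity codes are treated as sums over compatible states.
    """
    engine = LikelihoodEngine.from_matrix(matrix, models, scheme)
    _check_leaf_set(tree, matrix.taxa)
    root = _from_dendropy(tree, engine.taxa)
    return engine.loglik(root)


@dataclass
class OptimizeResult:
    models: object
    tree: dendropy.Tree
    log_likelihood: float
    trace: list = field(default_factory=list)


def optimize_parameters(tree: dendropy.Tree, matrix, models, scheme=None, *,
                        tol: float = 1e-3, max_rounds: int = 20,
                        free_params=("exchangeabilities", "base_frequencies",
                                     "gamma_shape", "p_invariant"),
                        branch_passes: int = 1) -> OptimizeResult:
    """Coordinate ascent over branch lengths and per-partition model
    parameters on a fixed topology.

    Alternates one-edge-at-a-time Brent branch optimization with bounded
    L-BFGS-B over the selected model parameters of each partition
    (``gamma_shape`` in [0.02, 100], ``p_invariant`` in [0, 0.95]) until the
    round-over-round improvement drops below ``tol``.  The log-likelihood
    trace is non-decreasing by construction.
    """
    engine = LikelihoodEngine.from_matrix(matrix, models, scheme)
    _check_leaf_set(tree, matrix.taxa)
    root = _from_dendropy(tree, engine.taxa)
    trace = [engine.loglik(root)]
    for _ in range(max_rounds):
        ll = engine.optimize_branch_lengths(root, passes=branch_passes)
        if free_params:
            for p in engine.parts:
                ll = max(ll, _optimize_part_model(engine, root, p, free_params))
        trace.append(ll)
        if trace[-1] - trace[-2] < tol:
            break
    out_models = ({p.name: p.model for p in engine.parts}
                  if scheme is not None else engine.parts[0].model)
    dtree = _to_dendropy(root)
    return OptimizeResult(out_models, dtree, trace[-1], trace)


def _optimize_part_model(engine: LikelihoodEngine, root: _Node, p: _Part,
                         free_params) -> float:
    m = p.model
    x0, bounds, unpack = _pack_model(m, free_params)
    if not len(x0):
        return engine._part_loglik(root, p)
    others = sum(engine._part_loglik(root, q) for q in engine.parts if q is not p)

    def objective(x):
        p.set_model(unpack(x))
        try:
            return -engine._part_loglik(root, p)
        except NumericalError:
            return 1e12

    base = -objective(x0)
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200})
    if -res.fun > base:
        p.set_model(unpack(res.x))
    else:
        p.set_model(m)
    return others + engine._part_loglik(root, p)


def _pack_model(m: SubstitutionModel, free_params):
    x0, bounds, fields = [], [], []
    if "exchangeabilities" in free_params:
        x0 += list(np.log(np.asarray(m.exchangeabilities[:5])))
        bounds += [(-10, 10)] * 5
        fields.append(("exch", 5))
    if "base_frequencies" in free_params:
        f = np.asarray(m.base_frequencies)
        x0 += list(np.log(f[:3] / f[3]))
        bounds += [(-10, 10)] * 3
        fields.append(("freq", 3))
    if "gamma_shape" in free_params:
        x0.append(np.log(m.gamma_shape))
        bounds.append((np.log(0.02), np.log(100.0)))
        fields.append(("alpha", 1))
    if "p_invariant" in free_params:
        p = min(max(m.p_invariant, 1e-6), 0.9499)
        x0.append(np.log(p / (0.95 - p)))
        bounds.append((-12, 12))
        fields.append(("pinv", 1))

    def unpack(x):
        kw = {"exchangeabilities": m.exchangeabilities,
              "base_frequencies": m.base_frequencies,
              "gamma_shape": m.gamma_shape,
              "p_invariant": m.p_invariant,
              "n_gamma_categories": m.n_gamma_categories}
        i = 0
        for name, width in fields:
            seg = np.asarray(x[i:i + width])
            i += width
            if name == "exch":
                kw["exchangeabilities"] = tuple(np.exp(seg)) + (1.0,)
            elif name == "freq":
                f = np.concatenate([np.exp(seg), [1.0]])
                kw["base_frequencies"] = tuple(f / f.sum())
            elif name == "alpha":
                kw["gamma_shape"] = float(np.exp(seg[0]))
            else:
                kw["p_invariant"] = float(0.95 / (1.0 + np.exp(-seg[0])))
        return SubstitutionModel(**kw)

    return np.asarray(x0), bounds, unpack


def search_tree(matrix, models, scheme=None, n_starts: int = 1,
                seed: int = 0) -> dendropy.Tree:
    """Heuristic ML tree search: per start, random-order stepwise addition
    then NNI hill climbing; returns the best tree over starts (deterministic
    for a fixed seed).  The tree carries its score as ``log_likelihood``."""
    engine = LikelihoodEngine.from_matrix(matrix, models, scheme)
    root, ll = _search_engine(engine, n_starts, np.random.default_rng(seed))
    tree = _to_dendropy(root)
    tree.log_likelihood = ll
    return tree


def _search_engine(engine: LikelihoodEngine, n_starts: int,
                   rng: np.random.Generator) -> tuple[_Node, float]:
    n = len(engine.taxa)
    if n < 4:
        raise InvalidArgumentError("tree search requires at least 4 taxa")
    best_root, best_ll = None, -np.inf
    for _ in range(n_starts):
        order = [int(i) for i in rng.permutation(n)]
        root = engine.stepwise_addition(order)
        engine.nni_search(root)
        ll = engine.optimize_branch_lengths(root, passes=10)
        if ll > best_ll + 1e-9:
            best_root, best_ll = _copy_tree(root), ll
    return best_root, best_ll


@dataclass
class BootstrapResult:
    """Bipartition frequencies (percent) over bootstrap pseudo-replicates."""

    n_replicates: int
    frequencies: dict  # canonical split -> percent
    taxa: list[str]
    trees: list | None = None


def bootstrap(matrix, models, scheme=None, n_replicates: int = 100,
              seed: int = 0, searches_per_rep: int = 1,
              keep_trees: bool = False) -> BootstrapResult:
    """Nonparametric bootstrap: columns resampled with replacement within
    each partition (partition sizes preserved), a full tree search per
    pseudo-replicate, bipartition frequencies in percent over replicates."""
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    engine = LikelihoodEngine.from_matrix(matrix, models, scheme)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    trees = [] if keep_trees else None
    all_taxa = frozenset(engine.taxa)
    for _ in range(n_replicates):
        weight_arrays = []
        for p in engine.parts:
            if p.n_sites == 0:
                weight_arrays.append(np.zeros(p.patterns.shape[0]))
                continue
            draw = rng.integers(0, p.n_sites, size=p.n_sites)
            site_counts = np.bincount(draw, minlength=p.n_sites).astype(float)
            weight_arrays.append(np.bincount(
                p.pattern_of_site, weights=site_counts,
                minlength=p.patterns.shape[0]))
        rep = engine.clone_with_weights(weight_arrays)
        root, _ = _search_engine(rep, searches_per_rep, rng)
        for split in _tree_bipartitions(root, all_taxa):
            counts[split] = counts.get(split, 0) + 1
        if keep_trees:
            trees.append(_newick(root))
    freqs = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return BootstrapResult(n_replicates, freqs, list(engine.taxa), trees)


def annotate_support(tree: dendropy.Tree, result: BootstrapResult) -> dendropy.Tree:
    """Label each internal edge of ``tree`` with its bootstrap percentage
    (0 when the bipartition never occurred).  Bipartitions in ``result``
    that are absent from the tree are attached as
    ``tree.unrepresented_bipartitions`` (the "[-]" cases)."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if labels != set(result.taxa):
        raise InvalidArgumentError("tree and bootstrap result taxa differ")
    all_taxa = frozenset(result.taxa)
    n = len(all_taxa)
    present = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if not 2 <= len(below) <= n - 2:
            continue
        split = canonical_bipartition(below, all_taxa)
        present.add(split)
        support = result.frequencies.get(split, 0.0)
        node.label = f"{support:g}"
    tree.unrepresented_bipartitions = {
        s: f for s, f in result.frequencies.items() if s not in present}
    return tree


def _check_leaf_set(tree: dendropy.Tree, taxa) -> None:
    labels = {leaf.taxon.label if leaf.taxon else leaf.label
              for leaf in tree.leaf_node_iter()}
    if labels != set(taxa):
        raise InvalidArgumentError(
            f"tree leaves do not match matrix taxa: {sorted(labels ^ set(taxa))}")
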