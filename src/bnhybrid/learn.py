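"""Hybrid Bayesian-network structure learning.

Two-phase scheme: a constraint-based pass (MMPC or one of the IAMB family)
discovers each node's neighbourhood and yields an undirected skeleton; a
score-based search (greedy hill climbing or tabu search with BIC) then
orients the edges while restricted to that skeleton.  The named hybrids are

    mmhc            = MMPC skeleton + hill climbing
    mmpc-tabu       = MMPC skeleton + tabu search
    inter.iamb-tabu = interleaved IAMB skeleton + tabu search
    fast.iamb-tabu  = fast IAMB skeleton + tabu search

All conditional-independence decisions use the G² test at a single
significance level alpha; tests whose n/df support falls below the adequacy
heuristic count as "no evidence of dependence".  Both searches are exactly
deterministic given the data: equally scoring moves are broken by the
lexicographically smallest (operation, parent, child) triple.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np

from .citest import DEFAULT_ALPHA, g2_test
from .core import DAG, Dataset, Skeleton
from .errors import InconsistentUniverseError

__all__ = [
    "NeighborhoodResult",
    "TabuParams",
    "SearchState",
    "HybridResult",
    "mmpc_neighborhood",
    "iamb_neighborhood",
    "skeleton_from_neighborhoods",
    "FamilyScoreCache",
    "bic_score",
    "hill_climb",
    "tabu_search",
    "learn_hybrid",
    "ALGORITHMS",
]

#: default cap on conditioning-set size inside constraint-based passes
DEFAULT_MAX_COND = 3

#: score deltas within this absolute tolerance count as ties (score-equivalent
#: orientations differ only by float rounding on large log-likelihood sums),
#: and ties go to the lexicographically smallest (operation, parent, child)
TIE_TOL = 1e-6


@dataclass
class NeighborhoodResult:
    """Outcome of a per-target constraint pass.

    ``members`` is the CPC for MMPC and the Markov blanket MB(T) for the
    IAMB family.  ``trace`` logs (candidate, "add"/"remove", p-value) in
    execution order and replays to ``members``.
    """

    target: str
    members: frozenset[str]
    trace: list[tuple[str, str, float]] = field(default_factory=list)

    def replay(self) -> frozenset[str]:
        s: set[str] = set()
        for cand, action, _p in self.trace:
            if action == "add":
                s.add(cand)
            else:
                s.discard(cand)
        return frozenset(s)


def _subsets(pool: Sequence[str], max_size: int | None) -> Iterable[tuple[str, ...]]:
    pool = sorted(pool)
    top = len(pool) if max_size is None else min(max_size, len(pool))
    for k in range(top + 1):
        yield from itertools.combinations(pool, k)


def _p_eff(data: Dataset, x: str, t: str, cond: Sequence[str]) -> float:
    return g2_test(data, x, t, cond).effective_p


def mmpc_neighborhood(
    data: Dataset,
    target: str,
    alpha: float = DEFAULT_ALPHA,
    max_cond: int | None = DEFAULT_MAX_COND,
) -> NeighborhoodResult:
    """Max-min parents-and-children discovery for one target.

    Phase I grows the CPC with the max-min heuristic: each round admits the
    candidate whose *weakest* association with the target over all tested
    conditioning subsets S ⊆ CPC is strongest, stopping when every remaining
    candidate is independent of the target given some subset.  Phase II
    removes false positives X for which Ind(X; T | S) holds for some
    S ⊆ CPC \\ {X}.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    data.column(target)  # raises UnknownNodeError early
    others = sorted(n for n in data.names if n != target)
    trace: list[tuple[str, str, float]] = []

    # max-p over all conditioning subsets tested so far, per candidate;
    # candidates at >= alpha have been separated and are dropped for good
    max_p: dict[str, float] = {x: 0.0 for x in others}
    tested_new: list[str] | None = None  # None => only the empty set so far
    cpc: list[str] = []
    candidates = set(others)

    while candidates:
        for x in sorted(candidates):
            if tested_new is None:
                subsets: Iterable[tuple[str, ...]] = [()]
            else:
                # only subsets containing the newest CPC member are new
                newest = tested_new[-1]
                rest = [c for c in cpc if c != newest]
                cap = len(rest) if max_cond is None else min(max_cond - 1, len(rest))
                subsets = (
                    (newest,) + s
                    for k in range(cap + 1)
                    for s in itertools.combinations(sorted(rest), k)
                )
            for s in subsets:
                p = _p_eff(data, x, target, s)
                if p > max_p[x]:
                    max_p[x] = p
                if max_p[x] >= alpha:
                    break
        separated = {x for x in candidates if max_p[x] >= alpha}
        candidates -= separated
        if not candidates:
            break
        best = min(candidates, key=lambda x: (max_p[x], x))
        cpc.append(best)
        candidates.discard(best)
        trace.append((best, "add", max_p[best]))
        tested_new = cpc

    # Phase II: backward false-positive removal
    for x in sorted(cpc):
        pool = [c for c in cpc if c != x]
        for s in _subsets(pool, max_cond):
            p = _p_eff(data, x, target, s)
            if p >= alpha:
                cpc.remove(x)
                trace.append((x, "remove", p))
                break
    return NeighborhoodResult(target, frozenset(cpc), trace)


def iamb_neighborhood(
    data: Dataset,
    target: str,
    alpha: float = DEFAULT_ALPHA,
    variant: str = "plain",
) -> NeighborhoodResult:
    """Markov-blanket discovery via incremental association (IAMB family).

    plain  — grow by repeatedly admitting argmax assoc(X; T | CMB) while the
             admission test is significant, then a single backward shrink.
    inter  — interleave a full shrinking pass after every admission, pruning
             false positives before they distort later association ranks.
    fast   — per pass, rank candidates by G² significance (conditional on
             the blanket at pass start) and speculatively admit them in that
             order while each admission test stays significant and reliable;
             shrink between passes.
    """
    if variant not in ("plain", "inter", "fast"):
        raise ValueError(f"unknown IAMB variant {variant!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    data.column(target)
    others = sorted(n for n in data.names if n != target)
    cmb: list[str] = []
    trace: list[tuple[str, str, float]] = []

    def shrink() -> bool:
        changed = False
        again = True
        while again:
            again = False
            for x in sorted(cmb):
                p = _p_eff(data, x, target, [c for c in cmb if c != x])
                if p >= alpha:
                    cmb.remove(x)
                    trace.append((x, "remove", p))
                    changed = again = True
                    break
        return changed

    if variant == "fast":
        while True:
            admitted = False
            base = list(cmb)
            ranked = sorted(
                (x for x in others if x not in cmb),
                key=lambda x: (g2_test(data, x, target, base).effective_p, x),
            )
            for x in ranked:
                res = g2_test(data, x, target, cmb)
                if res.effective_p < alpha and res.reliable:
                    cmb.append(x)
                    trace.append((x, "add", res.p_value))
                    admitted = True
                else:
                    break
            shrink()
            if not admitted:
                break
        return NeighborhoodResult(target, frozenset(cmb), trace)

    while True:
        pool = [x for x in others if x not in cmb]
        if not pool:
            break
        scored = [(x, g2_test(data, x, target, cmb)) for x in pool]
        best, res = min(scored, key=lambda xr: (xr[1].effective_p, -xr[1].neg_log_p, xr[0]))
        if res.effective_p >= alpha:
            break
        cmb.append(best)
        trace.append((best, "add", res.p_value))
        if variant == "inter":
            shrink()
    if variant == "plain":
        shrink()
    return NeighborhoodResult(target, frozenset(cmb), trace)


def skeleton_from_neighborhoods(
    results: dict[str, NeighborhoodResult],
    data: Dataset | None = None,
    alpha: float = DEFAULT_ALPHA,
    spouse_screen: bool = False,
    max_cond: int | None = DEFAULT_MAX_COND,
) -> Skeleton:
    """Symmetric AND-rule skeleton from per-node neighbourhoods.

    {X, Y} is an adjacency iff Y ∈ members(X) and X ∈ members(Y).  For
    Markov-blanket learners (``spouse_screen=True``) residual spouse links
    survive the AND-rule, so each adjacency is additionally screened: it is
    dropped if Ind(X; Y | S) holds for some S ⊆ MB(X)\\{Y} or S ⊆ MB(Y)\\{X}.
    """
    universe = set(results)
    for tgt, res in results.items():
        if res.target != tgt or not res.members <= universe - {tgt}:
            raise InconsistentUniverseError(
                f"neighbourhood of {tgt!r} references nodes outside the universe"
            )
    skel = Skeleton(universe)
    for x in sorted(universe):
        for y in sorted(results[x].members):
            if x < y and x in results[y].members:
                skel.add(x, y)
    if spouse_screen:
        if data is None:
            raise ValueError("spouse_screen requires the dataset")
        for pair in sorted(skel.adjacencies, key=sorted):
            x, y = sorted(pair)
            pools = (results[x].members - {y}, results[y].members - {x})
            severed = False
            for pool in pools:
                for s in _subsets(sorted(pool), max_cond):
                    if _p_eff(data, x, y, s) >= alpha:
                        skel.remove(x, y)
                        severed = True
                        break
                if severed:
                    break
    return skel


# ---------------------------------------------------------------------------
# scoring


class FamilyScoreCache:
    """Decomposable BIC with per-(node, parent-set) memoisation.

    family score = Σ_{j,k} n_ijk · ln(n_ijk / n_ij)  −  (r−1)·q / 2 · ln n

    where r is the child cardinality and q the number of parent
    configurations (product of full parent cardinalities, observed or not).
    Zero-count cells contribute 0.
    """

    def __init__(self, data: Dataset):
        self.data = data
        self._cache: dict[tuple[str, frozenset[str]], float] = {}
        self._log_n = np.log(data.n)

    def family(self, node: str, parents: Iterable[str]) -> float:
        parents = frozenset(parents)
        key = (node, parents)
        if key in self._cache:
            return self._cache[key]
        data = self.data
        r = data.cardinality(node)
        q = 1
        flat = np.zeros(data.n, dtype=np.int64)
        for p in sorted(parents):
            flat = flat * data.cardinality(p) + data.column(p)
            q *= data.cardinality(p)
        flat = flat * r + data.column(node)
        counts = np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)
        row = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(counts > 0, counts * np.log(np.where(counts > 0, counts / row, 1.0)), 0.0)
        loglik = float(terms.sum())
        penalty = 0.5 * (r - 1) * q * self._log_n
        score = loglik - penalty
        self._cache[key] = score
        return score

    def total(self, g: DAG) -> float:
        return sum(self.family(n, g.parents(n)) for n in g.nodes)


def bic_score(data: Dataset, g: DAG, cache: FamilyScoreCache | None = None) -> float:
    """BIC of a DAG: decomposable log-likelihood minus (r−1)q/2 · ln n per family."""
    cache = cache or FamilyScoreCache(data)
    return cache.total(g)


# ---------------------------------------------------------------------------
# search


@dataclass(frozen=True)
class TabuParams:
    """Tabu-search knobs: list capacity, stagnation budget, iteration cap."""

    tabu_length: int = 10
    max_stagnant: int = 15
    max_iter: int = 200

    def __post_init__(self):
        if self.tabu_length < 1 or self.max_stagnant < 1 or self.max_iter < 1:
            raise ValueError("tabu parameters must be positive")


@dataclass
class SearchState:
    """Running state of a local search; best never trails current."""

    current: DAG
    current_score: float
    best: DAG
    best_score: float
    tabu_list: list[frozenset]
    iteration: int = 0


def _legal_moves(g: DAG, restrict: Skeleton | None):
    """Yield (op, u, v) moves in deterministic lexicographic order.

    "add" is confined to skeleton adjacencies when a restriction is given;
    "delete" and "reverse" touch existing edges only and are always allowed.
    Acyclicity is pre-checked here.
    """
    nodes = sorted(g.nodes)
    for u in nodes:
        for v in nodes:
            if u == v or g.has_edge(u, v):
                continue
            if restrict is not None and not restrict.has(u, v):
                continue
            if not g.has_edge(v, u) and g.is_acyclic_after("add", u, v):
                yield ("add", u, v)
    for u, v in sorted(g.edges):
        yield ("delete", u, v)
    for u, v in sorted(g.edges):
        if g.is_acyclic_after("reverse", u, v):
            yield ("reverse", u, v)


def _move_delta(g: DAG, cache: FamilyScoreCache, op: str, u: str, v: str) -> float:
    pv = g.parents(v)
    if op == "add":
        return cache.family(v, pv | {u}) - cache.family(v, pv)
    if op == "delete":
        return cache.family(v, pv - {u}) - cache.family(v, pv)
    pu = g.parents(u)
    return (
        cache.family(v, pv - {u})
        - cache.family(v, pv)
        + cache.family(u, pu | {v})
        - cache.family(u, pu)
    )


def _apply(g: DAG, op: str, u: str, v: str) -> None:
    if op == "add":
        g.add_edge(u, v)
    elif op == "delete":
        g.remove_edge(u, v)
    else:
        g.remove_edge(u, v)
        g.add_edge(v, u)


def _empty_dag(data: Dataset) -> DAG:
    return DAG(data.names)


def hill_climb(
    data: Dataset,
    restrict: Skeleton | None = None,
    seed_graph: DAG | None = None,
    cache: FamilyScoreCache | None = None,
    max_iter: int = 10_000,
) -> DAG:
    """Greedy best-improvement search over add/delete/reverse moves.

    Stops at the first iteration where no move strictly improves the BIC.
    Deterministic: score ties go to the lexicographically smallest
    (operation, parent, child) triple.
    """
    if restrict is not None and restrict.nodes != frozenset(data.names):
        raise InconsistentUniverseError("restriction skeleton must cover the data")
    g = seed_graph.copy() if seed_graph is not None else _empty_dag(data)
    cache = cache or FamilyScoreCache(data)
    for _ in range(max_iter):
        best_move, best_delta = None, TIE_TOL
        for move in _legal_moves(g, restrict):
            delta = _move_delta(g, cache, *move)
            if delta > best_delta + TIE_TOL:
                best_move, best_delta = move, delta
        if best_move is None:
            break
        _apply(g, *best_move)
    return g


def _fingerprint(g: DAG) -> frozenset:
    return frozenset(g.edges)


def tabu_search(
    data: Dataset,
    restrict: Skeleton | None = None,
    params: TabuParams | None = None,
    seed_graph: DAG | None = None,
    cache: FamilyScoreCache | None = None,
    return_state: bool = False,
):
    """Tabu search over DAGs: best legal non-tabu move each step, even downhill.

    Visited structures (canonical edge-set fingerprints) live in a FIFO tabu
    list of bounded capacity; the aspiration criterion pardons a tabu move
    whenever it strictly beats the best score seen.  Terminates after
    ``max_stagnant`` consecutive non-improving steps or ``max_iter`` total.
    Returns the best structure found (optionally with the final SearchState).
    """
    if restrict is not None and restrict.nodes != frozenset(data.names):
        raise InconsistentUniverseError("restriction skeleton must cover the data")
    params = params or TabuParams()
    cache = cache or FamilyScoreCache(data)
    g = seed_graph.copy() if seed_graph is not None else _empty_dag(data)
    current_score = cache.total(g)
    best, best_score = g.copy(), current_score
    tabu: list[frozenset] = [_fingerprint(g)]
    stagnant = 0
    iteration = 0
    for iteration in range(1, params.max_iter + 1):
        chosen, chosen_delta = None, None
        for move in _legal_moves(g, restrict):
            delta = _move_delta(g, cache, *move)
            _apply(g, *move)
            fp = _fingerprint(g)
            _undo(g, *move)
            if fp in tabu and current_score + delta <= best_score + TIE_TOL:
                continue  # tabu and no aspiration
            if chosen is None or delta > chosen_delta + TIE_TOL:
                chosen, chosen_delta = move, delta
        if chosen is None:
            break
        _apply(g, *chosen)
        current_score += chosen_delta
        tabu.append(_fingerprint(g))
        if len(tabu) > params.tabu_length:
            tabu.pop(0)
        if current_score > best_score + 1e-9:
            best, best_score = g.copy(), current_score
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= params.max_stagnant:
                break
    if return_state:
        state = SearchState(g, current_score, best, best_score, tabu, iteration)
        return best, state
    return best


def _undo(g: DAG, op: str, u: str, v: str) -> None:
    if op == "add":
        g.remove_edge(u, v)
    elif op == "delete":
        g.add_edge(u, v)
    else:
        g.remove_edge(v, u)
        g.add_edge(u, v)


# ---------------------------------------------------------------------------
# hybrid composition


@dataclass
class HybridResult:
    """A learned DAG plus full provenance of the two-phase run."""

    dag: DAG
    skeleton: Skeleton
    neighborhoods: dict[str, NeighborhoodResult]
    skeleton_method: str
    search_method: str
    alpha: float
    params: TabuParams | None
    seed: int | None = None


_SKELETON_METHODS = ("mmpc", "iamb", "inter.iamb", "fast.iamb")
_SEARCH_METHODS = ("hc", "tabu")

#: named algorithms in the benchmark comparison
ALGORITHMS = {
    "mmhc": ("mmpc", "hc"),
    "mmpc-tabu": ("mmpc", "tabu"),
    "inter.iamb-tabu": ("inter.iamb", "tabu"),
    "fast.iamb-tabu": ("fast.iamb", "tabu"),
}


def learn_hybrid(
    data: Dataset,
    skeleton_method: str = "inter.iamb",
    search_method: str = "tabu",
    alpha: float = DEFAULT_ALPHA,
    params: TabuParams | None = None,
    max_cond: int | None = DEFAULT_MAX_COND,
    seed: int | None = None,
) -> HybridResult:
    """Two-phase hybrid learner: constraint skeleton, then restricted search.

    ``skeleton_method`` ∈ {mmpc, iamb, inter.iamb, fast.iamb};
    ``search_method`` ∈ {hc, tabu}.  Both phases are deterministic given the
    data; ``seed`` is recorded in the provenance for pipeline bookkeeping.
    """
    if skeleton_method not in _SKELETON_METHODS:
        raise ValueError(f"unknown skeleton method {skeleton_method!r}")
    if search_method not in _SEARCH_METHODS:
        raise ValueError(f"unknown search method {search_method!r}")
    neighborhoods = {}
    for node in sorted(data.names):
        if skeleton_method == "mmpc":
            res = mmpc_neighborhood(data, node, alpha, max_cond)
        else:
            variant = {"iamb": "plain", "inter.iamb": "inter", "fast.iamb": "fast"}[
                skeleton_method
            ]
            res = iamb_neighborhood(data, node, alpha, variant)
        neighborhoods[node] = res
    skel = skeleton_from_neighborhoods(
        neighborhoods,
        data=data,
        alpha=alpha,
        spouse_screen=skeleton_method != "mmpc",
        max_cond=max_cond,
    )
    cache = FamilyScoreCache(data)
    if search_method == "hc":
        dag = hill_climb(data, restrict=skel, cache=cache)
    else:
        dag = tabu_search(data, restrict=skel, params=params, cache=cache)
    return HybridResult(
        dag, skel, neighborhoods, skeleton_method, search_method, alpha, params, seed
    )
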