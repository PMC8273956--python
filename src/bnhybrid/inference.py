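"""Maximum-likelihood parameter learning and exact posterior inference.

Parameters are fitted per family as (count + smoothing) / (row total +
smoothing·levels); smoothing 0 is the pure maximum-likelihood estimate used
throughout the risk-reasoning application, with unseen parent
configurations falling back to a uniform row (and flagged).

Posterior queries run variable elimination with a min-degree elimination
order; sequential "risk reasoning" accumulates evidence one increment at a
time and reports the posterior after each prefix, mirroring how a clinician
would update the probability of disease as findings arrive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CPT,
    DAG,
    Dataset,
    DiscreteBayesianNetwork,
)
from .errors import UnknownNodeError, ValidationError, ZeroProbabilityEvidenceError

__all__ = [
    "Evidence",
    "PosteriorResult",
    "fit_mle",
    "query",
    "risk_chain",
    "FitReport",
]


@dataclass
class FitReport:
    """Side-channel of ``fit_mle``: parent configurations never observed."""

    unseen: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)


def fit_mle(
    graph: DAG,
    data: Dataset,
    smoothing: float = 0.0,
    report: FitReport | None = None,
) -> DiscreteBayesianNetwork:
    """Fit one CPT per family by (smoothed) maximum likelihood.

    smoothing=0 is the raw MLE; parent configurations with zero observations
    get a uniform distribution and are recorded in ``report.unseen``.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if set(graph.nodes) != set(data.names):
        raise ValidationError("graph nodes must match dataset variables")
    cpts: dict[str, CPT] = {}
    for node in data.names:
        var = data.variable(node)
        parents = tuple(sorted(graph.parents(node)))
        parent_levels = tuple(data.variable(p).levels for p in parents)
        r = var.cardinality
        q = int(np.prod([len(ls) for ls in parent_levels])) if parents else 1
        flat = np.zeros(data.n, dtype=np.int64)
        for p in parents:
            flat = flat * data.cardinality(p) + data.column(p)
        flat = flat * r + data.column(node)
        counts = np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        table = np.empty_like(counts)
        seen = totals[:, 0] + smoothing * r > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            table[seen] = (counts[seen] + smoothing) / (totals[seen] + smoothing * r)
        if not seen.all():
            table[~seen] = 1.0 / r
            if report is not None:
                cpt_tmp = CPT(node, parents, var.levels, parent_levels,
                              np.full((q, r), 1.0 / r))
                for i in np.flatnonzero(~seen):
                    report.unseen.append((node, cpt_tmp.configurations()[int(i)]))
        cpts[node] = CPT(node, parents, var.levels, parent_levels, table)
    return DiscreteBayesianNetwork(list(data.variables), graph, cpts)


Evidence = dict  # variable name -> observed level


@dataclass(frozen=True)
class PosteriorResult:
    target: str
    distribution: dict[str, float]
    evidence: dict[str, str]

    def __getitem__(self, level: str) -> float:
        return self.distribution[level]


class _Factor:
    """Dense factor over a tuple of variables (numpy array, one axis each)."""

    __slots__ = ("vars", "values")

    def __init__(self, vars_: tuple[str, ...], values: np.ndarray):
        self.vars = vars_
        self.values = values

    def multiply(self, other: "_Factor") -> "_Factor":
        all_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._expand(all_vars)
        b = other._expand(all_vars)
        return _Factor(all_vars, a * b)

    def _expand(self, all_vars: tuple[str, ...]) -> np.ndarray:
        # align axes to all_vars, inserting broadcast axes for absent vars
        src = list(self.vars)
        perm = [src.index(v) for v in all_vars if v in src]
        arr = np.transpose(self.values, perm)
        shape = []
        it = iter(arr.shape)
        for v in all_vars:
            shape.append(next(it) if v in src else 1)
        return arr.reshape(shape)

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1:], self.values.sum(axis=axis)
        )


def _network_factors(net: DiscreteBayesianNetwork, evidence: dict[str, str]):
    factors = []
    for name, cpt in net.cpts.items():
        dims = tuple(cpt.parents) + (name,)
        shape = tuple(len(ls) for ls in cpt.parent_levels) + (len(cpt.child_levels),)
        arr = cpt.table.reshape(shape)
        # slice out observed levels
        keep_vars, index = [], []
        for v, ls in zip(dims, cpt.parent_levels + (cpt.child_levels,)):
            if v in evidence:
                index.append(ls.index(evidence[v]))
            else:
                index.append(slice(None))
                keep_vars.append(v)
        factors.append(_Factor(tuple(keep_vars), np.asarray(arr[tuple(index)], dtype=float)))
    return factors


def _validate_evidence(net: DiscreteBayesianNetwork, evidence: dict[str, str]):
    vm = net.variable_map
    for var, level in evidence.items():
        if var not in vm:
            raise UnknownNodeError(f"evidence variable {var!r} not in network")
        if level not in vm[var].levels:
            raise UnknownNodeError(
                f"evidence level {level!r} not declared for {var!r}"
            )


def query(
    net: DiscreteBayesianNetwork,
    target: str,
    evidence: dict[str, str] | None = None,
) -> PosteriorResult:
    """Exact posterior P(target | evidence) by variable elimination.

    The elimination order is the min-degree heuristic on the factor
    hypergraph; correctness does not depend on the order.  Raises
    ZeroProbabilityEvidenceError when the evidence has probability 0.
    """
    evidence = dict(evidence or {})
    _validate_evidence(net, evidence)
    if target in evidence:
        raise ValueError("target must not be observed")
    if target not in net.variable_map:
        raise UnknownNodeError(f"unknown target {target!r}")
    factors = _network_factors(net, evidence)

    hidden = {v.name for v in net.variables} - set(evidence) - {target}
    while hidden:
        # min-degree: eliminate the variable whose combined factor is smallest
        def cost(h: str) -> tuple[int, str]:
            vs: set[str] = set()
            for f in factors:
                if h in f.vars:
                    vs.update(f.vars)
            return (len(vs), h)

        h = min(hidden, key=cost)
        hidden.discard(h)
        related = [f for f in factors if h in f.vars]
        factors = [f for f in factors if h not in f.vars]
        if not related:
            continue
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        factors.append(prod.marginalize(h))

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    # only `target` remains
    values = np.asarray(result._expand((target,))).reshape(-1)
    z = values.sum()
    if z <= 0:
        raise ZeroProbabilityEvidenceError(
            f"evidence {evidence!r} has probability 0 under the network"
        )
    dist = values / z
    levels = net.variable_map[target].levels
    return PosteriorResult(target, dict(zip(levels, dist.tolist())), evidence)


def risk_chain(
    net: DiscreteBayesianNetwork,
    target: str,
    evidence_sequence: list[dict[str, str]],
) -> list[PosteriorResult]:
    """Posterior after each cumulative evidence prefix (sequential reasoning).

    ``evidence_sequence`` holds disjoint increments; the first element of the
    returned list is the prior (empty prefix), so the list has
    len(evidence_sequence) + 1 entries.
    """
    seen: dict[str, str] = {}
    out = [query(net, target, {})]
    for inc in evidence_sequence:
        overlap = set(inc) & set(seen)
        if overlap:
            raise ValueError(f"evidence increments overlap on {sorted(overlap)}")
        seen.update(inc)
        out.append(query(net, target, dict(seen)))
    return out
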