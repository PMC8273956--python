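"""Domain types: categorical variables, directed graphs, CPTs, networks, datasets.

A discrete Bayesian network is a pair B = (G, theta): a DAG ``G`` over
categorical variables together with one conditional probability table per
node, so that the joint factorises as  P(X1..Xn) = prod_i P(Xi | parents(Xi)).
Everything downstream (independence tests, structure search, sampling,
inference) works on these types.

Level order is declaration order, never lexicographic, and parent
configuration tuples follow the CPT's declared parent order; this makes file
round-trips bit-stable.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CycleError,
    SchemaViolationError,
    UnknownEdgeError,
    UnknownNodeError,
    ValidationError,
)

__all__ = [
    "CategoricalVariable",
    "DirectedGraph",
    "DAG",
    "Skeleton",
    "CPT",
    "DiscreteBayesianNetwork",
    "Dataset",
    "topological_order",
]


@dataclass(frozen=True)
class CategoricalVariable:
    """A named discrete variable with an ordered set of levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ValidationError(f"variable {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"variable {self.name!r} has duplicate levels")

    @property
    def cardinality(self) -> int:
        return len(self.levels)

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise UnknownNodeError(
                f"level {level!r} not declared for variable {self.name!r}"
            ) from None


class DirectedGraph:
    """Mutable directed graph over string node identifiers.

    Self-loops are rejected; edges must reference declared nodes.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -----------------------------------------------------
    def add_node(self, node: str) -> None:
        self._parents.setdefault(node, set())
        self._children.setdefault(node, set())

    def add_edge(self, u: str, v: str) -> None:
        self._check_node(u)
        self._check_node(v)
        if u == v:
            raise ValidationError(f"self-loop {u!r} -> {v!r} not allowed")
        self._children[u].add(v)
        self._parents[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.has_edge(u, v):
            raise UnknownEdgeError(f"edge {u!r} -> {v!r} not present")
        self._children[u].discard(v)
        self._parents[v].discard(u)

    # -- queries -----------------------------------------------------------
    def _check_node(self, node: str) -> None:
        if node not in self._parents:
            raise UnknownNodeError(f"unknown node {node!r}")

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._parents)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (u, v) for u, kids in self._children.items() for v in kids
        )

    def n_edges(self) -> int:
        return sum(len(kids) for kids in self._children.values())

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._children.get(u, ())

    def parents(self, node: str) -> frozenset[str]:
        self._check_node(node)
        return frozenset(self._parents[node])

    def children(self, node: str) -> frozenset[str]:
        self._check_node(node)
        return frozenset(self._children[node])

    def copy(self) -> "DirectedGraph":
        g = type(self)()
        g._parents = {n: set(ps) for n, ps in self._parents.items()}
        g._children = {n: set(cs) for n, cs in self._children.items()}
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}({len(self._parents)} nodes, "
            f"{self.n_edges()} edges)"
        )

    # -- reachability (used for incremental acyclicity checks) -------------
    def reaches(self, src: str, dst: str) -> bool:
        """True iff a directed path src ->* dst exists (src == dst counts)."""
        if src == dst:
            return True
        stack, seen = [src], {src}
        while stack:
            for w in self._children[stack.pop()]:
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False


class DAG(DirectedGraph):
    """Directed acyclic graph; acyclicity is checkable, not enforced per edge.

    Search code mutates a DAG through pre-validated moves, so edge insertion
    does not re-run a full cycle check.  ``topological_order`` raises
    CycleError if an invalid sequence of mutations produced a cycle.
    """

    def is_acyclic(self) -> bool:
        try:
            topological_order(self)
            return True
        except CycleError:
            return False

    def is_acyclic_after(self, op: str, u: str, v: str) -> bool:
        """Would applying move (op, u, v) leave the graph acyclic?

        op is "add", "delete" or "reverse"; the graph is not mutated.
        """
        self._check_node(u)
        self._check_node(v)
        if op == "delete":
            if not self.has_edge(u, v):
                raise UnknownEdgeError(f"edge {u!r} -> {v!r} not present")
            return True
        if op == "add":
            if u == v:
                return False
            # u -> v closes a cycle iff v already reaches u
            return not self.reaches(v, u)
        if op == "reverse":
            if not self.has_edge(u, v):
                raise UnknownEdgeError(f"edge {u!r} -> {v!r} not present")
            # v -> u closes a cycle iff u reaches v via a path other than u->v
            self.remove_edge(u, v)
            try:
                return not self.reaches(u, v)
            finally:
                self.add_edge(u, v)
        raise ValueError(f"unknown move kind {op!r}")


def topological_order(g: DirectedGraph) -> list[str]:
    """Kahn's algorithm; deterministic (sorted) tie-breaking.

    Raises CycleError carrying one cycle's node sequence if none exists.
    """
    indeg = {n: len(g.parents(n)) for n in g.nodes}
    ready = sorted(n for n, d in indeg.items() if d == 0)
    order: list[str] = []
    while ready:
        n = ready.pop(0)
        order.append(n)
        for m in sorted(g.children(n)):
            indeg[m] -= 1
            if indeg[m] == 0:
                ready.append(m)
        ready.sort()
    if len(order) != len(indeg):
        remaining = {n for n, d in indeg.items() if d > 0}
        # walk parents inside the remaining set until a node repeats
        start = min(remaining)
        walk, seen = [start], {start}
        while True:
            prev = min(p for p in g.parents(walk[-1]) if p in remaining)
            if prev in seen:
                cycle = walk[walk.index(prev):] + [prev]
                raise CycleError(reversed(cycle))
            walk.append(prev)
            seen.add(prev)
    return order


class Skeleton:
    """Undirected adjacency structure (a DAG stripped of orientations)."""

    def __init__(self, nodes: Iterable[str], adjacencies: Iterable[frozenset] = ()):
        self.nodes = frozenset(nodes)
        self._adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for pair in adjacencies:
            a, b = tuple(pair)
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            raise ValidationError(f"self-adjacency {a!r}")
        if a not in self.nodes or b not in self.nodes:
            raise UnknownNodeError(f"adjacency {{{a!r}, {b!r}}} references unknown node")
        self._adj[a].add(b)
        self._adj[b].add(a)

    def remove(self, a: str, b: str) -> None:
        self._adj[a].discard(b)
        self._adj[b].discard(a)

    def has(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def neighbors(self, node: str) -> frozenset[str]:
        if node not in self.nodes:
            raise UnknownNodeError(f"unknown node {node!r}")
        return frozenset(self._adj[node])

    @property
    def adjacencies(self) -> frozenset[frozenset]:
        return frozenset(
            frozenset((a, b)) for a, nbrs in self._adj.items() for b in nbrs
        )

    def __len__(self) -> int:
        return len(self.adjacencies)

    @classmethod
    def from_dag(cls, g: DirectedGraph) -> "Skeleton":
        return cls(g.nodes, (frozenset(e) for e in g.edges))


@dataclass
class CPT:
    """Conditional probability table P(child | parents).

    ``table`` has shape (q, r): one row per parent configuration (row-major
    over ``parent_levels`` in declared parent order; q=1 for roots) and one
    column per child level.
    """

    child: str
    parents: tuple[str, ...]
    child_levels: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: np.ndarray

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.child_levels = tuple(self.child_levels)
        self.parent_levels = tuple(tuple(ls) for ls in self.parent_levels)
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod([len(ls) for ls in self.parent_levels])) if self.parents else 1
        r = len(self.child_levels)
        if self.table.shape != (q, r):
            raise ValidationError(
                f"CPT for {self.child!r}: table shape {self.table.shape} != ({q}, {r})"
            )
        if np.any(self.table < -1e-12) or np.any(self.table > 1 + 1e-12):
            raise ValidationError(f"CPT for {self.child!r}: entries outside [0, 1]")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError(f"CPT for {self.child!r}: rows do not sum to 1")

    @property
    def n_configurations(self) -> int:
        return self.table.shape[0]

    def configurations(self):
        """Parent-level tuples in row order."""
        if not self.parents:
            return [()]
        return list(itertools.product(*self.parent_levels))

    def row_index(self, config: Sequence[str]) -> int:
        if len(config) != len(self.parents):
            raise ValidationError(
                f"CPT for {self.child!r}: configuration arity {len(config)}"
            )
        idx = 0
        for level, levels in zip(config, self.parent_levels):
            idx = idx * len(levels) + levels.index(level)
        return idx

    def prob(self, config: Sequence[str]) -> dict[str, float]:
        row = self.table[self.row_index(tuple(config))]
        return dict(zip(self.child_levels, row.tolist()))


@dataclass
class DiscreteBayesianNetwork:
    """A DAG plus one CPT per node; the joint factorises over families."""

    variables: list[CategoricalVariable]
    graph: DAG
    cpts: dict[str, CPT] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable names")
        if set(names) != set(self.graph.nodes):
            raise ValidationError("graph nodes do not match declared variables")
        if set(self.cpts) != set(names):
            raise ValidationError("need exactly one CPT per variable")
        by_name = {v.name: v for v in self.variables}
        for name, cpt in self.cpts.items():
            if cpt.child != name:
                raise ValidationError(f"CPT child {cpt.child!r} filed under {name!r}")
            if set(cpt.parents) != set(self.graph.parents(name)):
                raise ValidationError(
                    f"CPT parents of {name!r} do not match graph parents"
                )
            if cpt.child_levels != by_name[name].levels:
                raise ValidationError(f"CPT child levels mismatch for {name!r}")
            for p, ls in zip(cpt.parents, cpt.parent_levels):
                if ls != by_name[p].levels:
                    raise ValidationError(
                        f"CPT parent levels mismatch for {p!r} in family of {name!r}"
                    )
        if not self.graph.is_acyclic():
            raise ValidationError("graph contains a cycle")

    @property
    def variable_map(self) -> dict[str, CategoricalVariable]:
        return {v.name: v for v in self.variables}

    def __getitem__(self, name: str) -> CategoricalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise UnknownNodeError(f"unknown variable {name!r}")


class Dataset:
    """Complete categorical observations, stored as integer level codes.

    ``codes`` is an (n, p) int array; entry [i, j] indexes into
    ``variables[j].levels``.  Missing data is rejected (complete-case
    analysis); pass ``dropna=True`` to ``from_dataframe`` for listwise
    deletion.
    """

    def __init__(self, variables: Sequence[CategoricalVariable], codes: np.ndarray):
        self.variables = list(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable names in dataset")
        codes = np.asarray(codes)
        if codes.ndim != 2 or codes.shape[1] != len(self.variables):
            raise ValidationError("codes must be (n, p) with one column per variable")
        if codes.shape[0] < 1:
            raise ValidationError("dataset needs at least one row")
        self.codes = np.ascontiguousarray(codes, dtype=np.int32)
        self._col = {v.name: j for j, v in enumerate(self.variables)}
        for j, v in enumerate(self.variables):
            col = self.codes[:, j]
            if col.min() < 0 or col.max() >= v.cardinality:
                raise ValidationError(f"codes out of range for variable {v.name!r}")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.codes[:, self._col[name]]
        except KeyError:
            raise UnknownNodeError(f"unknown variable {name!r}") from None

    def variable(self, name: str) -> CategoricalVariable:
        return self.variables[self._col[name]]

    def cardinality(self, name: str) -> int:
        return self.variable(name).cardinality

    # -- conversions -------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        schema: Sequence[CategoricalVariable] | None = None,
        dropna: bool = False,
    ) -> "Dataset":
        if dropna:
            df = df.dropna()
        elif df.isna().any().any():
            raise ValidationError(
                "missing values present; pass dropna=True for listwise deletion"
            )
        if schema is None:
            # levels inferred in first-appearance order
            schema = [
                CategoricalVariable(
                    str(c), tuple(pd.unique(df[c].astype(str)))
                )
                for c in df.columns
            ]
        else:
            schema = list(schema)
            if [v.name for v in schema] != [str(c) for c in df.columns]:
                raise ValidationError("schema variables do not match dataframe columns")
        codes = np.empty((len(df), len(schema)), dtype=np.int32)
        violations = []
        for j, v in enumerate(schema):
            mapping = {lev: i for i, lev in enumerate(v.levels)}
            col = df.iloc[:, j].astype(str)
            mapped = col.map(mapping)
            bad = mapped.isna()
            if bad.any():
                for i in np.flatnonzero(bad.to_numpy())[:20]:
                    violations.append((int(i), v.name, col.iloc[int(i)]))
            else:
                codes[:, j] = mapped.to_numpy(dtype=np.int32)
        if violations:
            raise SchemaViolationError(violations)
        return cls(schema, codes)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for j, v in enumerate(self.variables):
            levels = np.asarray(v.levels, dtype=object)
            cols[v.name] = levels[self.codes[:, j]]
        return pd.DataFrame(cols)

    def __repr__(self) -> str:
        return f"Dataset({self.n} rows, {len(self.variables)} variables)"


def joint_enumeration(net: DiscreteBayesianNetwork):
    """Yield (assignment dict, probability) over every joint configuration.

    Brute force: intended for validation and small-network oracles only
    (product of cardinalities up to ~2^20).
    """
    order = topological_order(net.graph)
    level_lists = [net[name].levels for name in order]
    cpts = {name: net.cpts[name] for name in order}
    for combo in itertools.product(*level_lists):
        assignment = dict(zip(order, combo))
        p = 1.0
        for name in order:
            cpt = cpts[name]
            cfg = tuple(assignment[par] for par in cpt.parents)
            p *= cpt.table[cpt.row_index(cfg), cpt.child_levels.index(assignment[name])]
        yield assignment, p
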