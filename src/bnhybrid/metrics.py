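"""Structural error metrics and the benchmark experiment driver.

A learned DAG is compared with the benchmark truth edge by edge:

    R(E)  reversed  — adjacent in both, opposite orientation
    M(E)  missing   — adjacent in the truth only
    A(E)  extra     — adjacent in the learned graph only
    S(E)  total     = A(E) + M(E) + 0.5·R(E)

A reversal costs half an error because the adjacency itself was found.
Comparison is DAG-vs-DAG, deliberately not equivalence-class aware: an edge
learned against the true orientation counts as reversed even when the two
graphs are Markov equivalent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .core import DAG
from .errors import NegativeComponentError, NodeSetMismatchError
from .learn import ALGORITHMS, TabuParams, learn_hybrid
from .netgen import load_fixture, replicate_datasets

__all__ = [
    "StructuralErrorReport",
    "BenchmarkTable",
    "compare_structures",
    "weighted_total",
    "run_benchmark",
]

REVERSE_WEIGHT = 0.5


def weighted_total(r: float, m: float, a: float) -> float:
    """S(E) = A(E) + M(E) + 0.5·R(E); accepts real-valued (mean) components."""
    if r < 0 or m < 0 or a < 0:
        raise NegativeComponentError("error components must be non-negative")
    return a + m + REVERSE_WEIGHT * r


@dataclass(frozen=True)
class StructuralErrorReport:
    reversed_: int
    missing: int
    extra: int

    @property
    def total(self) -> float:
        return weighted_total(self.reversed_, self.missing, self.extra)

    def as_dict(self) -> dict:
        return {"R": self.reversed_, "M": self.missing, "A": self.extra,
                "S": self.total}


def compare_structures(learned: DAG, truth: DAG) -> StructuralErrorReport:
    """Count reversed / missing / extra edges of ``learned`` against ``truth``."""
    if learned.nodes != truth.nodes:
        raise NodeSetMismatchError("graphs are defined over different node sets")
    le, te = learned.edges, truth.edges
    reversed_ = sum(1 for (u, v) in te if (v, u) in le)
    missing = sum(1 for (u, v) in te if (u, v) not in le and (v, u) not in le)
    extra = sum(1 for (u, v) in le if (u, v) not in te and (v, u) not in te)
    return StructuralErrorReport(reversed_, missing, extra)


@dataclass
class BenchmarkCell:
    size: int
    algorithm: str
    rep: int
    seed: int
    report: StructuralErrorReport
    restriction_ok: bool  # learned edges all inside the phase-1 skeleton


@dataclass
class BenchmarkTable:
    """Mean R/M/A/S per (sample size, algorithm) over replicates."""

    fixture: str
    reps: int
    base_seed: int
    cells: list[BenchmarkCell] = field(default_factory=list)
    failures: int = 0

    def mean(self, size: int, algorithm: str) -> dict[str, float]:
        sel = [c for c in self.cells if c.size == size and c.algorithm == algorithm]
        if not sel:
            raise KeyError(f"no cells for (n={size}, {algorithm})")
        k = len(sel)
        r = sum(c.report.reversed_ for c in sel) / k
        m = sum(c.report.missing for c in sel) / k
        a = sum(c.report.extra for c in sel) / k
        return {"R": r, "M": m, "A": a, "S": weighted_total(r, m, a), "reps": k}

    def sizes(self) -> list[int]:
        return sorted({c.size for c in self.cells})

    def algorithms(self) -> list[str]:
        seen: list[str] = []
        for c in self.cells:
            if c.algorithm not in seen:
                seen.append(c.algorithm)
        return seen

    def to_json(self) -> str:
        payload = {
            "fixture": self.fixture,
            "reps": self.reps,
            "base_seed": self.base_seed,
            "cells": [
                {"size": s, "algorithm": a, **self.mean(s, a)}
                for s in self.sizes()
                for a in self.algorithms()
            ],
            "replicates": [
                {
                    "size": c.size, "algorithm": c.algorithm, "rep": c.rep,
                    "seed": c.seed, **c.report.as_dict(),
                    "restriction_ok": c.restriction_ok,
                }
                for c in self.cells
            ],
        }
        return json.dumps(payload, indent=1)

    def render(self) -> str:
        """Plain-text table in the benchmark layout: R(E) M(E) A(E) S(E)."""
        lines = [f"{'Sample size':>11}  {'algorithm':<16} {'R(E)':>6} {'M(E)':>6} "
                 f"{'A(E)':>6} {'S(E)':>6}"]
        for s in self.sizes():
            for a in self.algorithms():
                m = self.mean(s, a)
                lines.append(
                    f"{s:>11}  {a:<16} {m['R']:>6.2f} {m['M']:>6.2f} "
                    f"{m['A']:>6.2f} {m['S']:>6.2f}"
                )
        return "\n".join(lines)


def run_benchmark(
    truth_fixture: str,
    algorithms: list[str],
    sizes: list[int],
    reps: int = 10,
    base_seed: int = 1,
    alpha: float = 0.05,
    params: TabuParams | None = None,
) -> BenchmarkTable:
    """Sample → learn → compare, for every (size, rep, algorithm) cell.

    Each algorithm name must be a key of ``learn.ALGORITHMS``.  A failed
    learner run is recorded as a warning and excluded from the mean; it
    never silently degrades to an empty graph.
    """
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithms: {unknown}")
    fixture = load_fixture(truth_fixture)
    truth = fixture.network.graph
    datasets = replicate_datasets(fixture.network, sizes, reps, base_seed)
    table = BenchmarkTable(truth_fixture, reps, base_seed)
    for si, size in enumerate(sizes):
        for rep in range(reps):
            data = datasets[(size, rep)]
            seed = base_seed * 10_000 + si * 100 + rep
            for algo in algorithms:
                skel_m, search_m = ALGORITHMS[algo]
                try:
                    result = learn_hybrid(
                        data, skel_m, search_m, alpha=alpha, params=params, seed=seed
                    )
                except Exception as exc:  # recorded, not swallowed silently
                    warnings.warn(
                        f"{algo} failed on (n={size}, rep={rep}): {exc}",
                        stacklevel=2,
                    )
                    table.failures += 1
                    continue
                ok = all(
                    result.skeleton.has(u, v) for u, v in result.dag.edges
                )
                table.cells.append(
                    BenchmarkCell(size, algo, rep, seed,
                                  compare_structures(result.dag, truth), ok)
                )
    return table
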