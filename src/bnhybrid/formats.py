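"""File formats: BIF 0.15 networks, a JSON network dialect, CSV datasets, DOT.

BIF (Bayesian Interchange Format) is the interchange standard; the parser
accepts the usual ``network`` / ``variable`` / ``probability`` blocks and is
lenient about value tokens (any run of non-delimiter characters), so level
labels like ``18.5~`` or ``≥6g`` survive a round trip.  Probabilities are
written with 12 significant digits, making write→read the identity up to
whitespace.

The JSON dialect mirrors the in-memory type model one-to-one and is the
debugging-friendly alternative to BIF.
"""

from __future__ import annotations

import json
import re
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import (
    CPT,
    DAG,
    CategoricalVariable,
    Dataset,
    DiscreteBayesianNetwork,
)
from .errors import ParseError, ValidationError

__all__ = [
    "read_bif",
    "write_bif",
    "read_json_network",
    "write_json_network",
    "read_csv_dataset",
    "write_csv_dataset",
    "write_dot",
]


# ---------------------------------------------------------------------------
# BIF

_DELIMS = set("{}()|,;[]")


def _tokenize(text: str):
    """Yield (token, line) pairs; // and % comments run to end of line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = re.split(r"//|%", line, maxsplit=1)[0]
        for m in re.finditer(r"[{}()|,;\[\]]|[^\s{}()|,;\[\]]+", line):
            yield m.group(0), lineno


class _TokenStream:
    def __init__(self, text: str):
        self._tokens = list(_tokenize(text))
        self._pos = 0

    def peek(self):
        return self._tokens[self._pos][0] if self._pos < len(self._tokens) else None

    @property
    def line(self):
        i = min(self._pos, len(self._tokens) - 1)
        return self._tokens[i][1] if self._tokens else 0

    def next(self):
        if self._pos >= len(self._tokens):
            raise ParseError("unexpected end of file", self.line)
        tok, _ = self._tokens[self._pos]
        self._pos += 1
        return tok

    def expect(self, tok: str):
        got = self.next()
        if got != tok:
            raise ParseError(f"expected {tok!r}, got {got!r}", self.line)

    def skip_block(self):
        """Consume a balanced { ... } block."""
        self.expect("{")
        depth = 1
        while depth:
            tok = self.next()
            if tok == "{":
                depth += 1
            elif tok == "}":
                depth -= 1


def _parse_float(tok: str, line: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"malformed probability {tok!r}", line) from None


def read_bif(path) -> DiscreteBayesianNetwork:
    """Parse a BIF file into a network; raises ParseError with the line."""
    with open(path, encoding="utf-8") as fh:
        ts = _TokenStream(fh.read())
    variables: list[CategoricalVariable] = []
    levels: dict[str, tuple[str, ...]] = {}
    cpt_specs: list[tuple[str, tuple[str, ...], list, int]] = []

    while ts.peek() is not None:
        kind = ts.next()
        if kind == "network":
            ts.next()  # name
            ts.skip_block()
        elif kind == "variable":
            name = ts.next()
            ts.expect("{")
            ts.expect("type")
            ts.expect("discrete")
            ts.expect("[")
            declared = int(ts.next())
            ts.expect("]")
            ts.expect("{")
            levs = []
            while ts.peek() != "}":
                tok = ts.next()
                if tok != ",":
                    levs.append(tok)
            ts.expect("}")
            if ts.peek() == ";":
                ts.next()
            ts.expect("}")
            if declared != len(levs):
                raise ParseError(
                    f"variable {name!r} declares {declared} levels, lists {len(levs)}",
                    ts.line,
                )
            variables.append(CategoricalVariable(name, tuple(levs)))
            levels[name] = tuple(levs)
        elif kind == "probability":
            line0 = ts.line
            ts.expect("(")
            child = ts.next()
            parents: list[str] = []
            if ts.peek() == "|":
                ts.next()
                while ts.peek() != ")":
                    tok = ts.next()
                    if tok != ",":
                        parents.append(tok)
            ts.expect(")")
            ts.expect("{")
            entries = []
            while ts.peek() != "}":
                tok = ts.next()
                if tok == "table":
                    probs = []
                    while ts.peek() != ";":
                        t2 = ts.next()
                        if t2 != ",":
                            probs.append(_parse_float(t2, ts.line))
                    ts.next()  # ;
                    entries.append(((), probs))
                elif tok == "(":
                    cfg = []
                    while ts.peek() != ")":
                        t2 = ts.next()
                        if t2 != ",":
                            cfg.append(t2)
                    ts.next()  # )
                    probs = []
                    while ts.peek() != ";":
                        t2 = ts.next()
                        if t2 != ",":
                            probs.append(_parse_float(t2, ts.line))
                    ts.next()  # ;
                    entries.append((tuple(cfg), probs))
                else:
                    raise ParseError(f"unexpected token {tok!r} in probability block",
                                     ts.line)
            ts.expect("}")
            cpt_specs.append((child, tuple(parents), entries, line0))
        else:
            raise ParseError(f"unexpected token {kind!r}", ts.line)

    cpts: dict[str, CPT] = {}
    for child, parents, entries, line0 in cpt_specs:
        if child not in levels:
            raise ParseError(f"probability block for undeclared variable {child!r}",
                             line0)
        child_levels = levels[child]
        parent_levels = tuple(levels[p] for p in parents)
        q = int(np.prod([len(ls) for ls in parent_levels])) if parents else 1
        table = np.full((q, len(child_levels)), np.nan)
        probe = CPT.__new__(CPT)  # row_index helper without validation
        probe.child, probe.parents = child, tuple(parents)
        probe.child_levels, probe.parent_levels = child_levels, parent_levels
        for cfg, probs in entries:
            if len(probs) != len(child_levels):
                raise ParseError(
                    f"{child!r}: {len(probs)} probabilities for "
                    f"{len(child_levels)} levels", line0,
                )
            idx = CPT.row_index(probe, cfg) if parents else 0
            table[idx] = probs
        if np.isnan(table).any():
            raise ValidationError(f"CPT for {child!r} is missing rows")
        cpts[child] = CPT(child, tuple(parents), child_levels, parent_levels, table)

    names = [v.name for v in variables]
    edges = [(p, c.child) for c in cpts.values() for p in c.parents]
    graph = DAG(names, edges)
    return DiscreteBayesianNetwork(variables, graph, cpts)


def _fmt(p: float) -> str:
    return f"{p:.12g}"


def write_bif(net: DiscreteBayesianNetwork, path, name: str = "network") -> None:
    lines = [f"network {name} {{", "}"]
    for v in net.variables:
        lines += [
            f"variable {v.name} {{",
            f"  type discrete [ {v.cardinality} ] {{ {', '.join(v.levels)} }};",
            "}",
        ]
    for v in net.variables:
        cpt = net.cpts[v.name]
        if cpt.parents:
            header = f"probability ( {v.name} | {', '.join(cpt.parents)} ) {{"
            lines.append(header)
            for cfg, row in zip(cpt.configurations(), cpt.table):
                probs = ", ".join(_fmt(p) for p in row)
                lines.append(f"  ( {', '.join(cfg)} ) {probs};")
            lines.append("}")
        else:
            lines += [
                f"probability ( {v.name} ) {{",
                f"  table {', '.join(_fmt(p) for p in cpt.table[0])};",
                "}",
            ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON dialect

def write_json_network(net: DiscreteBayesianNetwork, path=None) -> str:
    payload = {
        "variables": [{"name": v.name, "levels": list(v.levels)} for v in net.variables],
        "edges": sorted([list(e) for e in net.graph.edges]),
        "cpts": {
            name: {
                "parents": list(cpt.parents),
                "table": [[float(p) for p in row] for row in cpt.table],
            }
            for name, cpt in net.cpts.items()
        },
    }
    text = json.dumps(payload, indent=1, ensure_ascii=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def read_json_network(source) -> DiscreteBayesianNetwork:
    """Accepts a path or a JSON string."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source, encoding="utf-8") as fh:
            payload = json.load(fh)
    variables = [
        CategoricalVariable(v["name"], tuple(v["levels"])) for v in payload["variables"]
    ]
    levels = {v.name: v.levels for v in variables}
    graph = DAG([v.name for v in variables], [tuple(e) for e in payload["edges"]])
    cpts = {}
    for name, spec in payload["cpts"].items():
        parents = tuple(spec["parents"])
        cpts[name] = CPT(
            name, parents, levels[name], tuple(levels[p] for p in parents),
            np.asarray(spec["table"], dtype=float),
        )
    return DiscreteBayesianNetwork(variables, graph, cpts)


# ---------------------------------------------------------------------------
# CSV datasets

def read_csv_dataset(
    path, schema: Sequence[CategoricalVariable] | None = None, dropna: bool = False
) -> Dataset:
    """RFC-4180 CSV with a header row; levels inferred in first-appearance
    order when no schema is given, validated against it when present."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    return Dataset.from_dataframe(df, schema=schema, dropna=dropna)


def write_csv_dataset(data: Dataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DOT export

def write_dot(graph: DAG, path=None, name: str = "G") -> str:
    lines = [f"digraph {name} {{"]
    for n in sorted(graph.nodes):
        lines.append(f'  "{n}";')
    for u, v in sorted(graph.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
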