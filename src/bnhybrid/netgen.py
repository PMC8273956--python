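"""Bundled benchmark networks and ancestral (forward) sampling.

Three fixtures ship with the package:

``sprinkler4``
    The canonical 4-node cloud/sprinkler/rain/wet-grass network; small
    enough for closed-form oracle checks.

``car20``
    A 20-node / 22-edge car-diagnosis network used as the structure-recovery
    benchmark.  The published figure fixes only the topology, so the
    parameterisation here is a declared surrogate: every variable is binary
    {ok, bad}, every root has P(ok) = 0.8, and every non-root follows the
    noisy-threshold rule  P(ok | parents) = max(0.05, 0.95 − 0.60·b)  with b
    the number of parents in state "bad".  Dependencies are strong enough
    for recovery experiments and the rule is portable across languages.

``lipid10``
    A 10-node / 14-arc hyperlipidemia survey network.  The hyperlipidemia
    CPT is transcribed from the published conditional-probability table;
    every other CPT is a documented surrogate (see ``epi`` module notes).

Sampling is ancestral: nodes are drawn in topological order, each from its
CPT row given the already-sampled parents, using numpy's seeded PCG64
generator.  Replicated designs derive per-dataset seeds by the documented
rule  seed = base_seed·10_000 + size_index·100 + rep.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import (
    CPT,
    DAG,
    CategoricalVariable,
    Dataset,
    DiscreteBayesianNetwork,
    topological_order,
)
from .errors import UnknownFixtureError

__all__ = [
    "BenchmarkFixture",
    "load_fixture",
    "forward_sample",
    "replicate_datasets",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("car20", "sprinkler4", "lipid10")


@dataclass(frozen=True)
class BenchmarkFixture:
    name: str
    network: DiscreteBayesianNetwork
    notes: str


# ---------------------------------------------------------------------------
# sprinkler4

_SPRINKLER_EDGES = [
    ("Cloudy", "Sprinkler"),
    ("Cloudy", "Rain"),
    ("Sprinkler", "WetGrass"),
    ("Rain", "WetGrass"),
]


def _binary_cpt(child, parents, parent_levels, p_first, levels=("T", "F")):
    """CPT over two child levels from the per-row probability of the first."""
    p = np.asarray(p_first, dtype=float).reshape(-1, 1)
    return CPT(child, tuple(parents), tuple(levels), tuple(parent_levels),
               np.hstack([p, 1.0 - p]))


def _sprinkler4() -> DiscreteBayesianNetwork:
    tf = ("T", "F")
    variables = [CategoricalVariable(n, tf) for n in ("Cloudy", "Sprinkler", "Rain", "WetGrass")]
    graph = DAG([v.name for v in variables], _SPRINKLER_EDGES)
    cpts = {
        "Cloudy": _binary_cpt("Cloudy", (), (), [0.5]),
        "Sprinkler": _binary_cpt("Sprinkler", ("Cloudy",), (tf,), [0.1, 0.5]),
        "Rain": _binary_cpt("Rain", ("Cloudy",), (tf,), [0.8, 0.2]),
        "WetGrass": _binary_cpt(
            "WetGrass", ("Sprinkler", "Rain"), (tf, tf), [0.99, 0.90, 0.90, 0.00]
        ),
    }
    return DiscreteBayesianNetwork(variables, graph, cpts)


# ---------------------------------------------------------------------------
# car20

CAR20_EDGES = [
    ("BatteryAge", "BatteryState"),
    ("Alternator", "ChargingSystem"),
    ("ChargingSystem", "BatteryState"),
    ("BatteryState", "BatteryVoltage"),
    ("MainFuse", "VoltageAtPlug"),
    ("BatteryVoltage", "VoltageAtPlug"),
    ("Distributor", "VoltageAtPlug"),
    ("Distributor", "SparkTiming"),
    ("VoltageAtPlug", "SparkQuality"),
    ("SparkPlugs", "SparkQuality"),
    ("SparkTiming", "SparkQuality"),
    ("BatteryVoltage", "Starter"),
    ("StarterMotor", "Starter"),
    ("Starter", "CarCranks"),
    ("BatteryVoltage", "CarCranks"),
    ("FuelPump", "FuelSystem"),
    ("FuelSystem", "CarStarts"),
    ("AirFilter", "AirSystem"),
    ("AirSystem", "CarStarts"),
    ("SparkQuality", "CarStarts"),
    ("CarCranks", "CarStarts"),
    ("BatteryVoltage", "Headlights"),
]

CAR20_NODES = [
    "BatteryAge", "Alternator", "ChargingSystem", "BatteryState",
    "BatteryVoltage", "MainFuse", "Distributor", "VoltageAtPlug",
    "SparkPlugs", "SparkTiming", "SparkQuality", "StarterMotor", "Starter",
    "CarCranks", "FuelPump", "FuelSystem", "AirFilter", "AirSystem",
    "CarStarts", "Headlights",
]

#: surrogate noisy-threshold rule for binary {ok, bad} children
ROOT_P_OK = 0.8


def noisy_threshold_p_ok(n_bad_parents: int) -> float:
    return max(0.05, 0.95 - 0.60 * n_bad_parents)


def _car20() -> DiscreteBayesianNetwork:
    ok_bad = ("ok", "bad")
    variables = [CategoricalVariable(n, ok_bad) for n in CAR20_NODES]
    graph = DAG(CAR20_NODES, CAR20_EDGES)
    cpts = {}
    for node in CAR20_NODES:
        parents = tuple(sorted(graph.parents(node)))
        if not parents:
            cpts[node] = _binary_cpt(node, (), (), [ROOT_P_OK], ok_bad)
        else:
            rows = []
            for combo in itertools.product(ok_bad, repeat=len(parents)):
                b = sum(1 for lv in combo if lv == "bad")
                rows.append(noisy_threshold_p_ok(b))
            cpts[node] = _binary_cpt(
                node, parents, tuple(ok_bad for _ in parents), rows, ok_bad
            )
    return DiscreteBayesianNetwork(variables, graph, cpts)


# ---------------------------------------------------------------------------
# lipid10

LIPID10_EDGES = [
    ("Gender", "Smoking"),
    ("Gender", "PhysicalActivity"),
    ("Gender", "Hyperlipidemia"),
    ("PhysicalActivity", "BMI"),
    ("BMI", "Hyperlipidemia"),
    ("PhysicalActivity", "Hyperlipidemia"),
    ("BMI", "CentralObesity"),
    ("Hyperlipidemia", "Hypertension"),
    ("Hyperlipidemia", "Diabetes"),
    ("Smoking", "Hypertension"),
    ("SaltIntake", "Hypertension"),
    ("OilIntake", "Hypertension"),
    ("CentralObesity", "Hypertension"),
    ("CentralObesity", "Diabetes"),
]

PA_LEVELS = ("Insufficient", "Normal", "Sufficient")
BMI_LEVELS = ("<18.5", "18.5~", "24.0~", "28.0~")

#: detection rate of hyperlipidemia (percent "yes") per
#: (PhysicalActivity, Gender, BMI) configuration, transcribed from the
#: published conditional-probability table; row order is row-major over
#: PA_LEVELS x (male, female) x BMI_LEVELS.
HYPERLIPIDEMIA_YES_PERCENT = [
    # Insufficient, male
    35.149, 42.485, 62.074, 75.273,
    # Insufficient, female
    30.603, 42.336, 41.72, 62.112,
    # Normal, male
    5.189, 38.905, 56.312, 70.706,
    # Normal, female
    17.836, 29.592, 47.125, 56.547,
    # Sufficient, male
    47.642, 33.537, 56.358, 74.941,
    # Sufficient, female
    37.805, 35.827, 44.388, 51.761,
]

#: fraction of males among the survey's complete cases (2236 of 4567)
P_MALE = 2236 / 4567

# Surrogate CPTs for everything except the hyperlipidemia node (only the
# hyperlipidemia table is published).  Chosen once so that the enumerated
# marginal P(Hyperlipidemia = yes) lands in [0.42, 0.50] and central
# obesity rises steeply with BMI class.
_PA_GIVEN_GENDER = {  # (Insufficient, Normal, Sufficient)
    "male": (0.32, 0.40, 0.28),
    "female": (0.38, 0.40, 0.22),
}
_BMI_GIVEN_PA = {  # (<18.5, 18.5~, 24.0~, 28.0~)
    "Insufficient": (0.04, 0.42, 0.36, 0.18),
    "Normal": (0.05, 0.47, 0.33, 0.15),
    "Sufficient": (0.06, 0.52, 0.32, 0.10),
}
_SMOKING_YES_GIVEN_GENDER = {"male": 0.52, "female": 0.03}
_CENTRAL_OBESITY_YES_GIVEN_BMI = (0.02, 0.20, 0.55, 0.97)
_P_SALT_HIGH = 0.60
_P_OIL_HIGH = 0.55


def _lipid10() -> DiscreteBayesianNetwork:
    no_yes = ("no", "yes")
    variables = [
        CategoricalVariable("Gender", ("male", "female")),
        CategoricalVariable("Smoking", no_yes),
        CategoricalVariable("PhysicalActivity", PA_LEVELS),
        CategoricalVariable("SaltIntake", ("<6g", "≥6g")),
        CategoricalVariable("OilIntake", ("<25g", "≥25g")),
        CategoricalVariable("BMI", BMI_LEVELS),
        CategoricalVariable("CentralObesity", no_yes),
        CategoricalVariable("Hyperlipidemia", no_yes),
        CategoricalVariable("Hypertension", no_yes),
        CategoricalVariable("Diabetes", no_yes),
    ]
    names = [v.name for v in variables]
    graph = DAG(names, LIPID10_EDGES)
    gender = ("male", "female")

    yes = np.asarray(HYPERLIPIDEMIA_YES_PERCENT, dtype=float) / 100.0
    hyper = CPT(
        "Hyperlipidemia",
        ("PhysicalActivity", "Gender", "BMI"),
        no_yes,
        (PA_LEVELS, gender, BMI_LEVELS),
        np.column_stack([1.0 - yes, yes]),
    )

    pa_rows = np.array([_PA_GIVEN_GENDER[g] for g in gender])
    bmi_rows = np.array([_BMI_GIVEN_PA[a] for a in PA_LEVELS])

    levels_of = {v.name: v.levels for v in variables}

    def risk_cpt(child, parents, risky):
        """Noisy-threshold CPT: P(no) = max(0.05, 0.95 − 0.60·b) where b
        counts parents observed at their risky level."""
        parent_levels = tuple(levels_of[p] for p in parents)
        rows = []
        for combo in itertools.product(*parent_levels):
            b = sum(1 for lv, r in zip(combo, risky) if lv == r)
            rows.append(noisy_threshold_p_ok(b))
        rows = np.asarray(rows)
        return CPT(child, parents, no_yes, parent_levels,
                   np.column_stack([rows, 1.0 - rows]))

    cpts = {
        "Gender": CPT("Gender", (), gender, (), [[P_MALE, 1 - P_MALE]]),
        "Smoking": _binary_cpt(
            "Smoking", ("Gender",), (gender,),
            [1 - _SMOKING_YES_GIVEN_GENDER[g] for g in gender], no_yes,
        ),
        "PhysicalActivity": CPT(
            "PhysicalActivity", ("Gender",), PA_LEVELS, (gender,), pa_rows
        ),
        "SaltIntake": _binary_cpt("SaltIntake", (), (), [1 - _P_SALT_HIGH],
                                  ("<6g", "≥6g")),
        "OilIntake": _binary_cpt("OilIntake", (), (), [1 - _P_OIL_HIGH],
                                 ("<25g", "≥25g")),
        "BMI": CPT("BMI", ("PhysicalActivity",), BMI_LEVELS, (PA_LEVELS,), bmi_rows),
        "CentralObesity": _binary_cpt(
            "CentralObesity", ("BMI",), (BMI_LEVELS,),
            [1 - p for p in _CENTRAL_OBESITY_YES_GIVEN_BMI], no_yes,
        ),
        "Hyperlipidemia": hyper,
        "Hypertension": risk_cpt(
            "Hypertension",
            ("Hyperlipidemia", "Smoking", "SaltIntake", "OilIntake", "CentralObesity"),
            ("yes", "yes", "≥6g", "≥25g", "yes"),
        ),
        "Diabetes": risk_cpt(
            "Diabetes", ("Hyperlipidemia", "CentralObesity"), ("yes", "yes")
        ),
    }
    return DiscreteBayesianNetwork(variables, graph, cpts)


_BUILDERS = {
    "sprinkler4": (_sprinkler4, "canonical cloud/sprinkler/rain/wet-grass network"),
    "car20": (
        _car20,
        "car-diagnosis topology (20 nodes, 22 edges) with surrogate "
        "noisy-threshold parameterisation",
    ),
    "lipid10": (
        _lipid10,
        "hyperlipidemia survey network (10 nodes, 14 arcs); hyperlipidemia "
        "CPT from the published table, all other CPTs documented surrogates; "
        "enumerated marginal P(Hyperlipidemia=yes) = 0.45489 (frozen)",
    ),
}

_CACHE: dict[str, BenchmarkFixture] = {}


def load_fixture(name: str) -> BenchmarkFixture:
    """Return one of the bundled benchmark networks by name."""
    if name not in _BUILDERS:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if name not in _CACHE:
        builder, notes = _BUILDERS[name]
        _CACHE[name] = BenchmarkFixture(name, builder(), notes)
    return _CACHE[name]


# ---------------------------------------------------------------------------
# sampling


def forward_sample(net: DiscreteBayesianNetwork, n: int, seed: int) -> Dataset:
    """Ancestral sampling: draw nodes in topological order from their CPTs.

    Reproducible for a fixed seed; column order follows the network's
    variable declaration order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = topological_order(net.graph)
    names = [v.name for v in net.variables]
    col = {name: j for j, name in enumerate(names)}
    codes = np.empty((n, len(names)), dtype=np.int32)
    for name in order:
        cpt = net.cpts[name]
        if cpt.parents:
            idx = np.zeros(n, dtype=np.int64)
            for p, levels in zip(cpt.parents, cpt.parent_levels):
                idx = idx * len(levels) + codes[:, col[p]]
            rows = cpt.table[idx]
        else:
            rows = np.broadcast_to(cpt.table[0], (n, cpt.table.shape[1]))
        u = rng.random(n)
        cdf = np.cumsum(rows, axis=1)
        codes[:, col[name]] = np.minimum(
            (u[:, None] > cdf).sum(axis=1), cpt.table.shape[1] - 1
        )
    return Dataset(list(net.variables), codes)


def replicate_seed(base_seed: int, size_index: int, rep: int) -> int:
    """Documented derivation rule for per-dataset seeds."""
    return base_seed * 10_000 + size_index * 100 + rep


def replicate_datasets(
    net: DiscreteBayesianNetwork,
    sizes: list[int],
    reps: int,
    base_seed: int,
) -> dict[tuple[int, int], Dataset]:
    """``reps`` independent datasets per sample size, keyed by (size, rep).

    Seeds follow ``replicate_seed`` so any single cell can be regenerated
    without rerunning the whole design.
    """
    if reps < 1 or not sizes:
        raise ValueError("need reps >= 1 and at least one size")
    out: dict[tuple[int, int], Dataset] = {}
    for si, size in enumerate(sizes):
        for rep in range(reps):
            out[(size, rep)] = forward_sample(net, size, replicate_seed(base_seed, si, rep))
    return out
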