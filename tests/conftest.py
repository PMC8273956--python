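"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use a different computational route from the
implementation they check: the joint distribution is materialised as one
dense tensor by broadcasting CPTs (no variable elimination), and the G²
statistic is accumulated cell by cell over an explicit contingency cube.
"""

import itertools
import math

import numpy as np
import pytest

from bnhybrid.core import CPT, DAG, CategoricalVariable, Dataset
from bnhybrid.core import DiscreteBayesianNetwork
from bnhybrid.netgen import load_fixture


def binary_cpt(child, parents, parent_levels, p_first, levels=("T", "F")):
    p = np.asarray(p_first, dtype=float).reshape(-1, 1)
    return CPT(child, tuple(parents), tuple(levels), tuple(parent_levels),
               np.hstack([p, 1.0 - p]))


@pytest.fixture(scope="session")
def sprinkler():
    return load_fixture("sprinkler4").network


@pytest.fixture(scope="session")
def car20():
    return load_fixture("car20").network


@pytest.fixture(scope="session")
def lipid10():
    return load_fixture("lipid10").network


@pytest.fixture(scope="session")
def chain_net():
    """X -> Y -> Z with strong binary CPTs (for d-separation checks)."""
    tf = ("T", "F")
    vs = [CategoricalVariable(n, tf) for n in "XYZ"]
    g = DAG("XYZ", [("X", "Y"), ("Y", "Z")])
    return DiscreteBayesianNetwork(vs, g, {
        "X": binary_cpt("X", (), (), [0.5]),
        "Y": binary_cpt("Y", ("X",), (tf,), [0.9, 0.2]),
        "Z": binary_cpt("Z", ("Y",), (tf,), [0.85, 0.15]),
    })


def random_binary_dataset(n, p, seed, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"V{i}" for i in range(p)]
    vs = [CategoricalVariable(nm, ("a", "b")) for nm in names]
    return Dataset(vs, rng.integers(0, 2, size=(n, p)))


# ---------------------------------------------------------------------------
# oracle: dense joint tensor by CPT broadcasting (no elimination machinery)

def full_joint_tensor(net):
    """Joint probability as a dense array with one axis per variable,
    in variable declaration order."""
    names = [v.name for v in net.variables]
    axis = {nm: i for i, nm in enumerate(names)}
    cards = [v.cardinality for v in net.variables]
    joint = np.ones(cards)
    for nm in names:
        cpt = net.cpts[nm]
        dims = tuple(cpt.parents) + (nm,)
        shape = [1] * len(names)
        arr = cpt.table.reshape(
            tuple(len(ls) for ls in cpt.parent_levels) + (len(cpt.child_levels),)
        )
        # transpose CPT axes into declaration-order positions
        order = np.argsort([axis[d] for d in dims])
        arr = np.transpose(arr, order)
        for d in dims:
            shape[axis[d]] = net.variable_map[d].cardinality
        joint = joint * arr.reshape(shape)
    return joint, names


def oracle_posterior(net, target, evidence):
    """Exact posterior by summing the dense joint tensor."""
    joint, names = full_joint_tensor(net)
    vm = net.variable_map
    index = tuple(
        vm[nm].levels.index(evidence[nm]) if nm in evidence else slice(None)
        for nm in names
    )
    sub = joint[index]
    keep = [nm for nm in names if nm not in evidence]
    sub = sub.sum(axis=tuple(i for i, nm in enumerate(keep) if nm != target))
    z = sub.sum()
    if z <= 0:
        return None
    return dict(zip(vm[target].levels, (sub / z).tolist()))


def brute_force_g2(data, x, y, z=()):
    """Cell-by-cell G² over the explicit contingency cube."""
    xv, yv = data.variable(x), data.variable(y)
    zlevels = [data.variable(v).levels for v in z]
    df_rows = data.to_dataframe()
    stat = 0.0
    for combo in itertools.product(*zlevels) if z else [()]:
        sub = df_rows
        for v, lev in zip(z, combo):
            sub = sub[sub[v] == lev]
        n_z = len(sub)
        if n_z == 0:
            continue
        for xl in xv.levels:
            for yl in yv.levels:
                o = int(((sub[x] == xl) & (sub[y] == yl)).sum())
                if o == 0:
                    continue
                n_xz = int((sub[x] == xl).sum())
                n_yz = int((sub[y] == yl).sum())
                stat += o * math.log(o * n_z / (n_xz * n_yz))
    return 2.0 * stat


def dataset_from_counts(counts, names=("X", "Y")):
    """Two-variable dataset realising a 2D contingency table exactly."""
    counts = np.asarray(counts, dtype=int)
    rows = []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            rows += [[i, j]] * counts[i, j]
    vs = [
        CategoricalVariable(names[0], tuple(f"x{i}" for i in range(counts.shape[0]))),
        CategoricalVariable(names[1], tuple(f"y{j}" for j in range(counts.shape[1]))),
    ]
    return Dataset(vs, np.asarray(rows))
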