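"""Synthetic hyperlipidemia survey pipeline and logistic-regression comparison.

Emulates a cross-sectional chronic-disease survey: a 10-variable synthetic
population is drawn from the ``lipid10`` network (the real survey microdata
is not deposited), then analysed two ways —

1. classical epidemiology: univariate chi-square screening (entry screen
   p < 0.5), stepwise logistic regression with score-test entry at
   alpha_in = 0.05 and Wald removal at alpha_out = 0.10, odds ratios with
   95% Wald confidence intervals;
2. Bayesian network: hybrid structure learning plus exact risk reasoning.

The comparison report juxtaposes each covariate's odds ratio with its
graph role (direct neighbour of the outcome, indirectly connected, or
unconnected) — the distinction a regression model cannot make.

Covariates enter the regression as single numeric codes in level order
(ordinal/binary scoring, one coefficient per variable), not as one-hot
dummies.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .core import DAG, Dataset, DiscreteBayesianNetwork
from .errors import DegenerateError, NonConvergenceError, SeparationError
from .netgen import forward_sample, load_fixture

__all__ = [
    "Z_95",
    "generate_survey",
    "chi2_screen",
    "trend_test",
    "stepwise_logistic",
    "or_from_coef",
    "proportion_ci",
    "comparison_report",
    "LogisticFit",
    "CovariateRow",
]

#: z quantile for 95% confidence intervals
Z_95 = 1.959964

#: univariate entry screen for stepwise candidates
CANDIDATE_P = 0.50


def generate_survey(n: int = 4567, seed: int = 2015) -> Dataset:
    """Forward-sample a complete-case synthetic survey from ``lipid10``."""
    return forward_sample(load_fixture("lipid10").network, n, seed)


def _pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateError("contingency table has an empty margin")
    expected = rows * cols / n
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def chi2_screen(data: Dataset, outcome: str) -> dict[str, dict]:
    """Pearson chi-square of every covariate against a binary outcome.

    Returns per-covariate {chi2, df, p, candidate}; ``candidate`` marks
    variables passing the deliberately loose entry screen p < 0.5 used to
    feed the stepwise model.  No continuity correction is applied.
    """
    if data.cardinality(outcome) != 2:
        raise ValueError("outcome must be binary")
    y = data.column(outcome)
    out: dict[str, dict] = {}
    for name in data.names:
        if name == outcome:
            continue
        x = data.column(name)
        if len(np.unique(x)) < 2:
            raise DegenerateError(f"covariate {name!r} is constant")
        table = np.zeros((data.cardinality(name), 2))
        np.add.at(table, (x, y), 1.0)
        table = table[table.sum(axis=1) > 0]
        stat, df = _pearson_chi2(table)
        p = float(chi2.sf(stat, df))
        out[name] = {"chi2": stat, "df": df, "p": p, "candidate": p < CANDIDATE_P}
    return out


def trend_test(data: Dataset, ordinal: str, outcome: str) -> tuple[float, float]:
    """Cochran–Armitage test for trend with equally spaced scores.

    Returns (z, two-sided p).  The sign of z follows the declared level
    order of ``ordinal``: positive when the outcome's second level becomes
    more frequent at higher levels.
    """
    k = data.cardinality(ordinal)
    if k < 3:
        raise ValueError("ordinal variable needs >= 3 ordered levels")
    if data.cardinality(outcome) != 2:
        raise ValueError("outcome must be binary")
    x = data.column(ordinal)
    y = data.column(outcome)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise DegenerateError("constant variable in trend test")
    scores = np.arange(k, dtype=float)
    n_i = np.bincount(x, minlength=k).astype(float)
    r_i = np.bincount(x, weights=y, minlength=k)  # successes per level
    n = n_i.sum()
    r = r_i.sum()
    p_bar = r / n
    t = float((scores * (r_i - n_i * p_bar)).sum())
    s_mean = (scores * n_i).sum() / n
    var = p_bar * (1 - p_bar) * float((n_i * (scores - s_mean) ** 2).sum())
    if var <= 0:
        return 0.0, 1.0
    z = t / np.sqrt(var)
    return float(z), float(2 * norm.sf(abs(z)))


def or_from_coef(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% Wald CI from a coefficient and its standard error."""
    if se < 0:
        raise ValueError("standard error must be >= 0")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
    )


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float, float]:
    """Point estimate and CI for a binomial proportion (Wald; Wilson by flag)."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    z = float(norm.ppf(0.5 + level / 2))
    p = k / n
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / n)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = centre - half, centre + half
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, max(0.0, float(lo)), min(1.0, float(hi))


@dataclass(frozen=True)
class CovariateRow:
    """One line of the regression table, with the standard identities."""

    name: str
    beta: float
    se: float

    @property
    def wald(self) -> float:
        return (self.beta / self.se) ** 2

    @property
    def p_value(self) -> float:
        return float(chi2.sf(self.wald, 1))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        _, lo, hi = or_from_coef(self.beta, self.se)
        return lo, hi


@dataclass
class LogisticFit:
    outcome: str
    rows: list[CovariateRow]
    intercept: float
    intercept_se: float
    log: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [r.name for r in self.rows]

    def row(self, name: str) -> CovariateRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def _numeric_design(data: Dataset, columns: list[str]) -> np.ndarray:
    """Single ordinal code per variable: level index in declaration order."""
    return np.column_stack([data.column(c).astype(float) for c in columns])


def _fit_logit(y: np.ndarray, x: np.ndarray):
    """ML logistic fit via statsmodels; translates failure modes."""
    design = sm.add_constant(x, has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise SeparationError(str(exc)) from exc
    if not fit.mle_retvals.get("converged", False):
        raise NonConvergenceError("IRLS did not converge")
    if np.abs(fit.params).max() > 30:
        raise SeparationError("divergent coefficients indicate separation")
    return fit


def _score_test(y, x_current, probs, x_new) -> float:
    """Rao score test p-value for adding one column at beta_new = 0."""
    design = np.column_stack([np.ones(len(y)), x_current, x_new])
    u = design.T @ (y - probs)
    w = probs * (1 - probs)
    info = design.T @ (design * w[:, None])
    try:
        stat = float(u @ np.linalg.solve(info, u))
    except np.linalg.LinAlgError:
        return 1.0
    return float(chi2.sf(max(stat, 0.0), 1))


def stepwise_logistic(
    data: Dataset,
    outcome: str,
    candidates: list[str],
    alpha_in: float = 0.05,
    alpha_out: float = 0.10,
) -> LogisticFit:
    """Forward-entry / backward-removal stepwise logistic regression.

    Entry uses the Rao score test (p <= alpha_in, most significant first);
    removal uses the Wald test (p >= alpha_out, least significant first);
    iterate until stable.  The returned coefficients are a plain maximum-
    likelihood fit of the final variable set.
    """
    if data.cardinality(outcome) != 2:
        raise ValueError("outcome must be binary")
    y = data.column(outcome).astype(float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome is constant")
    missing = [c for c in candidates if c not in data.names]
    if missing:
        raise KeyError(f"unknown candidates {missing}")
    included: list[str] = []
    log: list[str] = []
    for _ in range(2 * len(candidates) + 1):
        changed = False
        # forward step: score test at the current MLE
        x_cur = _numeric_design(data, included) if included else np.empty((data.n, 0))
        fit = _fit_logit(y, x_cur)
        probs = fit.predict()
        pool = [c for c in candidates if c not in included]
        if pool:
            scored = [
                (c, _score_test(y, x_cur, probs, data.column(c).astype(float)))
                for c in pool
            ]
            best, p_in = min(scored, key=lambda cp: (cp[1], cp[0]))
            if p_in <= alpha_in:
                included.append(best)
                log.append(f"enter {best} (score p={p_in:.4g})")
                changed = True
        # backward step: Wald test on the refit
        if included:
            fit = _fit_logit(y, _numeric_design(data, included))
            wald_p = {
                name: float(chi2.sf((fit.params[i + 1] / fit.bse[i + 1]) ** 2, 1))
                for i, name in enumerate(included)
            }
            worst, p_out = max(wald_p.items(), key=lambda cp: (cp[1], cp[0]))
            if p_out >= alpha_out:
                included.remove(worst)
                log.append(f"remove {worst} (Wald p={p_out:.4g})")
                changed = True
        if not changed:
            break
    fit = _fit_logit(y, _numeric_design(data, included)) if included else _fit_logit(
        y, np.empty((data.n, 0))
    )
    rows = [
        CovariateRow(name, float(fit.params[i + 1]), float(fit.bse[i + 1]))
        for i, name in enumerate(included)
    ]
    return LogisticFit(outcome, rows, float(fit.params[0]), float(fit.bse[0]), log)


def comparison_report(
    bn: DiscreteBayesianNetwork | DAG,
    logit: LogisticFit,
    outcome: str,
) -> dict:
    """Classify covariates by graph role and juxtapose with odds ratios.

    direct      — graph-adjacent to the outcome (parent or child)
    indirect    — connected to the outcome, but not adjacent
    unconnected — no undirected path to the outcome
    """
    graph = bn.graph if isinstance(bn, DiscreteBayesianNetwork) else bn
    if outcome not in graph.nodes:
        raise KeyError(outcome)
    parents = sorted(graph.parents(outcome))
    children = sorted(graph.children(outcome))
    adjacent = set(parents) | set(children)
    # undirected connected component of the outcome
    component, stack = {outcome}, [outcome]
    while stack:
        n = stack.pop()
        for m in itertools.chain(graph.parents(n), graph.children(n)):
            if m not in component:
                component.add(m)
                stack.append(m)
    roles = {}
    for name in sorted(graph.nodes):
        if name == outcome:
            continue
        if name in adjacent:
            roles[name] = "direct"
        elif name in component:
            roles[name] = "indirect"
        else:
            roles[name] = "unconnected"
    rows = []
    for name, role in roles.items():
        entry = {"variable": name, "role": role}
        try:
            r = logit.row(name)
            entry.update(
                odds_ratio=r.odds_ratio,
                ci_lower=r.ci[0],
                ci_upper=r.ci[1],
                beta=r.beta,
                se=r.se,
                retained=True,
            )
        except KeyError:
            entry["retained"] = False
        rows.append(entry)
    report = {
        "outcome": outcome,
        "parents": parents,
        "children": children,
        "covariates": rows,
    }
    # round-trip safety: everything must be JSON-serialisable
    json.dumps(report)
    return report
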