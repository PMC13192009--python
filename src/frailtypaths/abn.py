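"""Discrete-time additive Bayesian network learning.

Survival data are expanded to person-period format (one row per subject
per follow-up interval, with a binary event indicator), continuous
predictors are percentile-binned to their bin medians, and a directed
acyclic graph over mixed Gaussian/binomial nodes is learned by exact
score maximisation.  Node scores are penalised log-likelihoods in BIC
form (higher is better); the search enumerates best parent sets per
node and assembles the optimal acyclic graph by dynamic programming
over node orders, so results are exactly optimal up to the stated node
bound rather than heuristic.

Role constraints mirror the epidemiological setup: demographic nodes
are exogenous (never acquire parents) and the mortality indicator is a
sink (never acquires children).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import json
import math

import numpy as np
import pandas as pd

MAX_EXACT_NODES = 14

__all__ = [
    "NodeSpec", "DagResult", "to_person_period", "discretize_percentile",
    "score_node", "learn_structure", "compare_parent_limits",
]


@dataclass(frozen=True)
class NodeSpec:
    name: str
    family: str = "gaussian"      # gaussian | binomial
    role: str = "endogenous"      # exogenous | endogenous | sink

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.role not in ("exogenous", "endogenous", "sink"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class DagResult:
    """Learned structure: parent sets, per-node and total scores."""

    parents: dict                 # node -> tuple of parent names
    node_scores: dict             # node -> penalised log-likelihood
    total_score: float
    parent_limit: int

    @property
    def arcs(self):
        return sorted((p, ch) for ch, ps in self.parents.items() for p in ps)

    def to_dot(self) -> str:
        lines = ["digraph abn {"]
        for node in self.parents:
            lines.append(f'  "{node}";')
        for p, ch in self.arcs:
            lines.append(f'  "{p}" -> "{ch}";')
        lines.append("}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "parents": {k: list(v) for k, v in self.parents.items()},
            "node_scores": self.node_scores,
            "total_score": self.total_score,
            "parent_limit": self.parent_limit,
        }, indent=2)


def to_person_period(cohort: pd.DataFrame, interval_width: float = 2.0,
                     baseline_cols=None, time_col="followup_time",
                     event_col="event", id_col="subject_id") -> pd.DataFrame:
    """Expand survival rows to person-period rows over half-open
    intervals [0, w), [w, 2w), ...

    A subject contributes one row per interval entered: ceil(t/w) rows
    when censored (a subject censored exactly on a boundary does not
    enter the next interval), and the event row is the interval that
    contains the event time.  period_event is 1 only on an event
    subject's final row.
    """
    t = cohort[time_col].to_numpy(float)
    e = cohort[event_col].to_numpy(int)
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    if interval_width <= 0:
        raise ValueError("interval_width must be positive")
    n_per = np.where(
        e == 1,
        np.floor(t / interval_width).astype(int) + 1,
        np.ceil(t / interval_width).astype(int),
    )
    if baseline_cols is None:
        baseline_cols = [c for c in cohort.columns
                         if c not in (time_col, event_col)]
    rows = np.repeat(np.arange(len(cohort)), n_per)
    out = cohort.iloc[rows][[id_col] + [c for c in baseline_cols
                                        if c != id_col]].reset_index(drop=True)
    period = np.concatenate([np.arange(1, k + 1) for k in n_per]) \
        if len(rows) else np.array([], dtype=int)
    out["period_index"] = period
    last = np.concatenate([np.arange(1, k + 1) == k for k in n_per]) \
        if len(rows) else np.array([], dtype=bool)
    out["period_event"] = (last & (np.repeat(e, n_per) == 1)).astype(int)
    return out


def discretize_percentile(values, n_bins: int = 5):
    """Percentile-bin a numeric vector, representing each bin by its median.

    Returns (representative values aligned to input, integer bin codes,
    bin edges).  The default of 5 bins (quintiles) is configurable;
    3 bins reproduce the tertile stratification used for plotting.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    x = pd.Series(np.asarray(values, dtype=float))
    if x.nunique(dropna=True) < 2:
        raise ValueError("values are constant; cannot discretise")
    try:
        codes, edges = pd.qcut(x, n_bins, labels=False, retbins=True,
                               duplicates="raise")
    except ValueError as exc:
        raise ValueError(
            f"not enough distinct values for {n_bins} percentile bins"
        ) from exc
    med = x.groupby(codes).median()
    rep = codes.map(med).to_numpy()
    return rep, codes.to_numpy(), edges


def _gaussian_loglik(y, Xp):
    n = len(y)
    if Xp is None or Xp.shape[1] == 0:
        resid = y - y.mean()
    else:
        X = np.column_stack([np.ones(n), Xp])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
    s2 = float(resid @ resid) / n
    if s2 <= 0:
        raise ValueError("degenerate Gaussian node: zero residual variance")
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def _logistic_loglik(y, Xp, max_iter=50, tol=1e-10):
    n = len(y)
    X = np.ones((n, 1)) if (Xp is None or Xp.shape[1] == 0) \
        else np.column_stack([np.ones(n), Xp])
    beta = np.zeros(X.shape[1])
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ValueError("binomial node is constant")
    beta[0] = math.log(pbar / (1 - pbar))
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (y - mu)
        if np.linalg.norm(g) < tol * n:
            break
        W = mu * (1 - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "perfect separation or collinearity in binomial node"
            ) from exc
        if np.linalg.norm(step) > 100:
            raise ValueError("perfect separation in binomial node")
        beta = beta + step
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def score_node(child: NodeSpec, parent_names, data: pd.DataFrame) -> float:
    """Penalised node score: log L - (k/2) log n (BIC form, higher better).

    k counts free parameters: intercept + one slope per parent, plus the
    residual variance for Gaussian children.
    """
    parent_names = tuple(parent_names)
    if child.name in parent_names:
        raise ValueError("a node cannot be its own parent")
    y = data[child.name].to_numpy(float)
    Xp = data[list(parent_names)].to_numpy(float) if parent_names else None
    n = len(y)
    if child.family == "gaussian":
        ll = _gaussian_loglik(y, Xp)
        k = len(parent_names) + 2
    else:
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError(f"binomial node {child.name!r} must be 0/1")
        ll = _logistic_loglik(y, Xp)
        k = len(parent_names) + 1
    return ll - 0.5 * k * math.log(n)


def _candidate_parents(spec, specs_by_name, banned):
    if spec.role == "exogenous":
        return []
    return [s.name for s in specs_by_name.values()
            if s.name != spec.name and s.role != "sink"
            and (s.name, spec.name) not in banned]


def learn_structure(data: pd.DataFrame, node_specs, parent_limit: int = 2,
                    banned_arcs=(), required_arcs=()) -> DagResult:
    """Exact score-based structure learning under role constraints.

    Enumerates every admissible parent set up to ``parent_limit`` per
    node, then finds the globally optimal acyclic assignment by dynamic
    programming over node subsets.  Ties are broken toward the
    lexicographically smallest parent set, so the result is
    deterministic and invariant to row order of ``data``.
    """
    specs = {s.name: s for s in node_specs}
    names = list(specs)
    nn = len(names)
    if nn > MAX_EXACT_NODES:
        raise ValueError(
            f"{nn} nodes exceeds the exact-search bound of {MAX_EXACT_NODES}")
    if parent_limit < 1:
        raise ValueError("parent_limit must be at least 1")
    idx = {nm: i for i, nm in enumerate(names)}
    banned = set(banned_arcs)
    required = {}
    for p, ch in required_arcs:
        if specs[ch].role == "exogenous":
            raise ValueError(f"required arc into exogenous node {ch!r}")
        if specs[p].role == "sink":
            raise ValueError(f"required arc out of sink node {p!r}")
        if (p, ch) in banned:
            raise ValueError(f"arc {p}->{ch} both banned and required")
        required.setdefault(ch, set()).add(p)

    # local scores for every admissible parent set, in lexicographic order
    local = {}  # name -> list of (parent mask, score, parent tuple)
    for nm in names:
        spec = specs[nm]
        cands = sorted(_candidate_parents(spec, specs, banned))
        req = required.get(nm, set())
        if not req <= set(cands):
            raise ValueError(f"required parents of {nm!r} are not admissible")
        entries = []
        for k in range(0, parent_limit + 1):
            for combo in combinations(cands, k):
                if not req <= set(combo):
                    continue
                mask = 0
                for p in combo:
                    mask |= 1 << idx[p]
                entries.append((mask, score_node(spec, combo, data), combo))
        if not entries:
            raise ValueError(f"no admissible parent set for node {nm!r}")
        local[nm] = entries

    # best parent set of each node within every subset of the other nodes
    full = 1 << nn
    NEG = -math.inf
    bp_score = {nm: np.full(full, NEG) for nm in names}
    bp_choice = {nm: [None] * full for nm in names}
    for nm in names:
        sc, ch = bp_score[nm], bp_choice[nm]
        for mask, s, combo in local[nm]:
            if s > sc[mask]:
                sc[mask], ch[mask] = s, combo
        own = 1 << idx[nm]
        for W in range(full):
            if W & own:
                continue
            best, bc = sc[W], ch[W]
            rem = W
            while rem:
                low = rem & -rem
                sub = W ^ low
                if sc[sub] > best or (sc[sub] == best and bc is not None
                                      and ch[sub] is not None
                                      and ch[sub] < bc):
                    best, bc = sc[sub], ch[sub]
                rem ^= low
            sc[W], ch[W] = best, bc

    # optimal order: best[W] = max over v in W of best[W\{v}] + bp(v, W\{v})
    best = np.full(full, NEG)
    best[0] = 0.0
    pick = [None] * full
    for W in range(1, full):
        rem = W
        while rem:
            low = rem & -rem
            v = low.bit_length() - 1
            prev = W ^ low
            if best[prev] == NEG:
                rem ^= low
                continue
            s = best[prev] + bp_score[names[v]][prev]
            if s > best[W] or (s == best[W] and (pick[W] is None or v < pick[W])):
                best[W], pick[W] = s, v
            rem ^= low
    if best[full - 1] == NEG:
        raise ValueError("constraints admit no acyclic structure")
    parents, node_scores = {}, {}
    W = full - 1
    while W:
        v = pick[W]
        nm = names[v]
        prev = W ^ (1 << v)
        parents[nm] = bp_choice[nm][prev]
        node_scores[nm] = float(bp_score[nm][prev])
        W = prev
    parents = {nm: tuple(parents[nm]) for nm in names}
    node_scores = {nm: node_scores[nm] for nm in names}
    return DagResult(parents=parents, node_scores=node_scores,
                     total_score=float(best[full - 1]),
                     parent_limit=parent_limit)


def compare_parent_limits(data: pd.DataFrame, node_specs, limits=(1, 2, 3),
                          plateau_threshold: float = 0.01,
                          banned_arcs=(), required_arcs=()):
    """Learn structures across parent limits and pick where fit plateaus.

    Returns (table of total scores per limit, selected limit, results
    dict).  The selected limit is the smallest whose improvement over
    the previous limit falls below ``plateau_threshold * |previous
    score|``; if improvement never plateaus the largest limit wins.
    """
    limits = sorted(limits)
    results = {L: learn_structure(data, node_specs, L, banned_arcs,
                                  required_arcs) for L in limits}
    scores = [results[L].total_score for L in limits]
    selected = limits[-1]
    for i in range(1, len(limits)):
        if scores[i] - scores[i - 1] < plateau_threshold * abs(scores[i - 1]):
            selected = limits[i - 1]
            break
    table = pd.DataFrame({"parent_limit": limits, "total_score": scores})
    return table, selected, results
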