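"""Equation-wise replication of a learned network with standard errors.

A fully recursive system without latent variables factorises over
nodes, so each endogenous node's equation can be fitted on its own with
the family the network assumed: linear regression for Gaussian nodes,
logistic regression for binomial nodes, and a Weibull proportional-
hazards model for the mortality sink (so its coefficients are log
hazard ratios, comparable with Cox fits).  Two designs are supported,
mirroring a simple-random-sample analysis (Model 1: unweighted,
model-based variance) and a survey-design analysis (Model 2: weighted
with a PSU-clustered sandwich variance).  False-discovery-rate control
across the resulting family of path p-values uses Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .abn import DagResult, NodeSpec
from .survival import fit_weibull_ph

__all__ = ["PathFit", "fit_path_models", "path_table", "adjust_fdr"]


@dataclass
class PathFit:
    """One fitted node equation of the recursive system."""

    child: str
    parents: tuple
    family: str                   # linear | logistic | weibull_survival
    coef: pd.Series
    se: pd.Series
    p: pd.Series
    variance_type: str            # model | psu_robust
    weighted: bool


def _fit_equation(child, parents, family, data, weights, groups):
    y = data[child].to_numpy(float)
    X = sm.add_constant(data[list(parents)].to_numpy(float), has_constant="add")
    names = ["(intercept)"] + list(parents)
    kw = {}
    if groups is not None:
        kw = {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
    if family == "linear":
        model = sm.WLS(y, X, weights=weights) if weights is not None \
            else sm.OLS(y, X)
        res = model.fit(**kw)
    else:
        model = sm.GLM(y, X, family=sm.families.Binomial(),
                       var_weights=weights)
        res = model.fit(**kw) if kw else model.fit()
    return (pd.Series(res.params, index=names),
            pd.Series(res.bse, index=names),
            pd.Series(res.pvalues, index=names))


def fit_path_models(dag: DagResult, data: pd.DataFrame, node_specs,
                    weight_col: str | None = None,
                    psu_col: str | None = None,
                    survival_node: str | None = None,
                    time_col: str = "followup_time") -> list[PathFit]:
    """Fit every endogenous node equation of ``dag`` on ``data``.

    ``survival_node`` names the mortality sink; its equation is a
    Weibull PH model on ``time_col`` with the node's value as the event
    indicator.  Passing ``weight_col``/``psu_col`` gives the
    survey-design variant (weighted, PSU-clustered variance); omitting
    both gives the simple-random-sample variant.
    """
    specs = {s.name: s for s in node_specs}
    weights = data[weight_col].to_numpy(float) if weight_col else None
    groups = data[psu_col].to_numpy() if psu_col else None
    vtype = "psu_robust" if psu_col else "model"
    fits = []
    for child, parents in dag.parents.items():
        spec = specs[child]
        if spec.role == "exogenous":
            continue
        if child == survival_node:
            wf = fit_weibull_ph(
                data, list(parents), time_col=time_col, event_col=child,
                weight_col=weight_col, cluster_col=psu_col)
            summ = wf.summary()
            fits.append(PathFit(
                child=child, parents=tuple(parents),
                family="weibull_survival", coef=summ["coef"],
                se=summ["se"], p=summ["p"], variance_type=vtype,
                weighted=weight_col is not None))
            continue
        family = "linear" if spec.family == "gaussian" else "logistic"
        coef, se, p = _fit_equation(child, parents, family, data,
                                    weights, groups)
        fits.append(PathFit(child=child, parents=tuple(parents),
                            family=family, coef=coef, se=se, p=p,
                            variance_type=vtype,
                            weighted=weight_col is not None))
    return fits


def path_table(fits: list[PathFit], fdr_q: float = 0.05) -> pd.DataFrame:
    """Tidy path-coefficient table (one row per parent->child arc) with
    Benjamini-Hochberg adjusted p-values across all arcs."""
    rows = []
    for f in fits:
        for parent in f.parents:
            rows.append({
                "child": f.child, "parent": parent, "family": f.family,
                "coef": f.coef[parent], "se": f.se[parent], "p": f.p[parent],
                "variance": f.variance_type, "weighted": f.weighted,
            })
    tab = pd.DataFrame(rows)
    if len(tab):
        adj, rej = adjust_fdr(tab["p"].to_numpy(), q=fdr_q)
        tab["p_fdr"] = adj
        tab["significant_fdr"] = rej
    return tab


def adjust_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up correction.

    Returns (adjusted p-values, rejection flags at level ``q``).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
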