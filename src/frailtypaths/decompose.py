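"""Counterfactual four-way decomposition of an exposure effect on
mortality through a single mediator.

The total effect of a binary exposure A on survival, on the excess
relative-risk (ERR) scale, is partitioned exactly into four components:
the controlled direct effect (CDE), the reference interaction (INTref),
the mediated interaction (INTmed) and the pure indirect effect (PIE).
The outcome model is a Cox proportional-hazards regression containing
an exposure-by-mediator product term; under a rare outcome the hazard
ratio stands in for the risk ratio, which is what licenses the
closed-form kernels below.  The mediator model is linear (continuous
EAA mediators) or logistic (binary frailty in the reverse direction).

With theta1, theta2, theta3 the exposure, mediator and interaction
log-HRs and M_{a'} | C = c the mediator potential value, define

    Q(a, a') = E[ exp(theta1*a + (theta2 + theta3*a) * M_{a'}) | c ].

For a Gaussian mediator with mean mu(a', c) and variance sigma^2 the
lognormal moment gives Q in closed form; for a Bernoulli mediator Q is
a two-point sum.  All components are ratios of Q values, so the
covariate term of the hazard cancels.  Inference is by nonparametric
bootstrap over subjects (over PSUs when a survey design is present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._cox import CoxData, newton_cox
from .simulate import CounterfactualTruth

COMPONENTS = ["ereri_cde", "ereri_intref", "ereri_intmed", "ereri_pie"]
PROPORTIONS = ["p_cde", "p_intref", "p_intmed", "p_pie"]
QUANTITIES = (["terira", "tereri"] + COMPONENTS + PROPORTIONS
              + ["op_m", "op_ati", "op_e"])

__all__ = [
    "DecompositionSpec", "OutcomeModelFit", "MediatorModelFit",
    "DecompositionResult", "q_integral", "decompose_fourway",
    "closed_form_components", "run_decomposition", "bootstrap_decomposition",
    "QUANTITIES", "COMPONENTS",
]


@dataclass
class DecompositionSpec:
    """What to decompose: exposure, mediator, covariates, reference values."""

    exposure: str
    mediator: str
    covariates: list
    mediator_family: str = "gaussian"       # gaussian | bernoulli
    exposure_levels: tuple = (1.0, 0.0)     # (a, a*)
    m_star: float | None = None             # default: sample mean of mediator
    covariate_values: np.ndarray | None = None  # default: sample means
    weight_col: str | None = None
    psu_col: str | None = None
    time_col: str = "followup_time"
    event_col: str = "event"
    conditioning: str = "means"             # means | average

    def __post_init__(self):
        if self.exposure_levels[0] == self.exposure_levels[1]:
            raise ValueError("exposure levels a and a* must differ")
        if self.mediator in self.covariates:
            raise ValueError("mediator cannot also be a covariate")
        if self.mediator_family not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown mediator family {self.mediator_family!r}")
        if self.conditioning not in ("means", "average"):
            raise ValueError("conditioning must be 'means' or 'average'")


@dataclass
class OutcomeModelFit:
    """Cox outcome model with exposure-mediator interaction."""

    theta1: float
    theta2: float
    theta3: float
    theta4: pd.Series
    cov: pd.DataFrame
    n_events: int


@dataclass
class MediatorModelFit:
    """Linear or logistic mediator regression M ~ exposure + covariates."""

    family: str
    beta0: float
    beta1: float
    beta2: np.ndarray
    sigma2: float | None = None     # residual variance, gaussian only

    def __post_init__(self):
        if self.family == "gaussian" and (self.sigma2 is None or self.sigma2 <= 0):
            raise ValueError("gaussian mediator model needs sigma2 > 0")

    def mean(self, a, c):
        """Mediator mean (gaussian) or success probability (bernoulli)."""
        lin = self.beta0 + self.beta1 * a + float(np.dot(self.beta2, c))
        return lin if self.family == "gaussian" else float(expit(lin))


@dataclass
class DecompositionResult:
    estimates: dict
    m_star: float
    covariate_values: np.ndarray
    outcome_fit: OutcomeModelFit | None = None
    mediator_fit: MediatorModelFit | None = None
    se: dict | None = None
    ci_low: dict | None = None
    ci_high: dict | None = None
    p: dict | None = None
    n_boot: int | None = None
    n_dropped: int | None = None

    def as_frame(self) -> pd.DataFrame:
        cols = {"estimate": self.estimates}
        for nm in ("se", "ci_low", "ci_high", "p"):
            v = getattr(self, nm)
            if v is not None:
                cols[nm] = v
        return pd.DataFrame(cols).reindex(QUANTITIES)


def q_integral(outcome: OutcomeModelFit, mediator: MediatorModelFit,
               a: float, a_prime: float, c) -> float:
    """Closed-form Q(a, a') kernel (see module docstring)."""
    k = outcome.theta2 + outcome.theta3 * a
    base = outcome.theta1 * a
    if mediator.family == "gaussian":
        mu = mediator.mean(a_prime, c)
        return float(np.exp(base + k * mu + 0.5 * k * k * mediator.sigma2))
    pi = mediator.mean(a_prime, c)
    return float(np.exp(base) * ((1.0 - pi) + pi * np.exp(k)))


def _components_from_q(q_aa, q_as, q_sa, q_ss, cde_num, tereri_warn=True):
    """Assemble the four ERR components from Q values.

    q_aa = Q(a,a), q_as = Q(a,a*), q_sa = Q(a*,a), q_ss = Q(a*,a*);
    cde_num is the CDE numerator evaluated at m*.
    """
    out = {}
    out["tereri"] = q_aa / q_ss - 1.0
    out["terira"] = out["tereri"] + 1.0
    out["ereri_cde"] = cde_num / q_ss
    out["ereri_intref"] = (q_as - q_ss) / q_ss - out["ereri_cde"]
    out["ereri_intmed"] = (q_aa - q_sa - q_as + q_ss) / q_ss
    out["ereri_pie"] = q_sa / q_ss - 1.0
    t = out["tereri"]
    if t == 0:
        if tereri_warn:
            warnings.warn("tereri is 0; proportions are undefined",
                          RuntimeWarning, stacklevel=3)
        for nm in PROPORTIONS + ["op_m", "op_ati", "op_e"]:
            out[nm] = np.nan
        return out
    for comp, prop in zip(COMPONENTS, PROPORTIONS):
        out[prop] = out[comp] / t
    out["op_m"] = out["p_pie"] + out["p_intmed"]
    out["op_ati"] = out["p_intref"] + out["p_intmed"]
    out["op_e"] = 1.0 - out["p_cde"]
    return out


def decompose_fourway(outcome: OutcomeModelFit, mediator: MediatorModelFit,
                      m_star: float, covariate_values,
                      exposure_levels=(1.0, 0.0)) -> dict:
    """Point four-way decomposition from fitted outcome/mediator models.

    Returns the full dictionary of quantities: terira, tereri, the four
    ERR components, their proportions and the overall summaries op_m
    (proportion mediated), op_ati (attributable to interaction) and
    op_e (eliminated).  The four components sum to tereri exactly.
    """
    a, a_s = exposure_levels
    c = np.asarray(covariate_values, dtype=float)
    q = {(x, y): q_integral(outcome, mediator, x, y, c)
         for x in (a, a_s) for y in (a, a_s)}

    def risk_at(x, m):
        return np.exp(outcome.theta1 * x + (outcome.theta2
                                            + outcome.theta3 * x) * m)

    cde_num = risk_at(a, m_star) - risk_at(a_s, m_star)
    return _components_from_q(q[(a, a)], q[(a, a_s)], q[(a_s, a)],
                              q[(a_s, a_s)], cde_num)


def closed_form_components(truth, covariate_values, m_star,
                           family="gaussian") -> CounterfactualTruth:
    """Exact components implied by known structural parameters.

    ``truth`` is a TruthParameters-like object (theta1..3, mediator_mean,
    sigma2); for the bernoulli family the mediator model coefficients
    are read on the logit scale.
    """
    out = OutcomeModelFit(theta1=truth.theta1, theta2=truth.theta2,
                          theta3=truth.theta3, theta4=pd.Series(dtype=float),
                          cov=pd.DataFrame(), n_events=0)
    c = np.asarray(covariate_values, dtype=float)
    if family == "gaussian":
        med = MediatorModelFit(family="gaussian", beta0=truth.beta0,
                               beta1=truth.beta1,
                               beta2=np.asarray(truth.beta2, float),
                               sigma2=truth.sigma2)
    else:
        med = MediatorModelFit(family="bernoulli", beta0=truth.beta0,
                               beta1=truth.beta1,
                               beta2=np.asarray(truth.beta2, float))
    est = decompose_fourway(out, med, m_star, c)
    return CounterfactualTruth(
        tereri=est["tereri"], ereri_cde=est["ereri_cde"],
        ereri_intref=est["ereri_intref"], ereri_intmed=est["ereri_intmed"],
        ereri_pie=est["ereri_pie"], method="closed_form",
    )


def _wlogit(X, y, w, max_iter=60, tol=1e-10):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        g = X.T @ (w * (y - mu))
        if np.linalg.norm(g) < tol * len(y):
            break
        Wd = w * mu * (1 - mu)
        step = np.linalg.solve((X * Wd[:, None]).T @ X, g)
        if np.linalg.norm(step) > 100:
            raise RuntimeError("separation in mediator logistic model")
        beta = beta + step
    return beta


class _Prepared:
    """Numpy view of the columns a decomposition needs, for fast resampling."""

    def __init__(self, data: pd.DataFrame, spec: DecompositionSpec):
        self.spec = spec
        self.A = data[spec.exposure].to_numpy(float)
        self.M = data[spec.mediator].to_numpy(float)
        self.C = data[list(spec.covariates)].to_numpy(float)
        self.t = data[spec.time_col].to_numpy(float)
        self.e = data[spec.event_col].to_numpy(int)
        self.w = (data[spec.weight_col].to_numpy(float)
                  if spec.weight_col else np.ones(len(data)))
        self.psu = (pd.factorize(data[spec.psu_col].to_numpy())[0]
                    if spec.psu_col else None)
        cols = np.column_stack([self.A, self.M, self.A * self.M, self.C])
        if not np.isfinite(cols).all():
            raise ValueError("missing values in decomposition columns")
        self.names = ([spec.exposure, spec.mediator,
                       f"{spec.exposure}:{spec.mediator}"]
                      + list(spec.covariates))


def _point(prep: _Prepared, idx=None, beta0=None, want_fits=False):
    spec = prep.spec
    if idx is None:
        A, M, C, t, e, w = prep.A, prep.M, prep.C, prep.t, prep.e, prep.w
    else:
        A, M, C = prep.A[idx], prep.M[idx], prep.C[idx]
        t, e, w = prep.t[idx], prep.e[idx], prep.w[idx]
    if e.sum() == 0:
        raise RuntimeError("no events")
    X = np.column_stack([A, M, A * M, C])
    d = CoxData(X, t, e, w)
    beta, info, ll, _ = newton_cox([d], ties="efron", beta0=beta0)
    nq = C.shape[1]
    outcome = OutcomeModelFit(
        theta1=float(beta[0]), theta2=float(beta[1]), theta3=float(beta[2]),
        theta4=pd.Series(beta[3:], index=list(spec.covariates)),
        cov=pd.DataFrame(np.linalg.inv(info), index=prep.names,
                         columns=prep.names) if want_fits else pd.DataFrame(),
        n_events=int(e.sum()),
    )
    Z = np.column_stack([np.ones(len(A)), A, C])
    if spec.mediator_family == "gaussian":
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Z * sw[:, None], M * sw, rcond=None)
        resid = M - Z @ coef
        dof = max(len(A) - Z.shape[1], 1)
        sigma2 = float(w @ resid**2 / w.sum() * len(A) / dof)
        med = MediatorModelFit("gaussian", float(coef[0]), float(coef[1]),
                               coef[2:], sigma2=sigma2)
    else:
        coef = _wlogit(Z, M, w)
        med = MediatorModelFit("bernoulli", float(coef[0]), float(coef[1]),
                               coef[2:])
    wm = w / w.sum()
    m_star = spec.m_star if spec.m_star is not None else float(wm @ M)
    cvals = (np.asarray(spec.covariate_values, float)
             if spec.covariate_values is not None else wm @ C)
    if spec.conditioning == "means":
        est = decompose_fourway(outcome, med, m_star, cvals,
                                spec.exposure_levels)
    else:
        est = _average_over_covariates(outcome, med, m_star, C, wm,
                                       spec.exposure_levels)
    return est, outcome, med, m_star, cvals, beta


def _average_over_covariates(outcome, med, m_star, C, wm, levels):
    """Components from Q values averaged over the empirical covariate
    distribution rather than evaluated at covariate means."""
    a, a_s = levels
    th2, th3 = outcome.theta2, outcome.theta3
    lin = C @ np.asarray(med.beta2, float)

    def qbar(x, y):
        k = th2 + th3 * x
        mu = med.beta0 + med.beta1 * y + lin
        if med.family == "gaussian":
            vals = np.exp(outcome.theta1 * x + k * mu + 0.5 * k * k * med.sigma2)
        else:
            pi = expit(mu)
            vals = np.exp(outcome.theta1 * x) * ((1 - pi) + pi * np.exp(k))
        return float(wm @ vals)

    def risk_at(x, m):
        return np.exp(outcome.theta1 * x + (th2 + th3 * x) * m)

    cde_num = risk_at(a, m_star) - risk_at(a_s, m_star)
    return _components_from_q(qbar(a, a), qbar(a, a_s), qbar(a_s, a),
                              qbar(a_s, a_s), cde_num)


def run_decomposition(data: pd.DataFrame, spec: DecompositionSpec
                      ) -> DecompositionResult:
    """Fit outcome and mediator models and decompose the exposure effect.

    The outcome Cox model contains the exposure-mediator product term;
    the mediator model is linear or logistic per the spec.  Components
    are evaluated at the (weighted) covariate means and the mediator
    reference m* defaults to the (weighted) mediator mean.
    """
    prep = _Prepared(data, spec)
    n_par = 3 + len(spec.covariates)
    if prep.e.sum() < 10 * n_par:
        warnings.warn(
            f"only {int(prep.e.sum())} events for {n_par} outcome parameters; "
            "estimates may be unstable", RuntimeWarning, stacklevel=2)
    est, outcome, med, m_star, cvals, _ = _point(prep, want_fits=True)
    return DecompositionResult(estimates=est, m_star=m_star,
                               covariate_values=cvals, outcome_fit=outcome,
                               mediator_fit=med)


def bootstrap_decomposition(data: pd.DataFrame, spec: DecompositionSpec,
                            n_boot: int = 500, seed: int = 0,
                            max_dropped_frac: float = 0.10
                            ) -> DecompositionResult:
    """Nonparametric bootstrap inference for the decomposition.

    Subjects are resampled with replacement (whole PSUs when a survey
    design is present, keeping the clustering in the resampling).
    Percentile 95% intervals and normal-approximation p-values are
    reported per quantity; resamples whose models fail (e.g. zero
    events) are dropped and counted, aborting if more than
    ``max_dropped_frac`` of them fail.
    """
    rng = np.random.default_rng(seed)
    prep = _Prepared(data, spec)
    est, outcome, med, m_star, cvals, beta_hat = _point(prep, want_fits=True)
    n = len(data)
    draws = {k: [] for k in QUANTITIES}
    dropped = 0
    for _ in range(n_boot):
        if prep.psu is not None and prep.psu.max() > 0:
            clusters = rng.integers(0, prep.psu.max() + 1,
                                    size=prep.psu.max() + 1)
            idx = np.concatenate([np.where(prep.psu == g)[0] for g in clusters])
        else:
            idx = rng.integers(0, n, size=n)
        try:
            b_est, *_ = _point(prep, idx=idx, beta0=beta_hat)
        except (RuntimeError, np.linalg.LinAlgError):
            dropped += 1
            continue
        for k in QUANTITIES:
            draws[k].append(b_est[k])
    if dropped > max_dropped_frac * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap resamples failed; data too sparse")
    se, lo, hi, pv = {}, {}, {}, {}
    for k in QUANTITIES:
        v = np.asarray(draws[k], dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            se[k] = lo[k] = hi[k] = pv[k] = np.nan
            continue
        se[k] = float(v.std(ddof=1))
        lo[k] = float(np.percentile(v, 2.5))
        hi[k] = float(np.percentile(v, 97.5))
        null = 1.0 if k == "terira" else 0.0
        if se[k] == 0:
            pv[k] = 0.0 if est[k] != null else 1.0
            lo[k] = hi[k] = float(est[k])
        else:
            pv[k] = float(2 * stats.norm.sf(abs((est[k] - null) / se[k])))
    return DecompositionResult(
        estimates=est, m_star=m_star, covariate_values=cvals,
        outcome_fit=outcome, mediator_fit=med, se=se, ci_low=lo, ci_high=hi,
        p=pv, n_boot=n_boot, n_dropped=dropped,
    )
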