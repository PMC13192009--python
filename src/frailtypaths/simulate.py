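"""Synthetic cohort generator with known counterfactual ground truth.

Emulates the joint structure the downstream analyses assume: exogenous
age/sex/race, a latent socioeconomic (SES) factor, five correlated
epigenetic-age-acceleration (EAA) measures shifted by frailty, sex and
SES, binary frailty-phenotype components whose prevalence depends on
age/sex/SES, and Weibull proportional-hazards survival times whose
log-hazard carries exposure, mediator, exposure-by-mediator and
covariate terms, with administrative plus exponential-dropout
censoring.  Because every structural coefficient is known, the true
counterfactual four-way decomposition of the frailty effect is
available in closed form or by Monte-Carlo potential-outcome
integration, which is what makes end-to-end recovery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

CLOCKS = ["horvath_eaa", "hannum_eaa", "phenoage_eaa", "grimage_eaa", "pace"]
FRAILTY_COMPONENTS = ["shrink", "weakness", "slowness", "exhaustion", "low_activity"]
RACE_LEVELS = ["NHW", "NHB", "Hispanic", "Other"]
#: covariate layout used by the outcome and mediator models
COVARIATES = ["age_c", "female", "race_nhb", "race_hispanic", "race_other", "ses_z"]
AGE_CENTER = 65.0

__all__ = [
    "CLOCKS", "FRAILTY_COMPONENTS", "RACE_LEVELS", "COVARIATES", "AGE_CENTER",
    "TruthParameters", "GeneratorConfig", "CounterfactualTruth",
    "generate_cohort", "mc_counterfactual_components", "apply_sampling_design",
    "covariate_matrix", "attach_covariates",
]


@dataclass
class TruthParameters:
    """Structural parameters of the outcome and mediator models.

    theta* are log hazard ratios in the Weibull PH outcome model
    h(t) = p*lam*t^(p-1)*exp(theta1*A + theta2*M + theta3*A*M + theta4'C);
    beta* parameterise the linear mediator model
    M = beta0 + beta1*A + beta2'C + N(0, sigma2).
    """

    theta1: float = 0.5          # frail vs non-frail direct log-HR
    theta2: float = 0.06         # per year of mediating EAA
    theta3: float = 0.01         # exposure x mediator interaction
    theta4: tuple = (0.085, -0.35, 0.20, 0.05, 0.05, -0.10)  # COVARIATES order
    beta0: float = 0.0
    beta1: float = 2.0           # frailty shift of the mediating clock, years
    beta2: tuple = (0.0, -1.5, 0.0, 0.0, 0.0, -0.8)
    sigma2: float = 16.0         # mediator residual variance (years^2)
    weibull_shape: float = 1.3
    weibull_scale: float = 0.0025

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    def mediator_mean(self, a, c):
        return self.beta0 + self.beta1 * a + float(np.dot(self.beta2, c))


def _default_eaa_cov():
    sd = np.array([5.0, 5.0, 5.0, 4.0, 0.10])
    corr = np.array([
        [1.00, 0.50, 0.35, 0.25, 0.15],
        [0.50, 1.00, 0.40, 0.30, 0.20],
        [0.35, 0.40, 1.00, 0.40, 0.30],
        [0.25, 0.30, 0.40, 1.00, 0.45],
        [0.15, 0.20, 0.30, 0.45, 1.00],
    ])
    return corr * np.outer(sd, sd)


@dataclass
class GeneratorConfig:
    """Everything the synthetic cohort draws from, with seeded determinism.

    Defaults describe a community cohort of older US adults: ages 50-85,
    slight female majority, four race/ethnicity groups, frail prevalence
    around one in eight, and an event fraction under 10% over ten years
    of follow-up so the rare-outcome approximation used by the
    decomposition is honest.
    """

    n_subjects: int = 2000
    age_range: tuple = (50.0, 85.0)
    p_female: float = 0.55
    race_probs: tuple = (0.55, 0.20, 0.17, 0.08)
    # latent SES: loadings of age (per decade over 65) and race dummies
    ses_loadings: tuple = (-0.10, -0.50, -0.40, -0.10)
    frailty_component_intercepts: tuple = (-2.3, -1.5, -1.3, -1.2, -1.0)
    # logit effects of age (per decade over 65), female sex, SES z-score
    frailty_covariate_effects: tuple = (0.35, 0.15, -0.45)
    eaa_means: tuple = (0.0, 0.0, 0.0, 0.0, 1.0)
    eaa_cov: np.ndarray = field(default_factory=_default_eaa_cov)
    eaa_shift_frail: tuple = (0.5, 0.5, 1.0, 2.0, 0.03)
    eaa_shift_female: tuple = (-1.0, -1.0, -1.0, -1.5, -0.02)
    eaa_shift_ses: tuple = (-0.2, -0.2, -0.4, -0.8, -0.015)
    survival_params: TruthParameters = field(default_factory=TruthParameters)
    mediator_clock: str = "grimage_eaa"
    admin_censor_time: float = 10.0
    dropout_rate: float = 0.01
    component_missing_rate: float = 0.0
    include_leukocytes: bool = False
    seed: int = 0

    def __post_init__(self):
        self.eaa_cov = np.asarray(self.eaa_cov, dtype=float)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if not np.isclose(sum(self.race_probs), 1.0):
            raise ValueError("race_probs must sum to 1")
        for p in (self.p_female, self.component_missing_rate, *self.race_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.eaa_cov.shape != (5, 5):
            raise ValueError("eaa_cov must be 5x5")
        if not np.allclose(self.eaa_cov, self.eaa_cov.T):
            raise ValueError("eaa_cov must be symmetric positive definite")
        if np.linalg.eigvalsh(self.eaa_cov).min() <= 0:
            raise ValueError("eaa_cov must be symmetric positive definite")
        if self.mediator_clock not in CLOCKS:
            raise ValueError(f"mediator_clock must be one of {CLOCKS}")

    def implied_truth(self) -> TruthParameters:
        """TruthParameters whose mediator model matches what the generator
        actually does for the configured mediating clock."""
        j = CLOCKS.index(self.mediator_clock)
        sp = self.survival_params
        return TruthParameters(
            theta1=sp.theta1, theta2=sp.theta2, theta3=sp.theta3,
            theta4=tuple(sp.theta4),
            beta0=self.eaa_means[j],
            beta1=self.eaa_shift_frail[j],
            beta2=(0.0, self.eaa_shift_female[j], 0.0, 0.0, 0.0,
                   self.eaa_shift_ses[j]),
            sigma2=float(self.eaa_cov[j, j]),
            weibull_shape=sp.weibull_shape, weibull_scale=sp.weibull_scale,
        )

    def to_yaml(self, path):
        d = asdict(self)
        d["eaa_cov"] = self.eaa_cov.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "eaa_cov" in d:
            d["eaa_cov"] = np.asarray(d["eaa_cov"], dtype=float)
        if "survival_params" in d and isinstance(d["survival_params"], dict):
            d["survival_params"] = TruthParameters(**d["survival_params"])
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class CounterfactualTruth:
    """True four-way decomposition components on the excess-RR scale."""

    tereri: float
    ereri_cde: float
    ereri_intref: float
    ereri_intmed: float
    ereri_pie: float
    method: str                      # closed_form | monte_carlo
    mc_se: dict | None = None        # per-component MC standard errors

    @property
    def components(self) -> dict:
        return {
            "ereri_cde": self.ereri_cde, "ereri_intref": self.ereri_intref,
            "ereri_intmed": self.ereri_intmed, "ereri_pie": self.ereri_pie,
        }

    @property
    def proportions(self) -> dict:
        t = self.tereri
        out = {f"p_{k[6:]}": v / t for k, v in self.components.items()}
        out["op_m"] = out["p_pie"] + out["p_intmed"]
        out["op_ati"] = out["p_intref"] + out["p_intmed"]
        out["op_e"] = 1.0 - out["p_cde"]
        return out


def covariate_matrix(df: pd.DataFrame, age_center: float = AGE_CENTER) -> pd.DataFrame:
    """Covariates in the canonical COVARIATES layout (age centred in years)."""
    out = pd.DataFrame(index=df.index)
    out["age_c"] = df["age"] - age_center
    out["female"] = df["sex"].astype(float)
    for lvl in RACE_LEVELS[1:]:
        out[f"race_{lvl.lower()}"] = (df["race"] == lvl).astype(float)
    out["ses_z"] = df["ses_z"]
    return out


def attach_covariates(df: pd.DataFrame, age_center: float = AGE_CENTER
                      ) -> pd.DataFrame:
    """Cohort table with the canonical covariate columns appended
    (existing columns such as ses_z are not duplicated)."""
    cov = covariate_matrix(df, age_center)
    new = cov[[c for c in cov.columns if c not in df.columns]]
    return pd.concat([df.reset_index(drop=True),
                      new.reset_index(drop=True)], axis=1)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one seeded cohort table.

    Columns: subject_id, age, sex (0 male / 1 female), race, ses_z, the
    five frailty component indicators, frailty_score, frail, the five
    clock columns, followup_time, event, weight, psu, stratum and
    optionally leukocyte fractions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    age = rng.uniform(*config.age_range, size=n)
    female = rng.binomial(1, config.p_female, size=n)
    race = rng.choice(RACE_LEVELS, size=n, p=np.asarray(config.race_probs))
    age_dec = (age - AGE_CENTER) / 10.0

    race_d = np.column_stack([(race == lvl).astype(float) for lvl in RACE_LEVELS[1:]])
    la, *lr = config.ses_loadings
    ses_raw = la * age_dec + race_d @ np.asarray(lr) + rng.normal(size=n)
    ses_z = (ses_raw - ses_raw.mean()) / ses_raw.std(ddof=0)

    # frailty components: independent Bernoulli given covariates
    eff = np.asarray(config.frailty_covariate_effects)
    lin = eff[0] * age_dec + eff[1] * female + eff[2] * ses_z
    comps = np.column_stack([
        rng.binomial(1, expit(b0 + lin))
        for b0 in config.frailty_component_intercepts
    ])
    score = comps.sum(axis=1)
    frail = (score >= 3).astype(int)

    # EAA panel: correlated residual draw plus structural shifts
    eaa = rng.multivariate_normal(np.zeros(5), config.eaa_cov, size=n,
                                  method="cholesky")
    eaa += np.asarray(config.eaa_means)
    eaa += np.outer(frail, config.eaa_shift_frail)
    eaa += np.outer(female, config.eaa_shift_female)
    eaa += np.outer(ses_z, config.eaa_shift_ses)

    # survival: Weibull PH by inverse transform, dropout + admin censoring
    tp = config.survival_params
    med = eaa[:, CLOCKS.index(config.mediator_clock)]
    cmat = np.column_stack([age - AGE_CENTER, female, race_d, ses_z])
    eta = (tp.theta1 * frail + tp.theta2 * med + tp.theta3 * frail * med
           + cmat @ np.asarray(tp.theta4))
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (tp.weibull_scale * np.exp(eta))) ** (1.0 / tp.weibull_shape)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, config.admin_censor_time)
    followup = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    df = pd.DataFrame({
        "subject_id": np.arange(n), "age": age, "sex": female, "race": race,
        "ses_z": ses_z,
    })
    comp_df = pd.DataFrame(comps.astype(float), columns=FRAILTY_COMPONENTS)
    if config.component_missing_rate > 0:
        miss = rng.uniform(size=comps.shape) < config.component_missing_rate
        comp_df = comp_df.mask(miss)
    df = pd.concat([df, comp_df], axis=1)
    df["frailty_score"] = score
    df["frail"] = frail
    for j, clock in enumerate(CLOCKS):
        df[clock] = eaa[:, j]
    df["followup_time"] = followup
    df["event"] = event
    df["weight"] = 1.0
    df["psu"] = "P0"
    df["stratum"] = "S0"
    if config.include_leukocytes:
        # neutrophil/lymphocyte/monocyte fractions, independent of the rest
        fr = rng.dirichlet([55.0, 30.0, 8.0, 7.0], size=n)
        df["wbc_neut"] = fr[:, 0]
        df["wbc_lymph"] = fr[:, 1]
        df["wbc_mono"] = fr[:, 2]
    return df


def mc_counterfactual_components(
    truth: TruthParameters, covariate_values, m_star: float,
    n_draws: int = 10**6, seed: int = 0, family: str = "gaussian",
    n_batches: int = 50,
) -> CounterfactualTruth:
    """Monte-Carlo potential-outcome evaluation of the four-way components.

    Draws mediator potential values M_0, M_1 from the mediator model at
    fixed covariates and averages the rare-outcome risk surrogate
    exp(theta1*a + (theta2 + theta3*a)*m); the covariate term of the
    hazard cancels from every relative-risk ratio and is omitted.
    MC standard errors come from batching the draws.
    """
    if n_draws < 10**4:
        raise ValueError("n_draws must be at least 10^4 for stable components")
    rng = np.random.default_rng(seed)
    c = np.asarray(covariate_values, dtype=float)
    mu0 = truth.mediator_mean(0, c)
    mu1 = truth.mediator_mean(1, c)
    if family == "gaussian":
        eps = rng.normal(size=n_draws) * np.sqrt(truth.sigma2)
        m0, m1 = mu0 + eps, mu1 + eps
    elif family == "bernoulli":
        u = rng.uniform(size=n_draws)
        m0 = (u < expit(mu0)).astype(float)
        m1 = (u < expit(mu1)).astype(float)
    else:
        raise ValueError(f"unknown mediator family {family!r}")

    th1, th2, th3 = truth.theta1, truth.theta2, truth.theta3

    def components_from(m0b, m1b):
        q00 = np.exp(th2 * m0b).mean()
        q01 = np.exp(th2 * m1b).mean()
        q10 = np.exp(th1 + (th2 + th3) * m0b).mean()
        q11 = np.exp(th1 + (th2 + th3) * m1b).mean()
        e_cde = (np.exp(th1 + (th2 + th3) * m_star) - np.exp(th2 * m_star)) / q00
        e_intref = (q10 - q00) / q00 - e_cde
        e_intmed = (q11 - q01 - q10 + q00) / q00
        e_pie = q01 / q00 - 1.0
        return np.array([q11 / q00 - 1.0, e_cde, e_intref, e_intmed, e_pie])

    full = components_from(m0, m1)
    per_batch = np.stack([
        components_from(b0, b1)
        for b0, b1 in zip(np.array_split(m0, n_batches),
                          np.array_split(m1, n_batches))
    ])
    se = per_batch.std(axis=0, ddof=1) / np.sqrt(n_batches)
    names = ["tereri", "ereri_cde", "ereri_intref", "ereri_intmed", "ereri_pie"]
    return CounterfactualTruth(
        **dict(zip(names, full)), method="monte_carlo",
        mc_se=dict(zip(names, se)),
    )


def apply_sampling_design(
    cohort: pd.DataFrame, n_strata: int = 2, psus_per_stratum: int = 3,
    weight_model: dict | None = None, seed: int = 0,
) -> pd.DataFrame:
    """Attach survey-design columns: strata, PSUs and inverse-probability
    weights from a logistic inclusion model on demographics.

    ``weight_model`` maps {"intercept", "age_per_decade", "female", "ses"}
    to logit coefficients of the inclusion probability; all-zero
    coefficients give uniform weights.
    """
    wm = {"intercept": 0.0, "age_per_decade": 0.0, "female": 0.0, "ses": 0.0}
    if weight_model:
        unknown = set(weight_model) - set(wm)
        if unknown:
            raise ValueError(f"unknown weight_model keys: {sorted(unknown)}")
        wm.update(weight_model)
    rng = np.random.default_rng(seed)
    df = cohort.copy()
    logit = (wm["intercept"]
             + wm["age_per_decade"] * (df["age"].to_numpy() - AGE_CENTER) / 10.0
             + wm["female"] * df["sex"].to_numpy()
             + wm["ses"] * df["ses_z"].to_numpy())
    p = expit(logit)
    if np.any(p <= 1e-12):
        raise ValueError("degenerate weight model: inclusion probability 0")
    df["weight"] = 1.0 / p
    n_labels = n_strata * psus_per_stratum
    lab = rng.permutation(len(df)) % n_labels
    df["stratum"] = [f"S{k // psus_per_stratum}" for k in lab]
    df["psu"] = [f"S{k // psus_per_stratum}-P{k % psus_per_stratum}" for k in lab]
    return df
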