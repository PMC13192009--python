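"""Harmonised frailty scoring, residual epigenetic age acceleration and
the PCA socioeconomic-status index.

Three frailty instruments are supported, mirroring how the phenotype is
operationalised in large US aging cohorts:

``fried_nhanes``
    Fried phenotype with shrinking proxied by BMI < 18.5 kg/m^2 (strict),
    plus exhaustion, lifting difficulty (weakness), walking difficulty
    (slowness) and low physical activity.
``fried_hrs``
    Fried phenotype with shrinking operationalised as an annualised BMI
    loss > 1.48 kg/m^2/year (strict) and weakness as mean grip strength
    at or below sex-specific cutoffs (27.1 kg men, 16.6 kg women,
    inclusive).
``frail_scale``
    Five-item FRAIL scale (fatigue, resistance, ambulation, illness,
    weight loss) with illness defined as >= 5 of 11 chronic conditions;
    subjects need at least 3 valid components to be scored.

Every instrument sums its indicators to a 0-5 score classified as
robust (0), pre-frail (1-2) or frail (>= 3); the binary exposure used
downstream is frail vs pre-frail/robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BMI_SHRINK_CUTOFF = 18.5           # kg/m^2, strict less-than
BMI_LOSS_CUTOFF = 1.48             # kg/m^2 per year, strict greater-than
GRIP_CUTOFF_MALE = 27.1            # kg, inclusive
GRIP_CUTOFF_FEMALE = 16.6          # kg, inclusive
ILLNESS_CUTOFF = 5                 # chronic conditions of 11, inclusive

INSTRUMENT_COMPONENTS = {
    "fried_nhanes": ["shrink", "exhaustion", "weakness", "slowness",
                     "low_activity"],
    "fried_hrs": ["shrink", "weakness", "slowness", "exhaustion",
                  "low_activity"],
    "frail_scale": ["fatigue", "resistance", "ambulation", "illness",
                    "weight_loss"],
}

__all__ = [
    "FrailtyComponents", "FrailtyResult", "EAAColumn", "SesIndex",
    "score_frailty", "score_frailty_table", "compute_eaa_residuals",
    "residualize_panel", "compute_ses_index", "INSTRUMENT_COMPONENTS",
]


@dataclass
class FrailtyComponents:
    """Inputs for one subject under one instrument.

    Indicators may be given directly (0/1/None); criteria with published
    thresholds may instead be derived from raw inputs (bmi, bmi_slope,
    grip_kg with sex, chronic_condition_count).
    """

    instrument: str
    indicators: dict = field(default_factory=dict)
    bmi: float | None = None
    bmi_slope: float | None = None          # kg/m^2 per year, signed
    grip_kg: float | None = None
    sex: int | None = None                  # 0 male, 1 female (for grip cutoff)
    chronic_condition_count: int | None = None

    def __post_init__(self):
        if self.instrument not in INSTRUMENT_COMPONENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        bad = set(self.indicators) - set(INSTRUMENT_COMPONENTS[self.instrument])
        if bad:
            raise ValueError(
                f"indicators {sorted(bad)} not part of {self.instrument}")
        if self.chronic_condition_count is not None and not (
                0 <= self.chronic_condition_count <= 11):
            raise ValueError("chronic_condition_count must be in [0, 11]")


@dataclass
class FrailtyResult:
    score: int | None
    n_valid: int
    status: str                 # robust | pre_frail | frail | missing
    binary_exposure: int | None # 1 iff frail

    @staticmethod
    def classify(score: int) -> str:
        if score == 0:
            return "robust"
        if score <= 2:
            return "pre_frail"
        return "frail"


def _resolve_indicator(name: str, comps: FrailtyComponents):
    """Direct indicator wins; otherwise derive from raw input if present."""
    v = comps.indicators.get(name)
    if v is not None:
        if v not in (0, 1):
            raise ValueError(f"indicator {name!r} must be 0, 1 or missing")
        return int(v)
    inst = comps.instrument
    if name == "shrink":
        if inst == "fried_nhanes" and comps.bmi is not None:
            return int(comps.bmi < BMI_SHRINK_CUTOFF)
        if inst == "fried_hrs" and comps.bmi_slope is not None:
            return int(-comps.bmi_slope > BMI_LOSS_CUTOFF)
    if name == "weakness" and inst == "fried_hrs" and comps.grip_kg is not None:
        if comps.sex not in (0, 1):
            raise ValueError("grip strength requires sex (0 male, 1 female)")
        cutoff = GRIP_CUTOFF_FEMALE if comps.sex == 1 else GRIP_CUTOFF_MALE
        return int(comps.grip_kg <= cutoff)
    if name == "illness" and comps.chronic_condition_count is not None:
        return int(comps.chronic_condition_count >= ILLNESS_CUTOFF)
    return None


def score_frailty(comps: FrailtyComponents) -> FrailtyResult:
    """Score one subject; see module docstring for instrument semantics.

    Fried instruments require all five components observed (conservative
    complete-case); the FRAIL scale scores subjects with >= 3 valid
    components, summing over the observed ones.
    """
    names = INSTRUMENT_COMPONENTS[comps.instrument]
    values = [_resolve_indicator(nm, comps) for nm in names]
    n_valid = sum(v is not None for v in values)
    min_valid = 3 if comps.instrument == "frail_scale" else 5
    if n_valid < min_valid:
        return FrailtyResult(score=None, n_valid=n_valid, status="missing",
                             binary_exposure=None)
    score = sum(v for v in values if v is not None)
    status = FrailtyResult.classify(score)
    return FrailtyResult(score=score, n_valid=n_valid, status=status,
                         binary_exposure=int(status == "frail"))


def score_frailty_table(df: pd.DataFrame, instrument: str,
                        columns: dict | None = None) -> pd.DataFrame:
    """Vectorised scoring of a cohort table of indicator columns.

    ``columns`` maps component names to column names (defaults to the
    component names themselves).  Returns frailty_score, n_valid,
    frailty_status and frail columns aligned to ``df``.
    """
    names = INSTRUMENT_COMPONENTS[instrument]
    columns = columns or {}
    ind = pd.DataFrame({nm: df[columns.get(nm, nm)] for nm in names})
    bad = ~ind.isin([0, 1]) & ind.notna()
    if bad.any().any():
        raise ValueError("indicator columns must contain only 0, 1 or missing")
    n_valid = ind.notna().sum(axis=1)
    min_valid = 3 if instrument == "frail_scale" else 5
    score = ind.sum(axis=1, min_count=1)
    score[n_valid < min_valid] = np.nan
    status = pd.Series("missing", index=df.index)
    status[score == 0] = "robust"
    status[(score >= 1) & (score <= 2)] = "pre_frail"
    status[score >= 3] = "frail"
    frail = pd.Series(np.where(score.isna(), np.nan,
                               (score >= 3).astype(float)), index=df.index)
    return pd.DataFrame({"frailty_score": score, "n_valid": n_valid,
                         "frailty_status": status, "frail": frail})


@dataclass
class EAAColumn:
    """Residual EAA for one clock with the residualising regression."""

    residuals: np.ndarray
    intercept: float
    slope: float


def compute_eaa_residuals(dnam_age, chrono_age) -> EAAColumn:
    """Residuals of OLS of DNAm age on chronological age.

    Residuals are mean-zero and orthogonal to age by construction; rows
    with a missing value in either column get a missing residual.
    """
    y = np.asarray(dnam_age, dtype=float)
    x = np.asarray(chrono_age, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (dnam_age, age) pairs")
    if np.var(x[ok]) == 0:
        raise ValueError("chronological age is constant; cannot residualise")
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    res = np.full_like(y, np.nan)
    res[ok] = y[ok] - (intercept + slope * x[ok])
    return EAAColumn(residuals=res, intercept=float(intercept),
                     slope=float(slope))


def residualize_panel(df: pd.DataFrame, clock_cols, age_col="age"):
    """Residualise several DNAm-age columns against age at once.

    Returns (DataFrame of residual columns named ``<col>_eaa``, DataFrame
    of fitted intercept/slope per clock).
    """
    out, coefs = {}, {}
    for col in clock_cols:
        r = compute_eaa_residuals(df[col], df[age_col])
        out[f"{col}_eaa"] = r.residuals
        coefs[col] = {"intercept": r.intercept, "slope": r.slope}
    return pd.DataFrame(out, index=df.index), pd.DataFrame(coefs).T


@dataclass
class SesIndex:
    """First-principal-component SES score, standardised to a z-score."""

    z: np.ndarray
    loadings: pd.Series
    proportion_variance_explained: float


def compute_ses_index(indicators: pd.DataFrame,
                      sign_column: str | None = None) -> SesIndex:
    """PCA z-score over mixed ordinal/continuous SES indicators.

    Indicators are standardised and the first principal component of
    their correlation matrix is extracted; the score is re-standardised
    to mean 0, SD 1.  The component sign is fixed so the loading on
    ``sign_column`` (default: a column named 'education' if present,
    else the first column) is positive.
    """
    if indicators.shape[1] < 2:
        raise ValueError("need at least 2 SES indicators")
    X = indicators.to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete rows")
    sd = X[ok].std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(
                f"SES indicator {indicators.columns[j]!r} is constant")
    Z = (X - X[ok].mean(axis=0)) / sd
    corr = np.corrcoef(Z[ok], rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    if sign_column is None:
        sign_column = ("education" if "education" in indicators.columns
                       else indicators.columns[0])
    j = list(indicators.columns).index(sign_column)
    if v[j] < 0:
        v = -v
    raw = Z @ v
    z = np.full(len(indicators), np.nan)
    z[ok] = (raw[ok] - raw[ok].mean()) / raw[ok].std(ddof=1)
    return SesIndex(
        z=z, loadings=pd.Series(v, index=indicators.columns),
        proportion_variance_explained=float(evals[-1] / len(sd)),
    )
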