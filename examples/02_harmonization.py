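"""Score frailty under three instruments, residualise a DNAm age, and
build a PCA socioeconomic index."""

import numpy as np
import pandas as pd

from frailtypaths import (FrailtyComponents, score_frailty,
                          compute_eaa_residuals, compute_ses_index)

# Fried phenotype with BMI-derived shrinking (BMI < 18.5 kg/m^2)
subject = FrailtyComponents(
    "fried_nhanes",
    {"exhaustion": 1, "weakness": 1, "slowness": 0, "low_activity": 0},
    bmi=17.9)
res = score_frailty(subject)
print(f"fried_nhanes: score={res.score} status={res.status}")

# HRS variant: grip strength at the inclusive female cutoff counts
weak = FrailtyComponents(
    "fried_hrs",
    {"shrink": 0, "slowness": 0, "exhaustion": 0, "low_activity": 0},
    grip_kg=16.6, sex=1)
print(f"fried_hrs grip 16.6 kg (female): score={score_frailty(weak).score}")

# FRAIL scale: fewer than 3 valid components cannot be scored
partial = FrailtyComponents("frail_scale", {"fatigue": 1, "resistance": 1})
print(f"frail_scale with 2 valid components: {score_frailty(partial).status}")

# Residual epigenetic age acceleration: OLS residual of DNAm age on age
rng = np.random.default_rng(0)
age = rng.uniform(50, 85, 500)
dnam = 0.8 * age + 12 + rng.normal(0, 5, 500)
col = compute_eaa_residuals(dnam, age)
print(f"EAA residuals: mean={col.residuals.mean():+.1e}, "
      f"slope={col.slope:.3f} (fitted clock-vs-age slope)")

# SES index: first principal component of standardised indicators
ses = pd.DataFrame({
    "education": rng.integers(1, 6, 500).astype(float),
    "income": rng.integers(1, 6, 500).astype(float),
})
idx = compute_ses_index(ses)
print(f"SES z-score: sd={idx.z.std(ddof=1):.3f}, first-PC variance share="
      f"{idx.proportion_variance_explained:.2f}, "
      f"education loading={idx.loadings['education']:+.3f}")
# A positive education loading fixes the sign convention: higher z means
# higher socioeconomic position.
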