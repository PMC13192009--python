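"""Generate a seeded synthetic aging cohort and inspect its structure.

The generator draws demographics, a latent SES score, five correlated
epigenetic-age-acceleration (EAA) measures, binary frailty-phenotype
components and Weibull survival times whose log-hazard contains the
frailty exposure, a mediating EAA clock, their interaction and the
covariates — so the causal structure of the cohort is known exactly.
"""

from frailtypaths import GeneratorConfig, generate_cohort, apply_sampling_design

cfg = GeneratorConfig(n_subjects=5000, seed=1)
cohort = generate_cohort(cfg)
cohort = apply_sampling_design(cohort, n_strata=2, psus_per_stratum=3,
                               weight_model={"age_per_decade": 0.4}, seed=2)

print(f"subjects: {len(cohort)}")
print(f"frail prevalence: {cohort['frail'].mean():.3f}")
print(f"event fraction over {cfg.admin_censor_time:.0f} y: "
      f"{cohort['event'].mean():.3f}")
print(f"GrimAge EAA mean (frail vs not): "
      f"{cohort.loc[cohort.frail == 1, 'grimage_eaa'].mean():+.2f} vs "
      f"{cohort.loc[cohort.frail == 0, 'grimage_eaa'].mean():+.2f} years")
print(f"design: {cohort['psu'].nunique()} PSUs in "
      f"{cohort['stratum'].nunique()} strata, "
      f"weights {cohort['weight'].min():.2f}-{cohort['weight'].max():.2f}")
# The frail/non-frail EAA gap reflects the configured +2-year shift of
# GrimAge EAA under frailty; the event fraction stays below 10% so the
# rare-outcome reading of hazard ratios as risk ratios is honest.
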