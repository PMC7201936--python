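# Pure-mediation scenario: early-life body size affects disease only
# through adult body size. Every ScenarioSpec field is shown; the seed is
# mandatory so runs are reproducible.
scenario:
  n_variants: 100            # biallelic variants on the panel
  maf_range: [0.05, 0.45]    # minor-allele frequencies, uniform
  ld_block_size: 1           # variants per LD block (1 = independent)
  ld_rho: 0.0                # within-block liability equicorrelation
  n_early_variants: 30       # affect the early latent trait only
  n_adult_variants: 30       # affect the adult latent trait only
  n_shared_variants: 0       # affect both
  effect_size_sd_early: 0.15 # per-allele effects ~ N(0, sd)
  effect_size_sd_adult: 0.15
  beta_early_to_adult: 0.6   # mediation path (tracking into adulthood)
  beta_early_direct: 0.0     # early -> outcome, not via adult body size
  beta_adult_direct: 0.5     # adult -> outcome
  outcome_model: continuous  # or binary-logistic
  outcome_scale: latent      # outcome depends on latents (or: category)
  baseline_prevalence: 0.1   # binary outcomes only
  confounder_sd: 1.0         # shared confounder U
  confounder_loading_early: 0.2
  confounder_loading_adult: 0.2
  confounder_loading_outcome: 0.2
  menarche_beta_early: -0.5  # early latent -> age at menarche
  category_proportions: [0.333333333333333, 0.333333333333334, 0.333333333333333]
  allow_palindromic: false   # keep A/T and G/C pairs off the panel
  seed: 7

# Optional: reporting error on the early-life category.
# mode: none | nondifferential | differential-on-adult
misclassification:
  mode: nondifferential
  confusion:                 # rows: true category; columns: reported
    - [0.95, 0.05, 0.00]
    - [0.025, 0.95, 0.025]
    - [0.00, 0.05, 0.95]
  adult_dependence_slope: 0.0   # used by differential-on-adult only

# Optional: analysis thresholds (shown at their defaults).
analysis:
  p_threshold: 5.0e-8        # genome-wide significance for instruments
  r2_threshold: 0.001        # LD clumping ceiling
  palindrome_window: [0.42, 0.58]
  ci_quantile: 1.96
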