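# Default synthetic cohort: 28 tumor samples in 3 genotype groups.
# Concentration laws are median-matched scaled Betas on the published
# median (min-max) supports, in nmol/mg of tissue.  Epinephrine is present
# only in a per-group fraction of samples, mirroring the reported detection
# pattern; dopamine is absent throughout.
seed: 0
noise_sd: 0.5
linewidth_hz: 1.5
spectrometer_mhz: 500.13
grid:
  ppm_min: 0.5
  ppm_max: 9.0
  step: 0.0005
weight_mg:
  min: 15.0
  max: 20.0
reference:
  amount_nmol: 19.3
groups:
  sporadic:
    n: 10
    metabolites:
      succinate: {median: 0.03, min: 0.0, max: 0.06}
      glutathione: {median: 0.04, min: 0.03, max: 0.22}
      glutamate: {median: 1.36, min: 0.23, max: 2.55}
      atp_adp_amp: {median: 0.10, min: 0.03, max: 0.18}
      norepinephrine: {median: 0.90, min: 0.0, max: 4.60}
    epinephrine: {prevalence: 0.2, median: 0.985, min: 0.93, max: 1.04}
  SDHx:
    n: 12
    metabolites:
      succinate: {median: 3.6, min: 0.9, max: 9.07}
      glutathione: {median: 0.15, min: 0.05, max: 0.39}
      glutamate: {median: 0.67, min: 0.13, max: 1.52}
      atp_adp_amp: {median: 0.05, min: 0.0, max: 0.21}
      norepinephrine: {median: 0.87, min: 0.0, max: 2.40}
    epinephrine: {prevalence: 0.0833, median: 1.98, min: 1.90, max: 2.06}
  VHL:
    n: 6
    metabolites:
      succinate: {median: 0.06, min: 0.03, max: 0.12}
      glutathione: {median: 0.32, min: 0.17, max: 0.43}
      glutamate: {median: 1.49, min: 0.88, max: 2.18}
      atp_adp_amp: {median: 0.16, min: 0.06, max: 0.29}
      norepinephrine: {median: 1.80, min: 0.26, max: 4.53}
    epinephrine: {prevalence: 0.0}
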