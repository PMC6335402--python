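# Synthetic condition parameter sets for the trap-trace generator.
#
# These numbers are NOT measured values: they are invented defaults chosen
# so the generated cohorts reproduce the qualitative per-attempt trends of
# the three phenotype classes (WT: forces and persistence times increase at
# successive attempts; CDK5_KD: both decrease; COFACTOR_KD, standing in for
# any dynein-cofactor knockdown that abolishes adaptation: both flat).
# Units: forces pN, times s.
WT:
  base_peak_force: 2.5
  force_increment: 0.6
  base_persistence: 0.8
  persistence_increment: 0.35
  force_noise_sd: 0.6
  persistence_noise_sd: 0.3
  escape_midpoint: 6.5
  escape_steepness: 1.0
CDK5_KD:
  base_peak_force: 2.5
  force_increment: -0.3
  base_persistence: 1.0
  persistence_increment: -0.15
  force_noise_sd: 0.6
  persistence_noise_sd: 0.3
  escape_midpoint: 6.5
  escape_steepness: 1.0
COFACTOR_KD:
  base_peak_force: 2.5
  force_increment: 0.0
  base_persistence: 0.8
  persistence_increment: 0.0
  force_noise_sd: 0.6
  persistence_noise_sd: 0.3
  escape_midpoint: 6.5
  escape_steepness: 1.0
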