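# Default parameter table for the bacterial-warfare conjugation models.
# Every value here equals the package's built-in defaults; an empty config
# file resolves to exactly this configuration.
variant: default
scenario: killing_and_transfer
params:
  rC1: 1.0    # maximum intrinsic growth rate, attacker (1/t)
  rC2: 1.0    # maximum intrinsic growth rate, target (1/t)
  rC3: 1.0    # maximum intrinsic growth rate, transconjugant (1/t)
  KN1: 5.0    # Monod saturation constant, shared nutrient
  KN2: 5.0    # Monod saturation constant, attacker-private nutrient
  KN3: 5.0    # Monod saturation constant, target-lineage-private nutrient
  E: 10.0     # toxin killing efficiency (potency)
  b: 0.25     # conjugation rate
  gamma: 0.15 # investment in toxin production
  KC2T: 1.0   # affinity of toxin for the target strain
init:
  C1: 0.01    # initial attacker biomass
  C2: 0.01    # initial target biomass
  C3: 0.0     # initial transconjugant biomass
  N1: 1.0     # initial shared nutrient pool
  N2: 0.0     # initial attacker-private pool (1.0 under metabolic_diversity)
  N3: 0.0     # initial target-lineage-private pool (1.0 under metabolic_diversity)
  T: 0.0      # initial toxin
t_max: 5000.0
rtol: 1.0e-8
atol: 1.0e-10
convergence_tol: 1.0e-8
extinction_threshold: 1.0e-6
transfer_only_zero_gamma: false
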