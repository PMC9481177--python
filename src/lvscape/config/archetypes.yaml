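# Group archetypes for the synthetic cohort generator.
#
# Each archetype parameterises a mean-reverting bounded random walk for the
# per-network growth parameters alpha_i(t):
#   mu_lo/mu_hi  - range the per-network long-run means are drawn from
#   sd           - stationary spread of the walk around its mean
#   revert       - mean-reversion rate per step (0 < revert <= 1)
#   clip_lo/hi   - hard bounds keeping the walk in the valid regime
#
# "near_bifurcation" straddles the attractor-membership thresholds (some
# alpha dip negative, networks join and leave the attractor, cooperation is
# frequent); "saturated" keeps every alpha well above zero so the attractor
# always contains all networks; "intermediate" mostly keeps the attractor
# full but dips below the weakest membership thresholds occasionally.
# Values were calibrated once with scripts/calibrate_archetypes.py so the
# qualitative group ordering of the landscape measures is stable across
# seeds; edit here and re-run that script to re-calibrate.
near_bifurcation:
  mu_lo: -0.08
  mu_hi: 0.25
  sd: 0.22
  revert: 0.15
  clip_lo: -0.9
  clip_hi: 0.9
intermediate:
  mu_lo: 0.10
  mu_hi: 0.40
  sd: 0.095
  revert: 0.15
  clip_lo: -0.7
  clip_hi: 0.9
saturated:
  mu_lo: 0.65
  mu_hi: 0.90
  sd: 0.05
  revert: 0.15
  clip_lo: 0.25
  clip_hi: 1.1
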