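# Bundled Brière-parameter presets for Philaenus spumarius preimaginal stages.
#
# "parameterized": rates estimated from constant-temperature climatic-chamber
#   cohort experiments (10/18/24/30 °C).
# "calibrated": rates refined against weekly field surveys of nymphal stages
#   in Italian olive groves.
#
# Each stage gives the peak development rate v_max (day^-1) and the lower and
# upper development thresholds (°C); the Brière scale constant is
# reconstructed from v_max at load time.
#
# Entries marked "interpolated" are not individually published: they are
# filled from the published per-stage ranges and qualitative statements
# (see docs/methods.md) and should be treated as indicative.

parameterized:
  stages:
    egg: {v_max: 0.0373, t_inf: 6.5, t_sup: 32.0}
    n1:  {v_max: 0.2382, t_inf: 3.0, t_sup: 33.0}
    n2:  {v_max: 0.1747, t_inf: 3.0, t_sup: 33.0}
    n3:  {v_max: 0.2177, t_inf: 2.1, t_sup: 33.0}
    n4:  {v_max: 0.2382, t_inf: 3.0, t_sup: 33.0}
    n5:  {v_max: 0.1600, t_inf: 3.0, t_sup: 33.0}  # v_max interpolated

calibrated:
  stages:
    egg: {v_max: 0.0519, t_inf: 3.0, t_sup: 35.0}
    n1:  {v_max: 0.2200, t_inf: 3.0, t_sup: 33.0}  # v_max interpolated
    n2:  {v_max: 0.1650, t_inf: 3.0, t_sup: 33.0}  # v_max interpolated
    n3:  {v_max: 0.2177, t_inf: 2.1, t_sup: 33.0}
    n4:  {v_max: 0.2100, t_inf: 4.0, t_sup: 33.0}  # v_max and t_inf interpolated
    n5:  {v_max: 0.1441, t_inf: 5.0, t_sup: 33.0}

# Egg diapause termination: cumulative degree-days DD_e above threshold T_e,
# accumulated from 1 January (field-calibrated values).
diapause:
  t_e: 6.5
  dd_e: 120.0

# Initial distribution of egg physiological age on 1 January: Beta(alpha, beta)
# on x in [0, 1]; 90% of eggs between ages 0.58 and 0.99.
age_distribution:
  alpha: 5.67
  beta: 1.05
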