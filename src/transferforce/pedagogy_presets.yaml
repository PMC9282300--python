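# Skill-production presets for the pedagogy module.
#
# Production is modeled as P_x = amp * M_x * S_x^w, where M_x is a
# biomechanical capacity curve (logistic rise, logistic senescent fall) and
# S_x a saturating skill stock accumulated with experience at rate rho_s.
# The skill weight w sets how skill-limited the niche is.  "high_skill"
# saturates slowly and leans heavily on skill (extractive foraging /
# hunting); "low_skill" saturates within a few years and leans on capacity
# (collected foods).
high_skill:
  w: 0.9
  rho_s: 0.035
  s0: 0.02
  amp: 5200.0
  cap_rise_center: 14.0
  cap_rise_width: 3.0
  cap_fall_center: 62.0
  cap_fall_width: 9.0
low_skill:
  w: 0.3
  rho_s: 0.30
  s0: 0.05
  amp: 3400.0
  cap_rise_center: 14.0
  cap_rise_width: 3.0
  cap_fall_center: 62.0
  cap_fall_width: 9.0
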