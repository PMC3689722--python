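# Default micro-analytic code book for second-by-second dyadic free play.
# One code per second per participant; combined states are (infant, mother) pairs.
infant_codes:
  1: plays
  2: explores
  3: obeys
  4: cooperates
  5: defies
  6: neglects
  7: passive
  8: other
mother_codes:
  10: other
  11: follows
  12: enriches
  13: forces
  14: commands
  15: directs
  16: interrupts
  17: passive
  18: neglects
  19: inappropriate
  20: manipulates_toy
# Codes carrying no specific behavior; seconds holding them are spliced out
# before transition extraction.
other_codes: [8, 10]
harmony:
  # optimal interaction: infant plays, mother follows or enriches
  harmonious_states: [[1, 11], [1, 12]]
  # one partner adjusts to the other's idea
  smooth_mother_codes: [11, 12]
  smooth_infant_codes: [3, 4]
  # leadership refused, conflict
  disharmonious_infant_codes: [5, 6]
  disharmonious_mother_codes: [13, 14, 15]
  # lack of joint activity
  neglect_codes: [6, 18]
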