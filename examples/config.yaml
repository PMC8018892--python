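# Demo pipeline: simulate a risk-averse expected-utility agent on one
# continuity test, run the axiom test + IP fit, fit and compare two value
# models, and run the per-session choice regression.
#
#   riskchoice run --config examples/config.yaml --out-dir out/

seed: 1

simulate:
  agent:
    kind: value            # value | lexicographic | indifferent
    model:
      kind: EU_power       # EV | EU_power | EU_sshape | PW | additive | mean_variance
      params: {a: 0.8, tau: 0.05}
    side_bias: 0.0
    within_session_decline: 0.0
  design:
    a: 0.5                 # sure-reward magnitudes (ml) of the ranked triplet
    b: 0.25
    c: 0.0
    levels: 11             # mixture-probability grid: 0 to 1 in 0.1 steps
    repeats: 30            # trials per level per session
    sessions: 3

analyses:
  continuity: true
  models: [EV, EU_power, EU_sshape]
  regression: true
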