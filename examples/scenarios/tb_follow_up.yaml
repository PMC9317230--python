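# Continuous-endpoint tuberculosis follow-up scenario: TBscore as outcome,
# molecular point-of-care test (arm A) versus sputum smear microscopy (arm B).
# Planning uses the rounded clinically-stated difference of 0.2 points.
prevalence: {true: 0.15, assumed: 0.15}
tests:
  A: {se: 0.88, sp: 0.98}
  B: {se: 0.50, sp: 0.965}
outcomes:
  kind: continuous
  means: {tp: 2, fn: 5, fp: 4, tn: 1}
  sd: 2
  planning_delta: 0.2
design: {alpha: 0.05, power: 0.8, interim_fraction: 0.5}
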