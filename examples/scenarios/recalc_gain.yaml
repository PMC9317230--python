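# Binary-endpoint scenario in which the blinded recalculation pays off:
# the prevalence was assumed to be 0.2 at the planning stage but is truly 0.4.
prevalence: {true: 0.4, assumed: 0.2}
tests:
  A: {se: 0.95, sp: 0.90}
  B: {se: 0.70, sp: 0.75}
outcomes:
  kind: binary
  mu: {I_pos: 0.1, II_pos: 0.25, I_neg: 0.2, II_neg: 0.05}
design: {alpha: 0.05, power: 0.8, interim_fraction: 0.5}
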