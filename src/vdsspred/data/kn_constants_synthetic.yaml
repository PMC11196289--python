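# SYNTHETIC stand-in regression constants for the microsomal-binding model.
# These are NOT the published values: they are physically plausible test
# constants (positive logP slopes, mild descriptor penalties) constructed so
# the Korzekwa-Nagar pipeline can be exercised end-to-end in tests and
# examples.  Do not use for real predictions.
fum_regression_constants:
  const1: -1.5
  const2: -2.0
  const3: -3.0
  a1: 0.45
  a2: 0.35
  b2: -0.1
  b3: -0.1
  c2: 0.1
  d1: 0.02
  e: 0.3
  f: 0.3
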