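# Regression constants for the microsomal-binding (L*KL) model used by the
# Korzekwa-Nagar VDss method.  The published constants are distributed in an
# external supplement and are NOT bundled here; fill the values in (or point
# load_kn_regression_constants() at your own file) to enable the method.
# While any value is null the Korzekwa-Nagar method is unavailable.
fum_regression_constants:
  const1: null   # intercept, neutral-species term
  const2: null   # intercept, cation term
  const3: null   # intercept, anion term
  a1: null       # logP slope, neutral-species term
  a2: null       # logP slope, cation term
  b2: null       # H-bond acceptor coefficient, cation term
  b3: null       # H-bond acceptor coefficient, anion term
  c2: null       # H-bond donor coefficient, cation term
  d1: null       # dipole-moment coefficient, neutral-species term
  e: null        # SO-group coefficient (all terms)
  f: null        # NO2-group coefficient (all terms)
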