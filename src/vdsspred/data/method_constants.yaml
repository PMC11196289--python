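# Method constants for the six VDss prediction methods (70-kg human).
# Edit a copy and pass it to load_method_constants()/--constants to override.
body_weight_kg: 70.0
hematocrit: 0.45
# plasma (neutral lipid + neutral phospholipid) volume over plasma water
# volume; used by the adjusted-fup (perfusion-limited) method
vlipid_over_vwater: 0.0038095238095238095

oie_tozer:
  v_p: 0.0436      # plasma volume, L/kg
  v_e: 0.151       # extracellular fluid volume excluding plasma, L/kg
  r_ei: 1.4        # extracellular:plasma binding-protein ratio
  v_r: 0.38        # remainder (tissue) volume, L/kg

rodgers_rowland:
  v_plasma: 3.5    # plasma volume, L
  ph_iw: 7.22
  ph_p: 7.4
  f_nl_plasma: 0.0023
  f_np_plasma: 0.0013

korzekwa_nagar:
  v_p: 0.043       # plasma volume, L/kg
  v_t: 0.557       # tissue volume, L/kg
  r1_neutral: 0.116
  a: 20.0
  b: 0.76
  # microsomal-binding regression constants live in kn_constants.yaml
  fum_regression_constants: null

tcm_new:
  iw_wb: 0.48      # whole-body intracellular water, L/kg
  ew_wb: 0.22      # whole-body extracellular water, L/kg
  nl_wb: 0.149     # whole-body neutral-lipid equivalent, L/kg
  nlp_blood: 0.00075
  iw_blood: 0.29
  ew_blood: 0.53
  nl_blood: 0.004
  v_plasma: 0.04   # plasma volume, L/kg
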