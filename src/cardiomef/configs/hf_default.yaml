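# Default heart-failure ionic remodeling factors (multiplicative scales on
# the maximal conductances / exchanger scale of the myocyte model).
#
# CALIBRATION ARTIFACT: the remodeling directions follow the standard human
# heart-failure phenotype (down-regulated Ito, IKs, IK1 and INa, mildly
# reduced ICaL, up-regulated Na+/Ca2+ exchange); the magnitudes are chosen
# within experimentally reported human ranges so that the remodeled cell
# shows clear action-potential prolongation and a reduced calcium transient
# at 1 Hz pacing.  Every heart-failure result depends on these values; edit
# them and re-run the acceptance checks.  See docs/methods.md.
hf:
  enabled: true
  f_ito: 0.25
  f_iks: 0.20
  f_ik1: 0.40
  f_ina: 0.60
  f_ical: 0.88
  f_inaca: 1.65
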