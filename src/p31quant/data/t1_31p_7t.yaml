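# Longitudinal relaxation times (seconds) of 31P metabolites in skeletal
# muscle at 7 T, used for steady-state saturation correction at short TR.
#
# SYNTHETIC-REPRESENTATIVE DEFAULT SET: plausible order-of-magnitude values
# (PCr and phosphomonoesters/diesters long, ATP short), NOT a transcription
# of a specific literature table.  Replace with the relaxation table from
# your calibration source before analysing real data.
source: "p31quant synthetic-representative defaults (not a literature transcription)"
t1:
  PCr: 4.0
  gATP: 0.8
  aATP: 0.9
  bATP: 1.1
  PDE: 5.0
  Pi_a: 4.5
  Pi_b: 4.5
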