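# Mg-ATP equilibrium constants and limiting alpha-beta chemical shifts.
#
# SYNTHETIC-REPRESENTATIVE DEFAULT SET.  The values below are physically
# plausible round numbers chosen for simulation and round-trip testing:
# they reproduce the qualitative behaviour of published titration data
# (free ATP alpha-beta separation near 10.9 ppm, Mg-bound near 8.3 ppm,
# ATP mostly Mg-complexed at resting-muscle [Mg2+] ~ 0.5-1 mM, observed
# shift near 8.5-8.7 ppm).  They are NOT a transcription of any specific
# literature table; replace with a citable set before analysing real data.
#
# Formation constants in M^-1; shifts in ppm, convention delta(alpha)-delta(beta) > 0.
source: "p31quant synthetic-representative defaults (not a literature transcription)"
k_h: 5.0e+6
k_mg: 2.0e+4
k_mgh: 2.0e+3
k_mg2: 2.0e+1
d_atp: 10.85
d_hatp: 10.95
d_mgatp: 8.35
d_mghatp: 8.70
d_mg2atp: 8.10
flip_sign: false
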