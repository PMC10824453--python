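# Default neural-mass parameter profile: a two-population alpha-rhythm
# mass whose closed excitatory-inhibitory loop resonates near 10 Hz.
# Thalamic input statistics left null are calibrated at run time so the
# healthy operating point sits at the excitatory sigmoid midpoint.
Vd1: 7.0
Vd2: 7.0
C1: 86.154
C2: 1.655
he_params: [3.25, 100.0]
hi_params: [22.0, 45.0]
sigmoid_steepness: [0.56, 2.24]
thalamic_input: [null, null]
dmax: 5.0
coupling_gain: 2.0
input_gain: 1.0
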