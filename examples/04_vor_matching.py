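"""VOR transfer-function model: gain and spike-driven eye prediction.

Simulates the compensatory eye velocity evoked by a naturalistic head
movement through the afferent -> vestibular-nucleus -> neural-integrator ->
oculomotor-plant cascade (gain ~ 1, eye ~ -head), then feeds model VOR
neurons' spike trains through the downstream decoder (NI + plant) and scores
how well the predicted eye-velocity spectrum matches the actual one with the
matching index (1 = perfect agreement).  Regular neurons, which faithfully
encode the head-velocity time course, support much better eye-movement
prediction than irregular ones.
"""

import vestcode as vc

params = vc.VORParams(g_VOR=1.0)
head = vc.generate_naturalistic_stimulus(vc.StimulusSpec(duration=120.0,
                                                         seed=10))
eye = vc.simulate_vor(head, params)
gain, diag = vc.vor_gain(head, eye)
print(f"simulated VOR gain = {gain:.3f} (R^2 = {diag['r_squared']:.3f}); "
      "gain near 1 means eye velocity ~ -head velocity")

actual_spectrum = vc.power_spectrum(eye)
for cv in (0.1, 0.8):
    spec = vc.NeuronSpec(base_rate=50.0, target_cv=cv, sensitivity=0.5,
                         kernel_shape="vor", seed=11, vor_params=params)
    train = vc.generate_ln_response(head, spec)
    _, predicted = vc.predict_eye_from_spikes(train, params, rate_gain=0.5)
    match = vc.matching_index(predicted, actual_spectrum)
    print(f"VOR neuron with CV {cv:.1f}: matching index = {match.mi:.3f}")
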