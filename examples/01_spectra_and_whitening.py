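"""Resting-discharge spectra and temporal whitening of driven responses.

Builds model neurons with the same firing rate (50 sp/s) but different
interspike-interval variability (CV 0.1 vs 0.8).  At rest, low-frequency
spectral power follows the renewal-theory limit rate*CV^2, so regular
neurons transmit very little power in the 0-20 Hz band of naturalistic head
motion.  During naturalistic stimulation, the regular neuron's response
spectrum decays with frequency like the stimulus (not white), while the
irregular neuron's spectrum is nearly flat — temporal whitening — as
summarized by the whitening index over 0-20 Hz.
"""

import vestcode as vc

stim = vc.generate_naturalistic_stimulus(vc.StimulusSpec(duration=200.0,
                                                         seed=1))
for cv in (0.1, 0.8):
    resting = vc.generate_renewal_spiketrain(rate=50.0, cv=cv,
                                             duration=300.0, seed=2)
    stats = vc.isi_stats(resting)
    p0 = vc.power_spectrum(resting)
    spec = vc.NeuronSpec(base_rate=50.0, target_cv=cv, sensitivity=0.5,
                         kernel_shape="identity", seed=3)
    response = vc.generate_ln_response(stim, spec)
    wi = vc.whitening_index(vc.power_spectrum(response))
    print(f"CV target {cv:.1f}: measured rate {stats.firing_rate:5.1f} sp/s, "
          f"CV {stats.cv:.3f}")
    print(f"  resting low-frequency power {p0.band_mean(0.5, 2.0):6.2f} "
          f"sp^2/s (renewal theory: rate*CV^2 = {50 * cv**2:.2f})")
    print(f"  whitening index of the driven response over 0-20 Hz: "
          f"{wi.wi:.3f} (1 = flat spectrum, i.e. temporally white)")
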