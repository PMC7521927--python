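# vestcode

Coding-strategy analysis for central vestibular neurons: spike-train
spectral statistics, temporal whitening, linear–nonlinear (LN) spectrum
prediction, optimal linear stimulus reconstruction, coherence-based mutual
information, and a vestibulo-ocular reflex (VOR) transfer-function model —
plus a seeded synthetic-neuron cohort generator on which the whole pipeline
is exercised and tested.

## The scientific problem

Neurons in the vestibular nuclei show a wide range of resting-discharge
variability, summarized by the interspike-interval coefficient of variation
(CV: 0 clock-like, 1 Poisson-like).  During naturalistic head motion
(0–20 Hz yaw velocity), this variability sets a trade-off between two
coding strategies:

* **Temporal whitening** (optimized coding): irregular neurons produce a
  response power spectrum that is independent of frequency across the
  stimulus band.  Quantified by the whitening index
  WI = ∫₀²⁰ P_RR(f) df / (20 · max P_RR), which is 1 for a flat ("white")
  spectrum.
* **Faithful encoding**: regular neurons instead preserve the detailed
  time course of head velocity.  Quantified by the coding fraction
  CF = 1 − √⟨(S − S_rec)²⟩/σ_S of the optimal linear (Wiener)
  reconstruction S_rec = Σᵢ (Kᵢ ∗ Rᵢ), with K̃₁ = P_RS*(f)/P_RR(f) for one
  neuron and a 2×2 cross-spectral solve for pairs.

The package links both to information (coherence lower bound
MI = −∫ log₂(1 − C(f)) df and its water-filling optimality), predicts
response spectra with an LN cascade (P_RR,pred = P0 + P_FR,pred), and
closes the loop behaviorally: a four-stage VOR transfer-function model
(canal afferents → vestibular nucleus with velocity storage → neural
integrator → oculomotor plant) turns spike trains into predicted eye
velocity, scored against the actual eye-velocity spectrum with a matching
index in [0, 1].  On the synthetic cohort, whitening rises with CV while
CF, MI and the matching index fall — regular neurons are the ones whose
output can drive a compensatory VOR.

Intended users: systems/computational neuroscientists analyzing spike
trains recorded under continuous sensory stimulation, or anyone needing a
tested reference implementation of these estimators.

## Worked example

```python
import vestcode as vc

stim = vc.generate_naturalistic_stimulus(vc.StimulusSpec(duration=120.0, seed=6))
low  = vc.generate_ln_response(stim, vc.NeuronSpec(base_rate=50, target_cv=0.1,
                                                   sensitivity=0.5, seed=7))
high = vc.generate_ln_response(stim, vc.NeuronSpec(base_rate=50, target_cv=0.8,
                                                   sensitivity=0.5, seed=9))
for name, train in [("CV 0.1", low), ("CV 0.8", high)]:
    wi = vc.whitening_index(vc.power_spectrum(train)).wi
    cf = vc.reconstruct_and_score(train, stim).cf
    print(name, f"WI = {wi:.3f}  CF = {cf:.3f}")
```

prints (values from this exact script):

```
CV 0.1 WI = 0.247  CF = 0.716
CV 0.8 WI = 0.780  CF = 0.195
```

The regular neuron (CV 0.1) is far from white in-band (WI 0.25) but
supports a faithful reconstruction of the head-velocity waveform (CF 0.72:
72% of the stimulus SD is recovered); the irregular neuron (CV 0.8) is
nearly white (WI 0.78) but reconstructs poorly (CF 0.20).  The
`examples/` directory walks through each capability the same way —
spectra and whitening, LN prediction, reconstruction, VOR matching, and
the full cohort table with trend statistics; `vestcode --help` exposes the
same steps as a command line for file-based inputs.

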