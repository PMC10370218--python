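# cochamp

Signal-to-noise enhancement by spatially distributed, cochlea-like wave
amplification.

The mammalian cochlea amplifies faint sounds through the concerted action
of outer hair cells — yet amplification can only improve *sensitivity* if
it boosts signals more than the internal mechanical noise generated
inside the cochlea itself.  `cochamp` is a toolkit for analyzing exactly
that question, aimed at researchers in auditory biophysics and anyone
studying noise in distributed active media (active transmission lines,
laser-like gain media):

* **Cascaded noisy amplifiers.**  For a one-way chain of N amplifiers of
  gain g with an independent noise source at every node, the signal gain
  is G_sig = gⁿ, the noise gain follows from incoherent summation,
  G_noise[n] = sqrt((g^{2(n+1)} − 1)/((n+1)(g² − 1))), and the SNR
  enhancement R[n] = G_sig/G_noise exceeds 1 for every g > 1.  A
  bidirectional (isotropic) variant propagates noise both ways through a
  discrete Green's function G[n,n′] = Π g_m; there the optimal gain
  profile is high gain *before* the node of interest and strong
  attenuation after it — and no profile can raise the SNR everywhere at
  once.
* **Active cochlear waveguide.**  A 1-D transmission line
  (1/A)(A P′)′ + k²P = 0 with an exponential tonotopic map
  (70 kHz at the base → 4 kHz at the apex over 5 mm) and a
  single-degree-of-freedom partition admittance gives a complex
  wavenumber whose imaginary part is the local gain: with the amplifier
  on, Im(k) > 0 basal to the characteristic place x̂ and Im(k) < 0
  (sharp cut-off) apical to it; with the amplifier off, Im(k) < 0
  everywhere.  Solvers: a reflectionless WKB Green's function
  G(x,x′) ≈ (1/2i)·sqrt(A(x′)/A(x))·(k(x)k(x′))^{−1/2}·exp(−i∫k dx̂)
  and a finite-difference oracle, plus a 2-D finite-difference "box"
  cochlea for BM-velocity responses and reflective-stapes effects.
* **Incoherent internal noise.**  Noise is a field of independent
  sinusoidal sources (uniform phases, non-negative random magnitudes of
  mean μ and variance σ²); the propagated rms depends only on
  γ² = μ² + σ²:  N_rms(x) = γ·sqrt(∫|G(x,x′)|² dx′).
* **SNR profiles.**  R(x) ∝ |G(x,0)| / sqrt(∫₀ˣ|G|² + ∫ₓᴸ|G|²), with the
  basal/apical decomposition of the noise integral, CF-following
  narrowband enhancement R_on/R_off, and broadband (white 4–70 kHz)
  enhancement profiles.

## Worked example

```python
import numpy as np
from cochamp import CochlearModel, WKBProvider, snr_profile, \
    enhancement_profile_narrowband, enhancement_profile_broadband

model = CochlearModel()                      # calibrated default cochlea
print(round(model.characteristic_place(10e3) * 1e3, 3))   # 3.085  (mm)

prov = WKBProvider(model)
on, off = snr_profile(prov, 10e3, True), snr_profile(prov, 10e3, False)
j = np.argmin(np.abs(prov.x - model.characteristic_place(10e3)))
print(round(20 * np.log10(on.signal_rms[j] / off.signal_rms[j]), 2))  # 25.93
print(round(20 * np.log10(on.noise_rms[j] / off.noise_rms[j]), 2))    # 20.33
print(round(20 * np.log10(on.snr[j] / off.snr[j]), 2))                # 5.6

nb = enhancement_profile_narrowband(prov)
bb = enhancement_profile_broadband(prov, narrowband=nb)
print(round(nb.most_sensitive_enhancement_db, 2))   # 14.6   (dB)
print(round(bb.peak_enhancement_db, 2))             # 9.98   (dB)
```

Reading the numbers: at the 10-kHz characteristic place (3.09 mm from
the stapes) turning the amplifier on boosts the signal by 25.9 dB but
the accumulated internal noise by only 20.3 dB, a 5.6-dB SNR gain at
that single frequency and place.  Following the local characteristic
frequency along the cochlea, the most sensitive locations gain
≈ 14.6 dB of narrowband SNR, and for white signal and noise spanning the
full 4–70 kHz CF range the broadband SNR improves by ≈ 10 dB at its
best locations — location-dependent amplification followed by a sharp
wave cut-off is a noise-rejection strategy, not just a volume knob.

The same analyses are scriptable from the shell:

```bash
cochamp snr narrowband            # CF-following enhancement table
cochamp snr broadband             # white-band peak enhancement
cochamp figures --out out/        # all figure-panel analogue CSVs + manifest
```

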