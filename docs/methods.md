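# Methods

## The question and the two models

Amplification improves sensitivity only when signals are amplified more
than the internal noise added inside the amplifying medium.  Two
complementary models quantify this for cochlea-like distributed
amplification.

**Discrete chains** (`cochamp.chain`).  N linear amplifiers connect
nodes 0..N; an independent sinusoidal noise source of rms γ sits at
every node (including the input of the first amplifier and the output of
the last, removing any before/after ambiguity).  Noise adds in power
(incoherent summation).  For the one-way chain with uniform gain g the
noise rms at node n is γ·sqrt(Σ_{m=0..n} g^{2m}); the SNR enhancement
R[n] (on vs. off, i.e. g vs. 1) and the noise factor F_n = R_n/R_0
follow in closed form.  F as conventionally printed in the
cascaded-amplifier literature is the *power-domain* quantity; it equals
the square of the amplitude-domain ratio R_n/R_0, and both are exposed
(`noise_factor_power`, `noise_factor_amplitude`) so neither convention
is silently contradicted.  Note the large-gain limit: F_power → 1 − g⁻²,
so "F ≈ 1" holds to 1% at g = 10 and to 10⁻⁴ only at g ≥ 100.
The bidirectional chain amplifies noise identically in both directions
through the symmetric discrete Green's function G[n,n′] = Π_{m} g_m
(scattering between nodes is ignored; all sources have equal strength).
A Monte-Carlo simulator with explicit uniform-phase, fixed-magnitude
sources validates both closed forms; the general (μ, σ) magnitude law
lives in the noise module.

**Active waveguide** (`cochamp.waveguide`, `cochamp.cochlea2d`).  The
cochlea is a fluid-loaded duct whose partition (organ of Corti plus
tectorial membrane) responds with velocity V_CP = Y·P0.  Averaging the
fluid equations across the scalae gives the 1-D transmission line
(1/A)(A P′)′ + k² P = 0 with k² = −Z·Y_shunt; with the series fluid
impedance Z = iωM and a single-degree-of-freedom oscillator partition,

    k²(x, ω) = ω² (M/m_p) / (ω_c(x)² − ω² + i δ_eff ω ω_c(x)),

ω_c = 2π·CF(x), CF exponential from 70 kHz (base) to 4 kHz (apex).
Time convention e^{+iωt}; forward waves go as exp(−i∫k dx), so
Im(k) > 0 is gain per unit length.  The principal square root with
δ_eff > 0 yields Im(k) < 0 everywhere (passive/postmortem state).

## The active damping model

A *constant* negative damping cannot reproduce the required sign
structure of Im(k) (gain basal to the characteristic place, sharp
evanescent cut-off apical to it): with δ < 0 everywhere the principal
branch has Im(k) > 0 at every position.  What is needed — and what
realistic active cochlear models produce — is power injection below the
local resonance turning into dissipation above it.  The minimal
phenomenological form used here blends the two smoothly:

    δ_eff(x, ω) = δ_off + (δ_on − δ_off) · w(ω/ω_c) · ramp(x) + heli(x)
    w(r)    = 1 / (1 + (r/r₀)^p)                (sigmoid in log-frequency)
    ramp(x) = 1 − exp(−(x/x_on)²)               (basal activity onset)
    heli(x) = δ_h · exp((x − L)/x_h)            (apical termination zone)

* The sigmoid `w` makes δ_eff cross zero once, just basal to the naive
  resonance (at r* = (δ_off/(δ_off − δ_on) − 1 ... solving w = w*),
  about 6% below ω_c for the defaults), which is where Im(k) changes
  sign and the travelling wave peaks.  Consequently CF at the Im(k)
  crossing sits ~5–10% above the probe frequency rather than exactly at
  it; `characteristic_place` is defined by the crossing.
* The onset ramp (x_on = 0.4 mm) encodes that amplification needs space
  to build: waves whose characteristic places lie within a fraction of a
  millimetre of the stapes never traverse a substantial gain region, so
  near-base CF waves see essentially no SNR enhancement.  Without it the
  model's perfect scale invariance would hand high-CF waves a short
  "all-gain" chain and an unrealistic enhancement right at the entrance.
* The helicotrema-like damping zone (δ_h = 3 over x_h = 0.5 mm, present
  in both modes) absorbs the lowest-frequency waves near the apex, as
  the real helicotrema does.  It also prevents the broadband enhancement
  from being dominated by band-edge waves whose cut-off region is
  truncated by the apical boundary.

### Parameters (all user-overridable; defaults are the calibrated model)

| parameter | default | meaning |
|---|---|---|
| L | 5 mm | duct length (mouse-like) |
| H | 0.5 mm | fluid chamber height (2-D model) |
| CF range | 70 → 4 kHz | exponential tonotopic map |
| sqrt(M/m_p) | 17 000 m⁻¹ | wavenumber scale; ≈ 0.24 mm wavelength and ≈ 32 grid points per wavelength at the response peak |
| δ_on | −0.08 | active damping ratio (power injection) |
| δ_off | +0.20 | passive damping ratio |
| p, r₀ | 16, 1.0 | activity-blend steepness and centre |
| x_on | 0.4 mm | basal activity-onset length |
| δ_h, x_h | 3, 0.5 mm | helicotrema damping and extent |
| grid | 1024 | ≥ 20 points per shortest in-band wavelength (validated) |

The damping ratios, wavenumber scale and the two zone lengths are
calibration constants: they were chosen once so the model reproduces the
qualitative active-cochlea phenomenology — 25–45 dB of on/off signal
gain at the characteristic place, a cut-off of more than 20 dB within
half a millimetre past the peak, ≈ 15 dB narrowband and ≈ 10 dB
broadband SNR enhancement at the most sensitive locations, and WKB
validity (|dk/dx|/k² < 0.75 throughout the band, giving ≤ 1 dB
WKB-vs-finite-difference error basal to the peak).  Weaker damping or a
longer peak wavelength degrades both the enhancement and the WKB
accuracy; the calibration is recorded here and in
`cochamp.config.DEFAULTS` and is not a per-analysis tuning knob.

## Solvers

**WKB Green's function.**  G(x,x′) = (1/2i)·sqrt(A(x′)/A(x))·
(k(x)k(x′))^{−1/2}·exp(−i ∫_{min}^{max} k dx̂), reflectionless at both
ends; the phase integral is a cumulative trapezoid on the grid.  The
area-weighted reciprocity A(x)G(x,x′) = A(x′)G(x′,x) holds by
construction and is verified to 10⁻⁸.  A warning (not an error) fires
when |k| nearly vanishes on a path or when the gradient criterion is
exceeded.

**1-D finite differences.**  Second-order discretization of the
self-adjoint form (A P′)′ + k²A P = f; stapes either as a prescribed
pressure (drive) or a radiation condition P′ = +ik(0)P (point-source
Green's functions); apex always the radiation condition P′ = −ik(L)P.
Radiation conditions are imposed through second-order ghost-point
elimination; one banded complex solve per frequency (or one multi-RHS
solve for the full Green's matrix).  The discrete point source is
−A(x′)·h on the right-hand side, which reproduces the continuum
normalization e^{−ik|x−x′|}/(2ik) in the uniform limit to < 0.1 dB.

**2-D box model.**  Laplace's equation for the pressure difference in a
rectangle (single-scala representation with the factor-of-two partition
condition ∂P/∂y = 2iωρY P at y = 0, rigid top, piston or
reflectance-calibrated mixed condition at the stapes, radiation at the
apex), discretized with the 5-point stencil and solved sparsely.  The
partition surface mass is tied to the 1-D calibration through
m_p = 2ρ/(H·(M/m_p)_{1D}), so in the shallow-fluid limit |k|H ≪ 1 the
depth-averaged 2-D solution reduces to the 1-D line (verified to
< 1 dB in that regime); near the peak |k|H > 1 and the 2-D model
develops its own deep-fluid dispersion, as real cochleae do.  The
stapes reflectance R_st is imposed as the wave reflectance of a
basally travelling wave via P′ = ik(0)·(1−R_st)/(1+R_st)·P.

**Where the peak is.**  The pressure-magnitude maximum sits a fixed
≈ 50 µm basal to the Im(k) = 0 crossing because of the WKB 1/sqrt(k)
amplitude prefactor — several grid cells at contract resolution, for any
smooth admittance.  The quantity that peaks *exactly* at the crossing is
the wave energy flux −Im(P*∂P/∂x), whose logarithmic growth rate is
2·Im(k); collocation tests therefore use the flux peak (verified to
within one grid cell against the finite-difference solution).

## Noise model and SNR analysis

Within a narrow band the internal noise is a set of independent
sinusoidal sources on the partition: phases uniform on [0, 2π),
magnitudes from a non-negative law with mean μ and variance σ².  Only
γ² = μ² + σ² enters the propagated noise power, so the law is a knob
whose irrelevance the Monte-Carlo machinery demonstrates.  The default
Rayleigh law is one-parameter and is scaled to match γ exactly (its
μ and σ individually obey the Rayleigh ratio); the log-normal option
matches both moments; `fixed` is the degenerate law.  One source per
grid cell with amplitude scaled by sqrt(Δx) makes the ensemble average
converge to the grid-independent quadrature
N_rms(x) = γ·sqrt(∫|G(x,x′)|²dx′).  Noise couples through the same
partition Green's function as the signal.

The SNR profile R(x) ∝ |G(x,0)|/sqrt(∫₀ˣ|G|² + ∫ₓᴸ|G|²) uses the
entrance wavenumber k(0) as amplification-independent — exact here,
since the activity onset ramp keeps the partition passive at x = 0.
Absolute SNRs would require a stimulus level and physical noise strength
that the analysis never fixes; all reported quantities are on/off
*ratios* (invariant under rescaling both) or curves normalized so that
postmortem signal and noise are equal at the characteristic place.

**Narrowband convention.**  One frequency per place (f = CF-following,
zero bandwidth): amplification-induced bandwidth narrowing is
deliberately excluded so that pure spatial amplification is isolated.
A CF point is flagged "near-base" when the active model has no Im(k)
crossing for it, when its on/off CF signal gain (dB) falls below 0.5 ×
the band maximum, or when its enhancement is ≤ 0 dB.  "Most sensitive
locations" are the unflagged points with maximal on-mode SNR.

**Broadband convention.**  White spectra over the model's full CF range
(4–70 kHz), 64 log-spaced frequencies by default, incoherent power
summation across frequency for both signal and noise (unspecified
phases).  Peak reporting excludes locations basal to the flagged
near-base region and a 0.25 mm apical margin lying inside the absorbing
termination/helicotrema zone.  The reported peak changes by < 0.3 dB
when the frequency count doubles; the apical-most profile points, where
the cochlear filters are sharpest relative to the frequency spacing,
converge last.

**Ablation.**  `ablate_cutoff` forces Im(k) ≥ 0 apical to the crossing
in a synthetic active variant (no evanescent cut-off, Re(k) untouched),
which lets apical noise reach the peak and strictly reduces the
enhancement there — isolating the cut-off's noise-rejection role.

## What the synthetic conditions do and do not show

The noise generator emulates spatially incoherent, spectrally white
internal sources of location-independent strength.  Real intracochlear
noise (thermal, channel gating, spontaneous OHC activity) has unknown
spectra, spatial correlations and tonotopic strength gradients; the
analysis deliberately depends only on γ², so conclusions about *ratios*
(on/off enhancement, basal/apical decomposition) are robust to the law
but not to spatial coherence — coherent noise is out of scope.  The
linear models apply near threshold only; compressive nonlinearity,
middle-ear filtering, reflection-source emissions and hair-cell/neural
noise are not modelled.  Passing tests therefore demonstrate properties
of the stated model class, not quantitative predictions for any
particular species; the ≈ 10–15 dB enhancement figures are properties of
the calibrated default model.

## Numerical choices and limitations

* Grid: ≥ 20 points per shortest in-band wavelength, enforced by a
  validator; the default 1024-point grid gives ≈ 32 at the peak.
  Self-convergence: < 0.2 dB (1-D) / < 0.5 dB (2-D) on halving.
* Quadratures are composite trapezoids; the basal/apical split uses the
  same weights so the parts sum to the total to round-off.
* Degenerate inputs: γ = 0 gives identically zero noise; silent drive
  gives a zero field; out-of-band frequencies and sub-contract grids
  raise errors naming the limit violated.
* Negative damping can in principle make the discretized operator
  near-singular at isolated frequencies; solves check for non-finite
  results and report the frequency.  None occur in-band at the default
  calibration.
* Monte-Carlo standard errors use the delta method
  (se(rms) = se(power)/(2·rms)); agreement contracts are stated at 3 SE.
* Boundary-adjacent Green's-matrix columns (sources on the first/last
  cell) are inaccurate at the few-dB level because a point source
  collides with the radiation condition; they carry half trapezoid
  weight in one cell of the noise integral, a negligible contribution.
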