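# Methods

This note documents the model implemented in `perisum`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Retinal front end

**Mosaics.** Detectors sit on regular hexagonal lattices (the densest
packing for circular receptive fields), density ρ = 2/(√3·s²) for
centre-to-centre spacing s. Coordinates are visual degrees with the
origin at the stimulus centre; no retinal-mm conversion is performed.
The default lattice phase puts a cell at the stimulus centre;
`phase_seed` jitters the global offset within one unit cell for
edge-effect studies. For pooling, the lattice is re-indexed on an
anisotropic rectangular grid (row pitch s·√3/2, column pitch s, odd
rows offset half a column); internally the columns are laid out at s/2
so the staggered rows embed in a true rectangular grid (a checkerboard
occupancy), which makes DoG pooling an exact 2-D convolution — it
matches the brute-force per-cell sum to machine precision.

**Receptive fields.** Difference of Gaussians with the classic macaque
median proportions: surround peak 1% of centre peak, surround SD 6.7×
centre SD, and the centre radius (the K_c/e point) equal to the lattice
spacing, i.e. σ_c = spacing/1.414. The kernel is truncated at 4σ_s
(residual tail mass < 10⁻³ of the surround). The kernel is normalised
to **unit lattice gain**: the sum of the kernel over its own lattice is
exactly 1, so a fully stimulated cell responds 1 and the total input S
counts stimulated RGCs. This calibration is what links the fitted
integration constant to critical RGC counts (S_c = x_c·τ/T equals the
product of Ricco's area and local density) and makes a 4×-denser cone
lattice under the same kernel respond exactly 4× — hence cone→RGC
convergence is applied as a continuous multiplicative weight c rather
than by re-meshing (the discrete construction exists in the tests as an
oracle).

**Stimuli and optics.** Discs of unit Weber contrast are rendered with
area-coverage anti-aliasing (flux accurate to ≲0.5% even for Goldmann
I). Optical blur uses the mean human MTF as a radial transfer function:
√(diffraction-limited MTF of a circular pupil) × Lorentzian with corner
frequency u₁ = 21.95 − 5.512·d + 0.3922·d² (d = pupil diameter in mm),
applied by Fourier multiplication after zero-padding to ≥2× support;
the padded support is kept so flux (the DC term) is conserved exactly.
Wavelength defaults to 555 nm (photopic). An optional straylight
correction multiplies the whole MTF by a transmitted-flux fraction
1/(1 + a_p·(1 + (age/70)⁴)) with a_p = 0.08/0.04/0.016 for
light/medium/dark irides — a deliberately simple frequency-flat
parameterisation (it dims, it does not blur); it defaults off and no
quantitative result here depends on it.

**Sampling and summation.** Cones point-sample the (blurred) image by
bilinear interpolation; per-RGC responses are the convergence-weighted
DoG pooling of those samples; the total input is the **signed** sum by
default. Signed summation makes S exactly linear in contrast and nearly
blur-invariant (blur only redistributes flux); the absolute-value
variant is retained because it amplifies optics effects for stimuli of
receptive-field scale on dense mosaics — for larger discs the smoothing
of the ± edge structure can dominate and reduce Σ|Rᵢ|, so the
"rectification amplifies blur" intuition holds only in that small-
stimulus regime.

**Area ↔ input mapping.** S(area) is evaluated on a geometric ladder of
disc areas and interpolated linearly in log₁₀–log₁₀. Two discreteness
effects are faithfully retained rather than smoothed away: below the
cell spacing the map plateaus at S ≈ 1 (only the centre cone is
stimulated), and near "magic" radii (disc rim grazing a lattice ring)
the count fluctuates by up to ~10%. The inverse map therefore uses only
the strictly increasing branch, and queries beyond the table warn past
0.3 log-units and fail past 1.

## The capacitor pooler

The total input S is integrated by a single leaky stage whose kernel is
h(t) = (S/τ)·e^(−tS/τ) — unit area, time constant τ/S, so larger inputs
integrate faster. With f(t) a unit step of duration T,

    R = [∫₀^∞ (f∗h)(t)ᵏ dt]^(1/k) · S^(1/k) = (τ·g(x))^(1/k),
    x = S·T/τ,  g(x) = ∫₀ˣ(1−e⁻ᵘ)ᵏ du + (1−e⁻ˣ)ᵏ/k.

R depends on (S, T) only through the product S·T (the spatiotemporal
input), which is what makes duration changes translate spatial
summation curves and vice versa. g is evaluated in closed form
(binomial expansion) for integer k; below x = 0.05 the expansion
cancels catastrophically and a 24-node Gauss–Legendre quadrature of the
smooth integrand is used instead; non-integer k falls back to adaptive
quadrature. A genuinely independent numerical route (midpoint-sampled
convolution on a fine time grid) agrees with the closed form to <0.5%
over x ∈ [10⁻³, 10³] and serves as the oracle in the tests.

Sensitivity readout: R is computed at unit contrast and
DLS = log₁₀R + Offset (dB = 10·DLS). Placing contrast inside S would
put it inside the time constant and make thresholds ill-defined in the
partial-summation regime, so it is rejected. A consequence of the
τ^(1/k) scale factor is that rescaling all convergence weights and τ by
λ is only an exact symmetry when the Offset absorbs −log₁₀(λ)/k; fitted
weighted/unweighted parameter pairs show exactly this pattern (τ ratio
= convergence ratio, offset difference = log₁₀c/k) while Ricco's area
is unchanged.

**Critical point.** The log-log slope of R in S (equivalently in T) is
x·(1−e⁻ˣ)^(k−1)/(k·g(x)), falling monotonically from 1 (Ricco/Bloch
complete summation) to 1/k (Piper-like partial summation). The critical
point is defined at slope 0.5, i.e. the root of
x(1−e⁻ˣ)^(k−1) = (k/2)·g(x), solved by Brent bracketing to 10⁻⁹;
for k = 4, x_c = 2.88221. The criterion only exists for k > 2 (the
asymptotic slope 1/k must lie below 0.5); k ≤ 2 raises. Critical input
and duration follow as S_c = x_c·τ/T and T_c = x_c·τ/S, so S_c·T is
constant across durations. Ricco's area is read by inverting the
**blur-free** area↔input map at S_c, estimating the neural summation
extent net of optics.

**Fitting.** Free parameters are log₁₀τ and Offset, k is fixed at 4.
The objective is the RMSE between observed and predicted sensitivity in
dB; Nelder–Mead from three deterministic starts (log₁₀τ = 2, 3, 4, each
with the offset matched to the mean level) with best-of selection.
Standard errors come from the Gauss–Newton linearisation of the
residuals. At least three data with distinct S·T products are required;
identical products make (τ, Offset) unidentifiable and raise.

## Psychophysical procedure simulators

**FOS curve.** p(x) = γ + (1−γ−λ)·Φ((µ−x)/σ) on the perimetric dB axis
(higher dB = dimmer), asymptotes γ and 1−λ.

**ZEST.** Uniform prior on [0, 50] dB at 0.1 dB resolution (the grid
makes the integer-dB stimulus rounding exact); likelihood a Gaussian
CDF with SD 1 dB and 3% guess/lapse, oriented so brighter (lower dB)
stimuli are more likely seen; stimulus = posterior mean rounded to
integer dB; stop at posterior SD < 1.5 dB (cap 200 trials, flagged via
the returned trial count). The returned estimate is the posterior mean;
simulations show |bias| < 0.5 dB for observers with σ ∈ [1, 4] dB.

**QUEST+.** Joint (µ, σ) grid: µ over seed ± 5 dB at 0.1 dB with a
truncated Gaussian prior (SD 4 dB); σ uniform on 1–10 dB in 0.5 dB
steps; guess/lapse fixed at 3%. Stimuli are integer dB spanning the µ
domain ± 3σ_max; each trial presents the candidate minimising the
expected posterior entropy; stop when the joint natural-log entropy
≤ 4.5 (the grid's maximum entropy is ≈ 7.6, so 4.5 is a mid-range
criterion). Entropy units and candidate grid are this package's
documented choices.

**MOCS.** Seven levels at FOS quantiles {10⁻⁴, .1, .3, .5, .7, .9,
1−10⁻⁴}, extremes forced ≥ 10 dB from the threshold, ≥ 1 dB spacing
enforced by spreading inner levels outward, then rounding to the 1 dB
instrument grid (order-preserving, applied last). 25 repeats per level;
four size/duration conditions at four locations give 2,800
presentations.

**Hierarchical FOS fit.** µ_loc ~ N(µ_pop, s_µ), log σ_loc ~
N(log σ_pop, s_σ), global lapse and guess ~ Beta(1, 19); hyperpriors
N(25, 20) on µ_pop, half-normal(5) and half-normal(1) on s_µ and s_σ,
log-normal(ln 3, 1) on σ_pop — these hyperpriors are this package's own.
Sampling by the emcee ensemble sampler (40 walkers, 1500 steps, 500
burn-in by default). A non-hierarchical variant (wide independent
priors, same likelihood code) exists for shrinkage comparisons;
partial pooling never widens per-location µ posteriors on shared-µ data.

**Response filtering.** Responses < 180 ms after stimulus onset or
falling inside an inter-stimulus pause window are flagged invalid.

**Synthetic observers.** µ = 10 × model-predicted DLS (optionally plus
Gaussian test–retest noise); σ = 10^(1.42 − 0.035·µ), clipped to
[0.5, 10] dB — a multiplicative-noise slope–threshold relation of the
Henson type (shallower FOS curves at lower sensitivity); the
coefficients are package defaults, configurable per call.

## Synthetic data and default conditions

The fixture generator reproduces the study design: 12 locations on the
diagonals ({±1,±1}, {±4,±4}, {±7,±7} deg), Goldmann I–V everywhere at
200 ms, five durations (15/30/55/105/200 ms) at the outer ring — 140
independent strategy threads — plus full MOCS trial tables for the four
extreme size/duration conditions. Test–retest noise defaults to 1 dB
(between the published same-condition retest RMS of ~1.2–1.7 dB per
measurement). The default density profile (P-OFF-RGC-RF 449.7 → 63.7
cells/deg², convergence 7.1 → 9.2 over 1.4–9.9 deg eccentricity,
log-linear in between) is a synthetic profile constructed to be
consistent with the published median Ricco areas, critical counts and
convergence-weighted/unweighted ratios; users with imaging-derived
estimates should supply their own table. Default generating constants
are the convergence-weighted medians (τ = 8625/7128/5789 input·ms,
Offset 2.31/2.42/2.40 dB/10 by eccentricity).

What the passing tests show: internal consistency (parameter recovery,
the critical-input identity, the symmetries of the pooler) and correct
implementation of the procedures. What they do not show: that real
observers obey the capacitor model — the generator is the model itself
plus Gaussian noise, with none of real data's fixation losses,
adaptation drifts, response-criterion shifts or instrument
miscalibration.

## Numerical choices and problem sizes

- Mosaic extent: stimulus radius + 3σ_s + 0.5 deg per side, so
  surrounds of stimulated cells never truncate; deep-interior
  assertions use margin ≥ the 4σ_s kernel reach.
- Blur pitch ≤ min(spacing/2, diameter/16, 0.004 deg), making the MTF
  at Nyquist negligible for every admissible pupil; a coarse grid whose
  stimulus carries > 1% outer-band spectral energy raises rather than
  aliasing silently.
- Area ladders use 25 points per context; simulation-based checks use
  100 mosaics/replicates and 10³ ZEST runs, sized to keep the whole
  suite around a minute on one core while leaving Monte-Carlo error
  well inside the asserted tolerances.
- The RGC-loss readout averages the degraded response curves over the
  random mosaics before re-reading Ricco's area (the noise-free
  mechanism estimate, ≈ 1/(1−loss)); per-mosaic ratios are available
  but carry the binomial noise of the ~15 surviving cells at the
  critical area plus a Jensen bias when exponentiated.

## Known limitations

- Single RGC class per run; no ON/OFF interplay, no spiking dynamics,
  no contrast gain control, no eccentricity-dependent DoG aspect ratio.
- The pooler has no response delay and integrates to infinity; it
  cannot describe the sensitivity decline reported for very long
  stimuli (irrelevant for ≤ 200 ms flashes).
- The straylight correction is frequency-flat by construction.
- Lattice-quantisation wiggles in S(area) are real features of a fixed
  concentric mosaic and propagate ~±3% into Ricco-area readouts at low
  densities.
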