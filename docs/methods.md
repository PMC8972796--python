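# Methods

This note records the model, the conventions the package is built on, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Signal model

Excitation is an instantaneous rotation by the flip angle α·B1 about the x
axis of the demodulated rotating frame; free evolution over one TR applies
transverse decay E2 = exp(−TR/T2), precession about z by the per-TR angle
θ, and T1 recovery toward the proton density pd. The complex transverse
signal is Mx + i·My, and a positive θ rotates it as exp(+iθ). An RF phase
increment Δφ per excitation, with the receiver demodulating at the RF
phase, is exactly equivalent to replacing θ by θ − Δφ; this equivalence is
used everywhere.

Two routes to the steady state are implemented and must agree: a
fixed-point Bloch iteration (stops when the per-step signal change is
below 1e−12 relative, capped at 100·T1/TR steps; the tight tolerance keeps
the accumulated fixed-point error below ~1e−9 even for CSF-like T1/TR) and
the analytic Freeman–Hill solution of the same cycle. The canonical
profile value is the post-pulse steady state decayed by exp(−TE/T2). The
additional free-precession ramp exp(iθ·TE/TR) accrued at the echo is
available behind `echo_phase=True` for inspecting the at-echo phase
profile; it is *not* part of the canonical profile because with TE = TR/2
it makes the complex profile anti-periodic over 2π, which would break the
integer-order harmonic decomposition that the whole band formalism rests
on. Magnitudes are identical either way.

### Configuration states

The Fourier coefficients of the 2π-periodic complex profile are the SSFP
configuration states: `harmonic_spectrum` returns the coefficient of
exp(+imθ) at order m. For tissues with T2 ≪ T1 at low flip angle the
spectrum is one-sided — orders m ≥ 0 decay geometrically with a ratio ρ
slightly below exp(−TR/T2), negative orders are negligible — which is the
asymmetry the one-sided band reconstruction exploits. Tissues with long T1
*and* T2 (CSF) violate this and additionally decay so slowly that many
orders are significant; see "aliasing" below. Band weights are computed at
unit proton density: pd scales the object, not the pattern, so equalizing
with these weights returns the pd-weighted object in absolute units.

## Acquisition model and conventions

The unbalanced spoiler winds `spoiler_cycles_per_voxel` precession cycles
per nominal voxel (default 1.0 — the gradient area 4π·k_max/γ). The
winding is negative with its zero at the first super-resolution sample of
each acquired voxel (the voxel's DFT reference point): with these two
choices, harmonic order q of the profile multiplies the object's spectrum
copy shifted *up* by 2q·k_max, and no stray per-band phases appear in the
band algebra.

The demodulated frame for phase increment Δφ is modeled as

    frame(y, x) = pd · m_ss(θ_sp(y) + ω(y, x) − Δφ) · e^{iω} · e^{−iΔφ} · E2(TE),

with ω = 2π·b0·TR. The per-frame receiver factor e^{−iΔφ} (the receiver
phase adjustment that keeps the pattern bookkeeping aligned with the
imaging grid) and the full-TR off-resonance reference phase e^{iω} at the
echo are the two bookkeeping choices that make k-space band m carry
exactly e^{−imΔφ}·e^{+imω}; the at-echo timing of a physical sequence
determines these only up to a fixed relabeling of the band grid, so they
are fixed here by the requirement that the band model, the multi-frequency
navigator and the conjugate-symmetry completion are mutually exact.

Profile fidelity multiplies the object by the converged pattern and
truncates k-space to the low-resolution band — exact after full
preparation, and the model the reconstruction inverts. Bloch fidelity runs
the per-isochromat recursion over every excitation: `n_dummy` dummies from
thermal equilibrium re-establish the steady state for each frame, then one
phase-encode line per excitation (bottom-to-top), so unconverged
magnetization leaks into the data exactly as in a scan. The readout axis
is ideal Fourier encoding. Receiver noise is i.i.d. circular complex
Gaussian added per k-space sample (E|n|² = σ²).

## Reconstruction

Band m = 1..M (band 1 central) occupies wide-grid frequencies
[(2m−3)h, (2m−1)h), h = n_pe/2; the output has (2M−1)·n_pe rows. One
pseudoinverse of Ψ serves every k-coordinate. Equalization divides band m
by F_{m−1}, dropping (with a warning) bands whose amplitude is below
1e−12 of the largest rather than amplifying them into noise. Completion
fills unmeasured samples with conj(S(−k)) modulo the grid; the Nyquist
row, its own mirror, stays zero if unmeasured — for smooth objects its
energy is negligible. Negative-order configuration states are omitted (the
one-sided route); `include_negative_orders` exists as a flag for long-T1/T2
work but the supported path is one-sided.

The multi-frequency reconstruction exploits that the solved central band
at trial offset ω_t acquires phase (ω_true − ω_t) per voxel: the low-pass
image from the zero-filled central band is itself the navigator, so the
per-voxel search over `n_freqs` equidistant offsets in [0, 2π) reduces to
quantizing the voxel phase. Ties break toward the smaller offset. When a
reference tissue is given, the constant configuration-state phase
arg(F₀) is removed from the navigator; without it that tissue-dependent
bias (≈ π/2·-ish common phase cancels, small residuals remain) is carried
into the ω map. The final image is assembled voxelwise from full
reconstructions at each selected offset. The ω map is reported in radians
per TR.

Linearity: the solve and equalization are linear in the frames; the
conjugate-symmetry completion is *antilinear* in the mirrored half, so the
complex pre-magnitude reconstruction distributes over real, not complex,
scalar combinations of the input frames.

## Aliasing and the choice of N

With N equidistant increments, pattern order q aliases onto solved band m
whenever q + 1 ≡ m (mod N). The contaminating amplitude is F_{m−1+N} ~
ρ^N, so N must exceed the number of significant configuration states:
for gray matter at TR = 8 ms (ρ ≈ 0.88) N = 36 suffices; CSF (ρ ≈ 0.98)
needs N well above 100. This is the structured, B0-localized variance
visible when N is small, and it is why the brain-phantom multi-frequency
experiment below uses N = 108.

## Analysis

* **PSF** — the k-space transfer function takes the *magnitude* envelope
  |F_{m−1}| on band m, both sides (the configuration-state phases are
  removed by equalization/phase correction in any consistent
  reconstruction; keeping the raw conjugated phases would cancel the
  sharpening of the odd terms). The modulus PSF is measured by linear
  interpolation on a grid oversampled 16× per band and zero-padded 64×.
  The limiting FWHM extends M until the outermost amplitude falls below
  1e−4 of the central one. M = 1 reproduces the sinc FWHM of the plain
  low-resolution voxel (120.7%).
* **Relative SNR** — the literal ratio of the two closed-form per-sample
  variances, √(M·N)/(Σ₀·√(Σₘ|F_{m−1}|⁻²)), with the spoiled-GRE
  comparator at TE = 0 and, by default, the Ernst angle — the standard
  optimum for spoiled GRE; an explicit `gre_flip` override is provided for
  protocols defining the optimum differently. Separate helpers
  (`combine_image_variance`, `gre_image_variance`) carry the same algebra
  through the mirror-doubling and DFT normalization to per-pixel image
  variances; those are what the Monte-Carlo tests check to 10%.
* **Interleave SNR** — the exact efficiency expression integrates the
  *magnitude* of the profile across the super-resolution voxel at the
  peak: the complex profile's rapid phase transition there would make the
  complex integral cancel spuriously. With the enhancement factor set by
  the profile FWHM and the comparator equal to the mean conventional
  (30°) profile, the exact value agrees with the 1/√enhancement
  approximation to ~10%.
* **Distortion** — (df/dy)·Δy_nom·TR is dimensionless: it is the local
  displacement *gradient* of the modulation pattern. The displacement law
  is δ(y) = b0(y)·TR·Δy_nom mm, verified end-to-end against simulated
  pattern-peak positions under a linear field gradient (coherence of the
  sign and coordinate conventions across modules).
* **Gradient area** — encode ×(2M−1), rewinder+spoiler ×(2M−1)/3; summing
  worst-case encode plus rewinder areas at equal super-resolution voxel
  size gives a total factor (2M−1)/2, i.e. 2.5 at M = 3.

## Synthetic data

The brain phantom is three nested elliptical compartments plus two
ventricles with fixed 3T literature values — CSF (2569/329 ms, pd 1.00),
gray matter (1331/80, 0.86), white matter (832/110, 0.77; reproduced as
printed even though its T2 exceeds gray matter's) — rendered at any n ≥ 32
(289 reproduces the reference scale at 1 mm voxels). Geometry is the
package's own; only the compartment values and scale matter to the
quantitative checks. Field maps are analytic (uniform, linear gradient,
smooth quadratic dome for B0; uniform, linear, radial for B1) and
deterministic. The generators emulate piecewise-constant tissue with
idealized fields; they have no texture, no noise correlations, no motion,
no slice profile, no finite RF pulses and no eddy currents — so passing
tests demonstrate the correctness and internal coherence of the method's
algebra and Bloch physics, not robustness to real-scanner imperfections.

## Experiment sizes used by the test suite

Chosen so each check isolates one effect at the smallest size where the
effect is clean: round-trip recovery on a 10-line, 105× oversampled
single-tissue object (the oversampling keeps discrete pattern aliasing
below the 1e−3 criterion); artifact suppression on a 63×63 phantom
(9 frames of 7 lines, 0.1° flip, dummy blocks 0/2/8 against a 400-block
reference); noise propagation with 500 Monte-Carlo repetitions at 8×8
frames; multi-frequency correction on a 128×128 phantom (16 lines, M = 3,
N = 108, 100 offsets, 80 Hz dome peak — ω beyond half a pattern period),
with artifact energy compared over the head foreground and the ω map
checked on the eroded interior.

## Known limitations

* The one-sided band model degrades for tissues with long T1 and T2
  unless N is large; no negative-order solver is wired into the default
  path.
* Equalization needs a reference tissue; in mixed objects other
  compartments keep a tissue-dependent residual PSF (real physics of the
  method, but it means absolute intensities are only exact for the
  reference tissue).
* B0 is assumed constant within each nominal voxel by the correction;
  strong intra-voxel gradients additionally stretch the pattern
  (quantified by the distortion factor) and are not removed.
* The spoiled-GRE comparator uses the Ernst angle; published comparisons
  built on a different flip-angle optimum will differ by the ratio of the
  comparator amplitudes.
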