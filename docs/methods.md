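# Methods

## Scope and conventions

`acoustrap` simulates single-sided, multi-focus acoustic trapping of
Mie-regime spheres (diameter ≥ 6λ) by a 2-D phased array.  All internal
quantities are SI; configuration files use µm / MHz / MRayl and are
converted at the YAML boundary.  The array lies in the z = 0 plane centred
on the origin; +z is the propagation direction.  Steady-state phasors are
used throughout: the `e^{jωt}` factor is dropped and propagation carries
`e^{−jkr}`.  Per-beam force calculations use a local frame with origin at
the focal point, z along the beam propagation direction and y across it;
`F_z < 0` points back toward the transducer (restoring), and for the
synthesized corner foci the local axis is the tilted array-centre → focus
direction (≈21° off the global z axis).

Default physical parameters (packaged preset `water_lipid_50mhz`):
25 × 25 elements, 27 µm pitch, 5 µm kerf (22 µm
square elements), 50 MHz, water (ρ₀ = 1000 kg/m³, c = 1500 m/s,
Z₁ = 1.5 MRayl, µ = σ = 8.9×10⁻⁴ Pa·s), lipid sphere (ρ = 950 kg/m³,
c₂ = 1450 m/s, Z₂ = 1.4 MRayl, diameters 240–360 µm = 8λ–12λ), four
control points at (±0.18, ±0.18, 0.67) mm with equal unit target
pressures.  The tabulated particle impedance (1.4 MRayl) is kept even
though ρc = 1.3775 MRayl; the ~1.6% difference measurably changes the
reflection contrast, so the validator accepts a 2% band rather than
silently replacing the value.

## Field synthesis

Each element is subdivided 4 × 4 (5.5 µm ≤ λ/4 midpoint quadrature; the
builder refuses spacings above λ/2).  The propagation matrix entry
`H(m,n) = jρ₀c/λ · Σ_s e^{−jkr}/r · dS` sums the element's sub-sources.
Doubling the subdivision changes every |H(m,n)| by < 0.1% (tested).

The minimum-norm excitation is computed through the SVD with singular
values below 10⁻⁸ of the largest treated as rank deficiency.  The
iterative weighting uses `W ∝ diag(1/|û_n|)` (unit trace, floored at 10⁻⁶
of the largest amplitude), i.e. IRLS toward uniform element drive — the
update that actually maximizes excitation efficiency and satisfies the
contract `spread(Û) ≤ spread(U)`; on the four-focus problem it converges
to a phase-only solution (spread 44 → 1.0) in two iterations while keeping
`‖HÛ − p‖/‖p‖ < 10⁻¹⁰`.

Two normalization modes exist: **peak-intensity** (default) rescales the
solved excitation so the spatial peak intensity is 150 W/cm²;
**total-power** rescales so the source-plane power is 4.25 mW.  Source
power is the baffled plane-piston value `P = Σ ½ρ₀c|u_n|²A_n`; mutual
radiation impedance between the ~0.7λ elements is neglected.  The two
modes are *not* equivalent for a full-array solution: the phase-only
excitation radiates 16.9 mW at 150 W/cm² peak, because a substantial
fraction of the power leaves through sidelobes rather than the four beam
cores (four ideal 22-µm-waist Gaussian beams at this peak would carry only
≈4.6 mW).  In total-power mode the peak intensity is correspondingly
≈38 W/cm².

## Beam characterization

Foci are strict local intensity maxima above a threshold fraction (default
0.5) of the global peak, refined off-grid by 3-point quadratic fits per
axis.  The beam waist ω₀ is defined as the **half-power full width** of
the focal-plane intensity profile through the focus (measured along the
array diagonal by direct fine-line rendering at 0.25 µm), and that same
ω₀ is used directly in the Gaussian wavefront-curvature and intensity
formulas — deliberately conflating half-power width with the 1/e² radius,
because the downstream force model is defined in terms of a single width
parameter; a `waist_convention="1/e2"` option divides by 2√(ln2/2) for
sensitivity analysis.

The synthesized four-focus field measures 32.6 µm half-power width at
f-number ≈ 1.  The paraxial lower bound for this aperture
(0.886·λz/D = 26.4 µm) plus obliquity and element-directivity apodization
make widths below ~26 µm physically unreachable for this array, so the
32.6 µm figure should be read as a property of the honest diffraction
model, and downstream force positions inherit it.

## Ray-acoustics force

The force on a sphere is integrated over its illuminated surface.  For an
entry point Q, the ray direction points from the wavefront curvature
centre on the beam axis through Q with signed curvature radius
ρ(z) = z + z_R²/z (z_R = πω₀²/λ, magnitude capped at 10¹² m near the
waist); entry points outside the wavefront (|Q_t| > |ρ|) carry no power.
Ray power through a patch is `I(Q)·cosθᵢ·dA` with I the analytic Gaussian
beam intensity at the entry point.  The refraction angle follows Snell's
law; rays past total internal reflection are fully reflected.

**Reflection convention.**  The q-factor closed forms are momentum budgets
and require *energy* fractions.  The default R is therefore the power
reflectance `r²` of the oblique fluid–fluid interface,
`r = (Z₂/cosθᵣ − Z₁/cosθᵢ)/(Z₂/cosθᵣ + Z₁/cosθᵢ)` (each impedance with
its own medium's propagation angle), with T = 1 − R.  An
`convention="amplitude"` variant retains the amplitude-magnitude quotient
(with the swapped angle placement that sometimes appears in print) for
comparison; feeding that amplitude value into the q-factors inflates the
reflection push ~30× at this weak contrast and suppresses axial trapping
entirely, which is how the two conventions can be told apart empirically.

**Gradient orientation.**  The gradient unit vector is perpendicular to
the ray in the plane of incidence with `ĝ·n̂ < 0` (n̂ the outward normal).
The orientation is fixed by the mirror limit: with R = 1 the perpendicular
force must push the sphere away from the struck side.  A fixed (per-sweep)
orientation would give an on-axis sphere a spurious net lateral force; the
per-ray orientation makes it cancel to machine precision (tested).

**Integration modes.**  `as-printed-2d` (default) integrates the single
zoy meridian with the 1-D measure `r₀² I |sinθ| cosθᵢ/c dθ` (unit
azimuthal measure); `surface-3d` integrates the full (θ, φ) surface with
`dA = r₀² sinθ dθ dφ`.  Both give identical signs, positions, trends and
convergence; the 3-D magnitudes are ≈3× larger.  The meridian mode's
magnitudes are the ones that line up with the reference trapping table, so
it is the default.  Quadrature: 1000 meridian nodes (2-D) or 500 × 360
(θ, φ) trapezoid nodes (3-D); doubling changes forces by ≪1% (tested).

Trapping summaries: maximum trapping force = the most negative axial
force (parabolic refinement); trapping region = contiguous negative
interval containing it (linearly interpolated edges); balanced position =
its upstream zero crossing with negative slope (the stable equilibrium);
maximum lateral force = max |F_y| across the axis through the balanced
position.  Forces below 10⁻¹⁸ N are treated as numerical zero so that an
acoustically matched particle (round-off forces ~10⁻²⁴ N) is reported as
untrapped.

## Dynamics

`m dv/dt = F(x) − 6πµr₀v`, integrated by adaptive RK45 (rtol 10⁻⁸, atol
10⁻⁹ m and 10⁻⁹ m/s, max step 1 ms) on a cubic-spline interpolant of a
pre-computed force profile.  Capture is declared when |v| < 1 µm/s within
1 µm of a stable force zero; leaving the profile domain truncates with an
escape flag.  For these parameters the momentum relaxation time
m/6πµr₀ ≈ 3–7 ms makes trajectories overdamped monotone approaches
(tested against the closed-form damped-oscillator solution to 0.1%).

Streaming: `v_s(z) = 2αI(z)ω₀²/(σc)` with α = α₀f², α₀ = 2.2×10⁻³
dB·cm⁻¹·MHz⁻² for water (≈63 Np/m at 50 MHz); drag `F_d = 3πσv_sω₀` along
+z.  The driving intensity I(z) is the **measured** on-axis profile of the
synthesized beam (rendered along the tilted beam axis), injected into
`StreamingModel` as a callable: the fitted Gaussian's axial law
overestimates the real beam's downstream intensity by an order of
magnitude (the real beam spreads with the aperture cone and interferes
with its three neighbours), which would let the drag spuriously erase the
trap.  With the measured profile the restoring interval persists under
streaming and is strictly shortened (270 → 210 µm for 240 µm spheres).
Release-and-capture trajectories follow radiation force + viscous drag;
the streaming drag defines the release point (the far edge of the
integrated-force restoring region) and is available as an option in the
equation of motion.  Radial streaming, gravity and buoyancy are not
modelled.

## Fixtures

Unit tests run against analytic objects with closed-form truth: a sampled
Gaussian beam (known half-power width and peak), a single square piston
element with a 10×-denser quadrature oracle for the on-axis pressure, and
a linear restoring-force profile whose damped relaxation is analytic.
These fixtures exercise the measurement and integration machinery, not the
multi-focus diffraction physics; the full pipeline is separately exercised
end-to-end in the acceptance tests.

## Known limitations

- The per-focus Gaussian beam model is a strong idealization of the real
  f/1 synthesized beam: it under-represents the beam's far-field divergence
  and ignores inter-beam interference downstream of the focal plane.
  Axial trapping positions and the lateral forces evaluated at them are
  the quantities most sensitive to this choice.
- The half-power-width ↔ 1/e²-waist conflation (kept deliberately) biases
  the Rayleigh range used for wavefront curvature.
- R and T are single-interface fluid coefficients; absorption inside the
  particle, mode conversion and non-spherical shapes are out of scope.
- The streaming closure is a single-length-scale Eckart balance, not a
  Navier–Stokes solution; only its sign/composition properties are relied
  upon.
- The plane-piston source-power formula neglects mutual radiation
  impedance (elements are ~0.7λ), so total-power normalization carries a
  systematic uncertainty of order 10%.
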