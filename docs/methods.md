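# Methods

## Kinetic model

The photocycle is modeled as a linear three-compartment system over the
normalized concentrations x = ([FADox], [FADH°], [FADH⁻]), dx/dt = A·x with

    A = [ -k1    k1b    k2b ]
        [  k1  -(k2+k1b)  0 ]
        [  0     k2    -k2b ]

All four rates are first-order (s⁻¹) and non-negative; columns of A sum to
zero, so total flavin is conserved exactly.  Assumptions inherited from the
model: photoreduction is single-step at the redox-state level (no excited
states or electron-transfer intermediates), blue light does not drive
FADH° → FADH⁻ appreciably (k₂ is attributed to green light), reoxidation is
pseudo-first-order (oxygen in excess), and temperature/pH enter only through
the values of the rates.

### Integration

`simulate_photocycle` uses classical fixed-step 4th-order Runge–Kutta
(default step 0.01 s, configurable).  For a linear system the RK4 update is
exactly the degree-4 Taylor polynomial of exp(hA), so n steps are applied
as a binary matrix power — identical to sequential stepping up to
floating-point reassociation, but O(log n), which keeps root-finding over
1800-s forward solves fast.  Against the matrix exponential the worst-case
error over all rate combinations in [10⁻⁴, 10⁻¹] s⁻¹ and times up to 2000 s
is below 10⁻⁶ (asserted in the tests); conservation holds to ~10⁻¹³.
Concentrations are never clipped inside the integrator so that conservation
checks stay meaningful; clipping happens only when noisy measured data are
converted to `StateVector`s.

### Closed forms

With k₂ = k₂b = 0 and dark initial condition the radical follows
[FADH°](t) = k₁/(k₁+k₁b)·(1 − e^{−(k₁+k₁b)t}); in darkness (k₁ = k₂ = 0)
[FADH°](t_d) = c₀·e^{−k₁b t_d} with the complementary FADox recovery; the
half-life of any first-order decay is τ½ = ln 2 / k.  Steady states solve
A·x = 0 with the conservation constraint; degenerate configurations (no
illumination-independent return path from a populated state, or all rates
zero) raise instead of returning an arbitrary vector, because a silently
"chosen" steady state usually means a misconfigured experiment.

## Spectra

Within 400–570 nm only FADox (blue band, 450 nm) and FADH° (blue + green,
560 nm) absorb; FADH⁻ is spectrally silent there and is always computed by
conservation, never from absorbance.  The radical's extinction is taken as
ε_H(450) = ε_H(560) = ε_ox(450)/2 (the "half rule", enforced by default in
`ExtinctionSet`); with absorbances normalized to the dark 450-nm value this
collapses Beer–Lambert to

    [FADox] = A(450) − A(560)      [FADH°] = 2·A(560).

Band values are read by nearest-neighbor lookup within ±2 nm.  Extinction
coefficients are stored in mol⁻¹ m² (1 M⁻¹cm⁻¹ = 0.1 mol⁻¹m²) and accepted/
emitted in M⁻¹cm⁻¹ at I/O boundaries; measured values used throughout are
ε_ox(450) = 6415.5 M⁻¹cm⁻¹ (cry1) and 5094 M⁻¹cm⁻¹ (cry2).

Physicality guard: derived concentrations may stray outside [0, 1] by a
tolerance (default 0.02) before being clamped and renormalized; larger
violations raise, naming the offending spectrum.  The default suits
low-noise data; analyses of noisier spectra should widen it (the pipeline
functions expose `physicality_tol`; the 1%-noise recovery studies use 0.1),
since the derived [FADH⁻] = 1 − A(450) − A(560) carries ~1.5× the
single-band noise and a hard 0.02 limit would reject perfectly usable
series.

## Estimation

**Dark reoxidation.** `fit_reoxidation` fits the exponential closed forms
by Levenberg–Marquardt (lmfit), initialized with the first observation for
the amplitude and a log-linear regression of the decaying part for the
rate; R² is reported with the centered total sum of squares, and constant
series return k₁b = 0 with a warning rather than failing.

**Rate inversion.** Both inversion algorithms exploit monotonicity: the
predicted [FADH°] is strictly increasing in k₁ (two-state) and strictly
decreasing in k₂ (three-state), so the observed concentration has a unique
preimage found by a doubling bracket plus Brent's method (absolute
tolerance 10⁻¹⁴ s⁻¹ — a bracketing method with bisection's guarantee).
k₁ inversion evaluates the two-state closed form (and reduces to
k₁ = −ln(1−[FADH°])/t when k₁b = 0); k₂ inversion evaluates full ODE
forward solves, with k₁b = k₂b = 0 selectable as the short-illumination
reduced mode.  An observation above the k₂ = 0 ceiling is inconsistent with
green-light depletion and raises; in the noisy pipelines, points *marginally*
above the ceiling are censored to k₂ = 0 instead, because rejecting a whole
series over one noise excursion would discard usable data.
Neglecting reoxidation is only self-consistent if k₁ is also re-derived
under the reduced model; the package's sensitivity test does exactly that
and finds the two analyses agree within 2% at 20-s illuminations (carrying
a full-model k₁ into a reduced inversion instead shifts σ₂ by ~25%, since
the two k₂ = 0 baselines differ by order k₁b·t).

**Cross sections and yields.** k = σ·I has no intercept (no light, no
photoreduction), so σ = ΣIk/ΣI² with R² against the uncentered total sum
of squares (a centered R² is ill-defined without an intercept); a single
nonzero-fluence point is permitted with R² undefined.  φ = σ/(2.3ε), with
the µmol→mol unit bridge (×10⁶) applied in exactly this one place; φ > 1
warns (signal amplification or a wrong ε).  Where both FADox-based and
FADH°-based estimates exist, `average_condition_summary` reports both and
their arithmetic mean as one summary-table row.

## In vivo mapping

Readouts (hypocotyl length, cry2 protein level) are converted to [FADH°]
by the affine, order-reversing map H(I) = (dark − readout)/(dark − sat),
clamped to [0, 1] — the minimal realization of "biological activity is
inversely proportional to the readout".  The anchors are configurable;
when omitted they default to the observed extremes, which pins the lowest
readout to H = 1 exactly.  That default is therefore unusable in
steady-state mode (H = 1 needs infinite k₁ and raises); calibrated anchors
outside the observed range should be supplied whenever the true saturation
level is known.

Two exposure modes: `steady_state` (growth assays, days of illumination —
H = k₁/(k₁+k₁b), inverted in closed form, and the analogous three-state
closed form for k₂) and `finite_t` (the 30-min degradation assay, default
1800 s — finite-time inversion).  Light-independent in vivo rates default
to literature flavin-lifetime values: k₁b = 0.0023 s⁻¹ (cry1),
7.2×10⁻⁴ s⁻¹ (cry2), k₂b = 0.011 s⁻¹, all overridable.

## Synthetic data

The generators emulate the four experiment archetypes — photoreduce/dark
recovery, blue dose series, blue+green dose series, in vivo dose–response —
from the same kinetic model the estimators invert, with ground truth
recorded in a sidecar.

*Basis spectra* are smooth stand-ins, not literature flavin spectra: the
oxidized band is a tail-subtracted Gaussian (width 30 nm) that is exactly
zero at 560 nm, and the radical band is a Gaussian centered at 505 nm,
hence exactly equal at 450 and 560 nm and scaled to ε_ox(450)/2.  Only the
constraints the two-band inversion uses are enforced; line shapes,
vibronic structure and baseline drift are not emulated.

*Noise.* Instrument noise is additive i.i.d. Gaussian on absorbance
(`noise_sd`, in units of the normalized dark A(450); 0.01 ≈ 0.005 AU raw on
a 0.51-AU dark peak).  Because the band-to-concentration map is linear,
noise propagates exactly: doubling `noise_sd` doubles the residual sd of
derived concentrations (asserted in the tests).  Biological readouts carry
multiplicative Gaussian noise (`readout_noise_frac`, a CV — the usual error
model for length and densitometry measurements), recorded in the stderr
column.  Fixed seeds give bit-identical outputs.

*Default designs.* 20-s illuminations; blue fluences (25, 50, 100, 200,
400) µmol m⁻²s⁻¹ — the linear range for a cry2-pH-7.5-like σ₁, where
k₁·t ≤ 1.3 and single-point inversion stays well-conditioned (saturating
fluences like 4×10³ are appropriate only for order-of-magnitude-smaller σ₁,
and are used that way in the acceptance script's pH-8.2 condition); green
fluences 0–1000 µmol m⁻²s⁻¹ under 100 µmol m⁻²s⁻¹ blue; dark recovery
sampled at 12 points over 3.5 half-lives; reoxidation experiments
illuminate at 200 µmol m⁻²s⁻¹.  In vivo: cry1 hypocotyl series use 10
fluence rates over 0.1–100 µmol m⁻²s⁻¹ (a standard three-decade
dose–response design, sized so that the steady-state inversion keeps the
top-fluence H near 0.5 where it is well-conditioned); cry2 degradation
series use 0.1–10 µmol m⁻²s⁻¹ at 30 min.

*What passing recovery tests shows — and does not.*  The generators share
the model's idealizations, so exact noiseless recovery demonstrates the
inverse machinery, not the model's adequacy for real spectra; effects the
generator omits (baseline drift, scattering, pigment shielding in tissue,
photon shot noise, signal amplification in downstream biology) are exactly
the effects recovery tests cannot probe.

*Measured recovery at the default designs* (medians over 100 seeds,
computed by the test suite): at 1% absorbance noise, k₁b ≈ 4% and σ₁ ≈ 3.4%
relative error; σ₂ ≈ 30% — intrinsically so, because the green sweep
depletes [FADH°] by only ~0.03 while each [FADH°] = 2A(560) point carries
sd 0.02, and no design within the stated fluence range changes that; σ₂
recovery to ~7% needs absorbance noise at the 0.25% level.  In vivo at 5%
readout CV: φ₁ (cry1, steady-state) ≈ 7%; φ₂ (green co-illumination)
≈ 17%.

## Numerical choices and edge cases

- Integrator step 0.01 s default; output times not commensurate with the
  step are finished with one shortened step.
- Bracketed root-finding caps the bracket at 10⁹ s⁻¹ and reports an
  inversion error beyond it (observation unattainable at any credible rate).
- `two_state_concentrations` uses expm1 to stay accurate for small k·t;
  k₁ = k₁b = 0 returns the dark state without forming 0/0.
- Rate round trips are exact to 10⁻⁸ relative for k ∈ [10⁻⁴, 1] s⁻¹ at
  k·t ≲ 5; near-complete conversion (k·t ≳ 20) is limited by float
  representation of 1 − [FADH°], not by the solver.
- CSV round trips are bit-exact (`%.17g` writing, round-trip float parsing).
- Duplicate acquisition times in one file get suffixed column names; the
  YAML sidecar is authoritative for per-column metadata.

## Known limitations

- The affine readout map is an assumption, not a measurement; in vivo
  results are only as good as the dark/saturated anchors.
- No uncertainty quantification beyond R² and Monte-Carlo recovery studies
  (no bootstrap or profile confidence intervals).
- Single-wavelength band lookup discards the rest of the spectrum; no
  multicomponent unmixing, baseline or scatter correction.
- The generic three-state engine can represent other photocycle variants
  (different resting/signaling states), but no dedicated configurations for
  them are provided.
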