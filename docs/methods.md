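# Methods

## Model and assumptions

`rdsearch` fits complex-minus-free CPMG dispersion difference profiles
ΔR₂(ν_CPMG) to a pseudo-three-state exchange model: fast two-site
exchange between free protein (F) and protein–DNA complex (C), plus slow
two-site exchange between the B-form-bound and Z-form-bound complex
sub-states (C_B ↔ C_Z). The two processes are treated as independent and
additive, each in its closed-form limit:

* fast limit: ΔR₂ = R₂₀ + (P_F P_C Δω_FC²/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)];
* slow limit: + k_ZB·[1 − sinc(Δω_BZ/4ν)], sinc(x) = sin(x)/x.

No general Bloch–McConnell / Carver–Richards treatment is attempted: the
model is valid only where the fast process is genuinely fast
(k_ex ≫ Δω_FC) and the slow process genuinely slow (k_ZB ≪ Δω_BZ), which
is the regime the closed forms describe. The additive slow term is
non-negative and bounded by 1.21723·k_ZB (the global maximum of 1 −
sinc), and both terms vanish as ν → ∞, so R₂₀ is the high-ν plateau of
the difference profile.

### Angular convention

The literature for this system reports Δω in Hz; whether those values
enter the formulas directly or as 2π·Hz is a convention choice that
rescales every recovered shift by 2π without changing the fit quality.
`AngularConvention` makes the choice explicit: the default `hz_direct`
plugs Hz values straight in, which reproduces the magnitudes of the
published parameters for this system (with 2π·Hz, a 396 Hz shift at the
observed dispersion amplitudes would imply unphysically large
amplitudes); `radians` is available for users whose shift tables follow
the textbook convention. The active mode is recorded in every
provenance block. Recovery tests are convention-invariant because
generation and fitting share the forward model.

### Populations

P_F and P_C are fixed configuration inputs (defaults 0.95 / 0.05 for
synthetic work), never fitted: from dispersion data alone only the
product P_F·P_C·Δω² is identifiable, so every reported Δω_FC is
conditional on the configured populations.

## Stage 1 — two-state fits and classification

For fixed k_ex the two-state model is linear in the per-field baselines
R₂₀ and in the amplitude A = P_F P_C Δω²/k_ex (with the cross-field
(f/f_ref)² factor built into the design matrix), so both are profiled
out by linear least squares and the fit is one-dimensional in k_ex.
That profile objective is scanned on a 400-point logarithmic grid over
the full k_ex range (1–2000 s⁻¹ by default) and polished by bounded
Brent minimisation between the bracketing grid points. This replaces
multi-start nonlinear least squares: the scan sees the whole 1-D
landscape, so local minima in k_ex cannot be missed at the grid
resolution. A negative profiled amplitude is clamped to zero
(baseline-only fit) and the residue flagged degenerate (flat profile,
k_ex unidentifiable); degenerate residues are excluded from the
shared-k_ex pool of the global fit.

Classification uses the unweighted SSE of the individual fit (residuals
in s⁻¹, no per-point weighting, as the pooled χ² objective implies) with
a strict `SSE > threshold` rule, default threshold 0.7. The cutoff is
data-scale-dependent: it presumes residuals in s⁻¹ on ~28-point
two-field profiles, and should be re-examined for other designs. The
spec leaves open whether the cutoff applies to individual- or global-fit
SSE; the package applies it to the individual fit (configurable via
which fit table is passed to `classify_residues`).

## Stage 2 — GSIR

Per residue, parameter vectors {R₂₀ per field, k_ex, k_ZB, Δω_FC, Δω_BZ}
are drawn uniformly: R₂₀ within ±0.2 s⁻¹ of the residue's two-state
baseline estimate (per field), k_ex in 1–2000 s⁻¹, k_ZB in 1–50 s⁻¹,
both shifts in 1–1500 Hz at the reference field. χ² is evaluated
vectorised over all draws (default 10⁵); the 5 lowest-χ² draws (ties
broken by draw order) are refined by trust-region-reflective least
squares (tolerances 10⁻¹⁰ on χ², cap 5000 function evaluations), and the
refined minimum is reported. Refinement can only improve the reported
minimum: if every refinement fails, the best raw sample is returned and
the result flagged unconverged.

Two deliberate choices:

* **Draw ranges vs refinement bounds.** The ranges above constrain the
  random draws only. Refinement runs inside wide physical bounds
  (R₂₀ ∈ [−20, 100] s⁻¹, k_ex ≤ 5000 s⁻¹, k_ZB ≤ 200 s⁻¹, shifts ≤ 3000
  Hz). Two reasons: the two-state baseline estimate of an oscillatory
  residue is biased by more than 0.2 s⁻¹ (the unmodelled slow term leaks
  into R₂₀), and legitimate shift minima can sit above 1500 Hz — clamping
  the polish to the draw box would silently distort both.
* **Cross-field constraints.** In multi-field mode a single {k_ex, k_ZB}
  pair is shared across fields by construction and shifts at field j are
  the reference value times j/ref (Hz shifts are proportional to the
  static field). R₂₀ is per-field: baseline offsets depend on the
  spectrometer. Single-field mode exists to demonstrate the resulting
  cross-field inconsistency, not for production use.

The "bootstrap" uncertainty (`gsir_bootstrap`) repeats the whole
sampling + refinement over B independent seeds (default 20) and reports
the spread of refined minima. This is an interpretation of a loosely
specified resampling procedure: it quantifies search variability, not
measurement error propagation.

## Stage 3 — GSTR

One shared {k_ex, k_ZB} plus per-residue {R₂₀ per field, Δω_FC, Δω_BZ}
minimise the pooled χ². Initial vectors are drawn from truncated
Gaussians: rates centred on the across-residue GSIR mean with sd =
width·σ(GSIR), truncated to the draw ranges; shifts centred on each
residue's own GSIR estimate with sd = 25% of that value ("middle value"
is read as the residue's own point estimate, not the across-residue
median — configurable by constructing `GaussianConstraint`s directly).
Degenerate σ = 0 cases (e.g. noise-free data where all residues agree)
get a floor of 1% of the centre, recorded in the constraint object. The
sweep runs rate widths {0.25, 0.5, 1, 1.5}·σ with a per-width derived
seed, averages the shared rates across converged widths (mean ± sd) and
reports the 1σ run separately; a failed width is excluded and listed in
`failed_widths`. Shift uncertainties are reported as the across-width
sd. No significance test between widths is performed; only the χ²
minima are reported.

The pooled GSTR minimum is necessarily ≥ the sum of per-residue GSIR
minima (shared rates are a constraint), with equality only when the
GSIR rate minima coincide.

## Synthetic data

The generator reproduces the acquisition design of the reference study:
two fields (800, 900 MHz ¹H), 14 ν_CPMG values in 25–1000 Hz
(log-spaced by default — the source gives range and count but not
spacing; an explicit grid can be passed), T_relax = 60 ms, and additive
homoscedastic Gaussian noise on ΔR₂ (the field's tables state no noise
model; an intensity-level option propagates noise through the
constant-time decay instead). Three benchmark bundles are built from
published parameter sets for the hZα(ADAR1)–d(CG)₃ system: per-residue
GSIR rows (11 residues), shared-rate GSTR values (averaged column by
default, k_ex = 844, k_ZB = 9.8 s⁻¹; the 1σ-run variant 858 / 8.7 via
`one_sigma=True`), and the shared two-state rate (832 s⁻¹, 19 residues
with per-residue shifts drawn uniformly in 50–450 Hz). R₂₀ is not
printed in those tables; benchmarks use 2.0 s⁻¹ per residue.

What passing recovery tests on these bundles shows — and does not show:
the search machinery finds the generating parameters of data that
exactly follow the forward model, under the stated noise. Real spectra
add baseline distortions, heteroscedastic intensity errors, off-resonance
and pulse-imperfection effects, and model misspecification (neither
exchange process is exactly in its limit); none of these are emulated,
so recovery here validates the optimisation, not the spectroscopy.

## Numerical choices and problem sizes

* sinc is evaluated via `np.sinc`, which handles the removable
  singularity at 0 exactly.
* Monte-Carlo sizes: GSIR 10⁵ draws per residue by default (the
  default test and acceptance runs use 3–10 × 10⁴, which on these
  benchmarks already bracket the global basin); GSTR 2 × 10⁴ draws per
  width. These complete in seconds per residue on one CPU.
* Seeds: every sampling call takes an explicit seed; derived seeds use
  fixed prime strides and stay below 2³¹. Fixed seeds give bit-identical
  results end to end.
* Ties in candidate extraction are broken by draw order (stable
  argsort).
* Refinement convergence: relative χ² change < 10⁻¹⁰ or the function
  evaluation cap (5000 GSIR / 20000 GSTR).

## Known limitations

* The closed-form limits break down for intermediate exchange; the
  package deliberately does not detect or warn about regime violations.
* The SSE classification cutoff is absolute, so it is sensitive to the
  number of points and the noise scale.
* Single-field GSIR estimates are structurally under-determined (the
  demonstrated 800-vs-900 MHz discrepancy); they are provided for
  comparison only.
* Populations are fixed inputs; mis-specifying P_C rescales all Δω_FC
  by √(P_F·P_C) ratios without changing fit quality.
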