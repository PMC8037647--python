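# rdsearch

Global-minimum search for multi-field CPMG relaxation-dispersion profiles
under a pseudo-three-state conformational-exchange model.

## The problem

Constant-time CPMG relaxation-dispersion (RD) experiments report chemical
exchange on the µs–ms timescale: the effective transverse relaxation rate
R₂,eff depends on the pulsing frequency ν_CPMG in a way set by exchange
rates, populations and chemical-shift differences. For a Z-DNA-binding
protein such as the Zα domain of human ADAR1 bound to d(CG)₃, the bound
DNA additionally interconverts slowly between B-form and Z-form, so the
protein's ¹⁵N amide dispersion profiles carry **two** superimposed
processes: a fast free ↔ complex exchange and a slow B ↔ Z exchange
within the complex. Fitting such multi-state profiles is notoriously
prone to local minima; `rdsearch` implements a hierarchical random-search
strategy that finds the global χ² minimum by exploiting data at two
static magnetic fields.

## The model

All fitting operates on complex-minus-free difference profiles
ΔR₂(ν) = R₂,eff^comp − R₂,eff^free, with R₂,eff = (1/T)·ln(I₀/I) from
constant-time peak decay. The forward model is the sum of two closed-form
limits:

    ΔR₂(ν) = R₂₀ + (P_F·P_C·Δω_FC²/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)]   (fast, F↔C)
             + k_ZB·[1 − sinc(Δω_BZ/4ν)]                                  (slow, C_B↔C_Z)

with sinc(x) = sin(x)/x. Shifts are stored in Hz at a reference field and
scale proportionally with the field; rate constants are field-independent.

The three-stage hierarchy:

1. **Two-state stage** — per-residue and shared-k_ex global fits of the
   fast term alone; residues with SSE > 0.7 are classified three-state.
2. **GSIR** (global search, individual residues) — per-residue uniform
   Monte-Carlo sampling of {R₂₀ per field, k_ex, k_ZB, Δω_FC, Δω_BZ},
   with cross-field constraints (shared rates, field-ratio-scaled
   shifts), followed by bounded least-squares refinement of the best
   candidates.
3. **GSTR** (global search, total residues) — one shared {k_ex, k_ZB} for
   all three-state residues plus per-residue shifts, initialised from
   truncated-Gaussian proposals centred on the GSIR results; the rate
   proposal width is swept over {0.25, 0.5, 1, 1.5}·σ (σ = across-residue
   GSIR sd) with a fixed 25% shift width, and the shared rates are
   reported as the across-width average.

Because the experimental spectra are not publicly deposited, the package
ships a synthetic generator that reproduces the study design (11–19
residues, 800 and 900 MHz, 14 ν_CPMG points in 25–1000 Hz, T = 60 ms)
from the published parameter tables, making parameter recovery the
primary verification surface.

## Worked example

Simulate the 11-residue shared-rate benchmark (true shared k_ex = 844 s⁻¹,
k_ZB = 9.8 s⁻¹) with 0.2 s⁻¹ Gaussian noise, then run the full pipeline:

```
$ rdsearch simulate --which gstr --noise 0.2 --seed 1 --out-dir sim
simulate: wrote 11 residues to sim
$ rdsearch pipeline --profiles sim/profiles.tsv --seed 2 --out-dir run
pipeline: two-state shared kex 864.2 s^-1; 11 three-state residues
pipeline: GSTR averaged kex 860.5 +/- 0.0, kzb 9.80 +/- 0.00 s^-1
$ cat run/rate_summary.tsv
method          kex_s1   kex_sd_s1  kzb_s1  kzb_sd_s1
two_state       864.19
gsir            869.05   214.13     9.94    0.54
gstr_averaged   860.49   0.00       9.80    0.00
gstr_1sigma     860.49              9.80
```

Reading the output: the naive shared two-state fit overestimates k_ex
because the oscillatory slow term is absorbed into the fast term; GSIR
gives per-residue estimates whose spread (±214 s⁻¹) reflects the
shallow per-residue χ² surfaces; the Gaussian-constrained GSTR stage
pools all residues and lands within 2% of the generating rates, with the
four constraint widths agreeing to machine precision (sd ≈ 0) at this
noise level. `run/gstr_residues.tsv` holds the per-residue Δω_FC and
Δω_BZ (Hz, 800 MHz) and `run/gsir.tsv` the per-residue stage-2 minima;
each table has a JSON provenance sidecar with the seeds, bounds and
constraint widths used.

The same flow is available in-library via `rdsearch.cli.run_pipeline`,
and the stages individually (`fit_two_state_global`, `gsir_run`,
`sweep_and_average`, ...).

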