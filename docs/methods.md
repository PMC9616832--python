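# Methods

This note documents the models and numerical choices behind photoxtal: a
pipeline for quantifying a photo-activated minority conformer in a crystal
(difference density, structure-factor extrapolation, occupancy refinement)
and for the linked global analysis of continuous-illumination UV/Vis and
FTIR data with a sequential kinetic scheme.

## The crystallographic model

A cryo-trapped crystal mid-photocycle is modelled as a two-state mixture: a
fraction α of unit cells in the light conformation L, the remainder in the
dark conformation D. The observed amplitudes are the coherent mixture

    F_mix(h) = |α·F_L(h) + (1−α)·F_D(h)|,

which is what occupancy refinement assumes for randomly intermixed
conformers. Calculated structure factors use the standard isotropic model

    F(h) = Σ_j occ_j · f_j(s) · exp(−B_j s²/4) · exp(2πi h·x_j),  s = 1/d,

with IT92 form factors. All Fourier work is in P1 with Friedel symmetry
imposed; coordinates are stored fractionally. Two independent paths exist
for F_calc — exact direct summation and FFT gridding (gemmi density
calculator) — and are cross-checked to 0.1% of the rms amplitude.

### Scaling and q-weighting

Light amplitudes are scaled onto dark by least squares over
k·exp(−B·s²/4) on common reflections (isotropic; the residual R is
reported). Differences ΔF = F_L − F_D with σΔF propagated in quadrature are
down-weighted by the resolution-binned q-weight

    w = 1 / (1 + σΔF²/⟨σΔF²⟩ + ΔF²/⟨ΔF²⟩),

bins of ~1000 reflections (minimum 8). This is the widely used heuristic
form; note it does not tend to 1 as noise vanishes (a noise-free difference
of typical size gets w ≈ 1/2), which matters for extrapolation (below).
Difference maps are synthesized from (w·ΔF, φ_D) with dark calculated
phases, F(000) excluded, grid spacing ≤ d_min/3.

Difference-map features carry half the true difference density when dark
phases are used — the classic factor 2. This is verified numerically in the
tests (DED feature at a vacated atom = α·Δρ/2 within a few %), and it is the
origin of the 200 in the population-transfer relation.

### Extrapolation and the population-transfer relation

Extrapolated structure factors amplify the minority signal:

    F_EXT(h) = F_calc,dark(h) + N_EXT · ΔF(h),    (added along φ_D)

Because the amplitude difference carries half the complex difference, the
F_EXT map reaches the pure light state at N_EXT ≈ 2/α; beyond that the dark
state is over-subtracted and negative density builds up at the positions the
light conformer vacated. Hence PT(%) = 200/N_EXT at the build-up onset.

Three numerical choices keep that calibration exact and are deliberate:

* **Signed handling of negative amplitude sums.** When F_calc + N·ΔF < 0 the
  synthesis uses amplitude |sum| with the phase flipped by 180°, which keeps
  the map exactly linear in N_EXT. Truncating at zero (offered as
  `truncate_negative=True`) biases the map toward the dark state and shifts
  the onset late by ~40%.
* **Unweighted differences in extrapolation.** Applying the heuristic
  q-weight inside F_EXT rescales the signal by ⟨w⟩ ≈ 0.5 and the onset
  accordingly; weighting is for map interpretation, not for the extrapolation
  ladder. `weight_mode="raw"`/`"normalized"` remain available.
* **Absolute-scale negative-density integrals.** The scan statistic
  Σ min(ρ, 0) over spheres around the vacated atoms is piecewise-linear in
  N_EXT on the absolute electron-density scale (each voxel contributes
  linearly once it crosses zero). σ-normalizing each map first would divide
  by a σ that itself grows with N and bend the curve. The characteristic
  N_EXT is the node of a two-segment piecewise-linear (hinge) fit over the
  scan grid (default N = 2…40, step 1).

The scan mask defaults to atoms displaced ≥ 2 Å between the conformers with
a 1.2 Å sphere radius: smaller displacements leave light-state density
inside the sphere and delay the apparent onset. A scan is declared signal
free (an explicit error, never a default value) unless the hinge slope is
negative, the build-up at the largest N exceeds three times the analytic
noise-only expectation (map noise sd from σΔF via Parseval, half-normal
mean per voxel), and the hinge improves on a single line by ≥ 1.5× in SSE.

### Occupancy refinement

R(α) = Σ| |F_obs| − k_α·|F_model(α)| | / Σ|F_obs| is minimized on a grid
(default 0…0.6, step 0.01) with the per-α least-squares scale k_α;
F_model is the coherent mixture of the two calculated sets. A seeded 5%
free set (seed 13) provides r_free as cross-validation. On noise-free
synthetic data the work and free minimizers agree to ≤ 0.02 and recovery is
exact to the grid step; at 3% amplitude noise, recovery is within 0.05 for
populations between 15% and 32%.

### Anomalous dispersion

`f_double_prime` queries the Cromer–Liberman tabulation (gemmi). For Cl it
returns 3.95 e⁻ at 2.9 keV and 0.40 e⁻ at 2.8 keV, bracketing the K edge at
2.822 keV; a request within ±2 eV of a sharp jump is flagged in the log and
answered at the requested energy.

## Geometry

Torsions follow the IUPAC right-hand convention in (−180°, 180°]
(`(0,0,0),(1,0,0),(1,1,0),(1,1,1)` → +90°). Distances optionally minimize
over P1 periodic images within ±1 cell — adequate for contact distances far
below the cell edges. Superposition is Kabsch SVD; outlier-rejection cycles
(pairs with residual > 2× current rmsd) are opt-in and reported via the
pair count. The hydrogen-bond census works from heavy atoms: the amide H is
placed anti to the bisector of the C′–N and CA–N bonds and the N–H···O
angle at H must reach the angular cutoff (defaults 3.5 Å, 120°; both
config-exposed, and every census output embeds its criteria). These
defaults recover the i→i+4 ladder of an ideal α-helix built at
(φ, ψ) = (−57°, −47°).

## The kinetic model

The sequential scheme EAS1 → EAS2 → … → EASn with rates k_i = 1/τ_i is
solved by the Bateman closed form; an infinite terminal lifetime makes the
last compartment absorbing, and only then does the tracked mass sum to 1 at
all times. Near-degenerate rates (pairwise within 1e-6 relative) fall back
to the matrix exponential per time point. FTIR acquisition windows are
handled by analytic averaging of each exponential basis term over
[t, t + window] (Gauss–Legendre quadrature in the degenerate branch); the
forward model used in fitting applies the same averaging, so the window is
part of the model, not a correction.

Global fitting is variable projection: the nonlinear search runs over
log-lifetimes only (Levenberg–Marquardt, 3 seeded multistarts with 0.3
log-units of jitter, seed 7 by default), and at each iterate the spectra
are the exact linear least-squares solution per dataset. Linked datasets
share lifetimes; each keeps its own EAS, which are signed (difference
spectra) — no non-negativity is imposed. Residuals are equally weighted per
point across datasets. Lifetime standard errors come from the Gauss–Newton
covariance in log space (delta method).

The saturating trace model is Y(t) = A1(1−e^{−t/t1}) + A2(1−e^{−t/t2}),
the rising form with negative exponents (a literal positive-exponent
reading diverges and cannot describe a saturating photoconversion curve).
Lifetimes are reported ordered. With A1 = 0 the parameters are not
separately identifiable; the tests therefore check collapse in function
space rather than parameter values for that nested case.

`composition_at` reports percentage compositions with the steady-state
compartment excluded by default, since an absorbing sink otherwise
dominates late-time percentages.

Stick spectra (computed vibrational lines) are broadened with Lorentzians
of 4 cm⁻¹ FWHM after scaling frequencies by 0.97, area proportional to
intensity; differences of two broadened sets give bleach/induced patterns.

## Synthetic data: what it emulates, and what it does not

`make_two_state_crystal` builds a P1 cell (20×22×24 Å) holding a 10-atom
planar zig-zag carbon chain (the polyene stand-in) plus randomly placed
C/N/O decoys at ≥ 2 Å separation, default 90 atoms in total so the moved
atoms are a few percent of the scattering — the chromophore-in-protein
regime; with much larger moved fractions the light-dark scale factor
absorbs part of the real mixture amplitude deficit and biases the PT
relation. The light conformer rotates the chain tail about a designated
bond (default 80°), conserving all bond lengths and angles; data extend to
d_min = 1.3 Å (≈10⁴ reflections). Noise is Gaussian on amplitudes with
sd = noise_frac·|F| recorded as σF. Not modelled: solvent, crystal
disorder, light attenuation through crystal depth (α is imposed, not
derived from illumination), Wilson/intensity-level error models.

`make_photo_timeseries` / `make_linked_photo_pair` generate
D = C(τ)·S + ε with the study's lifetimes (13, 38, 162 s, ∞) as defaults,
600 s of illumination, 1 s UV/Vis sampling, FTIR rows averaged over 35 s
windows, per-species Gaussian band spectra (positive absorption bands for
UV/Vis, signed difference-like bands for FTIR) and noise at 1% of the
maximum signal. Baseline drift, wavelength-dependent noise and instrument
response are not modelled. `make_saturating_trace` defaults to the 550 nm
photoconversion parameters (A1=0.02, t1=38 s, A2=0.44, t2=291 s, σ=0.005,
0.5 s sampling).

All generators are deterministic per seed (bit-identical regeneration) and
attach a `SyntheticTruth` record carrying every parameter a recovery test
needs. Passing recovery tests on these generators demonstrates that the
analysis chain is correct and well-calibrated under its own model
assumptions; it does not demonstrate robustness to the systematic errors of
real data (absorption, radiation damage, non-isomorphism, baseline drift).

## Problem sizes

Defaults are desk-scale by design: ~10⁴ reflections per crystal dataset,
~4×10⁴ spectral points per linked pair, maps of ~10⁵ voxels. The complete
synthetic pipeline (both branches) runs in well under a minute on one core.

## Known limitations

* Isotropic scaling only; the anisotropic 6-parameter variant is not
  implemented.
* Occupancy refinement assumes exactly two states; no multi-conformer
  mixtures.
* The q-weight is the heuristic Ren/Šrajer form; the exact Bayesian variant
  with a |ΔF_true|² prior is not implemented.
* H-bond detection is geometric only (no energy model, no protonation).
* The breakpoint estimator assumes a single dominant conformational change;
  several independent changes with different effective populations would
  blur the onset.
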