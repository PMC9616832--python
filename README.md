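# photoxtal

Tools for quantifying photo-activated minority states in protein crystals
and solutions: q-weighted difference electron-density (DED) maps,
structure-factor extrapolation with population-transfer estimation,
two-state occupancy refinement, conformer geometry analysis, and linked
global fitting of continuous-illumination UV/Vis + FTIR time series with a
sequential kinetic scheme.

The motivating use case is photoreceptor crystallography of the kind done
on the Orange Carotenoid Protein: a crystal is illuminated, an intermediate
accumulates at occupancy α ≪ 1, and the questions are *what moved* and
*how much of the crystal moved* — while solution spectroscopy of the same
photocycle asks *how fast* each step proceeds.

## The methods in brief

**Difference maps.** With light and dark amplitudes scaled together
(k·e^{−Bs²/4} least squares), differences ΔF = F_L − F_D are down-weighted
per reflection by the q-weight

    w = 1 / (1 + σΔF²/⟨σΔF²⟩ + ΔF²/⟨ΔF²⟩)   (resolution-binned means)

and synthesized with phases from the calculated dark model. Features in
this map carry half the true difference density (the dark-phase factor 2).

**Extrapolation and population transfer.** Extrapolated structure factors
F_EXT = F_calc,dark + N_EXT·ΔF amplify the minority state; the map reaches
the pure light state at N_EXT ≈ 2/α, and pushing further over-subtracts the
dark state. The onset of negative density around the vacated atom
positions, found by a two-segment piecewise-linear fit over an N_EXT scan,
therefore measures the population transfer PT(%) = 200/N_EXT.

**Occupancy refinement.** R(α) between observed amplitudes and the coherent
two-state mixture |α·F_L + (1−α)·F_D| is minimized on an α grid with a
held-out free set for cross-validation.

**Kinetics.** The sequential scheme EAS1 → EAS2 → … → EASn (Bateman
closed-form concentrations, absorbing terminal compartment allowed) is fit
to one or more spectral matrices by variable projection: lifetimes are
shared across linked datasets (e.g. UV/Vis + FTIR), spectra are solved
linearly at each step, FTIR acquisition windows are handled by analytic
time-averaging. A saturating double-exponential fit covers single-channel
photoconversion traces, and Lorentzian broadening of computed stick spectra
(0.97 frequency scaling, 4 cm⁻¹ FWHM) supports comparison with calculated
IR frequencies.

Synthetic-data generators for all of these (two-state toy crystals with a
torsion flip, photo-kinetic matrices, saturating traces) ship as first-class
code with ground-truth records, so every stage has parameter-recovery tests.

## Worked example

Simulate a two-state crystal with a 25% light population and 3% amplitude
noise, then run the full crystal pipeline:

```
$ photoxtal simulate-crystal --seed 11 --alpha 0.25 --noise-frac 0.03 --out-dir sim
$ photoxtal run-crystal --config crystal.yaml     # paths + mask from sim/truth.json
{
  "scale": {
    "k": 1.0083034329939917,
    "b": 0.056132090514769604,
    "residual": 0.05535629366398837
  },
  "n_ded_peaks_3sigma": 28,
  "n_ext_char": 8.0,
  "pt_percent": 25.0,
  "alpha_hat": 0.25,
  "alpha_hat_free": 0.25,
  "dark_light_rmsd": 0.5059259627301713,
  "rmsd_pairs": 90
}
```

Reading this output: the light data sit on the dark scale (k ≈ 1.008) with
a 5.5% post-scaling residual (the 3% noise on both sets plus the real
difference signal); the σ-normalized DED map shows 28 peaks beyond ±3σ
where the chain tail flipped; negative density in the extrapolated maps
starts building at N_EXT = 8, i.e. a population transfer of 200/8 = 25%;
and R-factor occupancy refinement independently returns α̂ = 0.25 on both
the work and free sets — both estimators recover the simulated 25%
population exactly. The 0.51 Å dark/light RMSD over all 90 atoms is the
size of the conformational change being detected.

The solution side runs the same way from spectra CSVs
(`photoxtal run-solution --config solution.yaml`), reporting fitted
lifetimes, rates, per-dataset EAS and composition percentages; on the
default synthetic linked pair it recovers the generating lifetimes
(13, 38, 162 s, ∞) within a few percent, e.g. a second-compartment rate of
0.0263 s⁻¹. Single-channel inputs are routed to the double-exponential
trace fit. Every run writes a JSON manifest (inputs, parameters, package
version, seed) next to its outputs; reruns are byte-identical.

## Layout

- `photoxtal.structio` — domain types (cells, models, reflections, maps,
  spectra) and PDB/mmCIF, MTZ/CSV, CCP4 IO (via gemmi/pandas)
- `photoxtal.diffmap` — structure factors, scaling, q-weights, map
  synthesis and quantification, f″ lookup
- `photoxtal.extrapolation` — F_EXT, N_EXT scans, occupancy refinement
- `photoxtal.geometry` — torsions, distances, Kabsch RMSD, H-bond census,
  B-factor statistics
- `photoxtal.spectrokinetics` — Bateman solutions, variable-projection
  global fitting, trace fits, stick-spectrum broadening
- `photoxtal.synthetic_data` — ground-truth-labelled generators
- `photoxtal.cli` — `photoxtal` command-line interface and the two
  pipeline drivers

See `docs/methods.md` for the models, assumptions, numerical choices and
their rationale.
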