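# parbslide

Simulation and analysis of ParB sliding-clamp dynamics on DNA, for
single-molecule biophysicists studying bacterial chromosome segregation.

The bacterial partition protein ParB binds 16 bp palindromic *parS*
centromere sites. Binding of CTP converts the *parS*-bound dimer into a
topologically closed sliding clamp that escapes the site and diffuses
one-dimensionally along non-specific DNA — the mechanism behind ParB
"spreading" over kilobases around *parS* and, at low forces, ParB-mediated
DNA condensation. `parbslide` implements this three-step model as a
stochastic simulator and couples it to the analysis stages used on the
instrument data:

* **Substrate maps** — coordinate maps (bp) of the multi-*parS* constructs
  used in dual-trap, magnetic-tweezers and tethered-particle experiments,
  including EcoRI roadblock sites and head-to-head tandem (double-length)
  tethers.
* **Clamp simulator** — fixed-timestep Brownian dynamics: loading only at
  vacant *parS* sites, CTP-gated conversion to a diffusing clamp
  (Gaussian steps of variance 2·D·dt), reflecting roadblocks and DNA ends,
  unbinding and photobleaching as exponential clocks.
* **Confocal rendering** — kymographs and 2D scans with a Gaussian PSF
  (FWHM 250 nm), 100 nm pixels, 0.1 ms pixel dwell and Poisson shot noise.
* **Kymograph analysis** — sub-pixel peak detection, nearest-neighbour
  track linking, time-averaged MSD, and the linear fit
  `MSD = 2·D·t + offset` whose half-slope is the diffusion constant;
  per-trajectory estimates are pooled into an ensemble mean ± SEM.
* **TPM analysis** — full-trace RMS bead excursions
  `RMS = sqrt(mean[(x−x̄)² + (y−ȳ)²])` and the drift-suppressed windowed
  variant `RMS_τ` (window-local means, τ = 8.3 s), with a sustained-drop
  condensation detector and a correlated-noise bead-trace generator.
* **MT / WLC mechanics** — Marko–Siggia worm-like chain
  `F = (kBT/Lp)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]`, force–extension fitting of
  (Lp, Lc), the ±15 % contour-length quality filter, equipartition force
  calibration `F = kBT·L/⟨x²⟩`, and condensation metrics for extension
  time courses at sub-piconewton hold forces.

## Worked example

```python
import parbslide as pb

m = pb.build_substrate("39x_parS")
print(f"{m.name}: {m.length} bp, {len(m.parS_sites)} parS sites, "
      f"contour {m.contour_length_nm/1000:.2f} um")
print("inter-cluster gap:",
      pb.feature_distance(m, "cluster1_end", "cluster2_start"), "bp")

result = pb.diffusion_recovery_experiment(d_true=0.4, min_tracks=300, seed=7)
print(f"recovered D = {result['D_mean']:.3f} +/- {result['D_sem']:.3f} um^2/s "
      f"(n={result['n_tracks']} tracks, ground truth 0.4)")
print(f"in sequence units: {pb.diffusion_um2_to_bp2(result['D_mean']):.3g} bp^2/s")

drifted = pb.simulate_bead_trace(tether_bp=1717, drift_velocity=2.0, seed=11)
series = pb.rms_windowed(drifted, tau=8.3)
print(f"TPM bead, 1717 bp tether: full-trace RMS {pb.rms_full(drifted):.0f} nm, "
      f"drift-suppressed mean RMS_tau {pb.mean_rms_tau(series):.0f} nm")

fit = pb.fit_wlc(pb.generate_fec(persistence_nm=50.0, contour_um=2.0,
                                 noise_fraction=0.02, seed=4))
print(f"WLC fit: Lp = {fit.persistence_nm:.1f} nm, Lc = {fit.contour_um:.2f} um, "
      f"accepted = {pb.filter_contour(fit, 2.0)}")
```

Output:

```
39x_parS: 18497 bp, 39 parS sites, contour 6.29 um
inter-cluster gap: 1905.0 bp
recovered D = 0.393 +/- 0.015 um^2/s (n=301 tracks, ground truth 0.4)
in sequence units: 3.4e+06 bp^2/s
TPM bead, 1717 bp tether: full-trace RMS 316 nm, drift-suppressed mean RMS_tau 187 nm
WLC fit: Lp = 50.3 nm, Lc = 2.00 um, accepted = True
```

Reading the numbers: the 39× *parS* substrate reproduces the printed
1905 bp gap between its two site clusters. The recovery experiment pushes
a known diffusion constant through the whole chain — simulate clamps,
render kymographs, track, fit MSDs — and the ensemble mean returns it
within its standard error. For the tethered bead, a 2 nm/s stage drift
inflates the naive full-trace RMS (316 nm) far above the true excursion
amplitude, while the windowed RMS_τ (187 nm ≈ √2 × 139.5 nm per-axis σ)
is immune to it. The worm-like chain fit recovers persistence and contour
length from a noisy force–extension table and passes the ±15 % contour
filter.

## Command line

A thin CLI mirrors the library stages:

```sh
parbslide render --substrate 39x_parS --condition CTP --duration 10 --seed 1 --out kymo.txt
parbslide track kymo.txt --threshold 5 --out tracks.tsv
parbslide msd tracks.tsv --out estimates.json
parbslide tpm trace.tsv --tau 8.3 --out tpm.json
parbslide wlc fit fec.tsv --expected-contour 2.0 --out fit.json
parbslide run config.yaml          # full ctrap / mt / tpm archetype
```

Kymographs and scans are written as ASCII count matrices or 16-bit TIFF;
trajectories, bead traces and force–extension tables as TSV; results as
JSON; substrate maps as BED-like text or GFF3.

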