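# Methods

## The model

`parbslide` simulates ParB–DNA dynamics as a three-step sliding-clamp
mechanism on a one-dimensional lattice of base-pair coordinates:

1. **Loading.** A ParB dimer binds a vacant 16 bp *parS* palindrome as an
   immobile open clamp. Loading is a Poisson process per vacant site
   (`load_rate`); each site holds at most one resident dimer.
2. **Conversion.** CTP binding closes the clamp, which escapes *parS* and
   becomes a freely sliding ring (`convert_rate`). Conversion requires a
   functional CTP pocket and Mg²⁺: the apo, CDP and EDTA conditions and
   the R80A variant set `convert_rate = 0`. The R149G variant cannot bind
   *parS* at all (`load_rate = 0`). CTP and the non-hydrolysable analogue
   CTPγS are mapped to identical rates, since clamp closure needs CTP
   binding, not hydrolysis; an optional `unload_rate` (default 0) models
   hydrolysis-driven unloading under CTP only.
3. **Sliding and loss.** A closed clamp performs unbiased 1D diffusion
   with constant `D` along the DNA contour, is reflected by bound
   roadblock footprints (catalytically dead EcoRI) and — in the default
   bead-tethered geometry — by the DNA ends, may unbind from non-specific
   DNA (`unbind_rate`), and photobleaches (`bleach_rate`) once the
   illumination starts.

Assumptions: clamps are point particles without mutual exclusion on
non-specific DNA (observed densities are sparse, so crowding is
negligible); parS-bound dimers are perfectly immobile; no ParB–ParB
bridging energetics are modelled — condensation is treated
phenomenologically in the tether-mechanics stage.

## Integration scheme

Fixed-timestep dynamics with step `dt`. Sliding steps are Gaussian with
variance 2·D·dt, which is the exact free-diffusion transition density;
reflection is implemented by folding the proposed coordinate into the
current segment, the exact propagator of reflected Brownian motion, so
the spatial scheme carries no dt-discretisation error of its own. State
transitions fire with probability 1 − exp(−rate·dt), the exact
exponential-clock probability; the only dt-dependence is the quantisation
of transition times to the grid, and halving dt leaves the clamp position
distribution statistically unchanged (tested by a two-sample KS check).
A validity guard rejects dt for which the rms step exceeds 5 % of the
substrate contour length. All randomness flows from a single
`numpy.random.default_rng(seed)`; identical (config, substrate) inputs
reproduce bit-identical trajectory sets.

## Parameters

| parameter | default | units | status |
|---|---|---|---|
| `D` (clamp diffusion) | 0.4 | µm²/s | matches the measured sliding constant |
| `load_rate` per vacant site | 0.2 | 1/s | free parameter, order-of-magnitude choice |
| `convert_rate` | 0.5 | 1/s | free parameter |
| `unbind_rate` from nsDNA | 0.02 | 1/s | free parameter (clamp lifetime ≫ imaging) |
| `parS_unbind_rate` | 0.01 | 1/s | free parameter; gives a stable *parS* signal over tens of seconds while keeping a steady state |
| `bleach_rate` | 0.1 | 1/s | free parameter; dye visible for tens of seconds, bleaching faster than protein turnover |
| rise per bp | 0.34 | nm | B-form DNA |
| *parS* footprint | 16 | bp | palindrome length |

No absolute loading/unbinding/bleaching rates were ever measured for this
system; the defaults above are the package's own choices, documented here
so users treat them as dials of the emulation, not as measurements. They
were chosen so that (i) *parS* sites saturate within a two-minute dark
incubation, (ii) clamps accumulate on non-specific DNA only under
CTP/CTPγS, and (iii) fluorescence decays over tens of seconds under
illumination.

### Substrate geometry

Constructs are 0-based, half-open bp interval maps. All printed
inter-feature distances are enforced exactly: the 39× *parS* substrate
carries 39 sites in six groups forming two clusters (13 + 26 sites)
separated by 1905 bp; the roadblock construct places one 5× EcoRI group
3613 bp downstream of the last *parS*, with outer segments of ≈1.3 and
≈5 kbp that bound roadblocks protect from spreading. Distances that were
never printed are package constants: 50 bp start-to-start spacing of
*parS* repeats within a group, 200 bp between groups inside a cluster, a
60 bp merged footprint per 5× EcoRI group (the bound-protein extent, not
per-site detail, is what reflects clamps), and a 500 bp gap from the
upstream EcoRI group to the first *parS*. The λ-DNA control is 48502 bp
with no sites. Tandem tethers are head-to-head doubles: the mirror image
of the map appended at the junction, doubling every site count.

### Optics

Kymographs are repeated single-line scans; 2D scans add a transverse
Gaussian of the same σ. Defaults: 100 nm pixels, 0.1 ms pixel dwell,
250 nm PSF FWHM, 25 ms line period, 5×10⁵ photons/s per emitter and
10⁴ background counts/s/pixel — photon rates are free parameters chosen
to give single-emitter peaks of ~20 counts over a ~1 count background,
the regime of the real scans; no excitation-power calibration is
attempted. The PSF is truncated at ±4σ (<0.01 % mass). Emitter positions
are frozen at the start of each line: the line period (tens of ms) is
~250× the pixel dwell, so intra-line motion blur is negligible. Expected
counts are Poisson-sampled; bleached and detached emitters contribute
nothing.

## Kymograph analysis

Peaks are local maxima above a count threshold, refined by three-point
parabolic interpolation (clamped to ±0.5 px); peaks closer than a merge
radius keep the brighter member. Linking is greedy nearest-neighbour
between consecutive lines with a maximum jump and no gap closing; tracks
shorter than a minimum length are dropped. The threshold, merge radius,
jump and length are exposed configuration (defaults: 5 counts, 3 px,
0.5 µm/line, 10 lines) since the original tracker's settings are not
recorded anywhere.

MSD is the time-averaged, overlapping-pair estimator on tracks clipped
to their first 2.5 s (a fixed analysis window that makes every track
contribute a comparable sample), with lags up to 25 % of the clipped
length. The diffusion fit is ordinary least squares of MSD on lag time
over lag indices 2–10: half the slope is D, the intercept absorbs static
localization noise. Lag 1 is excluded because localization noise loads
most heavily there; the window is configurable. Per-track estimates —
including negative ones, whose removal would bias the mean upward — are
pooled into an arithmetic mean ± SEM. A track is classified
"immobile/parS-bound" when its fitted D < 0.05 µm²/s *and* its mean
position lies within a *parS* window ± 250 nm (one resolution element);
`trim_parS_dwell` removes the leading immobile residence of a track so
diffusion is measured on non-specific DNA only, mirroring how the
instrument trajectories were measured outside *parS*.

### The parameter-recovery experiment

`diffusion_recovery_experiment` validates the whole chain — simulate →
render → track → trim → MSD → fit — against a known ground truth. Its
ensemble uses tandem double-length tethers (≈12.6 µm contour),
sparse labelling (`load_rate` 0.02/s per site, emulating the low duty
cycle of quantum-dot-labelled protein so concurrent emitters rarely
cross), a linking radius scaled to ~4.5 per-line step standard deviations
at the ground-truth D so large steps are not censored, a 2 px merge
radius, and absorbing DNA ends: free ends remove the reflection-induced
MSD suppression that bead-occluded ends impose on tracks dwelling near
them, so the estimator is validated against unconfined diffusion. With
300-track ensembles the recovered mean sits within a few per cent of
ground truth across 0.1–1.0 µm²/s; a residual negative bias of order
5 % remains at the highest diffusivity (residual confinement within the
finite molecule plus occasional tracker merges when paths cross), with a
per-ensemble scatter of 2–4 % (SEM). Problem sizes — 300–450 tracks from
a few hundred to a couple of thousand simulated molecules, 3 s
simulations at dt = 5 ms — are the package's default validation scale.

### Intensity profiles

Profiles average a 500 nm transverse band along the DNA axis; the
background estimate is the median of pixels ≥ 3σ off the axis (2D scans)
or the median line-wise minimum (kymographs). Region quantification
subtracts that background; fold-enhancement is the ratio of region values
between conditions. Bleaching curves are fitted by least squares to a
single exponential with a floor.

## Tethered-particle motion

The full-trace estimator `RMS = sqrt(mean[(x−x̄)²+(y−ȳ)²])` uses global
means and is inflated by slow drift. The windowed estimator computes the
same quantity with window-local means in a sliding boxcar of span τ
(stride one sample) and averages the series over the recording. τ must
exceed the bead–tether correlation time; the guard enforces the ~8 s
calibration floor of this geometry (override possible, with a warning),
and the working value is 8.3 s. Note one estimator subtlety: for a
correlated trace, a finite window underestimates the variance by
≈ 2·t_corr/τ (≈12 % in variance, 6 % in RMS at the default 0.5 s
correlation time), so windowed and full-trace RMS agree closely only for
nearly-white traces; drift-suppression comparisons are therefore made
against a drift-free twin (same seed), for which the bias cancels
exactly.

The bead-trace generator is phenomenological: each axis is a stationary
exponentially-correlated Gaussian (AR(1)) process, default correlation
time 0.5 s, sampled at 120 Hz for 300 s. The amplitude defaults to the
Gaussian-chain estimate σ = sqrt(2·Lp·Lc/3) (139.5 nm per axis for a
1717 bp tether at Lp = 50 nm) — "roughly as expected for the tether
length", not a hydrodynamic bead–tether model. Optional linear drift and
an amplitude step (×`step_factor` at `step_time`) emulate stage drift and
a condensation event. Condensation is declared when RMS_τ falls below
(1 − 0.3) × baseline (median of the first 20 % of the series) for at
least 20 s; both constants are package choices.

## Magnetic tweezers and the worm-like chain

The WLC flavour is the classic Marko–Siggia interpolation without an
enthalpic stretching term — at the ≤5 pN forces of these experiments the
extensible correction is negligible. kBT is computed from the user
temperature (default 298 K, giving 4.114 pN·nm; the experiments' ambient
temperature is not recorded). `wlc_extension` inverts the force relation
by bisection (Brent, relative tolerance 10⁻¹²). Fitting minimises
extension residuals over (Lp, Lc) with `scipy.optimize.least_squares`
from a fixed 3×3 multi-start grid (Lp ∈ {30, 50, 70} nm,
Lc ∈ {0.8, 1.0, 1.2} × max extension), keeping the lowest-cost solution —
deterministic by construction. The ±15 % contour-length filter is
inclusive at the boundary ("±15 %" reads as a tolerance) and numerically
guarded against float rounding exactly at the boundary. Force calibration
uses the inverted-pendulum equipartition relation F = kBT·L/⟨x²⟩ on the
in-plane excursions.

Condensation time courses at a 0.33 pN hold force are summarised by the
condensed fraction (1 − plateau/naked extension, plateau = median of the
last 10 %), the initial rate (− least-squares slope over the first 30 s),
and a verdict requiring a >25 % extension deficit sustained for ≥30 s.
The maximum condensation force of a protein force–extension curve is the
largest sampled force whose measured extension falls ≥25 % short of the
naked-DNA WLC prediction. These thresholds are package constants — the
experiments report condensation qualitatively — and no mechanistic
clamp-density → bridging model is attempted: the condensing-trace
generator is an exponential extension decay with configurable rate and
plateau, and the pipeline's "does condition X condense" logic is a rule
(loading and conversion active, and ≥5 *parS* sites under tension in the
magnetic tweezers, any *parS* at zero force in TPM) matching the observed
pattern across conditions and substrates.

## Pipeline and reproducibility

`run_pipeline` executes one of three archetypes (`ctrap`, `mt`, `tpm`)
from a single YAML config with per-stage parameter blocks; every default
the user did not set is logged. All randomness derives from one root
seed via `numpy.random.SeedSequence` child streams, so a config
reproduces its whole result bundle bit-for-bit; every summary quantity is
recomputable from the persisted intermediates (ASCII/TIFF images, TSV
tables, JSON sidecars).

## What the synthetic data does and does not capture

The generators emulate: *parS*-restricted loading, CTP gating, 1D sliding
at realistic D, roadblock reflection, diffraction-limited imaging with
shot noise and bleaching, WLC tether mechanics, and drifting correlated
bead traces. They do not emulate: ParB–ParB networking and the resulting
*parS*-proximal enrichment beyond simple site occupancy (so measured
fold-enhancements at *parS* are lower than on the instrument),
nucleotide-exchange kinetics, bead hydrodynamics, camera/scanner
artefacts, or force-dependent clamp behaviour. Passing tests therefore
demonstrate correctness of the analysis chain and internal consistency
of the model — not that the free-parameter defaults quantitatively match
any particular instrument record.

## Known limitations

* The recovery ensemble shows a residual ≲5 % downward bias at
  D = 1 µm²/s (confinement within the finite molecule and rare tracker
  identity merges); the validation band is ±10 %.
* Greedy linking has no gap closing or split/merge topology; crossing
  emitters can swap identities.
* Intra-group *parS* spacing and exact EcoRI coordinates are package
  defaults, not measured values; only printed distances are exact.
* The MT condensation stage is phenomenological end to end; it tests the
  detection and quantification logic, not condensation physics.
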