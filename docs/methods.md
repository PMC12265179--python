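# Methods

This note documents the physical models, numerical choices and known limits
of the package. It is written for a reader who wants to judge what the
simulations and quantifications do — and do not — establish.

## 1. Materials and composition algebra

A material is a set of (element, atomic fraction) pairs plus a mass density;
number densities follow from ρ·N_A/⟨A⟩. The default Epon-Araldite
stoichiometry is H 0.52, C 0.39, O 0.085, N 0.005 at ρ = 1.25 g/cm³ — a
typical published epoxy-resin composition, fully overridable through the
YAML material config (`materials.load_materials`), since embedding recipes
vary. Stained material substitutes 3 at.% Pb proportionally from all resin
elements (the substitution basis for the stain is not constrained by
anything we model, and at 3 at.% the choice is second order).

Gallium implantation supports two modes. `replace_carbon` swaps part of the
C fraction for Ga and leaves every other fraction untouched — the assumption
used for the simulated images. `additive` dilutes all resin fractions by
(1−g). At 50 at.% Ga the carbon budget of the H-inclusive stoichiometry
(39 at.%) cannot supply the whole implant, so the `epon_ga50` preset and the
50 % phantoms use the additive mode; at 25 at.% the replace-carbon mode is
used. The density of implanted (and stained) material follows
inverse-mass-fraction mixing of the base material with elemental Ga
(5.91 g/cm³) — i.e. ideal volume additivity. Constant-volume substitution
would give a still higher density; published measurements of FIB-hardened
polymer skins sit lower (~2–3 g/cm³). Density is therefore exposed as
config; its influence is discussed in §6.

The at.%-Ga conversion is 100·r/(1+r) for a Ga:C ratio r, exact internally;
display rounding is applied only when printing. The optimal-implant design
rule is the geometric mean √(Z_organic·Z_stain); with Z_organic = 7 and
Z_stain = 82 it gives ≈ 24, rationalising why Ga (Z = 31) works so well.

## 2. Electron physics

The keV engine uses the screened-relativistic Rutherford total cross
section

σ(Z,E) = 5.21×10⁻⁷ · Z²/E² · 4π/(α(1+α)) · ((E+511)/(E+1024))²  [nm², E keV]

with screening α = 3.4×10⁻³ Z^0.67/E, scattering angles sampled by the
analytic CDF inversion cosθ = 1 − 2αu/(1+α−u), and the Joy–Luo modified
Bethe stopping power with J(Z) = (9.76 Z + 58.5 Z^−0.19)×10⁻³ keV, valid to
the 50 eV tracking floor. This is the single-scattering /
continuous-slowing-down model family of the established keV Monte Carlo
codes for SEM imaging; there are no discrete inelastic events, no secondary
cascade, and no X-ray physics. Mott-type partial-wave corrections would
shift absolute backscatter yields by tens of percent at these energies but
preserve the contrast orderings and depth trends the analysis rests on.

## 3. The Monte Carlo transport engine

Specimens are voxel grids (half-open boxes, z ≥ 0 into the block, vacuum
above z = 0). Free-flight lengths are sampled from the exponential with the
local inverse mean free path; flights are truncated at voxel boundaries and
resampled (exact, by memorylessness). Energy decreases along each segment at
the stopping power evaluated at segment-start energy; with segments at most
a few nm the second-order error is negligible and per-trajectory energy
book-keeping closes to < 10⁻⁹ keV (tested). Azimuths are uniform; the
scattering element within a voxel is chosen ∝ nᵢσᵢ(E). Electrons end as
backscattered (exit through z = 0), transmitted (bottom), escaped-side, or
absorbed (below 50 eV). The ESB filter accepts backscattered electrons with
exit energy ≥ the grid voltage (700 eV default; the alternative reading of
the instrument setting, an 800 eV floor at 1.5 keV, is one config value
away). No detector solid-angle restriction is applied — the in-lens
geometry collects the upward hemisphere.

Physics tables (inverse mean free path, stopping power, element-selection
probabilities) are precomputed per material on a 256-point log energy grid
and interpolated; transport is vectorised over electrons.

Two performance choices matter for reproducibility semantics:

* **Per-pixel streams (default for images).** Each pixel owns a random
  stream spawned from the user seed, so a pixel's value is independent of
  which other pixels were simulated (tested) and images are bit-reproducible.
* **Batched transport (layer-count and vesicle experiments).** All electrons
  of all pixels advance in one vectorised pass under a single spawned
  stream; results are deterministic for a fixed seed and pixel set. In
  batched imaging runs electrons are additionally abandoned once their
  energy falls below the ESB grid voltage: such electrons can never be
  accepted, so filter-accepted statistics are unaffected (tested), while the
  sub-threshold random walk is skipped.

Bulk yield sanity points at 1.5 keV with the 700 eV floor: plain resin
≈ 0.053, 25 at.% Ga ≈ 0.30, 50 at.% Ga ≈ 0.33, stained (3 at.% Pb) resin
≈ 0.32.

## 4. Phantoms and imaging experiments

The depth-step phantom holds five 30×30 nm², 5-nm-thick squares of stained
resin at depths 0–5 … 20–25 nm, with lateral voxels of 3 nm and z-voxels of
2.5 nm (so the 5-nm interval boundaries are exactly representable). The
phantom's margins (75 nm) and depth extent (60 nm) are set by an energy-loss
bound: an electron that can still clear the 700 eV exit filter at 1.5 keV
has less than ~70 nm of total path available, so no detectable trajectory
can reach the grid edges; measured extrema (accepted max depth ≈ 31 nm,
accepted path ≤ 66 nm) confirm the bound. Ga implantation is applied
uniformly over the phantom (the implanted layer spans the whole BSE
information depth); a layered profile is available for sensitivity work.

A stain square is *visible* when its relative contrast
(feature−background)/background is ≥ c₀ = 0.02 **and** its feature-averaged
SNR — (feature mean − background mean)/(background pixel SD/√N_feature) —
is ≥ s₀ = 5 (Rose criterion). The published readout was a visual judgement
of rendered images; this is the declared operationalisation. The defaults
were fixed once against the no-implant condition (which must show all five
layers) and then held for every Ga condition; both knobs are parameters, and
`apply_criterion` re-scores stored statistics across the documented range
c₀ ∈ [0.01, 0.05] without re-simulating. The counting protocol simulates
every pixel of each square footprint (100 pixels each) plus 200
background-band pixels at 3000 trajectories/pixel, rather than a full
frame — the statistics of the readout are identical and the cost drops by
~20×. The layer count maps to a z-resolution interval
[5·(count−1), 5·count] nm.

The vesicle phantom is a 40-nm sphere with a 5-nm stained shell (3 at.% Pb),
centre 35 nm deep (top of the shell 15 nm below the face). Ablation is
modelled by dropping top voxel layers. The contrast experiment compares the
projected-footprint pixels against a background ring at twice the vesicle
radius.

## 5. HAADF jump-ratio quantification

Profiles are extracted from images by band-averaging perpendicular to a
line, or read from two-column tables. The estimator takes the plateau as the
mean of the interior-most 25 % of samples, the peak as the raw profile
maximum, the onset width as the 10→90 % rise distance, and the decay length
from an exponential fit of the above-plateau excess toward the interior. A
3-sample moving-mean peak variant is available, but for a ~6-nm-wide peak
sampled at 2 nm it underestimates the peak by ≈ 5 %, far larger than the
sub-percent Poisson bias of the raw maximum at realistic (≥10⁴ count)
plateaus, so the raw maximum is the default. The onset-width and
decay-length numbers are convention-bound estimators (the 10→90 rise of the
absolute signal resolves ≈ 0.8 of the generator's smoothstep width); they
are meant for comparing profiles, not as unbiased shape parameters.
Profiles whose interior plateau has relative SD > 20 % are rejected as
unquantifiable.

The inversion solves the linear thin-section model of §"README" for the
implanted dose g. Hydrogen is excluded from both sums (the annular detector
is insensitive to it; its cross section is ~3 % of carbon's in this model).
The mass-loss scenario "50 % C loss, total O loss" treats the trace N
(0.5 at.%) like C; the choice is numerically negligible.

**Calibration.** The effective cross sections come from the screened
Rutherford differential form integrated analytically over the detector
annulus (default 38–200 mrad at 300 keV). The actual detector angles and
the tabulated cross sections behind the published estimates are not
available, so the screening exponent is the model's single free knob: it is
fixed once so that the no-loss inversion of the block-face jump ratio 3.9
returns Ga:C = 0.38, giving exponent 1.2196 and σ_Ga/σ_C ≈ 10.5. After
that one-time calibration every other inversion is a prediction.

**Limit of agreement.** The linear model makes the no-loss Ga:C exactly
proportional to (ℛ−1). The two published no-loss data points do not share a
slope: 0.38/2.9 = 0.131 against 0.185/1.26 = 0.147 per unit (ℛ−1) — a ~12 %
internal tension that no choice of cross sections or composition can close
within this model class. Calibrated on the block-face point, the package
therefore predicts Ga:C ≈ 0.165 (not 0.185) for the section edge at
ℛ = 2.26, and ≈ 0.92 (not 0.86) for the 50 %-C-loss block-face scenario.
These deviations are reported as-is; the corresponding checks in the test
suite are expected to fail at their ±5 % tolerance and document the
discrepancy rather than absorb it into a second knob.

## 6. BSE imaging results and their sensitivity

At the study conditions (1.5 keV, 700 eV floor, 3000 trajectories/pixel,
fixed criterion) the package reproduces 5 visible layers without Ga
(z-resolution 20–25 nm) and 2 layers at 50 at.% Ga (5–10 nm), with
monotonically non-increasing counts across the documented criterion range.
At 25 at.% Ga it finds 2 visible layers where the published readout saw 3:
the 10–15 nm layer lands at ≈ 1 % contrast and SNR ≈ 4, just under every
admissible criterion setting. The gap traces to the implanted-layer density:
with volume-additive mixing the 25 % replace-carbon layer reaches
3.6 g/cm³, which compresses the information depth (90th-percentile depth of
origin ≈ 9 nm) slightly below what the third layer needs. A lighter layer
(~2.5 g/cm³, within the plausible range for FIB-hardened epoxy) stretches
the information depth by the few nm required. The density stays at its
declared default rather than being tuned to the published count; the
sensitivity is the finding.

## 7. EELS quantification

Backgrounds are fit as A·E^−r on log-log axes by weighted least squares
(weights √counts, matching the Poisson variance of log counts) over 50-eV
pre-edge windows ending 10 eV below each onset; edges are integrated over
100 eV past the onset after subtracting the extrapolated background. Edge
onsets default to C K 284 eV, O K 532 eV, Ga L₂,₃ 1115 eV (the published
measurement window starts at 1140 eV; the onset is config). Uncertainties
propagate window counting statistics plus the background-extrapolation
variance estimated from fit residuals; no systematic terms.

σ(Ga L₂,₃) is never taken from a shell model — L-shell hydrogenic models
are unreliable — but calibrated from a Ga₂O₃ reference spectrum via
σ_Ga/σ_O = (I_Ga/I_O)·(N_O/N_Ga) with N_Ga/N_O = 2/3. The O K/C K bridge is
a hydrogenic K-shell generalised-oscillator-strength model integrated over
the collection aperture (10 mrad) and the 100 eV window at 300 keV, giving
σ_OK/σ_CK = 0.271 at the default conditions (cross-checked against an
independent adaptive quadrature of the same GOS). Quantifying the reference
against its own k-factor returns N_Ga/N_O = 2/3 exactly — an algebraic
identity used as a regression test.

## 8. Synthetic data: what it does and does not emulate

The generators produce (i) voxel phantoms; (ii) block-face HAADF profiles —
zero in vacuum, plateau·[1+(ℛ−1)g(x)] in the block, with g a cubic
smoothstep rise over the onset width times an exponential decay, and Poisson
noise; (iii) EELS spectra — power-law background plus sawtooth edges
(step × E^−3 tail), normalised so the windowed channel-sum integral equals
the requested edge integral exactly, with Poisson noise. Default EELS counts
(C K integral 4×10⁵ over a ~1.2×10⁴ counts/channel background) are chosen so
the region-to-region scatter of the quantified Ga:C matches the scale of the
published 10-region spread (±0.012); the HAADF plateau default is 10⁴
counts.

Every generator is seeded and deterministic, and emits its ground truth as a
JSON sidecar. What passing the round-trip tests shows is that the estimators
are unbiased and correctly scaled *for data following these models*; real
spectra have plural scattering and fine structure, real profiles have
diffusion tails of unknown form (the exponential is a declared stand-in),
and real images have detector noise beyond trajectory statistics. None of
those are modelled.

## 9. Interfaces

The library modules are the programmatic interface; the numbered scripts
under `analysis/` are thin drivers that run each stage and write its tables
under `results/`. Cross-section tables export to CSV, images to 32-bit TIFF
with JSON provenance sidecars, phantoms to HDF5, profiles and spectra to
two-column CSV. There are no console entry points; the scripts fill that
role for an analysis of this shape.

## 10. Known limitations

* Screened Rutherford (not Mott/ELSEPA) elastic scattering; absolute yields
  are approximate, orderings robust.
* No charging, no ion-transport simulation of the implantation profile
  itself (the Ga layer is an input composition), no radiation-damage or
  mechanical modelling.
* The HAADF model is ratio-only (no absolute thickness/composition), with
  one calibrated knob absorbing the unknown detector geometry; §5 describes
  the residual internal tension of the published numbers under this model.
* The implanted-layer density rule is the dominant systematic for the
  25 at.% imaging condition (§6).
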