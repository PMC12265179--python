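# fibsemga

**Why FIB-SEM sees so sharply in depth: Monte Carlo imaging and composition
analysis of the gallium-implanted block face.**

Focused-ion-beam scanning electron microscopy (FIB-SEM) produces
near-isotropic ~5–10 nm 3-D reconstructions of stained, resin-embedded cells
— far better depth resolution than Monte Carlo modelling of a 1.5 keV
backscattered-electron (BSE) probe in plain epoxy predicts (~25 nm), and at
electron fluences that collapse the same blocks in knife-based
serial-block-face imaging. The resolution is explained by the Ga⁺ milling
beam itself: it implants a thin (~20 nm) surface layer holding tens of
atomic-percent gallium, which raises the mean atomic number of the matrix,
compresses the depth from which detectable BSEs originate, hardens the
surface, and carries away charge.

This package re-implements the computational side of that argument for
microscopists and image-analysis researchers:

* an event-by-event **Monte Carlo BSE simulator** (screened-Rutherford
  elastic scattering, Joy–Luo continuous slowing-down, voxelized phantoms,
  energy-selective backscatter (ESB) grid filtering) that reproduces the
  visible-layer z-resolution readout and the buried-vesicle contrast
  reversal;
* the **HAADF-STEM jump-ratio inversion**: a thin-section Z-contrast signal
  model with annulus-integrated elastic cross sections that converts the
  peak/plateau ratio ℛ of a block-face line profile into a Ga:C atomic
  ratio under explicit mass-loss scenarios;
* the **EELS core-loss quantification**: power-law background subtraction,
  100 eV edge windows, Ga₂O₃ reference calibration of σ(Ga L₂,₃), and a
  hydrogenic K-shell σ(O K)/σ(C K) bridge;
* **synthetic-data generators** (voxel phantoms, block-face HAADF profiles,
  EELS spectra) with known ground truth, so the whole pipeline is testable
  without any downloads.

## The models in brief

Electron transport samples free flights $s = -\lambda\ln(1-u)$ with
$\lambda^{-1} = \sum_i n_i\,\sigma_i(Z_i,E)$, deflects by the analytic
inverse CDF $\cos\theta = 1 - 2\alpha u/(1+\alpha-u)$ of the screened
Rutherford cross section ($\alpha = 3.4\times10^{-3}Z^{0.67}/E$), and loses
energy continuously at the Joy–Luo rate
$\mathrm{d}E/\mathrm{d}s \propto (\rho/E)\sum_i c_i (Z_i/A_i)\ln\!\big(1.166(E+0.85J_i)/J_i\big)$.
A BSE is counted when an electron re-exits the entrance face with at least
the ESB grid voltage (700 V) of kinetic energy.

The HAADF signal of a thin section is modelled as
$I \propto \sum_i N_i \sigma_i$ (hydrogen excluded), so the jump ratio of
the implanted layer over intact resin,

$$\mathcal{R} = \frac{\sum_i \mathrm{ret}_i f_i \sigma_i + g\,\sigma_{\mathrm{Ga}}}{\sum_i f_i \sigma_i},$$

is linear in the implanted Ga dose $g$ and inverts exactly;
Ga:C $= g/(\mathrm{ret}_C f_C)$. EELS atomic ratios follow
$N_{\mathrm{Ga}}/N_C = (I_{\mathrm{Ga}}/I_C)\,\sigma_C/\sigma_{\mathrm{Ga}}$
with $\sigma_{\mathrm{Ga}}$ tied to a Ga₂O₃ reference standard.

## Worked example

```python
from fibsemga import materials as M, haadf_quant as hq
from fibsemga.electron_physics import HAADFCrossSectionModel, calibrate_screening_exponent

model = HAADFCrossSectionModel(screening_exponent=calibrate_screening_exponent())
resin = M.preset("epon_araldite")
for R, scenario in [(3.9, M.NO_LOSS), (3.9, M.C50_O100), (2.26, M.NO_LOSS)]:
    est = hq.invert_jump_ratio(R, resin, scenario, model)
    print(f"R={R}: Ga:C = {est.ga_c_ratio:.3f} -> {est.at_percent_ga:.1f} at.% Ga ({est.scenario})")
```

prints

```
R=3.9: Ga:C = 0.380 -> 27.5 at.% Ga (no-loss)
R=3.9: Ga:C = 0.925 -> 48.0 at.% Ga (c50-o100)
R=2.26: Ga:C = 0.165 -> 14.2 at.% Ga (no-loss)
```

i.e. the block-face jump ratio of 3.9 corresponds to ~28 at.% Ga if the
resin stays intact, and close to 50 at.% if half the carbon and all the
oxygen were ablated — the range that motivates the 25 % and 50 % implant
conditions of the imaging simulations. Those simulations are driven by the
numbered scripts:

```bash
python analysis/01_composition_conversions.py   # at.% table + optimal-implant-Z rule
python analysis/02_calibrate_haadf_model.py     # annulus cross sections
python analysis/03_quantify_haadf_profiles.py   # jump ratios -> Ga content
python analysis/04_quantify_eels.py             # EELS Ga:C over 10 regions
python analysis/05_depth_response.py            # BSE depth-of-origin vs implant
python analysis/06_visible_layers.py            # visible-layer counts (z-resolution)
python analysis/07_vesicle_stack.py             # buried-vesicle contrast reversal
```

`06` reports, at 3000 trajectories/pixel (a few minutes on one core): 5
visible stain layers without Ga (z-resolution 20–25 nm) falling to 2 layers
at 50 at.% Ga (5–10 nm), with every layer's contrast and Rose-criterion SNR;
`05` shows the mechanism — the 90th-percentile depth of origin of detected
BSEs drops from ~20 nm in plain resin to ~7 nm at 50 at.% Ga.

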