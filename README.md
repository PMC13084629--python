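# vcdtmm

A rigorous 4×4 transfer-matrix simulator for mid-infrared absorbance and
vibrational circular dichroism (VCD) of homogeneous, isotropic chiral layers.

The model treats each layer as a Pasteur medium with scalar, dispersive
permittivity ε(ν̅), permeability μ(ν̅) (default 1) and chirality parameter
κ(ν̅). The two circular-polarization eigenmodes propagate with refractive
indices n± = √(εμ) ± κ; interfaces couple them at oblique incidence, which the
4×4 block transfer matrix captures exactly. On top of the core solver the
package provides:

- **materials** — multi-oscillator Lorentzian dispersion models for ε and κ,
  tabulated-dispersion files, and the packaged eight-band `ideal_absorber`
  preset (equidistant, equal-amplitude absorption bands; κ₀ = 10⁻⁵);
- **tmm** — interface/propagation/total 4×4 transfer matrices, generalized
  Snell refraction with evanescent-branch handling, extraction of the 2×2
  circular-basis transmission and reflection operators, helicity-resolved
  transmittances;
- **spectra** — decadic absorbance, VCD = −log₁₀(T₋/T₊) (plus the ΔT/T̄
  alternative), slant-path Beer–Lambert baselines, and angular–spectral maps
  decomposing the VCD signal into thin-film-interference and
  helicity-coupling artifacts;
- **aperture** — incoherent plane-wave averaging over illumination/collection
  numerical-aperture cones (average transmittances first, then take the log);
- **io / cli** — YAML/JSON configs, CSV readers/writers, and a `vcdtmm`
  command-line tool.

Conventions: wavenumbers in cm⁻¹, thicknesses in μm (converted to cm
internally), angles in degrees at all user surfaces, time dependence
e^(−iωt) so passive media have Im ε ≥ 0 and Im n ≥ 0. A caveat worth
knowing: helicity transmittances and reflectances use bare squared amplitude
moduli without cos θ flux projection, so energy bookkeeping across dissimilar
half-spaces is approximate (it is exact for identical ambient/exit media).

## CLI

```sh
# helicity-resolved spectrum of a 1 um ideal-absorber film at normal incidence
vcdtmm simulate --thickness-um 1 --out spectrum.csv

# angular-spectral artifact decomposition map (9 angles x 200-4500 cm^-1)
vcdtmm map --thickness-um 10 --n-theta 9 --theta-max 80 --out map.csv

# NA-averaged spectra for focused illumination/collection
vcdtmm aperture --na-in 0.7 --na-out 0.3 --thickness-um 25 --out na.csv

# dump eps, kappa and n_+/- tables of the packaged preset
vcdtmm material --preset ideal_absorber --out material.csv
```

Every subcommand also accepts `--config config.yaml`:

```yaml
materials:
  film:
    preset: ideal_absorber    # or oscillators:/dispersion_file:/constants:
stack:
  ambient: vacuum
  layers:
    - material: film
      thickness_um: 25.0
  exit: vacuum
illumination:
  theta_deg: [0, 50, 80]      # or aperture: {na_in: 0.7, na_out: 0.3, n_angles: 64}
grid: {start: 200, stop: 4500, step: 1}
```

## Scripts

- `python scripts/acceptance.py --seed 1 --out results/acceptance.json` —
  writes the machine-readable acceptance report (currently an empty target
  set; the quantitative checks live in `tests/test_acceptance.py`).
- `scripts/plot_absorbance_vs_thickness.py`, `scripts/plot_vcd_vs_thickness.py`,
  `scripts/plot_vcd_model_comparison.py`, `scripts/plot_deviation_maps.py` —
  figure reproductions from the packaged preset (write PNGs under `scratch/`
  by default; `--out`/`--step` to customize).

## Library example

```python
import numpy as np
from vcdtmm import ideal_absorber, single_layer_stack, compute_spectrum

nu = np.arange(200.0, 4500.0, 1.0)
film = single_layer_stack(ideal_absorber(), thickness_um=25.0)
spec = compute_spectrum(film, nu, theta_deg=50.0)
print(spec.vcd[np.searchsorted(nu, 1500.0)])
```
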