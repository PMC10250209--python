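# tightropekit

Quantitative analysis of single-molecule **DNA tightrope** experiments and
their companion gel assays, built for studies of how a DNA-damage sensor
(UV-DDB) relieves product inhibition of the glycosylase SMUG1 by displacing
it from abasic sites — and, more generally, for any protein-on-DNA
facilitated-dissociation study that produces the same kinds of data:

* **Residence times / CRTD.** The cumulative residence time distribution,
  S(t) = P(T ≥ t), of dwell times of fluorescently labeled proteins on DNA
  is fit to a single exponential S(t) = e^(−kt) to give the binding
  half-life t½ = ln 2 / k. Movies end after 300 s, so particles that outlive
  the movie are right-censored; the default CRTD uses product-limit
  (Kaplan–Meier) at-risk accounting, and a naive censored-dropping mode is
  provided to demonstrate its bias.
* **Motion analysis / MSD.** For motile phases of a trajectory the
  time-averaged mean squared displacement
  MSD(nΔt) = 1/(N−n) Σᵢ (x₍ᵢ₊ₙ₎ − xᵢ)² is fit two ways: linearly,
  MSD = 2D(nΔt) + y, for the 1D diffusion coefficient D (fits with
  R² < 0.8 or using < 10 % of the MSD plot are flagged rejected); and
  log–log for the anomalous exponent α (MSD ∝ t^α).
* **Tight-binding isotherms.** Electrophoretic mobility shift data taken at
  8 nM DNA — the same order as the Kd — are fit with the quadratic
  ligand-depletion isotherm
  `% bound = 100 · ((D+P+K_d) − √((D+P+K_d)² − 4DP)) / (2D)`,
  with DNA fixed and the plateau constrained to 100 %, leaving the apparent
  Kd as the single free parameter.
* **Excision kinetics.** Denaturing-gel band tables are converted to percent
  product, fit to A(1 − e^(−k_obs·t)), and summarized as fold stimulation
  (endpoint or initial-rate basis) and its concentration dependence.
* **Kymograph tracking and co-localization.** Per-column centroid or
  Gaussian localization of particles in kymographs, stationary/motile phase
  segmentation, and greedy nearest-neighbor pairing of two-color detections
  on lesion-array DNA (one abasic site every 2 kb).

A fully seeded synthetic-data module generates every input the pipeline
consumes (exponential dwell times with censoring, fractional-Brownian-motion
trajectories with localization noise, rendered kymographs, isotherms, and
excision time courses), so the whole analysis chain can be validated against
known ground truth.

## Worked example

```python
import numpy as np
import tightropekit as tk

# Residence times at the two measured dissociation rates
dwells_alone = tk.simulate_dwell_times(1.400e-4, 1000, window=np.inf, seed=1)
dwells_comp  = tk.simulate_dwell_times(1.195e-3, 1000, window=np.inf, seed=2)
fit_alone = tk.fit_crtd(tk.build_crtd(dwells_alone))
fit_comp  = tk.fit_crtd(tk.build_crtd(dwells_comp))
print(f"half-life alone:       {fit_alone.half_life:7.1f} s")
print(f"half-life +competitor: {fit_comp.half_life:7.1f} s")
print(f"fold: {tk.half_life_fold(fit_alone, fit_comp):.2f}")

# Apparent Kd from a noisy tight-binding isotherm (truth 15 nM, 8 nM DNA)
data = tk.simulate_isotherm(15.0, 8.0, np.geomspace(1, 400, 10),
                            noise_sd=5.0, replicates=3, seed=3)
fit = tk.fit_kd(data)
print(f"Kd = {fit.kd_apparent:.1f} +/- {fit.kd_stderr:.1f} nM")
```

prints

```
half-life alone:        4960.2 s
half-life +competitor:   554.6 s
fold: 8.94
Kd = 15.7 +/- 1.0 nM
```

The two half-lives recover the simulation truths (ln 2 / k = 4950 s and
580 s) within sampling error; their ratio is the ~8–9-fold
facilitated-dissociation effect of adding the competitor. The fitted Kd
lands within one standard error of the 15 nM truth despite 5 % gel noise.

The same operations are exposed on the command line:

```bash
tightropekit simulate dwells --rate 1.4e-4 --n 1000 --seed 1 --out dwells.tsv
tightropekit crtd dwells.tsv --out fit.json
tightropekit run --seed 1 --out demo_out   # full synthetic pipeline
```

## Layout

| module | contents |
|---|---|
| `tightropekit.synthetic` | seeded generators for all input types |
| `tightropekit.binding` | quadratic tight-binding model, Kd fits, fold tables |
| `tightropekit.kymo` | kymograph extraction, phase segmentation |
| `tightropekit.diffusion` | MSD, diffusion-coefficient and α fitting |
| `tightropekit.residence` | CRTD fits, behavior tables, χ², co-localization |
| `tightropekit.excision` | gel quantification, time-course fits, folds |
| `tightropekit.io` | TSV/TIFF/JSON/YAML I/O and the pipeline driver |
| `tightropekit.cli` | `tightropekit` console entry point |

See `docs/methods.md` for the models, estimator choices, defaults and known
limitations.
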