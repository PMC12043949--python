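# nucleomech

Quantitative analysis of how substrate viscoelasticity shapes the cell
nucleus, packaged as a Python library and a `nucleomech` command-line tool.

Cells grown on hydrogels sense not only stiffness but also how fast the
substrate relaxes applied stress. On slow- versus fast-relaxing alginate
gels of matched initial modulus, nuclei differ in volume, chromatin
compaction, lamin-envelope folding ("wrinkling"), histone-mark levels, and
the mobility of tracer proteins and chromatin loci. `nucleomech` implements
the full measurement chain for such experiments:

- **rheology** — fit a two-element Maxwell–Wiechert model to bulk
  stress-relaxation curves, report the time at which stress falls to half
  its initial value (τ½ ≈ 1000 s for a slow-relaxing gel, ≈ 200 s for a
  fast-relaxing one), the initial elastic modulus from the 5–10% strain
  window of a compression ramp, and frequency sweeps normalized by
  G′(1 rad/s).
- **morphometry** — segment nuclei in confocal z-stacks, measure nuclear
  volume as the sum of per-slice cross-section areas times the z-step, and
  a chromatin compaction index (integrated DNA-stain intensity per unit
  volume). 2-D segmentation and per-nucleus mean intensities for
  histone-mark immunostains.
- **wrinkling** — a lamin nuclear-wrinkling index: mean Gaussian-derivative
  edge magnitude inside the eroded nucleoplasm of an intensity-normalized
  lamin image, with a permutation test that checks the index is not a
  disguised readout of nucleus size.
- **frap** — FRAP trace normalization, single-exponential recovery fits,
  and recovery half-times t½ = τᵣ·ln 2.
- **dynamics** — drift and rotation correction of particle tracks (Kabsch
  estimation from nuclear landmarks), time-averaged mean-squared
  displacement, power-law fits MSD(τ) = D·τ^α over the first half of the
  lag range with an R² > 0.8 acceptance gate, and the derived confinement
  time T = (1/D)^(1/α).
- **simkit** — seeded generators for every data type above, each returning
  its ground truth, so the whole chain is testable end to end.
- **workbench** — typed CSV/TIFF I/O with strict schemas, a declarative
  pipeline runner, and the `nucleomech` CLI.

## Worked example

```python
from nucleomech import dynamics, frap, morphometry, rheology, simkit, wrinkling

# --- rheology: a slow-relaxing gel, sigma(t) = 2 exp(-t/1442.695) kPa + 1% noise
curve, _ = simkit.gen_relaxation([1.0], [1442.695], sigma0=2.0,
                                 t_max=4000.0, dt=1.0, noise_sd=0.01, seed=7)
fit = rheology.fit_relaxation(curve)
print(fit.sigma0, fit.tau_half, fit.plateau)
# sigma0 = 2.001 kPa, tau_half = 999.0 s, plateau = 0.0000

# --- FRAP: noisy recovery trace, true tau_r = 14.427 s
trace, _ = simkit.gen_frap_trace(tau_r=14.427, noise_sd=1.8, seed=11)
ffit = frap.fit_recovery(frap.normalize_trace(trace))
# tau_r = 15.00 s, t_half = 10.40 s, mobile fraction = 0.855

# --- morphometry: 5 x 5 x 3 um ellipsoid nucleus, true volume 314.2 um^3
stack, _ = simkit.gen_nucleus_stack((5.0, 5.0, 3.0), noise_sd=2.0, seed=11)
mask = morphometry.segment_stack(stack)
res = morphometry.compaction_index(stack, mask)
# volume = 313.1 um^3, compaction = 33331.5 a.u./um^3

# --- wrinkling: index grows with fold amplitude, flat nuclei sit at the floor
for amp in (0.0, 1.0, 2.0):
    img, _, _ = simkit.gen_lamin_image(fold_amplitude=amp, noise_sd=2.0, seed=7)
    print(wrinkling.wrinkling_index(img).index)
# 0.0014, 0.0063, 0.0111

# --- dynamics: 200 subdiffusive tracks, alpha = 0.5, D = 0.01
tracks, _ = simkit.gen_tracks(200, 20, 120.0, 0.5, 0.01, seed=3)
curves = [dynamics.time_avg_msd(t) for t in tracks]
ens = dynamics.fit_powerlaw(dynamics.ensemble_msd(curves))
# alpha = 0.485, D = 0.0107 um^2/s^alpha, R^2 = 0.9994
```

## Command line

```
$ nucleomech simulate --what relaxation --seed 1 --out demo
wrote demo/relaxation.csv
$ nucleomech rheo --in demo/relaxation.csv --out demo
wrote demo/rheo_fit.json
$ cat demo/rheo_fit.json
{
 "sigma0_kpa": 2.0,
 ...
 "tau_half_s": 999.9999716579302,
 "residual_rmse_kpa": 1.16e-16
}
```

Other subcommands: `nucleus` (volume + compaction from a TIFF stack),
`wrinkle`, `frap`, `msd`, and `run` (a multi-stage pipeline described by a
YAML config; every run writes `config.resolved.yaml` and a `run_log.json`
with the config hash and seed so results are reproducible byte for byte).

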