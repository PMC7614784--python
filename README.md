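# recombikit

Quantitative analysis of RAD51 filament-assembly assays — the measurement
side of studying how the RAD51-paralog complex BCDX2
(RAD51B-RAD51C-RAD51D-XRCC2) stimulates assembly of RAD51 nucleoprotein
filaments on single-stranded DNA. It is aimed at single-molecule and
biochemistry labs who record:

* **kymographs** (fluorescence along one tethered ssDNA molecule over time)
  and need assembly kinetics, apparent nucleation rates, filament
  growth/disassembly rates, binding-event frequencies and FRET event
  structure;
* **negative-stain EM micrographs** of RAD51 filaments and need automated
  curvilinear detection, length measurement and condition comparisons;
* **fluorescence-anisotropy titrations**, whose ssDNA affinities must be
  fitted with the tight-binding quadratic isotherm
  `Y = Amin + (Amax−Amin)·[(x+L+K_D) − √((x+L+K_D)² − 4xL)]/(2L)`
  because probe concentration L and K_D are comparable;
* **HPLC chromatograms and TLC ATPase assays**, quantified into nucleotides
  per complex and percent ATP hydrolysis via standard curves and
  Beer-Lambert arithmetic.

Since raw data of this kind are rarely re-distributable, every analysis
stage ships with a seeded forward simulator (`recombikit.synthgen`) that
emits its ground truth — nucleation event lists, boundary trajectories,
true contour lengths, true K_D — so each estimator is validated end-to-end
by parameter recovery. The scientific background and all modelling choices
are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
from recombikit import synthgen, biochem, kymo

# ssDNA affinity: simulate an anisotropy titration at the ATP-condition
# affinity and fit it back
titr, truth = synthgen.simulate_titration(0.16, nucleotide_condition="ATP", seed=1)
fit = biochem.fit_binding_isotherm(titr)
print(f"K_D = {fit.kd_uM:.3f} uM (95% CI {fit.ci95_kd[0]:.3f}-{fit.ci95_kd[1]:.3f})")

# nucleation kinetics: simulate a kymograph with discrete nucleation sites
# and estimate the apparent nucleation rate from peak-count saturation
params = synthgen.SimKymoParams(
    length_um=120.0, duration_s=200.0, frame_interval_s=2.5,
    k_nuc=0.015, v_grow=0.0, nucleus_footprint_nm=800.0,
    nucleation_site_period_nm=2000.0, seed=1)
km, gt = synthgen.simulate_kymograph(params)
est = kymo.estimate_nucleation_rate(km, "rad51")
print(f"apparent rate k = {est.apparent_rate:.4f} 1/s, "
      f"plateau {est.fit.a_max:.0f} clusters, true events {len(gt.nucleation_events)}")
```

prints

```
K_D = 0.154 uM (95% CI 0.130-0.177)
apparent rate k = 0.0276 1/s, plateau 60 clusters, true events 59
```

The fitted K_D recovers the generating 0.16 μM within its confidence
interval at the benchmark's noise level, and the fitted saturation rate
sits near the generating per-site activation rate (k_nuc × site period =
0.030 s⁻¹) with the plateau matching the 59 simulated nucleation events.

## Command line

Every stage is also exposed as a subcommand with YAML config, explicit
seed, CSV/TIFF outputs and a `summary.json` echoing all thresholds:

```bash
recombikit synth kymo       --config kymo.yaml --seed 3 --out run/
recombikit kymo nucleation  --input run/kymo_rad51.tiff --out analysis/
recombikit nsem detect      --input micrograph.tiff --out filaments/
recombikit biochem fit-kd   --input titration.csv --out fit/
```

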