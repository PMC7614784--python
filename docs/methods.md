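# Methods

`recombikit` reimplements the quantitative procedures used to characterise
how the RAD51-paralog complex BCDX2 (RAD51B-RAD51C-RAD51D-XRCC2) stimulates
RAD51 nucleoprotein-filament assembly on single-stranded DNA: single-molecule
kymograph kinetics, negative-stain EM filament measurement, equilibrium
ssDNA-binding fits, and nucleotide stoichiometry / ATPase quantification.
Because the raw experimental data for such studies are not generally
available in reusable form, every analysis stage is paired with a forward
simulator (`recombikit.synthgen`) that emits its hidden ground truth, and
validation is by parameter recovery.

## Kymograph model and generator

A kymograph is a time x position raster of fluorescence along one tethered
ssDNA molecule (rows = frames, time increasing downward; columns = position,
0-based; default calibration 100 nm/pixel, 5 s/frame, matching typical
confocal scanning conditions for this assay).

The generator implements a nucleation-extension-disassembly process:

- **Nucleation** is a Poisson process with rate density `k_nuc`
  (events·μm⁻¹·s⁻¹) restricted to uncovered substrate. Placement is
  hard-core: a nucleus is born with footprint `nucleus_footprint_nm`
  (default 200 nm, roughly a diffraction-limited early cluster) that must
  fit inside a free gap.
- **Extension**: each cluster's two boundaries advance at `v_grow` (nm/s per
  end); `polarity_bias` splits the total growth between the ends
  (0.5 = symmetric; the filament's known 3'→5' growth polarity can be
  expressed by moving it toward 0 or 1, but no rate asymmetry is quantified,
  so the default is unbiased). Boundaries stop at collisions and substrate
  ends.
- **Disassembly** (separate simulator, emulating transfer into an ATP-free
  channel): pre-formed segments shrink at `k_off` nm/s per end; nucleation
  off.
- **Imaging**: covered pixels emit Poisson photons (`photon_rate` counts per
  pixel per frame, default 40) over a free-fluorophore background
  (`background_rate`, default 5); single-exponential photobleaching is
  optional. The profile is blurred along the position axis with a Gaussian
  PSF (`psf_sigma_px`, default 1) and Gaussian read noise added (default
  sd 2). `shot_noise=False` replaces Poisson draws by their expectation for
  noise-free oracle tests. An optional second channel renders the
  anti-correlated RPA signal (displaced wherever the filament channel is
  covered).

Everything takes an explicit integer seed; identical (parameters, seed) give
bit-identical rasters and ground truth.

### Discrete nucleation-site mode

`nucleation_site_period_nm` switches nucleation from the continuous
hard-core process to regularly spaced independent sites, each activating at
rate `k_nuc x period`. This exists because of a real property of the
peak-count readout: for the continuous excluded-volume process the expected
number of distinct clusters over time follows random-sequential-adsorption
(Rényi) kinetics, which is *not* a single exponential, so the rate constant
obtained by fitting `y = A_max(1 - exp(-k t))` to cluster counts is not
proportional to the generating `k_nuc` (the bias depends on the observation
window). With discrete sites the expected occupied-site count is exactly
`M(1 - exp(-k_nuc p t))` and the fitted rate is proportional to `k_nuc` by
construction. The rate-recovery benchmarks therefore run in site mode
(240 sites of 2 μm on 480 μm of substrate, 800 nm footprints, 200 s at
2.5 s/frame, no growth), which isolates the nucleation readout from
growth/merging confounds. The continuous process remains the default for
every other purpose.

## Kymograph analysis

- **Assembly signal**: per-frame summed channel intensity normalized to the
  per-frame mean of a user-chosen background pixel interval; fitted with
  `y = A_max(1 - exp(-k t))` by least squares (`scipy.optimize.curve_fit`,
  k bounded ≥ 0, Student-t asymptotic 95% CI on k). `half_life_s = ln 2 / k`.
  All-zero input and optimizer failures return `converged=False` with a
  `k = 0` sentinel.
- **Apparent nucleation rate**: each frame's spatial profile is
  Savitzky-Golay smoothed (5-pixel window, quadratic order — the order must
  be below the window and 2 is the common choice); local maxima are counted
  with `scipy.signal.find_peaks` using a minimum separation of 3 px (one
  PSF) and a prominence threshold, and the counts-vs-time curve is fitted
  with the same saturating exponential; the fitted k (s⁻¹) is the apparent
  nucleation rate. `initial_event_rate = A_max·k` additionally reports the
  extrapolated absolute event rate at t = 0.
- **Peak-detection noise scale.** The prominence threshold is
  `prominence_sigmas` times a robust noise estimate taken from
  *frame-to-frame differences* of the smoothed image
  (`1.4826·MAD/√2`). Static structure — covered plateaus and their edges —
  cancels in temporal differences, so the estimate stays correct on a
  filling substrate where the intensity histogram is bimodal and both a
  global MAD and spatial-difference estimators inflate with coverage and
  make detection density-dependent. Against this estimator, pure-noise
  maxima reach ~7x the scale and true cluster peaks ~20-40x at the
  generator's default SNR, so the default `prominence_sigmas = 10` sits in
  the gap; it was calibrated on synthetic blanks and signals (the original
  study's detector settings are not recorded). On noise-free input the
  threshold falls back to 10% of the dynamic range, suppressing the tiny
  shoulder ripples polynomial smoothing leaves at plateau edges.
- **Edge (growth/disassembly) rates**: from a seed (frame, pixel) inside a
  segment, the connected run above `threshold_fraction` (default 0.5) of the
  seed-frame plateau is followed; the chosen side's outermost pixel per
  frame, converted to nm, is regressed linearly on time. The rate is signed
  so outward motion is positive. Losing the segment for more than
  `max_gap_frames` truncates with a warning.
- **Binding events**: 8-connected spatiotemporal components above
  `median + intensity_sigmas x robust SD`, minimum duration filter;
  frequencies are counts of event starts per half-open window (default
  30 s, the early-binding window used for this assay).
- **FRET events**: donor/acceptor traces (extracted from kymographs with a
  3-px window average) are segmented by thresholding the acceptor against
  the measured donor bleed-through plus `step_sigmas` noise SDs (noise from
  first differences), with remaining samples split donor-only vs dark by the
  donor's own floor; a 3-sample running mean suppresses single-sample
  flicker before labelling, so recovered phase boundaries are accurate to
  about one sample. The anticorrelation statistic is the Pearson r of the
  two channels over the non-dark portion; energy transfer makes it negative.
- **Force traces**: downsampled to 3 Hz (the plotting rate for this assay)
  by non-overlapping half-open block means; a trailing partial block is
  dropped, so the output length is `floor(duration x target)` and the mean
  is preserved on exact partitions.

## NS-EM filament measurement

Micrographs (default 5.85 Å/pixel) are band-passed with a
difference-of-Gaussians (defaults σ1 = 2 px, σ2 = 6 px: about one filament
width versus the background scale at this magnification; the study names no
values). The ridge mask is `median + threshold_sigmas x robust SD` (default
3; for noise-free rasters, where MAD is zero, half the dynamic range). The
mask is skeletonized (`skimage.morphology.skeletonize`), split at junction
pixels (more than two skeleton neighbours — crossings are not joined, which
diverges from whatever the original unnamed "curvilinear line analysis" did
and is flagged as such), and each branch of at least `min_length_px = 5`
chain-metric pixels becomes a trace.

**Arc length.** The raw 8-connected chain metric (1 per axial step, √2 per
diagonal) is exact at 0°/45°/90° but overestimates intermediate orientations
by up to ~8% and further inflates on noise-meandering skeletons. Reported
lengths therefore come from the Euclidean arc length of the ordered path
after a 5-point moving average of its coordinates, which cuts staircase
corners while leaving straight paths untouched; the chain metric is kept as
the minimum-length filter. With this estimator, recovery tests on
non-overlapping synthetic filaments reach 100% recall with per-filament
errors within 10%; skeleton end-erosion (~2-3 px per end) dominates the
residual error and makes very short traces (< ~30 px) unreliable.

Condition comparisons follow the study's statistics: per-micrograph counts
by Welch two-tailed t-test, pooled lengths by two-sided Mann-Whitney U —
exact enumeration when both pools have n ≤ 8, tie-corrected normal
approximation otherwise. (At very small n the normal approximation deviates
from exact by far more than 0.01 in p, so the exact path is used there
rather than asserting agreement.)

The generator renders persistence-sampled unit-step random walks (heading
variance 1/persistence_px per step) with Gaussian cross-section, disc-shaped
background particles and Gaussian noise; filaments reaching the border are
clipped with the clipped length recorded. `avoid_overlap=True` redraws
filaments that would touch an existing one (and keeps particles off
filaments), producing the non-overlapping fields used by the recall
benchmarks.

## Equilibrium binding

Anisotropy titrations are fitted with the tight-binding quadratic isotherm

    Y = Amin + (Amax−Amin) · [(x+L+K_D) − √((x+L+K_D)² − 4xL)] / (2L)

with the probe concentration L fixed (default 0.05 μM) — required because
K_D and L are comparable, so free ≈ total protein does not hold. The
discriminant is clamped at zero against roundoff in the stoichiometric
limit. Fits return (K_D, Amin, Amax) with a Jacobian-based Student-t 95% CI
on K_D; monotone-flat data are flagged unconverged. Replicates may be
averaged before fitting or fitted per replicate and summarized afterwards;
the benchmarks fit per replicate and take the median, and coverage of the
CI was checked by simulation (≈94-95% at the benchmark design). The
generator's anisotropy window is a_min = 0.05, a_max = 0.22 — typical
fluorescein-probe values; noise sd 0.005 is the benchmark's measurement
noise; 14 approximately half-log protein concentrations span 0.001-10 μM.

## Nucleotide stoichiometry and ATPase

Chromatogram peaks (260 nm) are integrated per species window after
subtracting a linear baseline drawn between the window endpoints
(trapezoidal rule); concentrations come from standard curves fitted as
lines through the origin (response proportional to amount). Nucleotides per
complex = peak concentration / protein concentration. When the protein
concentration itself comes from A280, the extinction coefficient
(80,220 M⁻¹cm⁻¹ for the complex) must be adjusted by 2,390 M⁻¹cm⁻¹ per
bound nucleotide — which depends on the answer; a two-pass scheme (assume
4 nt, compute, recompute once) resolves the circularity. Generator
retention centres are ADP 6.5 / ATP 9.0 / ATPγS 12.5 min with σ = 0.08 min
(plausible ion-pair RP-HPLC spacing; peaks closer than 4σ raise a
resolution warning) and unit response factors.

TLC ATPase lanes give percent hydrolysis = 100·ADP/(ADP+ATP), invariant to
common rescaling of both spots, and a turnover rate in μM ATP·min⁻¹ per μM
enzyme from the assay constants (15 μM ATP, 1 μM complex, 30 min). The
benchmark's wild-type fraction hydrolysed is 0.4 over the incubation — a
realistic sub-saturating operating point chosen once; only the *relative*
mutant/wild-type activity (0.5) is compared against the study's number, and
that ratio is independent of the operating point.

## What the simulators do and do not emulate

The generators reproduce the statistical structure the analyses rely on —
Poisson nucleation with excluded volume, linear boundary motion, shot +
read camera noise, PSF blur, anti-correlated displacement, log-normal
contour lengths, Gaussian chromatogram peaks with proportional response,
conserved two-spot TLC signal. They do not emulate optical-trap mechanics
(force appears only as a deterministic proxy of coverage), acceptor
photophysics beyond single-exponential bleaching, stain/defocus artefacts
in micrographs, detector nonlinearity, or retention-time drift. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise models, not robustness to every instrumental artefact of
real data.

## Numerical choices and degenerate inputs

- Robust scale = 1.4826 x MAD throughout.
- Coordinates 0-based; intervals half-open; kymograph rows are frames.
- Division-by-zero guards: zero background mean, zero donor intensity and
  both-TLC-spots-zero are errors; all-zero fits return sentinels, not
  exceptions.
- Exponential-fit initialisation: A from the data maximum, k from the first
  nonzero point's secant slope with a 3/t_max fallback.
- Isotherm-fit initialisation: K_D seeded at the half-rise concentration.
- Mann-Whitney exact/asymptotic switch at n = 8 per pool.
- Benchmark problem sizes (240 nucleation sites, 16-20 replicate seeds,
  768² px micrographs, 200-point titration sweeps) were chosen so that the
  recovered medians' sampling error is several times smaller than the
  acceptance tolerances while the whole suite stays desk-scale.

## Known limitations

- Junction splitting biases NS-EM length distributions short in crowded
  fields; compare conditions at matched densities.
- The apparent nucleation rate from peak-count saturation is a
  phenomenological constant; its proportionality to the true event rate
  density holds in the discrete-site benchmark regime but not for arbitrary
  growth/merging regimes (see above).
- Edge-rate tracking follows one connected segment and does not handle
  crossing or merging trajectories.
- The FRET segmentation assumes a single event per trace with monotone
  phase order fret → donor-only → dark; interleaved re-binding events are
  labelled but not paired into kinetic cycles.
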