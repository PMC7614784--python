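"""Forward simulators for every assay modality the analysis stages consume.

Each simulator takes an explicit integer seed (no global RNG state), and
returns its observable together with a :class:`SimGroundTruth` holding the
hidden event list / generating parameters, so every analysis stage can be
validated by parameter recovery.

The kymograph simulator implements a stochastic nucleation-extension-
disassembly process on a 1-D substrate: nucleation is a spatial Poisson
process restricted to uncovered substrate (excluded volume), each nucleus
is born with a finite footprint and extends both boundaries at a constant
speed until collision or the substrate end, and covered pixels emit
Poisson photon counts (with optional single-exponential bleaching) that
are PSF-blurred and read-noise-corrupted. An optional second channel is
the anti-correlated ssDNA-binding-protein (RPA) signal, displaced wherever
the filament channel is covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .biochem import BindingTitration, Chromatogram, TlcAssay, quadratic_binding_model
from .kymo import EventTrace, Kymograph
from .nsem import Micrograph

__all__ = [
    "SimKymoParams",
    "SimMicrographParams",
    "SimGroundTruth",
    "simulate_kymograph",
    "simulate_disassembly_kymograph",
    "simulate_fret_trace",
    "simulate_micrograph",
    "simulate_titration",
    "simulate_chromatogram",
    "simulate_tlc",
    "DEFAULT_RETENTION_MIN",
]


# ---------------------------------------------------------------------------
# parameter / ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimKymoParams:
    """Generating parameters for the nucleation-extension kymograph model.

    Rates: ``k_nuc`` is the nucleation rate density on *uncovered*
    substrate (events per μm per s); ``v_grow`` the extension speed per
    boundary (nm/s); ``k_off`` the per-end shrink speed (nm/s) used by the
    disassembly simulator. ``polarity_bias`` splits total growth between
    the two ends (0.5 = symmetric). New nuclei occupy
    ``nucleus_footprint_nm`` at birth. ``background_rate`` is the mean
    free-fluorophore count per pixel per frame; set ``shot_noise=False``
    for deterministic (expectation-valued) emission.
    """

    length_um: float = 20.0
    duration_s: float = 150.0
    frame_interval_s: float = 5.0
    pixel_size_nm: float = 100.0
    k_nuc: float = 0.1               # events um^-1 s^-1 on uncovered substrate
    v_grow: float = 5.0              # nm s^-1 per end
    k_off: float = 10.0              # nm s^-1 per end (disassembly mode)
    polarity_bias: float = 0.5
    nucleus_footprint_nm: float = 200.0
    nucleation_site_period_nm: float | None = None
    psf_sigma_px: float = 1.0
    photon_rate: float = 40.0        # counts per covered pixel per frame
    background_rate: float = 5.0     # counts per pixel per frame
    read_noise_sd: float = 2.0
    bleach_rate: float = 0.0         # s^-1 per fluorophore
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length_um", "duration_s", "frame_interval_s", "pixel_size_nm"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0")
        for name in ("k_nuc", "v_grow", "k_off", "nucleus_footprint_nm",
                     "psf_sigma_px", "photon_rate", "background_rate",
                     "read_noise_sd", "bleach_rate"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.polarity_bias <= 1.0:
            raise ValueError("polarity_bias must be in [0, 1]")


@dataclass
class SimMicrographParams:
    """Generating parameters for synthetic filament micrographs."""

    image_size_px: tuple[int, int] = (768, 768)
    pixel_size_A: float = 5.85
    n_filaments: int = 20
    length_log_mu: float = np.log(900.0)   # log-nm
    length_log_sigma: float = 0.3
    persistence_px: float = 200.0
    filament_width_px: float = 2.0
    filament_amplitude: float = 1.0
    background_particles_per_um2: float = 10.0
    particle_radius_px: float = 3.0
    particle_amplitude: float = 0.6
    noise_sd: float = 0.15
    avoid_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_A <= 0 or self.filament_width_px <= 0:
            raise ValueError("calibration and width must be > 0")
        if self.n_filaments < 0 or self.noise_sd < 0:
            raise ValueError("counts and noise must be >= 0")


@dataclass
class SimGroundTruth:
    """Hidden event list emitted by every simulator for recovery tests."""

    nucleation_events: list[tuple[float, float]] = field(default_factory=list)
    boundary_trajectories: dict[int, list[tuple[float, float, float]]] = field(default_factory=dict)
    coverage_fraction: np.ndarray | None = None
    segment_counts: np.ndarray | None = None
    true_rates: dict[str, float] = field(default_factory=dict)
    true_lengths_nm: np.ndarray | None = None
    filament_paths: list[np.ndarray] = field(default_factory=list)
    clipped: list[bool] = field(default_factory=list)
    true_kd_uM: float | None = None
    phase_boundaries_s: tuple[float, float] | None = None
    true_concentrations_uM: dict[str, float] = field(default_factory=dict)
    true_fractions: np.ndarray | None = None


# ---------------------------------------------------------------------------
# interval helpers (intervals are half-open [lo, hi) in nm)
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    out = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _complement(intervals: list[tuple[float, float]], length: float):
    gaps, prev = [], 0.0
    for lo, hi in intervals:
        if lo > prev:
            gaps.append((prev, lo))
        prev = max(prev, hi)
    if prev < length:
        gaps.append((prev, length))
    return gaps


def _sample_in_gaps(rng, gaps) -> float | None:
    total = sum(hi - lo for lo, hi in gaps)
    if total <= 0:
        return None
    u = rng.uniform(0.0, total)
    for lo, hi in gaps:
        if u < hi - lo:
            return lo + u
        u -= hi - lo
    return gaps[-1][1]


# ---------------------------------------------------------------------------
# kymograph simulators
# ---------------------------------------------------------------------------

def _render_kymograph(params: SimKymoParams, covered: np.ndarray,
                      t_cov: np.ndarray, rng, rpa_channel: bool) -> Kymograph:
    """Render pixel coverage masks into noisy photon-count rasters."""
    n_frames, n_px = covered.shape
    times = np.arange(n_frames)[:, None] * params.frame_interval_s
    survival = np.exp(-params.bleach_rate * np.clip(times - t_cov, 0.0, None))
    expected = params.background_rate + params.photon_rate * covered * survival
    channels = {}
    for name, exp_img in [("rad51", expected)] + (
        [("rpa", params.background_rate + params.photon_rate * (1.0 - covered))]
        if rpa_channel else []
    ):
        img = rng.poisson(exp_img).astype(float) if params.shot_noise else exp_img.copy()
        if params.psf_sigma_px > 0:
            img = ndimage.gaussian_filter1d(img, params.psf_sigma_px, axis=1,
                                            mode="reflect")
        if params.read_noise_sd > 0:
            img = img + rng.normal(0.0, params.read_noise_sd, img.shape)
        channels[name] = img
    return Kymograph(channels, params.frame_interval_s, params.pixel_size_nm)


def simulate_kymograph(params: SimKymoParams,
                       rpa_channel: bool = False) -> tuple[Kymograph, SimGroundTruth]:
    """Simulate filament assembly on a 1-D substrate and image it.

    Nucleation events per frame follow a Poisson law with intensity
    ``k_nuc`` per μm of currently uncovered substrate per second; positions
    are uniform over the uncovered gaps (hard-core: the nucleus footprint
    must fit inside a gap). Each nucleus is born with the configured
    footprint and its two boundaries extend at ``v_grow`` (split by
    ``polarity_bias``) until collision or substrate end. Identical
    (params, seed) give bit-identical output.

    When ``nucleation_site_period_nm`` is set, nucleation instead occurs at
    discrete, regularly spaced sites, each activating independently at rate
    ``k_nuc x period``. The expected number of occupied sites is then
    exactly M (1 - exp(-k_nuc * period * t)) — a true single-exponential
    saturation whose rate constant is proportional to ``k_nuc``, which is
    the regime the rate-recovery benchmarks use (see methods note).
    """
    rng = np.random.default_rng(params.seed)
    length_nm = params.length_um * 1000.0
    dt = params.frame_interval_s
    n_frames = int(round(params.duration_s / dt))
    n_px = int(round(length_nm / params.pixel_size_nm))
    v_left = 2.0 * params.v_grow * (1.0 - params.polarity_bias)
    v_right = 2.0 * params.v_grow * params.polarity_bias
    w = params.nucleus_footprint_nm

    nuclei: list[tuple[float, float]] = []   # (t_birth_s, x_center_nm)
    gt = SimGroundTruth(true_rates={"k_nuc": params.k_nuc, "v_grow": params.v_grow,
                                    "k_off": 0.0})
    coverage = np.zeros(n_frames)
    seg_counts = np.zeros(n_frames, dtype=int)
    covered = np.zeros((n_frames, n_px))
    t_cov = np.full((n_frames, n_px), np.inf)
    px_first_cov = np.full(n_px, np.inf)
    px_centers = (np.arange(n_px) + 0.5) * params.pixel_size_nm

    def segments_at(t: float) -> list[tuple[float, float]]:
        raw = []
        for t0, x0 in nuclei:
            if t < t0:
                continue
            lo = max(x0 - w / 2.0 - v_left * (t - t0), 0.0)
            hi = min(x0 + w / 2.0 + v_right * (t - t0), length_nm)
            raw.append((lo, hi))
        return _merge(raw)

    site_period = params.nucleation_site_period_nm
    if site_period is not None:
        if not site_period > 0:
            raise ValueError("nucleation_site_period_nm must be > 0")
        site_centers = np.arange(site_period / 2.0, length_nm, site_period)
        site_rate = params.k_nuc * site_period / 1000.0   # events/s per site
        site_occupied = np.zeros(site_centers.size, dtype=bool)

    for f in range(n_frames):
        t_frame = f * dt
        segs = segments_at(t_frame)
        # nucleation during [t_frame, t_frame + dt)
        if site_period is not None:
            free = np.nonzero(~site_occupied)[0]
            fire = free[rng.random(free.size) < 1.0 - np.exp(-site_rate * dt)]
            for idx in fire:
                t_ev = t_frame + rng.uniform(0.0, dt)
                x = float(site_centers[idx])
                site_occupied[idx] = True
                nuclei.append((t_ev, x))
                gt.nucleation_events.append((t_ev, x / 1000.0))
        else:
            gaps = _complement(segs, length_nm)
            free_um = sum(hi - lo for lo, hi in gaps) / 1000.0
            n_new = rng.poisson(params.k_nuc * free_um * dt)
            frame_born: list[tuple[float, float]] = []
            for _ in range(n_new):
                t_ev = t_frame + rng.uniform(0.0, dt)
                # hard-core placement: the footprint must fit inside a gap
                allowed = [(lo + w / 2.0, hi - w / 2.0) for lo, hi in gaps
                           if hi - lo > w]
                x = _sample_in_gaps(rng, allowed)
                if x is None:
                    break
                nuclei.append((t_ev, x))
                gt.nucleation_events.append((t_ev, x / 1000.0))
                # frame-born footprints exclude further nucleation immediately
                frame_born.append((x - w / 2.0, x + w / 2.0))
                gaps = _complement(_merge(segs + frame_born), length_nm)

        # record state at the *end* of the frame interval (what the next
        # exposure integrates); frame f shows coverage at its own time
        segs = segments_at(t_frame)
        coverage[f] = sum(hi - lo for lo, hi in segs) / length_nm
        seg_counts[f] = len(segs)
        mask = np.zeros(n_px, dtype=bool)
        for lo, hi in segs:
            mask |= (px_centers >= lo) & (px_centers < hi)
        newly = mask & ~np.isfinite(px_first_cov)
        px_first_cov[newly] = t_frame
        covered[f] = mask.astype(float)
        t_cov[f] = px_first_cov
        for nid, (t0, x0) in enumerate(nuclei):
            if t_frame < t0:
                continue
            for lo, hi in segs:
                if lo <= x0 <= hi:
                    gt.boundary_trajectories.setdefault(nid, []).append(
                        (t_frame, lo, hi))
                    break

    gt.coverage_fraction = coverage
    gt.segment_counts = seg_counts
    kymo = _render_kymograph(params, covered, t_cov, rng, rpa_channel)
    return kymo, gt


def simulate_disassembly_kymograph(
    params: SimKymoParams,
    initial_coverage: list[tuple[float, float]],
) -> tuple[Kymograph, SimGroundTruth]:
    """Simulate bidirectional disassembly of pre-formed segments.

    ``initial_coverage`` lists non-overlapping (start_um, end_um) segments;
    each shrinks at ``k_off`` nm/s per end (nucleation is off, matching
    transfer into an ATP-free channel).
    """
    iv = sorted(initial_coverage)
    for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
        if b0 < a1:
            raise ValueError("initial intervals must not overlap")
    for a0, a1 in iv:
        if a1 <= a0:
            raise ValueError("initial intervals must have positive length")

    rng = np.random.default_rng(params.seed)
    length_nm = params.length_um * 1000.0
    dt = params.frame_interval_s
    n_frames = int(round(params.duration_s / dt))
    n_px = int(round(length_nm / params.pixel_size_nm))
    px_centers = (np.arange(n_px) + 0.5) * params.pixel_size_nm

    covered = np.zeros((n_frames, n_px))
    t_cov = np.zeros((n_frames, n_px))   # pre-covered at t = 0
    coverage = np.zeros(n_frames)
    gt = SimGroundTruth(true_rates={"k_nuc": 0.0, "v_grow": 0.0,
                                    "k_off": params.k_off})
    for f in range(n_frames):
        t = f * dt
        mask = np.zeros(n_px, dtype=bool)
        cov = 0.0
        for sid, (s0_um, s1_um) in enumerate(iv):
            lo = s0_um * 1000.0 + params.k_off * t
            hi = s1_um * 1000.0 - params.k_off * t
            if hi <= lo:
                continue
            cov += hi - lo
            mask |= (px_centers >= lo) & (px_centers < hi)
            gt.boundary_trajectories.setdefault(sid, []).append((t, lo, hi))
        coverage[f] = cov / length_nm
        covered[f] = mask.astype(float)
    gt.coverage_fraction = coverage
    kymo = _render_kymograph(params, covered, t_cov, rng, rpa_channel=False)
    return kymo, gt


# ---------------------------------------------------------------------------
# single-event FRET traces
# ---------------------------------------------------------------------------

def simulate_fret_trace(
    phase_durations: tuple[float, float, float],
    donor_level: float = 100.0,
    acceptor_fret_level: float = 80.0,
    bleedthrough_level: float = 5.0,
    noise_sd: float = 0.0,
    sample_interval_s: float = 0.2,
    donor_fret_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[EventTrace, SimGroundTruth]:
    """Simulate a three-phase donor/acceptor event trace.

    Phase 1 (FRET): acceptor emits at ``acceptor_fret_level`` while the
    donor is quenched to ``donor_fret_fraction`` of its level. Phase 2
    (acceptor-labelled partner gone): full donor, acceptor at the
    bleed-through background. Phase 3: both channels dark. Ground truth
    carries the two phase boundaries.
    """
    d1, d2, d3 = phase_durations
    if min(d1, d2, d3) < 0:
        raise ValueError("phase durations must be >= 0")
    rng = np.random.default_rng(seed)
    n = [int(round(d / sample_interval_s)) for d in (d1, d2, d3)]
    total = sum(n)
    t = np.arange(total) * sample_interval_s
    donor = np.concatenate([
        np.full(n[0], donor_fret_fraction * donor_level),
        np.full(n[1], donor_level),
        np.zeros(n[2]),
    ])
    acceptor = np.concatenate([
        np.full(n[0], acceptor_fret_level),
        np.full(n[1], bleedthrough_level),
        np.zeros(n[2]),
    ])
    if noise_sd > 0:
        donor = donor + rng.normal(0.0, noise_sd, total)
        acceptor = acceptor + rng.normal(0.0, noise_sd, total)
    gt = SimGroundTruth(phase_boundaries_s=(d1, d1 + d2))
    return EventTrace(t, donor, acceptor), gt


# ---------------------------------------------------------------------------
# micrographs
# ---------------------------------------------------------------------------

def simulate_micrograph(params: SimMicrographParams
                        ) -> tuple[Micrograph, SimGroundTruth]:
    """Render persistence-sampled curvilinear filaments over background.

    Contour lengths are log-normal (``length_log_mu``, ``length_log_sigma``
    in log-nm); each filament is a unit-pixel-step random walk whose
    heading diffuses with variance 1/persistence_px per step, drawn with a
    Gaussian cross-section. Filaments reaching the image border are
    clipped, with the clipped length recorded in the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    canvas = np.zeros((h, w))
    occupied = np.zeros((h, w), dtype=bool)   # dilated footprint of drawn paths
    keepout = max(int(np.ceil(3.0 * params.filament_width_px)), 3)
    gt = SimGroundTruth()
    margin = 4.0
    px_per_nm = 10.0 / params.pixel_size_A

    def sample_path():
        target_nm = float(rng.lognormal(params.length_log_mu, params.length_log_sigma))
        n_steps = max(int(round(target_nm * px_per_nm)), 2)
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        pts = [(r, c)]
        clipped = False
        for _ in range(n_steps):
            theta += rng.normal(0.0, 1.0 / np.sqrt(params.persistence_px))
            r += np.sin(theta)
            c += np.cos(theta)
            if not (margin <= r < h - margin and margin <= c < w - margin):
                clipped = True
                break
            pts.append((r, c))
        return np.asarray(pts), clipped

    lengths = []
    for _ in range(params.n_filaments):
        path, clipped = sample_path()
        if params.avoid_overlap:
            for _ in range(50):
                ri = np.round(path[:, 0]).astype(int)
                ci = np.round(path[:, 1]).astype(int)
                if not occupied[ri, ci].any():
                    break
                path, clipped = sample_path()
        if path.shape[0] < 2:
            continue
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
        lengths.append(steps * params.pixel_size_A / 10.0)
        gt.filament_paths.append(path)
        gt.clipped.append(clipped)
        if clipped:
            warnings.warn("filament clipped at image boundary")
        ridx = np.clip(np.round(path[:, 0]).astype(int), 0, h - 1)
        cidx = np.clip(np.round(path[:, 1]).astype(int), 0, w - 1)
        canvas[ridx, cidx] = 1.0
        if params.avoid_overlap:
            for dr in range(-keepout, keepout + 1):
                for dc in range(-keepout, keepout + 1):
                    occupied[np.clip(ridx + dr, 0, h - 1),
                             np.clip(cidx + dc, 0, w - 1)] = True
    # Gaussian cross-section; renormalize so ridge apex ~ filament_amplitude
    img = ndimage.gaussian_filter(canvas, params.filament_width_px)
    if img.max() > 0:
        img = img / img.max() * params.filament_amplitude

    area_um2 = h * w * (params.pixel_size_A / 1e4) ** 2
    n_particles = rng.poisson(params.background_particles_per_um2 * area_um2)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(n_particles):
        pr, pc = rng.uniform(0, h), rng.uniform(0, w)
        if params.avoid_overlap and occupied[int(pr), int(pc)]:
            continue
        disc = (rr - pr) ** 2 + (cc - pc) ** 2 <= params.particle_radius_px ** 2
        img[disc] += params.particle_amplitude
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    gt.true_lengths_nm = np.asarray(lengths)
    return Micrograph(img, params.pixel_size_A), gt


# ---------------------------------------------------------------------------
# titrations, chromatograms, TLC
# ---------------------------------------------------------------------------

DEFAULT_PROTEIN_CONCS_UM = np.logspace(-3, 1, 14)   # 0.001 - 10 uM, half-log-ish


def simulate_titration(
    true_kd_uM: float,
    a_min: float = 0.05,
    a_max: float = 0.22,
    probe_conc_uM: float = 0.05,
    protein_concs_uM=None,
    noise_sd: float = 0.005,
    nucleotide_condition: str = "",
    seed: int = 0,
) -> tuple[BindingTitration, SimGroundTruth]:
    """Forward-simulate an anisotropy titration from the quadratic isotherm."""
    rng = np.random.default_rng(seed)
    x = (np.asarray(protein_concs_uM, dtype=float)
         if protein_concs_uM is not None else DEFAULT_PROTEIN_CONCS_UM.copy())
    y = quadratic_binding_model(x, probe_conc_uM, true_kd_uM, a_min, a_max)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, x.size)
    gt = SimGroundTruth(true_kd_uM=true_kd_uM)
    return BindingTitration(x, y, probe_conc_uM, nucleotide_condition), gt


DEFAULT_RETENTION_MIN = {"ADP": 6.5, "ATP": 9.0, "ATPgS": 12.5}


def simulate_chromatogram(
    nt_concs_uM: dict[str, float],
    retention_centers_min: dict[str, float] | None = None,
    peak_sigma_min: float = 0.08,
    response_factors: dict[str, float] | None = None,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    time_max_min: float = 15.0,
    dt_min: float = 0.005,
    seed: int = 0,
) -> tuple[Chromatogram, SimGroundTruth]:
    """Simulate a 260 nm ion-pair HPLC trace with Gaussian nucleotide peaks.

    Each species contributes a Gaussian at its retention centre whose
    *area* equals ``response_factor x concentration`` on a flat baseline.
    Peaks closer than 4 sigma raise a resolution warning.
    """
    centers = dict(retention_centers_min or DEFAULT_RETENTION_MIN)
    rf = response_factors or {}
    unknown = set(nt_concs_uM) - set(centers)
    if unknown:
        raise ValueError(f"species without retention centre: {sorted(unknown)}")
    used = sorted(centers[s] for s in nt_concs_uM)
    for a, b in zip(used, used[1:]):
        if b - a < 4.0 * peak_sigma_min:
            warnings.warn("peaks closer than 4 sigma: poorly resolved")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, time_max_min + dt_min / 2, dt_min)
    y = np.full_like(t, baseline)
    for species, conc in nt_concs_uM.items():
        if conc < 0:
            raise ValueError("concentrations must be >= 0")
        area = rf.get(species, 1.0) * conc
        amp = area / (peak_sigma_min * np.sqrt(2.0 * np.pi))
        y = y + amp * np.exp(-0.5 * ((t - centers[species]) / peak_sigma_min) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.size)
    gt = SimGroundTruth(true_concentrations_uM=dict(nt_concs_uM))
    return Chromatogram(t, y), gt


def simulate_tlc(
    fraction_hydrolysed,
    total_signal: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TlcAssay, SimGroundTruth]:
    """Simulate per-lane (ADP, ATP) TLC spot intensities.

    Before noise, the two spots of each lane sum exactly to
    ``total_signal`` with the ADP spot carrying the hydrolysed fraction.
    """
    f = np.atleast_1d(np.asarray(fraction_hydrolysed, dtype=float))
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    adp = f * total_signal
    atp = (1.0 - f) * total_signal
    if noise_sd > 0:
        adp = np.clip(adp + rng.normal(0.0, noise_sd, f.size), 0.0, None)
        atp = np.clip(atp + rng.normal(0.0, noise_sd, f.size), 0.0, None)
    gt = SimGroundTruth(true_fractions=f)
    return TlcAssay(adp, atp), gt
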