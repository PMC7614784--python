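"""Kymograph kinetics: assembly fits, nucleation rates, edge rates, events.

A kymograph is a 2-D raster of fluorescence along a single tethered DNA
molecule: rows are frames (time increases downward), columns are position
pixels. All operations here work on that convention; positions are
converted to nm with the kymograph's pixel calibration and times to
seconds with its frame interval. Coordinates are 0-based, intervals
half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal, stats

__all__ = [
    "Kymograph",
    "EventTrace",
    "ExponentialFit",
    "NucleationEstimate",
    "EdgeRate",
    "BindingEvent",
    "FretEvent",
    "ForceTrace",
    "normalize_assembly_signal",
    "fit_saturating_exponential",
    "estimate_nucleation_rate",
    "measure_edge_rate",
    "detect_binding_events",
    "analyze_fret_event",
    "downsample_force",
]


def robust_sd(x) -> float:
    """Robust scale estimate: 1.4826 x median absolute deviation."""
    x = np.asarray(x, dtype=float).ravel()
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """Multi-channel time x position raster with physical calibration."""

    channels: dict[str, np.ndarray]
    frame_interval_s: float
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("kymograph needs at least one channel")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if not (self.frame_interval_s > 0 and self.pixel_size_nm > 0):
            raise ValueError("calibrations must be > 0")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_pixels(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclass
class EventTrace:
    """Two-channel intensity trace over a single binding event."""

    time_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.time_s.shape == self.donor.shape == self.acceptor.shape):
            raise ValueError("time, donor and acceptor must have equal length")


@dataclass
class ExponentialFit:
    """Fit of the saturating exponential y = A_max (1 - exp(-k t))."""

    a_max: float
    k: float
    half_life_s: float
    residual_sse: float
    converged: bool
    ci95_k: tuple[float, float] = (np.nan, np.nan)


@dataclass
class NucleationEstimate:
    peak_counts: np.ndarray
    fit: ExponentialFit
    apparent_rate: float           # fitted k, s^-1
    initial_event_rate: float      # A_max * k, events s^-1 at t = 0


@dataclass
class EdgeRate:
    boundary_positions: np.ndarray  # (time_s, position_nm) rows
    rate_nm_per_s: float            # signed: positive = growth (outward)
    r_squared: float
    side: str = "right"


@dataclass
class BindingEvent:
    channel: str
    start_s: float
    end_s: float
    position_px: tuple[int, int]    # half-open [lo, hi)
    mean_intensity: dict[str, float] = field(default_factory=dict)


@dataclass
class FretEvent:
    phases: list[tuple[str, float, float]]   # (label, start_s, end_s)
    donor_trace: np.ndarray
    acceptor_trace: np.ndarray
    anticorrelation: float


@dataclass
class ForceTrace:
    time_s: np.ndarray
    force_pN: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.time_s.shape != self.force_pN.shape:
            raise ValueError("time and force must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


# ---------------------------------------------------------------------------
# assembly signal
# ---------------------------------------------------------------------------

def normalize_assembly_signal(kymo: Kymograph, channel: str,
                              background_region: tuple[int, int]) -> np.ndarray:
    """Per-frame total channel intensity normalized to a background region.

    ``background_region`` is a half-open pixel interval [lo, hi) covering a
    part of the substrate that carries only the free-fluorophore background.
    Each frame's summed intensity is divided by the mean intensity of that
    region in the same frame, so slow illumination drift divides out.
    """
    lo, hi = background_region
    if not (0 <= lo < hi <= kymo.n_pixels):
        raise ValueError("background_region must be a non-empty in-bounds interval")
    img = kymo[channel]
    bg = img[:, lo:hi].mean(axis=1)
    if np.any(bg == 0):
        raise ValueError("zero background mean: normalization undefined")
    return img.sum(axis=1) / bg


def fit_saturating_exponential(t, y) -> ExponentialFit:
    """Least-squares fit of y = A_max (1 - exp(-k t)).

    Returns ``converged=False`` (with k = 0) for all-zero data or when the
    optimizer fails or lands on a non-positive rate. The half-life is
    ln 2 / k. A Jacobian-based Student-t 95% CI on k is attached.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 points")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if np.all(y == 0):
        return ExponentialFit(0.0, 0.0, np.inf, 0.0, converged=False)

    a0 = float(max(y.max(), 1e-12))
    # initial slope -> k seed; fall back to 1/(t_range/3)
    nz = np.nonzero(t > 0)[0]
    k0 = float(y[nz[0]] / (a0 * t[nz[0]])) if nz.size else 0.1
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 3.0 / max(t.max(), 1.0)

    def model(tv, a_max, k):
        return a_max * (1.0 - np.exp(-k * tv))

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[a0, k0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20_000,
        )
    except (RuntimeError, ValueError):
        return ExponentialFit(np.nan, 0.0, np.inf, np.nan, converged=False)

    a_max, k = float(popt[0]), float(popt[1])
    resid = y - model(t, *popt)
    sse = float(resid @ resid)
    dof = max(t.size - 2, 1)
    se_k = float(np.sqrt(max(pcov[1, 1], 0.0)))
    tq = stats.t.ppf(0.975, dof)
    ci = (k - tq * se_k, k + tq * se_k)
    converged = k > 0 and np.isfinite(a_max)
    half = np.log(2.0) / k if k > 0 else np.inf
    return ExponentialFit(a_max, k, half, sse, converged, ci)


# ---------------------------------------------------------------------------
# nucleation
# ---------------------------------------------------------------------------

def count_frame_peaks(kymo: Kymograph, channel: str, smooth_window_px: int = 5,
                      prominence_sigmas: float = 10.0, min_separation_px: int = 3,
                      polyorder: int = 2) -> np.ndarray:
    """Per-frame count of resolvable intensity peaks along the position axis.

    Each frame's spatial profile is Savitzky-Golay smoothed (default 5-px
    window, quadratic), then local maxima with prominence at least
    ``prominence_sigmas`` robust background SDs are counted. A minimum peak
    separation of ``min_separation_px`` avoids double-counting maxima inside
    one diffraction-limited spot.
    """
    img = kymo[channel]
    if kymo.n_pixels < smooth_window_px:
        raise ValueError("image narrower than the smoothing window")
    if kymo.n_frames == 0:
        raise ValueError("kymograph has zero frames")
    smoothed = signal.savgol_filter(img, smooth_window_px, polyorder, axis=1)
    # noise scale from frame-to-frame differences: static structure (covered
    # segments, their edges) cancels, leaving only the camera/shot noise of
    # the smoothed image, however crowded the substrate is
    if kymo.n_frames > 1:
        sigma = robust_sd(np.diff(smoothed, axis=0)) / np.sqrt(2.0)
    else:
        sigma = robust_sd(np.diff(smoothed, axis=1)) / np.sqrt(2.0)
    if sigma > 0:
        prominence = prominence_sigmas * sigma
    else:
        # noise-free raster: suppress the tiny shoulder ripples the
        # polynomial smoother leaves at plateau edges
        dyn = float(smoothed.max() - np.median(smoothed))
        prominence = max(0.1 * dyn, 1e-9)
    counts = np.empty(kymo.n_frames, dtype=int)
    for i in range(kymo.n_frames):
        peaks, _ = signal.find_peaks(
            smoothed[i], prominence=prominence, distance=min_separation_px
        )
        counts[i] = peaks.size
    return counts


def estimate_nucleation_rate(kymo: Kymograph, channel: str,
                             smooth_window_px: int = 5,
                             prominence_sigmas: float = 10.0,
                             min_separation_px: int = 3) -> NucleationEstimate:
    """Apparent nucleation rate from the saturation kinetics of peak counts.

    Peak counts per frame are fitted with y = A_max (1 - exp(-k t)); the
    fitted k (s^-1) is the apparent nucleation rate. ``initial_event_rate``
    (= A_max * k) additionally expresses the extrapolated absolute event
    rate at t = 0 in events/s, which is what simulation benchmarks compare
    across conditions.
    """
    counts = count_frame_peaks(kymo, channel, smooth_window_px,
                               prominence_sigmas, min_separation_px)
    if np.all(counts == 0):
        fit = ExponentialFit(0.0, 0.0, np.inf, 0.0, converged=False)
        return NucleationEstimate(counts, fit, 0.0, 0.0)
    fit = fit_saturating_exponential(kymo.times_s(), counts.astype(float))
    rate = fit.k if fit.converged else 0.0
    return NucleationEstimate(counts, fit, rate, fit.a_max * rate)


# ---------------------------------------------------------------------------
# edge (growth / disassembly) rates
# ---------------------------------------------------------------------------

def _segment_bounds(row: np.ndarray, px: int, threshold: float) -> tuple[int, int] | None:
    """Half-open bounds of the above-threshold run containing (or nearest) px."""
    mask = row >= threshold
    if not mask.any():
        return None
    if not mask[px]:
        cand = np.nonzero(mask)[0]
        px = int(cand[np.argmin(np.abs(cand - px))])
    lo = px
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = px + 1
    while hi < row.size and mask[hi]:
        hi += 1
    return lo, hi


def measure_edge_rate(kymo: Kymograph, channel: str,
                      segment_seed: tuple[int, int],
                      threshold_fraction: float = 0.5,
                      side: str = "right",
                      max_gap_frames: int = 3) -> EdgeRate:
    """Growth/disassembly rate of one filament edge by boundary regression.

    Starting from a seed (frame, pixel) inside a filament segment, the
    segment is followed frame by frame; per frame the boundary is the
    outermost pixel of the connected run whose intensity is at least
    ``threshold_fraction`` of the segment plateau (the seed-frame maximum
    near the seed). Boundary positions (nm) are regressed linearly on time;
    the returned rate is signed so that outward motion (growth) is
    positive. Losing the segment for more than ``max_gap_frames``
    consecutive frames truncates the trace with a warning.
    """
    frame0, px0 = segment_seed
    img = kymo[channel]
    if not (0 <= frame0 < kymo.n_frames and 0 <= px0 < kymo.n_pixels):
        raise ValueError("segment_seed outside kymograph")
    lo0 = max(px0 - 10, 0)
    plateau = float(img[frame0, lo0:px0 + 11].max())
    threshold = threshold_fraction * plateau
    if plateau <= 0 or img[frame0, px0] < threshold:
        raise ValueError("seed pixel below threshold in its frame")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")

    times, positions = [], []
    center = px0
    gap = 0
    for f in range(frame0, kymo.n_frames):
        bounds = _segment_bounds(img[f], center, threshold)
        if bounds is None or abs((bounds[0] + bounds[1]) // 2 - center) > 20 + gap * 10:
            gap += 1
            if gap > max_gap_frames:
                warnings.warn(f"segment lost at frame {f}; trace truncated")
                break
            continue
        gap = 0
        lo, hi = bounds
        center = (lo + hi) // 2
        edge_px = (hi - 1) if side == "right" else lo
        times.append(f * kymo.frame_interval_s)
        positions.append(edge_px * kymo.pixel_size_nm)

    pts = np.column_stack([times, positions]) if times else np.empty((0, 2))
    if len(times) < 3:
        raise ValueError("fewer than 3 boundary samples: cannot regress")
    res = stats.linregress(times, positions)
    slope = float(res.slope)
    rate = slope if side == "right" else -slope
    r2 = float(res.rvalue ** 2) if np.std(positions) > 0 else 0.0
    return EdgeRate(pts, rate, r2, side)


# ---------------------------------------------------------------------------
# binding events
# ---------------------------------------------------------------------------

def detect_binding_events(kymo: Kymograph, channel: str,
                          intensity_sigmas: float = 5.0,
                          min_duration_frames: int = 2,
                          window_s: float = 30.0
                          ) -> tuple[list[BindingEvent], np.ndarray]:
    """Connected above-threshold spatiotemporal regions as binding events.

    The threshold is ``median + intensity_sigmas x robust SD`` of the
    channel. Events shorter than ``min_duration_frames`` are discarded.
    The second return value counts events *starting* within successive
    half-open windows of ``window_s`` seconds (the first window gives the
    early-binding frequency).
    """
    img = kymo[channel]
    threshold = float(np.median(img)) + intensity_sigmas * robust_sd(img)
    mask = img > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    events: list[BindingEvent] = []
    for sl_t, sl_x in ndimage.find_objects(labels):
        if (sl_t.stop - sl_t.start) < min_duration_frames:
            continue
        region = labels[sl_t, sl_x] > 0
        means = {
            name: float(arr[sl_t, sl_x][region].mean())
            for name, arr in kymo.channels.items()
        }
        events.append(BindingEvent(
            channel,
            start_s=sl_t.start * kymo.frame_interval_s,
            end_s=sl_t.stop * kymo.frame_interval_s,
            position_px=(sl_x.start, sl_x.stop),
            mean_intensity=means,
        ))
    duration = kymo.n_frames * kymo.frame_interval_s
    n_windows = max(int(np.ceil(duration / window_s)), 1)
    freq = np.zeros(n_windows, dtype=int)
    for ev in events:
        freq[min(int(ev.start_s // window_s), n_windows - 1)] += 1
    return events, freq


# ---------------------------------------------------------------------------
# FRET event segmentation
# ---------------------------------------------------------------------------

def _phase_runs(labels: np.ndarray, time: np.ndarray, dt: float):
    phases = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            phases.append((str(labels[start]), float(time[start]),
                           float(time[i - 1] + dt)))
            start = i
    return phases


def analyze_fret_event(trace: EventTrace, bleedthrough_level: float,
                       step_sigmas: float = 3.0,
                       smooth_samples: int = 3) -> FretEvent:
    """Segment a two-colour trace into fret / donor-only / dark phases.

    The acceptor channel is thresholded against the donor bleed-through
    level plus ``step_sigmas`` noise SDs (noise estimated robustly from
    first differences); samples above it are FRET. Remaining samples with
    donor signal above its own noise floor are donor-only; the rest are
    dark. The anticorrelation field is the Pearson r between donor and
    acceptor over the non-dark portion of the event (FRET transfer makes it
    negative).
    """
    d, a, t = trace.donor, trace.acceptor, trace.time_s
    if d.size < 2:
        raise ValueError("trace too short")
    dt = float(np.median(np.diff(t)))

    def noise_sd(x):
        return robust_sd(np.diff(x)) / np.sqrt(2.0)

    sd_a, sd_d = noise_sd(a), noise_sd(d)
    a_s = ndimage.uniform_filter1d(a, smooth_samples)
    d_s = ndimage.uniform_filter1d(d, smooth_samples)
    thr_a = bleedthrough_level + step_sigmas * sd_a
    thr_d = max(step_sigmas * sd_d, 1e-12)

    lab = np.where(a_s > thr_a, "fret",
                   np.where(d_s > thr_d, "donor_only", "dark"))
    phases = _phase_runs(lab, t, dt)

    active = lab != "dark"
    if active.sum() >= 3 and np.std(d[active]) > 0 and np.std(a[active]) > 0:
        r = float(np.corrcoef(d[active], a[active])[0, 1])
    elif np.std(d) > 0 and np.std(a) > 0:
        r = float(np.corrcoef(d, a)[0, 1])
    else:
        r = np.nan
    return FretEvent(phases, d, a, r)


def window_average_kymo_trace(kymo: Kymograph, channel: str, center_px: int,
                              window_px: int = 3) -> np.ndarray:
    """Per-frame intensity averaged over a window centred on a position.

    This reproduces the 3-pixel window averaging used when extracting
    single-event donor/acceptor traces from a kymograph.
    """
    half = window_px // 2
    lo = max(center_px - half, 0)
    hi = min(center_px + half + 1, kymo.n_pixels)
    return kymo[channel][:, lo:hi].mean(axis=1)


# ---------------------------------------------------------------------------
# force traces
# ---------------------------------------------------------------------------

def downsample_force(trace: ForceTrace, target_hz: float = 3.0) -> ForceTrace:
    """Downsample a force trace to ``target_hz`` by non-overlapping block means.

    Blocks are half-open intervals [t0 + i/f, t0 + (i+1)/f); a trailing
    partial block is dropped, so the output has
    floor(duration x target_hz) samples. Output timestamps sit at block
    centres.
    """
    if trace.sample_rate_hz < target_hz:
        raise ValueError("input rate below target rate")
    t0 = trace.time_s[0]
    duration = trace.time_s.size / trace.sample_rate_hz
    n_out = int(np.floor(duration * target_hz))
    idx = np.floor((trace.time_s - t0) * target_hz).astype(int)
    keep = idx < n_out
    sums = np.bincount(idx[keep], weights=trace.force_pN[keep], minlength=n_out)
    counts = np.bincount(idx[keep], minlength=n_out)
    force = sums / np.maximum(counts, 1)
    times = t0 + (np.arange(n_out) + 0.5) / target_hz
    return ForceTrace(times, force, target_hz)
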