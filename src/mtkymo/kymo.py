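"""From images to events: kymograph construction, tip-trace extraction,
phase segmentation, and grouping of segments into microtubule lifetimes.

A kymograph is a time x position raster sampled along a microtubule; the
plus-end tip appears as an intensity edge whose column advances during growth
and recedes during shrinkage.  This module automates what is classically done
by eye in ImageJ: the tip is localized per frame by a sub-pixel half-maximum
edge crossing, the resulting position-time trace is classified frame-by-frame
into growth / pause / shrinkage by a speed threshold, short runs are merged,
and phase boundaries are refined by local least-squares changepoint fits.
Segments are then grouped into per-microtubule lifetimes running from
emanation at the seed to complete depolymerization back to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import savgol_filter

from ._sampling import sample_polyline
from .model import (
    BARE,
    GROWTH,
    PAUSE,
    SHRINK,
    Calibration,
    DynamicsParameters,
    KymographImage,
    ModelError,
    StatePath,
    Trajectory,
)

__all__ = [
    "KymographImage",
    "Trace",
    "SegConfig",
    "TipDetectConfig",
    "PhaseSegment",
    "LifetimeRecord",
    "build_kymograph",
    "extract_tip_trace",
    "segment_trace",
    "split_lifetimes",
    "trace_from_trajectory",
    "segments_from_truth",
    "lifetimes_from_truth",
]

_EPS = 1e-9

#: state names used for segments (full words, unlike the model's G/P/S codes)
ST_GROWTH = "growth"
ST_PAUSE = "pause"
ST_SHRINK = "shrink"

_STATE_NAME = {GROWTH: ST_GROWTH, PAUSE: ST_PAUSE, SHRINK: ST_SHRINK}


class TraceError(ValueError):
    """Invalid trace, kymograph, or segmentation input."""


@dataclass
class Trace:
    """Tip position (um beyond the seed) per frame; NaN marks frames where
    no tip was detected."""

    frame_times: np.ndarray
    positions: np.ndarray
    calibration: Calibration | None = None
    n_undetected: int = 0
    mt_id: str | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frame_times.shape != self.positions.shape:
            raise TraceError("frame_times and positions must have equal length")
        if np.any(np.diff(self.frame_times) <= 0):
            raise TraceError("frame_times must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.positions < 0):
                raise TraceError("positions must be non-negative where present")

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.frame_times)))


@dataclass(frozen=True)
class TipDetectConfig:
    """Tip-detection settings.

    The detection threshold is ``background + max(threshold_k * noise_sd,
    detect_frac * lattice_amplitude)`` on a lightly smoothed raster; the
    half-amplitude term makes noiseless edges sub-pixel accurate, the
    noise-floor term suppresses false tips at low signal.  ``bare_as_zero``
    reports frames with a visible seed but no lattice signal as position 0
    (a bare seed) instead of missing.
    """

    threshold_k: float = 5.0
    detect_frac: float = 0.5
    smooth_sigma: float = 1.0
    max_gap_px: int = 2
    bare_as_zero: bool = True


@dataclass(frozen=True)
class SegConfig:
    """Phase-segmentation settings.

    pause_speed_threshold
        |velocity| at or below which a frame counts as paused (um/min).
    min_segment_frames
        Runs shorter than this are merged into the longer neighbor.
    smoothing_halfwidth
        Half-width (frames) of the running-median prefilter applied before
        velocity estimation; boundaries are later refined by least squares,
        so smoothing affects only the initial labeling.
    velocity_halfwidth
        Half-width (frames) of the local least-squares slope used to
        classify each frame.  Wider windows push the velocity noise floor
        well below the pause band at realistic signal-to-noise; the
        changepoint refinement restores the boundary resolution the wide
        window costs.
    seed_return_tolerance
        Position (um) below which the tip counts as returned to the seed;
        None resolves to one pixel of the trace's calibration.
    min_excursion
        A lifetime opens only once the tip exceeds this position (um).
        Excursions below a few pixels sit inside the optical blind zone
        (PSF blur plus the detection threshold), so opening at one pixel
        would create lifetimes no image-based analysis can reproduce.
        Nucleation is timed at the threshold crossing.
    min_event_displacement
        A growth or shrink run shorter than ``min_segment_frames`` is kept
        (not merged) when its net displacement exceeds this (um).  Shrinkage
        is often several pixels per frame, so a two-frame drop of half a
        micrometer is an unambiguous catastrophe even though its duration is
        below the run-length floor; merging it would silently delete a
        catastrophe/rescue pair.  Set well above the position noise.
    """

    pause_speed_threshold: float = 0.25
    min_segment_frames: int = 3
    smoothing_halfwidth: int = 1
    velocity_halfwidth: int = 3
    seed_return_tolerance: float | None = None
    min_excursion: float = 0.5
    min_event_displacement: float = 0.4

    def __post_init__(self) -> None:
        if self.pause_speed_threshold < 0:
            raise TraceError("pause_speed_threshold must be >= 0")
        if self.min_segment_frames < 2:
            raise TraceError("min_segment_frames must be >= 2")


@dataclass
class PhaseSegment:
    """One growth / pause / shrink phase over the half-open interval
    [t_start, t_end) seconds, with its least-squares slope in um/min."""

    state: str
    t_start: float
    t_end: float
    slope: float

    def __post_init__(self) -> None:
        if self.state not in (ST_GROWTH, ST_PAUSE, ST_SHRINK):
            raise TraceError(f"unknown segment state {self.state!r}")
        if self.t_end <= self.t_start:
            raise TraceError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class LifetimeRecord:
    """One microtubule's life from emanation at the seed to complete
    depolymerization back to it (or movie end, in which case ``censored``)."""

    segments: list[PhaseSegment]
    t_nucleation: float
    t_end: float
    censored: bool

    def validate(self) -> None:
        if not self.segments:
            raise TraceError("lifetime with no segments")
        t = self.segments[0].t_start
        for seg in self.segments:
            if abs(seg.t_start - t) > 1e-6:
                raise TraceError("lifetime segments are not contiguous")
            t = seg.t_end
        if self.segments[0].state != ST_GROWTH:
            raise TraceError("lifetime must start with a growth segment")
        if not self.censored and self.segments[-1].state != ST_SHRINK:
            raise TraceError("uncensored lifetime must end with a shrink segment")


# ---------------------------------------------------------------------------
# kymograph construction

def build_kymograph(
    stack: np.ndarray,
    polyline: list[tuple[float, float]],
    width: int = 1,
    calibration: Calibration | None = None,
) -> KymographImage:
    """Build a single-channel kymograph by sampling ``polyline`` (a list of
    (row, col) pixel vertices) in every frame of ``stack`` (T, Y, X),
    averaging across ``width`` pixels perpendicular to the line."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise TraceError("stack must be a non-empty (T, Y, X) array")
    rows = []
    for frame in stack:
        prof = sample_polyline(frame, polyline, width)
        rows.append(prof)
    raster = np.vstack(rows)
    return KymographImage(channels={"lattice": raster}, calibration=calibration or Calibration())


# ---------------------------------------------------------------------------
# tip extraction

def _robust_noise_sd(raster: np.ndarray) -> float:
    # first differences along position kill the (piecewise-smooth) signal;
    # MAD of differences estimates sqrt(2) * noise sd
    d = np.diff(raster, axis=1).ravel()
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def _seed_origin(seed_raster: np.ndarray) -> float:
    """Continuous column coordinate of the seed band's distal end."""
    profile = seed_raster.mean(axis=0)
    n = profile.size
    bg = float(np.median(profile[n // 2:]))
    amp = float(profile.max()) - bg
    noise = _robust_noise_sd(seed_raster) / max(np.sqrt(seed_raster.shape[0]), 1.0)
    if amp <= max(5.0 * noise, 1e-12):
        raise TraceError("no detectable seed band in the seed channel")
    half = bg + 0.5 * amp
    above = profile > half
    peak = int(np.argmax(profile))
    j = peak
    while j + 1 < n and above[j + 1]:
        j += 1
    if j + 1 >= n:
        raise TraceError("seed band extends to the edge of the ROI")
    frac = (profile[j] - half) / max(profile[j] - profile[j + 1], 1e-12)
    return float(j + np.clip(frac, 0.0, 1.0)) + 0.5


def extract_tip_trace(
    kymo: KymographImage,
    config: TipDetectConfig | None = None,
) -> Trace:
    """Localize the microtubule tip in every row of a two-channel kymograph.

    Per row, the tip is the farthest above-threshold lattice column that is
    contiguous with the seed band (gaps up to ``max_gap_px`` are bridged),
    refined to sub-pixel precision by interpolating the threshold crossing.
    Positions are micrometers beyond the distal end of the seed band.
    """
    config = config or TipDetectConfig()
    if "lattice" not in kymo.channels or "seed" not in kymo.channels:
        raise TraceError("kymograph must have 'lattice' and 'seed' channels")
    calib = kymo.calibration
    lattice = kymo.channels["lattice"]
    origin = _seed_origin(kymo.channels["seed"])

    S = gaussian_filter1d(lattice, config.smooth_sigma, axis=1, mode="nearest") \
        if config.smooth_sigma > 0 else lattice
    raw_sd = _robust_noise_sd(lattice)
    if config.smooth_sigma > 0:
        # variance shrink factor of a Gaussian kernel: sum(w^2) ~ 1/(2 sqrt(pi) sigma)
        sd = raw_sd * np.sqrt(1.0 / (2.0 * np.sqrt(np.pi) * config.smooth_sigma))
    else:
        sd = raw_sd
    bg = float(np.percentile(S, 20))
    amp = float(np.percentile(S, 99.5)) - bg
    thr = bg + max(config.threshold_k * sd, config.detect_frac * amp)

    n_rows, n_cols = S.shape
    col0 = int(np.floor(origin))
    A = S[:, col0:] > thr
    width = A.shape[1]
    if width < 2 or amp <= max(config.threshold_k * sd, 1e-12):
        warnings.warn("no lattice signal detected in any row", stacklevel=2)
        return Trace(
            frame_times=np.arange(n_rows) * calib.frame_interval,
            positions=np.full(n_rows, np.nan),
            calibration=calib,
            n_undetected=n_rows,
        )

    g = config.max_gap_px
    F = (~A).astype(np.int32)
    cs = np.cumsum(F, axis=1)
    if width > g:
        win = np.empty((n_rows, width - g), dtype=bool)
        win[:, 0] = cs[:, g] == g + 1
        win[:, 1:] = (cs[:, g + 1:] - cs[:, :-g - 1]) == g + 1
        has_gap = win.any(axis=1)
        first_gap = np.where(has_gap, np.argmax(win, axis=1), width)
    else:
        first_gap = np.full(n_rows, width)
    idx = np.arange(width)
    masked = np.where(A & (idx[None, :] < first_gap[:, None]), idx[None, :], -1)
    tip_rel = masked.max(axis=1)

    positions = np.full(n_rows, np.nan)
    n_undetected = 0
    detected = tip_rel >= 0
    rows = np.nonzero(detected)[0]
    j = col0 + tip_rel[rows]
    I0 = S[rows, j]
    j1 = np.minimum(j + 1, n_cols - 1)
    I1 = S[rows, j1]
    denom = I0 - I1
    frac = np.where(denom > 1e-12, (I0 - thr) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    crossing = j + np.clip(frac, 0.0, 1.0)
    positions[rows] = np.clip((crossing + 0.5 - origin), 0.0, None) * calib.pixel_size
    if config.bare_as_zero:
        positions[~detected] = 0.0
    else:
        n_undetected = int(np.count_nonzero(~detected))
        if n_undetected:
            warnings.warn(f"{n_undetected} rows with no detectable tip", stacklevel=2)
    return Trace(
        frame_times=np.arange(n_rows) * calib.frame_interval,
        positions=positions,
        calibration=calib,
        n_undetected=n_undetected,
    )


def trace_from_trajectory(traj: Trajectory) -> Trace:
    """Treat a simulated trajectory's exact lengths as a tip trace (the
    noise-free, acquisition-resolution ground truth)."""
    return Trace(
        frame_times=traj.frame_times.copy(),
        positions=traj.lengths.copy(),
        calibration=traj.calibration,
        mt_id=traj.mt_id,
    )


# ---------------------------------------------------------------------------
# segmentation

def _smooth_positions(x: np.ndarray, halfwidth: int) -> np.ndarray:
    # median, not mean: a running median suppresses position noise without
    # rounding the corners at phase transitions, so short pauses are not
    # eroded below the run-length floor by smeared boundary velocities
    if halfwidth <= 0 or x.size < 3:
        return x.astype(float)
    return median_filter(x.astype(float), size=2 * halfwidth + 1, mode="nearest")


def _classify(velocity: np.ndarray, threshold: float) -> np.ndarray:
    labels = np.zeros(velocity.size, dtype=int)  # 0 pause, 1 growth, -1 shrink
    labels[velocity > threshold] = 1
    labels[velocity < -threshold] = -1
    return labels


def _label_runs(labels: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append([start, i - 1, int(labels[start])])
            start = i
    return runs


def _merge_short_runs(
    runs: list[list[int]],
    min_frames: int,
    pos: np.ndarray | None = None,
    min_displacement: float = 0.0,
) -> list[list[int]]:
    def protected(r: list[int]) -> bool:
        # keep short growth/shrink runs whose displacement is unambiguous
        if pos is None or min_displacement <= 0 or r[2] == 0:
            return False
        end = min(r[1] + 1, pos.size - 1)
        return abs(pos[end] - pos[r[0]]) >= min_displacement

    runs = [list(r) for r in runs]
    while len(runs) > 1:
        candidates = [
            (r[1] - r[0] + 1, k) for k, r in enumerate(runs)
            if (r[1] - r[0] + 1) < min_frames and not protected(r)
        ]
        if not candidates:
            break
        shortest = min(candidates)[1]
        left = runs[shortest - 1] if shortest > 0 else None
        right = runs[shortest + 1] if shortest < len(runs) - 1 else None
        if left is not None and right is not None:
            n_left = left[1] - left[0] + 1
            n_right = right[1] - right[0] + 1
            target = right if n_right >= n_left else left
        else:
            target = left if right is None else right
        victim = runs[shortest]
        if target[0] > victim[0]:
            target[0] = victim[0]
        else:
            target[1] = victim[1]
        runs.pop(shortest)
        # absorb a now-adjacent same-label neighbor, if any
        for k in range(len(runs) - 1):
            if runs[k][2] == runs[k + 1][2] and runs[k][1] + 1 == runs[k + 1][0]:
                runs[k][1] = runs[k + 1][1]
                runs.pop(k + 1)
                break
    return runs


def _fit_slope(times: np.ndarray, pos: np.ndarray) -> float:
    """Least-squares slope in um/min (times in s)."""
    if pos.size < 2:
        return 0.0
    t = times - times.mean()
    denom = float(np.dot(t, t))
    if denom == 0:
        return 0.0
    return float(np.dot(t, pos - pos.mean()) / denom) * 60.0


def _sse(times: np.ndarray, pos: np.ndarray) -> float:
    if pos.size < 2:
        return 0.0
    t = times - times.mean()
    y = pos - pos.mean()
    denom = float(np.dot(t, t))
    if denom == 0:
        return float(np.dot(y, y))
    beta = np.dot(t, y) / denom
    r = y - beta * t
    return float(np.dot(r, r))


def _run_slope(times: np.ndarray, pos: np.ndarray, r: list[int],
               min_frames: int = 3) -> float:
    i0, i1 = r[0], r[1]
    if i1 - i0 + 1 < min_frames and i0 > 0:
        # sub-minimum runs exist only as displacement events (recovered dips
        # or refined steps); the displacement lives on the entering boundary,
        # so include the preceding frame in the fit
        i0 -= 1
    i1 = min(max(i1, i0 + 1), pos.size - 1)
    return _fit_slope(times[i0:i1 + 1], pos[i0:i1 + 1])


def _recover_dips(
    runs: list[list[int]], times: np.ndarray, pos: np.ndarray, config: SegConfig
) -> list[list[int]]:
    """Split sub-frame catastrophe/rescue dips out of growth and pause runs.

    A depolymerization episode shorter than the frame interval leaves no
    multi-frame shrink run — only one or two frames sitting far below the
    phase's fitted line (and the median prefilter removes them from the
    smoothed velocities entirely).  Frames more than the event-displacement
    threshold below the line, and well beyond the residual noise, become
    their own shrink run so the catastrophe/rescue pair is counted.
    """
    if config.min_event_displacement <= 0:
        return runs
    out: list[list[int]] = []
    for r in runs:
        n = r[1] - r[0] + 1
        if r[2] == -1 or n < max(4, config.min_segment_frames + 1):
            out.append(r)
            continue
        p = pos[r[0]:r[1] + 1]
        d = np.diff(p)
        dev = d - np.median(d)
        sd = 1.4826 * float(np.median(np.abs(dev - np.median(dev))))
        thr = max(0.5 * config.min_event_displacement, 6.0 * sd)
        drop = dev < -thr
        drop[0] = drop[-1] = False  # edge drops belong to boundary refinement
        if not drop.any():
            out.append(r)
            continue
        # a flagged diff i is a drop between frames i and i+1: the dip run
        # starts at frame i+1; consecutive flagged diffs extend it
        start = r[0]
        for i0, i1, lab in _label_runs(drop.astype(int)):
            if lab != 1:
                continue
            a, b = r[0] + i0 + 1, r[0] + i1 + 1
            if a - 1 >= start:
                out.append([start, a - 1, r[2]])
            out.append([a, b, -1])
            start = b + 1
        if start <= r[1]:
            out.append([start, r[1], r[2]])
    return out


def _interval_sse(times: np.ndarray, pos: np.ndarray):
    """O(1) straight-line SSE on any half-open frame interval, via prefix
    sums.  Returns sse(a, b) accepting scalar or array bounds."""
    t = times - times[0]
    p = pos
    z = np.zeros(1)
    St = np.concatenate([z, np.cumsum(t)])
    Stt = np.concatenate([z, np.cumsum(t * t)])
    Sp = np.concatenate([z, np.cumsum(p)])
    Stp = np.concatenate([z, np.cumsum(t * p)])
    Spp = np.concatenate([z, np.cumsum(p * p)])

    def sse(a, b):
        a = np.asarray(a)
        b = np.asarray(b)
        n = (b - a).astype(float)
        st = St[b] - St[a]
        stt = Stt[b] - Stt[a]
        sp = Sp[b] - Sp[a]
        stp = Stp[b] - Stp[a]
        spp = Spp[b] - Spp[a]
        with np.errstate(divide="ignore", invalid="ignore"):
            ctt = stt - st * st / n
            ctp = stp - st * sp / n
            cpp = spp - sp * sp / n
            out = np.where(ctt > 1e-300, cpp - ctp * ctp / np.maximum(ctt, 1e-300), cpp)
        return np.maximum(out, 0.0)

    def slope(a, b):
        n = float(b - a)
        st = St[b] - St[a]
        stt = Stt[b] - Stt[a]
        sp = Sp[b] - Sp[a]
        stp = Stp[b] - Stp[a]
        ctt = stt - st * st / n
        return (stp - st * sp / n) / ctt * 60.0 if ctt > 0 else 0.0

    return sse, slope


def _recover_pauses(
    runs: list[list[int]], times: np.ndarray, pos: np.ndarray, config: SegConfig,
    _depth: int = 0,
) -> list[list[int]]:
    """Insert pauses that frame-velocity thresholding merged into a moving run.

    A pause of a few frames inside a growth (or shrink) phase offsets the
    entire subsequent trace from the single-line fit, so an exhaustive
    two-changepoint least-squares search detects it far below the velocity
    noise floor.  The middle piece must last at least ``min_segment_frames``
    and have a slope inside the pause band; the split must lower the squared
    residual by a margin scaled to the residual noise (BIC-like), so pure
    noise does not fragment genuine runs.
    """
    out: list[list[int]] = []
    for r in runs:
        n = r[1] - r[0] + 1
        m = config.min_segment_frames
        if r[2] == 0 or n < 2 * m + m or _depth > 4:
            out.append(r)
            continue
        t = times[r[0]:r[1] + 1]
        p = pos[r[0]:r[1] + 1]
        sse, slope = _interval_sse(t, p)
        sse0 = float(sse(0, n))
        # candidate middles [i, i+L) with flanks >= m frames; longer pauses
        # survive velocity classification on their own, so cap the search
        best = (np.inf, -1, -1)
        for L in range(m, min(max(4 * m, 20), n - 2 * m) + 1):
            I = np.arange(m, n - m - L + 1)
            if I.size == 0:
                continue
            total = sse(np.zeros_like(I), I) + sse(I, I + L) + sse(I + L, np.full_like(I, n))
            k = int(np.argmin(total))
            if total[k] < best[0]:
                best = (float(total[k]), int(I[k]), int(I[k]) + L)
        sse1, i, j = best
        if i < 0:
            out.append(r)
            continue
        dof = max(n - 6, 1)
        sigma2 = sse1 / dof
        significant = (sse0 - sse1) > max(10.0 * np.log(n) * sigma2, 1e-9)
        mid_slope = slope(i, j)
        if significant and abs(mid_slope) <= config.pause_speed_threshold:
            left = [r[0], r[0] + i - 1, r[2]]
            middle = [r[0] + i, r[0] + j - 1, 0]
            right = [r[0] + j, r[1], r[2]]
            out.extend(_recover_pauses([left], times, pos, config, _depth + 1))
            out.append(middle)
            out.extend(_recover_pauses([right], times, pos, config, _depth + 1))
        else:
            out.append(r)
    return out


def _refine_boundaries(
    runs: list[list[int]], times: np.ndarray, pos: np.ndarray, halfwidth: int
) -> None:
    """Shift each run boundary within +/-(halfwidth+1) frames to minimize the
    total squared residual of straight-line fits on the two sides (in place).

    Smoothing before classification smears boundaries by up to the smoothing
    half-width; this local changepoint fit restores them, which matters most
    for steep shrink phases whose slopes a single contaminating frame skews.
    """
    w = halfwidth + 1
    for k in range(len(runs) - 1):
        a, b = runs[k], runs[k + 1]
        b0 = b[0]
        lo = max(a[0] + 2, b0 - w)
        hi = min(b[1], b0 + w)
        if lo > hi:
            continue
        best_c, best_cost = b0, np.inf
        for c in range(lo, hi + 1):
            cost = _sse(times[a[0]:c], pos[a[0]:c]) + _sse(times[c:b[1] + 1], pos[c:b[1] + 1])
            if cost < best_cost - 1e-12 or (
                abs(cost - best_cost) <= 1e-12 and abs(c - b0) < abs(best_c - b0)
            ):
                best_cost, best_c = cost, c
        a[1] = best_c - 1
        b[0] = best_c


def _segment_chunk(
    times: np.ndarray, pos: np.ndarray, config: SegConfig
) -> list[PhaseSegment]:
    dt = float(np.median(np.diff(times)))
    smoothed = _smooth_positions(pos, config.smoothing_halfwidth)
    w = 2 * config.velocity_halfwidth + 1
    if smoothed.size > w >= 3:
        v = savgol_filter(smoothed, w, polyorder=1, deriv=1, delta=dt) * 60.0
    else:
        v = np.gradient(smoothed, times) * 60.0  # um/min
    runs = _label_runs(_classify(v, config.pause_speed_threshold))
    runs = _merge_short_runs(runs, config.min_segment_frames, pos,
                             config.min_event_displacement)
    runs = _recover_dips(runs, times, pos, config)
    _refine_boundaries(runs, times, pos,
                       config.velocity_halfwidth + config.smoothing_halfwidth + 3)

    # relabel by fitted slope and merge same-state neighbors until stable;
    # leaving the current label requires clearing the band by 50% (hysteresis)
    # so position noise does not flip marginal runs
    for _ in range(5):
        for r in runs:
            slope = _run_slope(times, pos, r, config.min_segment_frames)
            thr_out = 1.5 * config.pause_speed_threshold
            if r[2] == 0:
                if slope > thr_out:
                    r[2] = 1
                elif slope < -thr_out:
                    r[2] = -1
            else:
                if abs(slope) <= config.pause_speed_threshold:
                    r[2] = 0
                elif slope > config.pause_speed_threshold:
                    r[2] = 1
                else:
                    r[2] = -1
        merged = []
        for r in runs:
            if merged and merged[-1][2] == r[2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        if len(merged) == len(runs):
            runs = merged
            break
        runs = merged

    runs = _recover_pauses(runs, times, pos, config)

    name = {1: ST_GROWTH, 0: ST_PAUSE, -1: ST_SHRINK}
    segments = []
    for k, r in enumerate(runs):
        t_start = times[r[0]]
        if k + 1 < len(runs):
            # boundary frame belongs to the later segment (half-open intervals)
            t_end = times[runs[k + 1][0]]
        else:
            t_end = times[r[1]] if r[1] > r[0] else times[r[0]] + dt
        slope = _run_slope(times, pos, r, config.min_segment_frames)
        if t_end > t_start:
            segments.append(PhaseSegment(state=name[r[2]], t_start=float(t_start),
                                         t_end=float(t_end), slope=slope))
    return segments


def segment_trace(trace: Trace, config: SegConfig | None = None) -> list[PhaseSegment]:
    """Partition a tip trace into growth / pause / shrink segments.

    Per-frame velocities (central differences of a lightly smoothed trace)
    are thresholded, runs shorter than ``min_segment_frames`` merged into the
    longer neighbor, boundaries refined by local least-squares changepoint
    fits, and each segment's slope refit on the raw positions.  Missing
    positions are bridged by linear interpolation when the gap is shorter
    than ``min_segment_frames``; longer gaps split the trace.
    """
    config = config or SegConfig()
    times = trace.frame_times
    pos = trace.positions.copy()
    present = ~np.isnan(pos)
    if np.count_nonzero(present) < 2 * config.min_segment_frames:
        raise TraceError("trace too short (or too sparse) to segment")

    # bridge short interior gaps
    nan_runs = _label_runs(np.isnan(pos).astype(int))
    for i0, i1, lab in nan_runs:
        if lab == 1 and i0 > 0 and i1 < pos.size - 1 and (i1 - i0 + 1) < config.min_segment_frames:
            pos[i0:i1 + 1] = np.interp(times[i0:i1 + 1],
                                       [times[i0 - 1], times[i1 + 1]],
                                       [pos[i0 - 1], pos[i1 + 1]])
    # split into contiguous chunks on the remaining gaps
    segments: list[PhaseSegment] = []
    chunk_runs = _label_runs(np.isnan(pos).astype(int))
    for i0, i1, lab in chunk_runs:
        if lab == 1:
            continue
        if (i1 - i0 + 1) < max(2, config.min_segment_frames):
            continue
        segments.extend(_segment_chunk(times[i0:i1 + 1], pos[i0:i1 + 1], config))
    if not segments:
        raise TraceError("no segmentable data in trace")
    return segments


# ---------------------------------------------------------------------------
# lifetimes

def _resolve_tolerance(config: SegConfig, trace: Trace) -> float:
    if config.seed_return_tolerance is not None:
        return config.seed_return_tolerance
    if trace.calibration is not None:
        return trace.calibration.pixel_size
    return 0.107


def split_lifetimes(
    segments: list[PhaseSegment],
    trace: Trace,
    config: SegConfig | None = None,
) -> list[LifetimeRecord]:
    """Group segments into per-microtubule lifetimes.

    A lifetime opens during a growth segment at the frame where the tip
    first exceeds ``min_excursion`` (the opening growth segment is clipped
    to start there); it closes when a shrink segment ends with the tip back
    within ``seed_return_tolerance`` of the seed.  A trace (or contiguous
    chunk) ending before closure yields a censored record.
    """
    config = config or SegConfig()
    tol = _resolve_tolerance(config, trace)
    times = trace.frame_times
    pos = trace.positions

    def frame_slice(seg: PhaseSegment) -> np.ndarray:
        i0 = int(np.searchsorted(times, seg.t_start - 1e-6))
        i1 = int(np.searchsorted(times, seg.t_end - 1e-6))
        return pos[i0:max(i1, i0 + 1)]

    def end_position(seg: PhaseSegment) -> float:
        # the segment covers [t_start, t_end); its spatial endpoint is the
        # boundary frame at t_end (owned by the next segment)
        i = min(int(np.searchsorted(times, seg.t_end - 1e-6)), times.size - 1)
        p = pos[i]
        return p if not np.isnan(p) else np.nan

    records: list[LifetimeRecord] = []
    open_segs: list[PhaseSegment] | None = None
    prev_end: float | None = None
    for seg in segments:
        contiguous = prev_end is not None and abs(seg.t_start - prev_end) < 1e-6
        if open_segs is not None and not contiguous:
            # chunk boundary while a lifetime is open: censored at the gap
            records.append(LifetimeRecord(open_segs, open_segs[0].t_start,
                                          open_segs[-1].t_end, censored=True))
            open_segs = None
        prev_end = seg.t_end
        if open_segs is None:
            if seg.state != ST_GROWTH:
                continue
            i0 = int(np.searchsorted(times, seg.t_start - 1e-6))
            i1 = int(np.searchsorted(times, seg.t_end - 1e-6))
            frames = np.arange(i0, max(i1, i0 + 1))
            above = frames[(~np.isnan(pos[frames])) & (pos[frames] > config.min_excursion)]
            if above.size == 0:
                continue
            t_nuc = float(times[above[0]])
            first = PhaseSegment(state=seg.state, t_start=min(t_nuc, seg.t_end - 1e-9),
                                 t_end=seg.t_end, slope=seg.slope)
            open_segs = [first]
        else:
            open_segs.append(seg)
        p_end = end_position(seg)
        if seg.state == ST_SHRINK and not np.isnan(p_end) and p_end <= tol:
            # close where the terminal shrink leaves the observable zone
            # (symmetric with the opening rule): shrink time below
            # min_excursion cannot contribute observable rescues
            i0 = int(np.searchsorted(times, seg.t_start - 1e-6))
            i1 = min(int(np.searchsorted(times, seg.t_end - 1e-6)), times.size - 1)
            frames = np.arange(i0, i1 + 1)
            below = frames[(~np.isnan(pos[frames])) & (pos[frames] <= config.min_excursion)]
            t_close = float(times[below[0]]) if below.size else seg.t_end
            # keep at least one frame of terminal shrink so the record's
            # closing segment has a representable duration
            dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
            t_close = max(t_close, min(seg.t_start + dt, seg.t_end))
            last = PhaseSegment(state=seg.state, t_start=seg.t_start,
                                t_end=t_close, slope=seg.slope)
            open_segs[-1] = last
            records.append(LifetimeRecord(open_segs, open_segs[0].t_start,
                                          t_close, censored=False))
            open_segs = None
    if open_segs is not None:
        records.append(LifetimeRecord(open_segs, open_segs[0].t_start,
                                      open_segs[-1].t_end, censored=True))
    for rec in records:
        rec.validate()
    return records


# ---------------------------------------------------------------------------
# ground-truth routes (continuous time, no discretization)

def segments_from_truth(path: StatePath, params: DynamicsParameters) -> list[PhaseSegment]:
    """Exact segments from a simulated state path (BARE episodes excluded)."""
    slope = {GROWTH: params.v_g, SHRINK: -params.v_s, PAUSE: 0.0}
    return [
        PhaseSegment(state=_STATE_NAME[s], t_start=t0, t_end=t1, slope=slope[s])
        for s, t0, t1 in path.episodes
        if s != BARE
    ]


def lifetimes_from_truth(path: StatePath, params: DynamicsParameters) -> list[LifetimeRecord]:
    """Exact lifetimes from a simulated state path.

    A lifetime runs from a growth episode starting at zero length to the end
    of the shrink episode that returns the length to zero (followed by BARE);
    a path ending mid-lifetime yields a censored record.
    """
    per_s = 1.0 / 60.0
    speed = {GROWTH: params.v_g * per_s, SHRINK: -params.v_s * per_s, PAUSE: 0.0, BARE: 0.0}
    name_slope = {GROWTH: params.v_g, SHRINK: -params.v_s, PAUSE: 0.0}
    records: list[LifetimeRecord] = []
    open_segs: list[PhaseSegment] | None = None
    L = 0.0
    for state, t0, t1 in path.episodes:
        L_end = max(L + speed[state] * (t1 - t0), 0.0)
        if state == BARE:
            if open_segs:  # should have been closed by the preceding shrink
                records.append(LifetimeRecord(open_segs, open_segs[0].t_start,
                                              open_segs[-1].t_end, censored=True))
                open_segs = None
            L = 0.0
            continue
        seg = PhaseSegment(state=_STATE_NAME[state], t_start=t0, t_end=t1,
                           slope=name_slope[state])
        if open_segs is None:
            if state == GROWTH:
                open_segs = [seg]
        else:
            open_segs.append(seg)
        if open_segs is not None and state == SHRINK and L_end <= 1e-9:
            records.append(LifetimeRecord(open_segs, open_segs[0].t_start, t1,
                                          censored=False))
            open_segs = None
        L = L_end
    if open_segs is not None:
        records.append(LifetimeRecord(open_segs, open_segs[0].t_start,
                                      open_segs[-1].t_end, censored=True))
    for rec in records:
        rec.validate()
    return records
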