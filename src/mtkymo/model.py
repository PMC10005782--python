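"""Stochastic three-state model of microtubule dynamic instability.

The plus end of a seed-anchored microtubule switches between growth (G),
pause (P) and shrinkage (S) as a continuous-time Markov chain with first-order
transition rates (min^-1).  Growth adds length at ``v_g`` (um/min), shrinkage
removes it at ``v_s``; a pausing end does not move.  Shrinkage is truncated
when the length returns to the stabilized seed, after which the bare seed
renucleates a new microtubule with exponential waiting time (rate ``k_nuc``).
Sampling is exact (event-driven); discretization happens only when a
continuous path is sampled onto the camera's frame grid.

This module is the synthetic stand-in for a TIRF assay in which microtubules
polymerize from GMPCPP-stabilized seeds and are imaged in two channels
(lattice / seed) every 3 s for 20 min at ~23 degC.  It also provides the
closed-form long-run expectations of the per-microtubule statistics
(catastrophe frequency, rescue frequency, pause fraction) that serve as
oracles for the estimators in :mod:`mtkymo.stats`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

GROWTH = "G"
PAUSE = "P"
SHRINK = "S"
BARE = "BARE"

_TIME_ATOL = 1e-9  # episode tiling tolerance, seconds


class ModelError(ValueError):
    """Invalid model parameters or simulation preconditions."""


@dataclass(frozen=True)
class Calibration:
    """Spatio-temporal calibration of an acquisition.

    frame_interval
        Seconds between frames (default 3 s, the assay's acquisition rate).
    pixel_size
        Micrometers per pixel (default 0.107 um, a typical TIRF value).
    """

    frame_interval: float = 3.0
    pixel_size: float = 0.107

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ModelError("frame_interval and pixel_size must be positive")


@dataclass(frozen=True)
class DynamicsParameters:
    """Rates and speeds of the three-state instability model.

    Speeds in um/min, rates in min^-1.  ``k_xy`` is the transition rate from
    state x to state y with g=growth, p=pause, s=shrinkage.  ``k_nuc`` is the
    renucleation rate from a bare seed; ``seed_length`` the stabilized seed
    length in um (used for rendering; tip lengths are measured beyond it).
    """

    v_g: float
    v_s: float
    k_gs: float = 0.0
    k_gp: float = 0.0
    k_pg: float = 0.0
    k_ps: float = 0.0
    k_sg: float = 0.0
    k_sp: float = 0.0
    k_nuc: float = 3.0
    seed_length: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v_g", "v_s", "k_gs", "k_gp", "k_pg", "k_ps", "k_sg", "k_sp"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be non-negative")
        if self.k_nuc <= 0:
            raise ModelError("k_nuc must be strictly positive")
        if self.seed_length <= 0:
            raise ModelError("seed_length must be strictly positive")
        # A shrinking end that cannot move (v_s = 0) and cannot leave S would
        # trap the chain in a state where simulated time cannot advance past
        # the seed boundary; reject such rate vectors outright.
        if (self.k_gs > 0 or self.k_ps > 0) and self.v_s == 0 and self.k_sg + self.k_sp == 0:
            raise ModelError(
                "shrinkage is reachable (k_gs or k_ps > 0) but inescapable: "
                "v_s = 0 and k_sg + k_sp = 0"
            )

    def exit_rate(self, state: str) -> float:
        return {
            GROWTH: self.k_gs + self.k_gp,
            PAUSE: self.k_pg + self.k_ps,
            SHRINK: self.k_sg + self.k_sp,
            BARE: self.k_nuc,
        }[state]


#: Illustrative control condition (the assay reports no rate constants, so
#: these are chosen to give realistic episode durations at 3 s / 20 min
#: imaging: catastrophe-limited growth, short rare pauses, frequent rescue).
BASELINE_PARAMS = DynamicsParameters(
    v_g=1.2, v_s=5.0,
    k_gs=0.25, k_gp=0.10, k_pg=3.0, k_ps=0.40, k_sg=1.3, k_sp=0.1,
    k_nuc=3.0, seed_length=1.0,
)

#: Gentler rate set (longer episodes, slower shrinkage) used when validating
#: the image pipeline end to end, where every phase must span several frames.
PIPELINE_VALIDATION_PARAMS = DynamicsParameters(
    v_g=1.2, v_s=4.0,
    k_gs=0.20, k_gp=0.08, k_pg=0.70, k_ps=0.08, k_sg=1.2, k_sp=0.1,
    k_nuc=2.0, seed_length=1.0,
)


def bhc_like(
    params: DynamicsParameters = BASELINE_PARAMS,
    pause_entry_factor: float = 25.0,
    pause_exit_factor: float = 0.5,
) -> DynamicsParameters:
    """Pause-promoting variant of ``params``.

    Scales the pause-entry rates (k_gp, k_sp) up and the pause-exit rates
    (k_pg, k_ps) down, emulating the synergistic pause promotion seen when
    the full BUB-1/HCP-1/CLS-2 module decorates the lattice.
    """
    return dataclasses.replace(
        params,
        k_gp=params.k_gp * pause_entry_factor,
        k_sp=params.k_sp * pause_entry_factor,
        k_pg=params.k_pg * pause_exit_factor,
        k_ps=params.k_ps * pause_exit_factor,
    )


@dataclass
class StatePath:
    """Exact continuous-time path: ordered (state, t_start, t_end) episodes
    tiling [0, total_duration] (seconds)."""

    episodes: list[tuple[str, float, float]]
    total_duration: float

    def validate(self) -> None:
        if not self.episodes:
            raise ModelError("empty state path")
        t = 0.0
        for state, t0, t1 in self.episodes:
            if state not in (GROWTH, PAUSE, SHRINK, BARE):
                raise ModelError(f"unknown state {state!r}")
            if not np.isclose(t0, t, atol=_TIME_ATOL):
                raise ModelError("episodes do not tile the duration")
            if t1 <= t0:
                raise ModelError("episode with non-positive duration")
            t = t1
        if not np.isclose(t, self.total_duration, atol=_TIME_ATOL):
            raise ModelError("episodes do not sum to total_duration")

    def state_times(self) -> dict[str, float]:
        """Total seconds spent in each state."""
        out = {GROWTH: 0.0, PAUSE: 0.0, SHRINK: 0.0, BARE: 0.0}
        for state, t0, t1 in self.episodes:
            out[state] += t1 - t0
        return out

    def transition_counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for (s0, *_), (s1, *_) in zip(self.episodes, self.episodes[1:]):
            out[(s0, s1)] = out.get((s0, s1), 0) + 1
        return out


@dataclass
class Trajectory:
    """Tip length (um beyond the seed) sampled on a uniform frame grid."""

    frame_times: np.ndarray
    lengths: np.ndarray
    calibration: Calibration
    truth: StatePath | None = None
    seed_length: float = 1.0
    mt_id: str | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.frame_times.shape != self.lengths.shape:
            raise ModelError("frame_times and lengths must have equal length")
        if np.any(self.lengths < 0):
            raise ModelError("lengths must be non-negative")


@dataclass(frozen=True)
class OpticsConfig:
    """Rendering settings for synthetic two-channel kymographs.

    Intensities are arbitrary camera units; ``psf_sigma`` is the Gaussian
    blur (pixels) standing in for the microscope PSF along the line; the
    lattice signal-to-noise ratio is lattice_intensity / noise_sigma.
    """

    psf_sigma: float = 1.3
    lattice_intensity: float = 100.0
    seed_intensity: float = 160.0
    background_level: float = 20.0
    noise_sigma: float = 0.0
    roi_length: int = 256

    def __post_init__(self) -> None:
        for name in ("psf_sigma", "lattice_intensity", "seed_intensity",
                     "background_level", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be non-negative")
        if self.roi_length <= 0:
            raise ModelError("roi_length must be a positive integer")


@dataclass
class KymographImage:
    """Two-channel time x position intensity raster.

    ``channels`` maps channel name -> 2-D array with rows = time frames and
    columns = position pixels; all channels share dimensions.  Standard
    channels are ``lattice`` (dynamic polymer) and ``seed`` (static GMPCPP
    seed band at the left edge; position origin for tip measurements is the
    distal end of that band).
    """

    channels: dict[str, np.ndarray]
    calibration: Calibration

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ModelError(f"channels differ in shape: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ModelError(f"non-finite intensities in channel {name!r}")
            self.channels[name] = arr

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def n_positions(self) -> int:
        return next(iter(self.channels.values())).shape[1]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_state_path(
    params: DynamicsParameters,
    duration: float,
    rng_seed,
    start_state: str = GROWTH,
) -> StatePath:
    """Exact event-driven sample of the instability chain over ``duration`` s.

    The chain starts in ``start_state`` with zero seed-relative length.
    Shrinkage episodes are truncated when the length reaches the seed, after
    which a BARE episode with exponential(k_nuc) waiting precedes renewed
    growth.  Reproducible for a fixed integer seed.
    """
    if duration <= 0:
        raise ModelError("duration must be positive")
    if start_state not in (GROWTH, PAUSE, SHRINK, BARE):
        raise ModelError(f"invalid start state {start_state!r}")
    rng = _as_rng(rng_seed)
    # rates are per minute, path times are in seconds
    per_s = 1.0 / 60.0
    out_rates = {
        GROWTH: ((PAUSE, params.k_gp * per_s), (SHRINK, params.k_gs * per_s)),
        PAUSE: ((GROWTH, params.k_pg * per_s), (SHRINK, params.k_ps * per_s)),
        SHRINK: ((GROWTH, params.k_sg * per_s), (PAUSE, params.k_sp * per_s)),
    }
    v_g = params.v_g * per_s  # um/s
    v_s = params.v_s * per_s

    episodes: list[tuple[str, float, float]] = []
    t = 0.0
    length = 0.0
    state = start_state
    while t < duration - _TIME_ATOL:
        if state == BARE:
            dt = rng.exponential(60.0 / params.k_nuc)
            t1 = min(t + dt, duration)
            episodes.append((BARE, t, t1))
            t = t1
            state = GROWTH
            continue
        rates = out_rates[state]
        total = rates[0][1] + rates[1][1]
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        if state == SHRINK:
            t_hit = length / v_s if v_s > 0 else np.inf
            if t_hit <= dt:
                # depolymerized back to the seed before any transition
                t1 = min(t + t_hit, duration)
                if t1 > t:
                    episodes.append((SHRINK, t, t1))
                length = max(0.0, length - v_s * (t1 - t))
                t = t1
                if t >= duration - _TIME_ATOL:
                    break
                length = 0.0
                state = BARE
                continue
        t1 = min(t + dt, duration)
        episodes.append((state, t, t1))
        if state == GROWTH:
            length += v_g * (t1 - t)
        elif state == SHRINK:
            length -= v_s * (t1 - t)
        t = t1
        if t >= duration - _TIME_ATOL:
            break
        u = rng.uniform(0.0, total)
        state = rates[0][0] if u < rates[0][1] else rates[1][0]
    path = StatePath(episodes=episodes, total_duration=duration)
    path.validate()
    return path


def path_lengths(path: StatePath, params: DynamicsParameters, times: np.ndarray) -> np.ndarray:
    """Seed-relative length (um) at arbitrary times, by piecewise integration."""
    per_s = 1.0 / 60.0
    speed = {GROWTH: params.v_g * per_s, SHRINK: -params.v_s * per_s, PAUSE: 0.0, BARE: 0.0}
    times = np.asarray(times, dtype=float)
    lengths = np.zeros_like(times)
    L0 = 0.0
    for i, (state, t0, t1) in enumerate(path.episodes):
        last = i == len(path.episodes) - 1
        if last:
            mask = (times >= t0 - _TIME_ATOL) & (times <= t1 + _TIME_ATOL)
        else:
            mask = (times >= t0 - _TIME_ATOL) & (times < t1 - _TIME_ATOL)
        if state == BARE:
            lengths[mask] = 0.0
            L0 = 0.0
            continue
        lengths[mask] = L0 + speed[state] * (times[mask] - t0)
        L0 += speed[state] * (t1 - t0)
        if state == SHRINK and L0 < _TIME_ATOL:
            L0 = 0.0
    return np.clip(lengths, 0.0, None)


def path_to_trajectory(
    path: StatePath,
    params: DynamicsParameters,
    calib: Calibration | None = None,
    mt_id: str | None = None,
) -> Trajectory:
    """Sample the integrated length of ``path`` on the camera frame grid."""
    calib = calib or Calibration()
    path.validate()
    n_frames = int(np.floor(path.total_duration / calib.frame_interval + _TIME_ATOL)) + 1
    times = np.arange(n_frames) * calib.frame_interval
    lengths = path_lengths(path, params, times)
    return Trajectory(
        frame_times=times,
        lengths=lengths,
        calibration=calib,
        truth=path,
        seed_length=params.seed_length,
        mt_id=mt_id,
    )


def render_kymograph(
    traj: Trajectory,
    optics: OpticsConfig | None = None,
    rng_seed=0,
) -> KymographImage:
    """Render a trajectory as a two-channel kymograph raster.

    The seed channel is a static band covering the seed pixels; the lattice
    channel covers [seed end, current tip] with sub-pixel tip coverage.  Both
    are blurred with ``psf_sigma``, offset by the background level, and (if
    ``noise_sigma > 0``) perturbed by i.i.d. Gaussian camera noise.
    """
    optics = optics or OpticsConfig()
    rng = _as_rng(rng_seed)
    calib = traj.calibration
    seed_px = traj.seed_length / calib.pixel_size
    x_tip = seed_px + traj.lengths / calib.pixel_size  # continuous tip column
    margin = 2.0 + 4.0 * optics.psf_sigma
    if np.max(x_tip) + margin > optics.roi_length:
        raise ModelError(
            f"trajectory (max tip column {np.max(x_tip):.1f} + margin {margin:.1f}) "
            f"exceeds roi_length {optics.roi_length}"
        )
    cols = np.arange(optics.roi_length, dtype=float)
    # per-pixel lattice coverage: pixel j covers [j, j+1); the lattice spans
    # [seed_px, x_tip] in continuous column coordinates
    cov = np.clip(
        np.minimum(x_tip[:, None], cols[None, :] + 1.0)
        - np.maximum(cols[None, :], seed_px),
        0.0,
        1.0,
    )
    lattice = optics.lattice_intensity * cov
    seed_cov = np.clip(seed_px - cols, 0.0, 1.0)
    seed = np.broadcast_to(optics.seed_intensity * seed_cov, lattice.shape).copy()
    if optics.psf_sigma > 0:
        lattice = gaussian_filter1d(lattice, optics.psf_sigma, axis=1, mode="nearest")
        seed = gaussian_filter1d(seed, optics.psf_sigma, axis=1, mode="nearest")
    lattice += optics.background_level
    seed += optics.background_level
    if optics.noise_sigma > 0:
        lattice = lattice + rng.normal(0.0, optics.noise_sigma, size=lattice.shape)
        seed = seed + rng.normal(0.0, optics.noise_sigma, size=seed.shape)
    return KymographImage(channels={"lattice": lattice, "seed": seed}, calibration=calib)


def fit_roi(traj: Trajectory, optics: OpticsConfig | None = None) -> OpticsConfig:
    """Return ``optics`` with roi_length just large enough for ``traj``."""
    optics = optics or OpticsConfig()
    calib = traj.calibration
    seed_px = traj.seed_length / calib.pixel_size
    need = int(np.ceil(seed_px + np.max(traj.lengths) / calib.pixel_size
                       + 3.0 + 4.0 * optics.psf_sigma)) + 4
    return dataclasses.replace(optics, roi_length=max(need, 64))


@dataclass(frozen=True)
class ExpectedDynamics:
    """Closed-form long-run statistics of an irreducible rate set."""

    f_cat: float          # catastrophes per minute of growth-excursion time
    f_res: float          # rescues per minute of shrinkage time
    pause_fraction: float  # long-run fraction of polymer time spent paused
    occupancy: dict[str, float] = field(default_factory=dict)


def stationary_occupancy(params: DynamicsParameters) -> dict[str, float]:
    """Stationary occupancies of the chain restricted to {G, P, S}.

    Ignores the seed boundary and renucleation (valid in the long-microtubule
    limit).  States unreachable from growth (e.g. pause in a two-state
    model) simply carry zero occupancy; the reachable class itself must be
    strongly connected or the limiting occupancies are undefined.
    """
    Q = np.array([
        [-(params.k_gs + params.k_gp), params.k_gp, params.k_gs],
        [params.k_pg, -(params.k_pg + params.k_ps), params.k_ps],
        [params.k_sg, params.k_sp, -(params.k_sg + params.k_sp)],
    ])
    adj = (Q > 0).astype(int)
    reach = np.linalg.matrix_power(adj + np.eye(3, dtype=int), 3) > 0
    keep = np.nonzero(reach[0])[0]  # states reachable from G (including G)
    if not reach[np.ix_(keep, keep)].all():
        raise ModelError("states reachable from growth do not communicate; "
                         "limiting occupancies are undefined")
    Qr = Q[np.ix_(keep, keep)]
    # exits toward unreachable states are impossible by construction, so the
    # restricted generator rows still sum to zero
    A = np.vstack([Qr.T, np.ones(keep.size)])
    b = np.zeros(keep.size + 1)
    b[-1] = 1.0
    pi_r, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.zeros(3)
    pi[keep] = pi_r
    return {GROWTH: float(pi[0]), PAUSE: float(pi[1]), SHRINK: float(pi[2])}


def expected_dynamics(
    params: DynamicsParameters,
    conventions=None,
) -> ExpectedDynamics:
    """Analytic oracle for the per-condition dynamics statistics.

    ``conventions`` may be a :class:`mtkymo.stats.Conventions` or the
    catastrophe-denominator string itself.  Under the default
    ``excursion_incl_pauses`` convention the catastrophe denominator is all
    non-shrinking polymer time (pi_G + pi_P); under ``growth_only`` it is
    pi_G alone.  The rescue frequency is the total exit rate from shrinkage.
    """
    denom_conv = getattr(conventions, "catastrophe_denominator", conventions)
    denom_conv = denom_conv or "excursion_incl_pauses"
    pi = stationary_occupancy(params)
    cat_flux = pi[GROWTH] * params.k_gs + pi[PAUSE] * params.k_ps
    if denom_conv == "excursion_incl_pauses":
        denom = pi[GROWTH] + pi[PAUSE]
    elif denom_conv == "growth_only":
        denom = pi[GROWTH]
    else:
        raise ModelError(f"unknown catastrophe denominator {denom_conv!r}")
    return ExpectedDynamics(
        f_cat=cat_flux / denom,
        f_res=params.k_sg + params.k_sp,
        pause_fraction=pi[PAUSE],
        occupancy=pi,
    )


def mt_rng(master_seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-microtubule RNG stream.

    Streams are derived from ``SeedSequence(master_seed, spawn_key=(index,
    stream))`` so condition-level results are reproducible and independent of
    simulation order; stream 0 is used for path sampling, stream 1 for
    rendering noise.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index, stream)))


def simulate_condition(
    params: DynamicsParameters,
    n_mt: int,
    duration: float = 1200.0,
    calib: Calibration | None = None,
    master_seed: int = 0,
) -> list[Trajectory]:
    """Simulate ``n_mt`` independent microtubules of ``duration`` seconds.

    Defaults mirror the acquisition settings (3 s frame interval, 20 min
    movies).  Ground-truth state paths are attached to each trajectory.
    """
    if n_mt <= 0:
        raise ModelError("n_mt must be positive")
    calib = calib or Calibration()
    trajs = []
    for i in range(n_mt):
        path = sample_state_path(params, duration, mt_rng(master_seed, i, 0))
        trajs.append(path_to_trajectory(path, params, calib, mt_id=f"mt{i:04d}"))
    return trajs
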