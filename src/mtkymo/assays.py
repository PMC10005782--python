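"""In vivo fluorescence quantifications and the embryonic-viability assay.

Implements the manual-ROI workflow used for oocyte imaging: linescan
intensity profiles along chromosomes, background-corrected integrated
intensity ratios for kinetochore signals, spindle microtubule density and
area measured on sum projections of four z-planes 45 s before anaphase
onset, and the proportion of viable progeny from brood counts.

The correction convention is a ratio, not a subtraction: integrated signal
intensity divided by the *average* background intensity.  On a uniform image
this ratio equals the ROI pixel count, so values are only comparable between
ROIs of similar size — which is why background linescans use the same length
and width as the signal linescan, and spindle background uses the same ROI
shape placed in the cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sampling import RoiError, sample_polyline
from .model import Calibration

__all__ = [
    "RoiSpec",
    "SpindleMetrics",
    "BroodCount",
    "linescan_profile",
    "integrated_ratio",
    "spindle_metrics",
    "synth_spindle",
    "embryonic_viability",
]


class AssayError(ValueError):
    """Invalid assay input."""


@dataclass
class RoiSpec:
    """A measurement region: polyline (with width), rectangle, or mask.

    * polyline — ``vertices`` is a list of (row, col) points, ``width`` the
      averaging width in pixels (odd).
    * rectangle — ``vertices`` is (r0, c0, r1, c1), half-open.
    * mask — ``mask`` is a boolean array matching the image shape.
    """

    kind: str
    vertices: tuple | list | None = None
    mask: np.ndarray | None = None
    width: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("polyline", "rectangle", "mask"):
            raise RoiError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "mask":
            if self.mask is None or not np.any(self.mask):
                raise RoiError("mask ROI must be non-empty")
            self.mask = np.asarray(self.mask, dtype=bool)
        elif self.vertices is None or len(self.vertices) == 0:
            raise RoiError("ROI vertices must be non-empty")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.kind == "mask":
            if self.mask.shape != shape:
                raise RoiError("mask shape does not match image")
            return self.mask
        if self.kind == "rectangle":
            r0, c0, r1, c1 = self.vertices
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise RoiError("rectangle ROI outside image bounds")
            m = np.zeros(shape, dtype=bool)
            m[int(r0):int(r1), int(c0):int(c1)] = True
            return m
        raise RoiError("polyline ROIs sample intensities; they have no pixel mask")

    def pixel_values(self, image: np.ndarray) -> np.ndarray:
        """Sampled intensity values of this ROI on ``image``."""
        image = np.asarray(image, dtype=float)
        if self.kind == "polyline":
            return sample_polyline(image, self.vertices, self.width)
        return image[self.to_mask(image.shape)]


@dataclass
class SpindleMetrics:
    """Spindle density ratio (integrated ROI intensity over mean background)
    and spindle area (um^2) on a sum projection."""

    density_ratio: float
    area: float
    n_zplanes_summed: int

    def __post_init__(self) -> None:
        if self.density_ratio < 0 or self.area < 0:
            raise AssayError("density_ratio and area must be non-negative")


@dataclass(frozen=True)
class BroodCount:
    """Progeny counts from one laying plate."""

    plate_id: str
    n_eggs_l1: int
    n_l4_adults: int

    def __post_init__(self) -> None:
        if self.n_eggs_l1 < 0 or self.n_l4_adults < 0:
            raise AssayError("counts must be non-negative")
        if self.n_l4_adults > self.n_eggs_l1:
            raise AssayError(
                f"plate {self.plate_id}: L4/adults ({self.n_l4_adults}) exceed "
                f"eggs/L1 ({self.n_eggs_l1})"
            )


def linescan_profile(image: np.ndarray, roi: RoiSpec, width: int | None = None) -> np.ndarray:
    """Intensity profile along a polyline ROI, averaged across its width."""
    if roi.kind != "polyline":
        raise RoiError("linescan requires a polyline ROI")
    return sample_polyline(np.asarray(image, dtype=float), roi.vertices,
                           width if width is not None else roi.width)


def integrated_ratio(image: np.ndarray, signal_roi: RoiSpec, noise_roi: RoiSpec) -> float:
    """Integrated signal intensity / average background-noise intensity.

    Dimensionally this is an effective pixel count times the mean
    signal-to-background ratio; it is invariant under multiplicative
    intensity rescaling and only comparable between equal-sized ROIs.
    """
    image = np.asarray(image, dtype=float)
    signal = signal_roi.pixel_values(image)
    noise = noise_roi.pixel_values(image)
    noise_mean = float(np.mean(noise))
    if noise_mean <= 0:
        raise AssayError("background-noise ROI has non-positive mean; ratio undefined")
    return float(np.sum(signal)) / noise_mean


def sum_projection(stack: np.ndarray, frame: int, n_z: int = 4) -> np.ndarray:
    """Sum-project ``n_z`` z-planes of a (T, Z, Y, X) stack at ``frame``."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise AssayError("stack must be 4-D (time, z, y, x)")
    if not (0 <= frame < stack.shape[0]):
        raise AssayError(f"frame {frame} outside stack (T={stack.shape[0]})")
    if stack.shape[1] < n_z:
        raise AssayError(f"stack has {stack.shape[1]} z-planes, {n_z} required")
    z0 = (stack.shape[1] - n_z) // 2
    return stack[frame, z0:z0 + n_z].sum(axis=0)


def spindle_metrics(
    stack: np.ndarray,
    spindle_roi: RoiSpec,
    background_roi: RoiSpec,
    t_anaphase_frame: int,
    calib: Calibration,
    lead_time_s: float = 45.0,
    n_z: int = 4,
) -> SpindleMetrics:
    """Spindle density and area ``lead_time_s`` before anaphase onset.

    Sum-projects ``n_z`` z-planes at the frame nearest
    ``t_anaphase_frame - lead_time_s / frame_interval``; the density ratio is
    the integrated spindle-ROI intensity divided by the mean background-ROI
    intensity on the same projection, and the area is the spindle-ROI pixel
    count scaled by the pixel size squared.
    """
    stack = np.asarray(stack, dtype=float)
    frame = int(round(t_anaphase_frame - lead_time_s / calib.frame_interval))
    if frame < 0:
        raise AssayError(
            f"frame at anaphase - {lead_time_s} s (index {frame}) precedes the movie"
        )
    proj = sum_projection(stack, frame, n_z=n_z)
    signal = spindle_roi.pixel_values(proj)
    noise = background_roi.pixel_values(proj)
    noise_mean = float(np.mean(noise))
    if noise_mean <= 0:
        raise AssayError("background ROI has non-positive mean on the projection")
    density = float(np.sum(signal)) / noise_mean
    area = float(signal.size) * calib.pixel_size ** 2
    return SpindleMetrics(density_ratio=density, area=area, n_zplanes_summed=n_z)


def synth_spindle(
    background_level: float = 10.0,
    spindle_gain: float = 40.0,
    spindle_rect: tuple[int, int, int, int] = (20, 20, 30, 30),
    background_rect: tuple[int, int, int, int] = (40, 40, 50, 50),
    shape: tuple[int, int] = (64, 64),
    n_t: int = 4,
    n_z: int = 4,
    noise: str = "none",
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    calib: Calibration | None = None,
) -> tuple[np.ndarray, SpindleMetrics]:
    """Synthetic (T, Z, Y, X) stack with closed-form ground-truth metrics.

    Every z-plane is uniform background plus an additive rectangle of
    ``spindle_gain`` over the spindle ROI.  Optional noise: ``poisson``
    (counts at the programmed means) or ``gaussian`` with ``noise_sigma``.
    The returned :class:`SpindleMetrics` is the noiseless expectation.
    """
    if background_level < 0 or spindle_gain < 0:
        raise AssayError("intensity levels must be non-negative")
    calib = calib or Calibration()
    rng = np.random.default_rng(rng_seed)
    plane = np.full(shape, background_level, dtype=float)
    r0, c0, r1, c1 = spindle_rect
    plane[r0:r1, c0:c1] += spindle_gain
    stack = np.broadcast_to(plane, (n_t, n_z) + shape).copy()
    if noise == "poisson":
        stack = rng.poisson(stack).astype(float)
    elif noise == "gaussian":
        stack = stack + rng.normal(0.0, noise_sigma, size=stack.shape)
    elif noise != "none":
        raise AssayError(f"unknown noise model {noise!r}")
    n_px = (r1 - r0) * (c1 - c0)
    truth = SpindleMetrics(
        density_ratio=n_px * n_z * (background_level + spindle_gain)
        / (n_z * background_level),
        area=n_px * calib.pixel_size ** 2,
        n_zplanes_summed=n_z,
    )
    return stack, truth


def embryonic_viability(counts: list[BroodCount]) -> pd.DataFrame:
    """Proportion of viable progeny per plate plus a pooled row.

    Per plate: L4/adults divided by eggs/L1.  Pooled: summed adults over
    summed eggs (lies between the per-plate extremes).
    """
    if not counts:
        raise AssayError("no brood counts provided")
    rows = []
    for c in counts:
        if c.n_eggs_l1 == 0:
            raise AssayError(f"plate {c.plate_id}: zero eggs/L1, viability undefined")
        rows.append({"plate_id": c.plate_id, "n_eggs_l1": c.n_eggs_l1,
                     "n_l4_adults": c.n_l4_adults,
                     "viability": c.n_l4_adults / c.n_eggs_l1})
    total_eggs = sum(c.n_eggs_l1 for c in counts)
    total_adults = sum(c.n_l4_adults for c in counts)
    rows.append({"plate_id": "pooled", "n_eggs_l1": total_eggs,
                 "n_l4_adults": total_adults,
                 "viability": total_adults / total_eggs})
    return pd.DataFrame(rows)
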