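"""Shared polyline intensity sampling (kymograph rows, linescans)."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


class RoiError(ValueError):
    """ROI outside image bounds or malformed."""


def polyline_arclength(vertices: np.ndarray) -> float:
    d = np.diff(vertices, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def polyline_coordinates(
    vertices, width: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-spaced sample coordinates along a polyline with perpendicular
    offsets.

    Returns (rows, cols) arrays of shape (n_samples, width).  ``vertices``
    are (row, col) pixel positions; ``width`` must be odd and >= 1.
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 2 or vertices.shape[1] != 2:
        raise RoiError("polyline needs at least two (row, col) vertices")
    if width < 1 or width % 2 == 0:
        raise RoiError("width must be odd and >= 1")
    arc = polyline_arclength(vertices)
    n_samples = max(int(round(arc)) + 1, 2)
    # cumulative arclength parameterization
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.linspace(0.0, arc, n_samples)
    r = np.interp(s, cum, vertices[:, 0])
    c = np.interp(s, cum, vertices[:, 1])
    # unit tangent per sample (from the segment each s falls in)
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tr = seg[seg_idx, 0] / seg_len[seg_idx]
        tc = seg[seg_idx, 1] / seg_len[seg_idx]
    tr = np.nan_to_num(tr)
    tc = np.nan_to_num(tc)
    # perpendicular (normal) direction
    nr, nc = -tc, tr
    offsets = np.arange(width) - width // 2
    rows = r[:, None] + nr[:, None] * offsets[None, :]
    cols = c[:, None] + nc[:, None] * offsets[None, :]
    return rows, cols


def sample_polyline(image: np.ndarray, vertices, width: int = 1) -> np.ndarray:
    """Bilinear intensity profile along a polyline, averaged across width.

    Raises :class:`RoiError` if any vertex lies outside the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise RoiError("image must be 2-D")
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise RoiError("vertices must be (row, col) pairs")
    if np.any(v[:, 0] < 0) or np.any(v[:, 0] > image.shape[0] - 1) or \
       np.any(v[:, 1] < 0) or np.any(v[:, 1] > image.shape[1] - 1):
        raise RoiError("polyline vertex outside image bounds")
    rows, cols = polyline_coordinates(v, width)
    vals = map_coordinates(image, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    return vals.reshape(rows.shape).mean(axis=1)
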