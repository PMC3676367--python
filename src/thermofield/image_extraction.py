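"""Plot temperature extraction from thermal frames.

A plot's temperature in one image (its IPT) is the arithmetic mean of the
pixels whose centres fall inside the plot's canopy polygon, after an
automated quality-control trim.  The QC step replaces the manual inspection
of the per-polygon pixel-temperature histogram: pixels further than ``k`` °C
from the polygon median (hot soil showing through the canopy, or cold sky
reflections) are excluded symmetrically, and the observation is flagged when
the excluded fraction exceeds a threshold.

Point-in-polygon membership uses the even-odd (ray-crossing) rule evaluated
at pixel centres ``(col + 0.5, row + 0.5)`` in 0-based pixel coordinates, so
a polygon covering the full cell ``[0, w] x [0, h]`` contains exactly the
``w x h`` pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trial_design import PlotKey, PlotObservation

__all__ = [
    "QCParams",
    "polygon_mask",
    "qc_outlier_mask",
    "extract_plot_temperature",
    "extract_observations",
]


@dataclass(frozen=True)
class QCParams:
    """Automated histogram-check parameters.

    ``k`` is the symmetric trim half-width around the polygon median (°C);
    ``flag_threshold`` the excluded fraction above which the observation is
    flagged as unreliable (and later dropped by the normaliser).
    """

    k: float = 3.0
    flag_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("QC trim half-width k must be > 0")
        if not 0 < self.flag_threshold <= 1:
            raise ValueError("flag_threshold must be in (0, 1]")


def polygon_mask(polygon: np.ndarray, width: int, height: int) -> np.ndarray:
    """Boolean (height, width) mask of pixels whose centres lie inside.

    Membership is decided by the even-odd rule: a pixel centre is inside iff
    a horizontal ray from it crosses the polygon boundary an odd number of
    times.  Vertices are (x, y) in pixel coordinates.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (n >= 3) x 2 array of (x, y) vertices")
    px = np.arange(width) + 0.5
    py = (np.arange(height) + 0.5)[:, None]
    inside = np.zeros((height, width), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= crosses & (px < x_at)
    return inside


def qc_outlier_mask(pixels: Sequence[float], k: float) -> tuple[np.ndarray, float]:
    """Symmetric median +/- k trim; returns (inclusion mask, excluded fraction).

    Pixels strictly above ``median + k`` or strictly below ``median - k`` are
    excluded — the automated stand-in for spotting outlier lobes in the
    per-polygon temperature histogram.
    """
    values = np.asarray(pixels, dtype=float)
    if values.size == 0:
        raise ValueError("empty pixel list")
    if k <= 0:
        raise ValueError("QC trim half-width k must be > 0")
    med = float(np.median(values))
    include = (values >= med - k) & (values <= med + k)
    if not include.any():
        raise ValueError("QC excluded every pixel")
    return include, float(1.0 - include.mean())


def extract_plot_temperature(
    frame,
    polygon: np.ndarray,
    qc: QCParams = QCParams(),
    plot: PlotKey | None = None,
    image_id: str = "",
) -> PlotObservation:
    """Mean canopy temperature of the polygon's interior pixels after QC.

    Parameters
    ----------
    frame
        A :class:`~thermofield.synthetic_data.ThermalFrame` or a 2-D array of
        temperatures (°C).
    polygon
        (n >= 3) x 2 array of (x, y) vertices, within frame bounds.
    qc
        Trim parameters; see :class:`QCParams`.
    plot, image_id
        Carried through onto the returned observation.

    Raises
    ------
    ValueError
        Degenerate polygon, polygon outside the frame, or no interior pixels.
    """
    pixels2d = np.asarray(getattr(frame, "pixels", frame), dtype=float)
    height, width = pixels2d.shape
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (n >= 3) x 2 array of (x, y) vertices")
    if (poly[:, 0].min() < 0 or poly[:, 0].max() > width
            or poly[:, 1].min() < 0 or poly[:, 1].max() > height):
        raise ValueError("polygon extends outside the frame bounds")
    mask = polygon_mask(poly, width=width, height=height)
    if not mask.any():
        raise ValueError("polygon contains no pixel centres")
    values = pixels2d[mask]
    include, frac = qc_outlier_mask(values, qc.k)
    kept = values[include]
    # mean anchored at the first pixel: exact when all pixels are equal
    ipt = float(kept[0] + math.fsum(kept - kept[0]) / len(kept))
    return PlotObservation(
        plot=plot if plot is not None else PlotKey("", -1, -1),
        image_id=image_id,
        ipt=ipt,
        n_pixels=int(include.sum()),
        n_excluded=int((~include).sum()),
        qc_flag=bool(frac > qc.flag_threshold),
    )


def extract_observations(
    frame,
    polygons: dict[PlotKey, np.ndarray],
    image_id: str,
    qc: QCParams = QCParams(),
) -> list[PlotObservation]:
    """Extract one observation per polygon from a single frame."""
    return [
        extract_plot_temperature(frame, polygons[key], qc=qc, plot=key, image_id=image_id)
        for key in sorted(polygons)
    ]
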