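"""Fluoroscopy-geometry analysis of biplane balloon projections.

The bench acquisition images the balloon under biplane fluoroscopy
(orthogonal AP and LAT projections, 0.5 mm/pixel).  Geometry is
recovered in three steps:

1.  *Calibration*: an arch with four radiopaque beads at known spacings
    provides two reference distances per projection; the scale
    coefficient averages the two single-pair ratios,
    w = b1_real/(2 b1_image) + b2_real/(2 b2_image),
    which halves the effect of beam distortion.
2.  *Contour extraction*: the balloon silhouette is thresholded and its
    half-contour r(z) traced with sub-pixel (linear threshold-crossing)
    interpolation; the revolution axis is the least-squares symmetry
    axis of the silhouette.
3.  *Volumetry*: the calibrated contour is revolved about the axis
    (conical-frusta quadrature) for the volume; the central diameter is
    the full silhouette width at the axial midpoint, averaged over the
    two projections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ContourError, InvalidInputError
from .geometry import InflationProtocol, solid_of_revolution_volume
from .units import mm3_to_ml


@dataclass(frozen=True)
class CalibrationArch:
    """Bead-marker calibration geometry.

    ``b1_real_mm`` / ``b2_real_mm`` are the known projected distances
    between the two bead pairs; ``image_distances`` maps a projection
    label ("AP", "LAT") to the corresponding measured image distances
    (in pixels or any consistent image unit).
    """

    b1_real_mm: float
    b2_real_mm: float
    image_distances: dict

    def __post_init__(self):
        if self.b1_real_mm <= 0.0 or self.b2_real_mm <= 0.0:
            raise InvalidInputError("real bead distances must be positive")
        for proj, (b1, b2) in self.image_distances.items():
            if b1 <= 0.0 or b2 <= 0.0:
                raise InvalidInputError(f"image distances for {proj!r} must be positive")


@dataclass(frozen=True)
class ContourPolyline:
    """Half-contour of one balloon silhouette: axial coordinate and radius.

    ``scale`` is "raw" (image units) until calibrated to mm.
    """

    z: np.ndarray
    r: np.ndarray
    projection: str = "AP"
    time_s: float = 0.0
    scale: str = "raw"  # raw | calibrated

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "r", r)
        if z.ndim != 1 or z.shape != r.shape or z.size < 3:
            raise ContourError("contour needs >= 3 (z, r) points")
        if np.any(r < 0.0):
            raise ContourError("contour radii must be >= 0 after axis alignment")
        if self.scale not in ("raw", "calibrated"):
            raise InvalidInputError("scale must be 'raw' or 'calibrated'")

    def calibrated(self, w: float) -> "ContourPolyline":
        """Return the contour scaled to mm by the calibration coefficient."""
        if self.scale == "calibrated":
            return self
        if w <= 0.0:
            raise InvalidInputError("calibration coefficient must be positive")
        return replace(self, z=self.z * w, r=self.r * w, scale="calibrated")


@dataclass
class ProjectionImage:
    """A synthetic grayscale fluoroscopy projection."""

    pixels: np.ndarray
    pixel_size_mm: float = 0.5
    projection: str = "AP"
    beads_px: list | None = None  # approximate (row, col) seeds of the bead markers

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError("image must be a 2-D grayscale array")
        if self.pixel_size_mm <= 0.0:
            raise InvalidInputError("pixel size must be positive")


def calibration_coefficient(arch: CalibrationArch, projection: str = "AP") -> float:
    """Scale coefficient w (mm per image unit) for one projection.

    w = b1_real/(2 b1_image) + b2_real/(2 b2_image): algebraically the
    mean of the two single-pair mm/image ratios.
    """
    if projection not in arch.image_distances:
        raise InvalidInputError(f"no image distances for projection {projection!r}")
    b1_img, b2_img = arch.image_distances[projection]
    return arch.b1_real_mm / (2.0 * b1_img) + arch.b2_real_mm / (2.0 * b2_img)


def measure_bead_distances(
    image: ProjectionImage, bead_threshold: float = 0.75, min_area: int = 4
) -> tuple[float, float]:
    """Measure the two bead-pair image distances (pixels) from a projection.

    Beads are the brightest structures in the synthetic projections; the
    four blobs above ``bead_threshold`` are located by intensity-weighted
    centroid, the two upper blobs form pair 1 and the two lower blobs
    pair 2 (matching the generator's arch layout).
    """
    mask = image.pixels >= bead_threshold
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = [i + 1 for i, s in enumerate(sizes) if s >= min_area]
    if len(keep) != 4:
        raise ContourError(f"expected 4 bead markers, found {len(keep)}")
    cents = ndimage.center_of_mass(image.pixels, labels, keep)
    cents = sorted(cents, key=lambda rc: rc[0])  # by row: top pair first
    pair1, pair2 = cents[:2], cents[2:]
    b1 = float(np.hypot(pair1[0][0] - pair1[1][0], pair1[0][1] - pair1[1][1]))
    b2 = float(np.hypot(pair2[0][0] - pair2[1][0], pair2[0][1] - pair2[1][1]))
    return b1, b2


def _subpixel_crossing(col: np.ndarray, idx_in: int, step: int, threshold: float) -> float:
    """Linear interpolation of the threshold crossing next to boundary pixel idx_in."""
    j_out = idx_in - step
    if j_out < 0 or j_out >= col.size:
        return float(idx_in)
    v_in, v_out = col[idx_in], col[j_out]
    if v_in == v_out:
        return float(idx_in)
    t = (threshold - v_out) / (v_in - v_out)
    return float(j_out + step * np.clip(t, 0.0, 1.0))


def extract_contour(
    image: ProjectionImage,
    threshold: float = 0.3,
    min_area: float = 40.0,
    projection: str | None = None,
) -> ContourPolyline:
    """Trace the balloon half-contour from a thresholded silhouette.

    The super-threshold region is identified by connected-component
    labelling; specks smaller than ``min_area`` pixels (noise, bead
    markers) are ignored, and zero or multiple remaining regions raise an
    error.  For every image column crossing the region the top and
    bottom silhouette edges are located at sub-pixel accuracy by linear
    interpolation of the threshold crossing, the symmetry axis is the
    least-squares line through the edge midpoints, and the radius is the
    half-width.  Coordinates are returned in raw image units (pixels).
    """
    img = image.pixels
    mask = img >= threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ContourError("no super-threshold region in image")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    big = [i + 1 for i, s in enumerate(sizes) if s >= min_area]
    if len(big) == 0:
        raise ContourError("no super-threshold region larger than min_area")
    if len(big) > 1:
        raise ContourError(f"{len(big)} disconnected super-threshold regions (expected 1)")
    region = labels == big[0]

    cols = np.nonzero(region.any(axis=0))[0]
    z_px, top, bot = [], [], []
    for x in cols:
        rows = np.nonzero(region[:, x])[0]
        j_top, j_bot = int(rows[0]), int(rows[-1])
        col = img[:, x]
        top.append(_subpixel_crossing(col, j_top, 1, threshold))
        bot.append(_subpixel_crossing(col, j_bot, -1, threshold))
        z_px.append(float(x))
    z_px = np.asarray(z_px)
    top = np.asarray(top)
    bot = np.asarray(bot)
    # least-squares symmetry axis (kept for diagnostics; radius uses half-width,
    # which is independent of the axis position)
    mid = 0.5 * (top + bot)
    _axis = np.polyfit(z_px, mid, 1)
    r_px = 0.5 * (bot - top)
    return ContourPolyline(
        z=z_px, r=r_px, projection=projection or image.projection, scale="raw"
    )


def revolve_volume(contour: ContourPolyline, w: float | None = None) -> float:
    """Volume (ml) of the solid of revolution of a (calibrated) contour.

    A raw contour requires the calibration coefficient ``w``; geometric
    scaling makes volume(contour, w) = w^3 * volume(contour, 1).
    """
    if contour.scale == "raw":
        if w is None:
            raise InvalidInputError("raw contour requires a calibration coefficient w")
        contour = contour.calibrated(w)
    return mm3_to_ml(solid_of_revolution_volume(contour.z, contour.r))


def average_initial_volume(
    contour_ap: ContourPolyline,
    contour_lat: ContourPolyline,
    w_ap: float | None = None,
    w_lat: float | None = None,
) -> float:
    """V0 (ml): mean of the AP and LAT revolved volumes of the initial frame."""
    return 0.5 * (revolve_volume(contour_ap, w_ap) + revolve_volume(contour_lat, w_lat))


def central_diameter(contour_ap: ContourPolyline, contour_lat: ContourPolyline) -> float:
    """Balloon diameter (mm): full width at the axial midpoint, AP/LAT average.

    The "central section" is the axial midpoint of each contour's
    bounding box; both contours must be calibrated to mm.
    """
    widths = []
    for c in (contour_ap, contour_lat):
        if c.scale != "calibrated":
            raise InvalidInputError("contours must be calibrated to mm first")
        z_mid = 0.5 * (c.z[0] + c.z[-1])
        if not (c.z[0] <= z_mid <= c.z[-1]):
            raise InvalidInputError("axial midpoint outside contour span")
        widths.append(2.0 * float(np.interp(z_mid, c.z, c.r)))
    return 0.5 * (widths[0] + widths[1])


def volume_timeline(
    v0_ml: float, protocol: InflationProtocol, times_s: np.ndarray
) -> np.ndarray:
    """Injected-volume series V(t) = V0 + Vdot * t at the given instants."""
    if v0_ml <= 0.0:
        raise InvalidInputError("V0 must be positive")
    times_s = np.asarray(times_s, dtype=float)
    return v0_ml + protocol.flow_rate_ml_s * times_s
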