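"""3D single-molecule spot detection in the dye channels.

Each dye stack is Gaussian-smoothed to suppress noise, band-pass filtered
with a (negated) Laplacian of Gaussian so diffraction-limited spots become
positive peaks, binarised at a detection threshold, and each above-threshold
regional maximum is reported as one spot with its xyz voxel position.
Plateau maxima collapse deterministically to a single spot at the rounded
plateau centroid.

Thresholds follow the one-mean-threshold-per-dye-per-sample scheme: a
threshold is derived from one representative plane per image (automatically
from the widest gap in the regional-maxima intensities, or supplied
manually), and the arithmetic mean across images of a sample is applied to
every stack of that sample.

Because the axial sampling (200 nm z-step) is coarser than the lateral
pixel pitch, filter scales are per-axis: ``sigma`` values are given as
(lateral, axial) voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima

__all__ = [
    "Spot",
    "DetectionThreshold",
    "log_filter",
    "aggregate_threshold",
    "detect_spots",
    "auto_threshold",
]


@dataclass(frozen=True)
class Spot:
    """One detected molecule: channel, voxel position and filtered intensity."""

    channel: str
    x: int
    y: int
    z: int
    intensity: float


@dataclass
class DetectionThreshold:
    """Per-image thresholds for one dye and their sample-wide mean."""

    channel: str
    per_image_values: list[float]
    mean_value: float


def _axis_sigmas(sigma: float | tuple[float, float]) -> tuple[float, float, float]:
    """Expand a (lateral, axial) or scalar sigma into (z, y, x) order."""
    if np.isscalar(sigma):
        lateral = axial = float(sigma)
    else:
        lateral, axial = (float(s) for s in sigma)
    if lateral <= 0 or axial <= 0:
        raise ValueError("filter sigmas must be positive")
    return (axial, lateral, lateral)


def log_filter(
    volume: np.ndarray,
    sigma_smooth: float | tuple[float, float] = 1.0,
    sigma_log: float | tuple[float, float] = (1.4, 1.2),
) -> np.ndarray:
    """Gaussian denoising followed by negated Laplacian-of-Gaussian filtering.

    Bright blobs of scale ~``sigma_log`` become positive peaks in the output;
    the response to a constant volume is zero. Sigmas are (lateral, axial)
    voxels to accommodate anisotropic sampling.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    if not np.issubdtype(vol.dtype, np.floating):
        vol = vol.astype(np.float64)
    smoothed = ndimage.gaussian_filter(vol, sigma=_axis_sigmas(sigma_smooth))
    return -ndimage.gaussian_laplace(smoothed, sigma=_axis_sigmas(sigma_log))


def aggregate_threshold(per_image_values, channel: str = "") -> DetectionThreshold:
    """Combine per-image thresholds into the sample-wide mean threshold."""
    values = [float(v) for v in per_image_values if np.isfinite(v)]
    if not values:
        raise ValueError("no finite per-image threshold values")
    return DetectionThreshold(
        channel=channel,
        per_image_values=values,
        mean_value=float(np.mean(values)),
    )


def detect_spots(
    filtered_volume: np.ndarray,
    threshold: float,
    channel: str = "TMR",
) -> list[Spot]:
    """Report every above-threshold regional maximum of a filtered volume.

    The volume is binarised at ``threshold`` (>=) and within the
    above-threshold voxels each 26-connected regional maximum yields one
    spot. A flat plateau maximum is reported once, at its rounded centroid.
    Spots are ordered by (z, y, x) for determinism.
    """
    vol = np.asarray(filtered_volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    above = vol >= threshold
    if not above.any():
        return []
    maxima = local_maxima(vol, connectivity=3) & above
    if not maxima.any():
        return []
    plateaus, n = ndimage.label(maxima, structure=np.ones((3, 3, 3), bool))
    centroids = ndimage.center_of_mass(maxima, plateaus, np.arange(1, n + 1))
    spots = []
    for cz, cy, cx in centroids:
        z, y, x = (int(round(c)) for c in (cz, cy, cx))
        spots.append(Spot(channel=channel, x=x, y=y, z=z, intensity=float(vol[z, y, x])))
    spots.sort(key=lambda s: (s.z, s.y, s.x))
    return spots


def auto_threshold(
    filtered_plane: np.ndarray,
    min_spots: int = 5,
    noise_factor: float = 5.0,
    require_spots: bool = False,
) -> float:
    """Pick a detection threshold from one representative filtered image.

    The spot-count-versus-threshold curve of an image with real spots has a
    wide plateau between the brightest noise maximum and the dimmest spot;
    this routine returns the midpoint of that plateau. Concretely, a noise
    floor is extrapolated from the bulk of the regional-maxima intensities
    (median plus ``noise_factor`` times the median-to-90th-percentile
    spread); if at least ``min_spots`` maxima clear the floor, the threshold
    is the midpoint between the brightest sub-floor maximum and the dimmest
    supra-floor maximum. Otherwise the image is treated as spot-free: a
    ceiling well above all its maxima is returned so detection yields zero
    spots, or with ``require_spots=True`` a ValueError is raised so the
    image can be excluded from a sample-wide mean.

    A manual threshold always takes precedence over this routine; a flat
    image raises, instructing manual thresholding.
    """
    plane = np.asarray(filtered_plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("expected a single 2D image")
    if np.ptp(plane) == 0:
        raise ValueError(
            "degenerate flat image: cannot auto-threshold, supply a manual threshold"
        )
    peaks = plane[local_maxima(plane, connectivity=2)]
    if peaks.size == 0:
        raise ValueError("no regional maxima found; supply a manual threshold")
    med = float(np.median(peaks))
    spread = float(np.quantile(peaks, 0.9)) - med
    if spread <= 0:
        spread = float(peaks.max() - med) or 1.0
    floor = med + noise_factor * spread
    bright = np.sort(peaks[peaks >= floor])
    if bright.size < min_spots:
        if require_spots:
            raise ValueError(
                f"no separable spot population ({bright.size} maxima above the "
                f"noise floor, need {min_spots})"
            )
        return float(peaks.max()) + noise_factor * max(spread, 1e-12)
    dim = peaks[peaks < floor]
    lower = float(dim.max()) if dim.size else floor
    return 0.5 * (lower + float(bright[0]))
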