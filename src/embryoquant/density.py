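"""Cell density in a depth window beneath a tissue surface.

The procedure mirrors how confinement is assessed in embryonic tissue: locate
the tissue surface, cut a thin substack a fixed distance beneath it (19-21 um
for the neural tube, 15-20 um for somites, at 0.5 um z-steps), take a maximum
intensity projection of the nuclear channel, count nuclei inside a manually
delineated region of interest, and divide count by area:

    cell density = number of nuclei / area

Counting accepts either provided centroids (manual clicks) or an automatic
Laplacian-of-Gaussian blob detector. A nucleus belongs to the ROI iff its
centroid lies on an ROI pixel (boundary pixels belong to the ROI); the
centroid rule keeps partial nuclei unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import blob_log

from .io import ImageStack, max_intensity_projection, substack

__all__ = [
    "DensityMeasurement",
    "extract_depth_substack",
    "detect_nuclei",
    "count_nuclei_in_roi",
    "compute_density",
    "measure_window_density",
    "find_surface_z",
]


@dataclass
class DensityMeasurement:
    """One depth-window density measurement for one embryo."""

    embryo_id: str
    tissue: str  # neural-tube | somite | other
    window_um: tuple[float, float]
    roi_area_um2: float
    nucleus_count: int
    cells_per_somite: int | None = None

    def __post_init__(self) -> None:
        if self.roi_area_um2 <= 0:
            raise ValueError("ROI area must be positive")
        if self.nucleus_count < 0:
            raise ValueError("count must be >= 0")

    @property
    def density_per_um2(self) -> float:
        return self.nucleus_count / self.roi_area_um2


def extract_depth_substack(
    stack: ImageStack, surface_z_um: float, window_um: tuple[float, float]
) -> ImageStack:
    """Substack covering ``[surface + d0, surface + d1)`` micrometres.

    Depths convert to z indices by flooring against the z-step; e.g. a
    [19, 21) um window at 0.5 um steps spans 4 slices. Raises if the window
    reaches beyond the acquired depth, naming the deficit.
    """
    d0, d1 = window_um
    if not 0 <= d0 < d1:
        raise ValueError(f"window [{d0}, {d1}) must be a nonempty depth interval")
    z0 = stack.depth_to_index(surface_z_um + d0)
    z1 = stack.depth_to_index(surface_z_um + d1)
    if z1 > stack.n_z:
        deficit_um = (z1 - stack.n_z) * stack.z_step_um
        raise ValueError(
            f"window [{d0}, {d1}) um below surface at {surface_z_um} um needs "
            f"{deficit_um:g} um more depth than the stack provides"
        )
    return substack(stack, z0, z1)


def find_surface_z(stack: ImageStack, channel: str = "membrane", k: float = 3.0) -> float:
    """Automatic surface depth (um): first z whose mean intensity exceeds
    background mean + k*SD, with background taken from the top slice."""
    vol = stack.channel(channel).astype(float)
    means = vol.mean(axis=(1, 2))
    bg_mean = float(vol[0].mean())
    bg_sd = float(vol[0].std())
    above = np.nonzero(means > bg_mean + k * bg_sd)[0]
    if above.size == 0:
        raise ValueError("no slice exceeds the background threshold; surface not found")
    return float(above[0] * stack.z_step_um)


def detect_nuclei(
    mip: np.ndarray,
    pixel_size_um: float,
    nucleus_radius_um: float = 3.0,
    threshold_rel: float = 0.2,
) -> np.ndarray:
    """Detect nucleus centroids on a nuclear-channel MIP.

    Band-pass blob detection (Laplacian of Gaussian) around the expected
    nucleus scale; returns an (n, 2) array of (y, x) centroids in pixels.
    """
    if not 0 < threshold_rel < 1:
        raise ValueError("threshold_rel must be in (0, 1)")
    r_px = nucleus_radius_um / pixel_size_um
    if r_px < 1:
        raise ValueError("nucleus radius below one pixel; detector out of range")
    img = mip.astype(float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.empty((0, 2))
    img = (img - lo) / (hi - lo)
    sigma = r_px / np.sqrt(2.0)
    blobs = blob_log(
        img,
        min_sigma=0.6 * sigma,
        max_sigma=1.6 * sigma,
        num_sigma=5,
        threshold=threshold_rel * float(np.ptp(img)),
    )
    return blobs[:, :2] if blobs.size else np.empty((0, 2))


def count_nuclei_in_roi(
    mip: np.ndarray,
    roi: np.ndarray,
    centroids: np.ndarray | None = None,
    pixel_size_um: float | None = None,
    **detector_kwargs,
) -> int:
    """Count nuclei whose centroid falls inside an ROI mask.

    Either pass precomputed ``centroids`` (e.g. manual annotations) or let
    the LoG detector find them (requires ``pixel_size_um``). A centroid on an
    ROI boundary pixel counts as inside.
    """
    roi = np.asarray(roi).astype(bool)
    if roi.shape != np.asarray(mip).shape:
        raise ValueError("ROI shape must match the image")
    if not roi.any():
        raise ValueError("empty ROI")
    if centroids is None:
        if pixel_size_um is None:
            raise ValueError("automatic detection needs pixel_size_um")
        centroids = detect_nuclei(mip, pixel_size_um, **detector_kwargs)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.size == 0:
        return 0
    iy = np.clip(np.round(centroids[:, 0]).astype(int), 0, roi.shape[0] - 1)
    ix = np.clip(np.round(centroids[:, 1]).astype(int), 0, roi.shape[1] - 1)
    return int(roi[iy, ix].sum())


def compute_density(count: int, roi_area_um2: float) -> float:
    """Cell density = number of nuclei / area (nuclei per um^2)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if not roi_area_um2 > 0:
        raise ValueError("ROI area must be positive")
    return count / roi_area_um2


def measure_window_density(
    stack: ImageStack,
    surface_z_um: float,
    window_um: tuple[float, float],
    roi: np.ndarray,
    embryo_id: str = "",
    tissue: str = "other",
    centroids: np.ndarray | None = None,
    **detector_kwargs,
) -> DensityMeasurement:
    """Full substack -> MIP -> count -> density pipeline for one window."""
    sub = extract_depth_substack(stack, surface_z_um, window_um)
    mip = max_intensity_projection(sub, "nuclear")
    count = count_nuclei_in_roi(
        mip, roi, centroids=centroids, pixel_size_um=stack.pixel_size_um,
        **detector_kwargs,
    )
    area = float(np.asarray(roi, dtype=bool).sum()) * stack.pixel_size_um**2
    return DensityMeasurement(
        embryo_id=embryo_id, tissue=tissue, window_um=tuple(window_um),
        roi_area_um2=area, nucleus_count=count,
    )
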