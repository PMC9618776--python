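"""Internal cell-mass detection and embryo lateral area.

Masses of invaded reporter-positive cells are found on a whole-embryo maximum
intensity projection of the reporter channel: pixels above the mean image
intensity plus a multiple of its standard deviation (default 4, population SD)
form a binary mask; connected components are labeled (8-connectivity by
default) and components smaller than a physical minimum area (default
0.0025 mm^2, chosen to exclude single cells) are ignored. A component whose
area equals the minimum exactly is kept — only strictly smaller objects are
dropped. Threshold statistics are taken over the whole MIP by default
(``threshold_domain="mip"``); restriction to an embryo ROI is available since
empty background dilutes the mean.

Each retained mass can be confirmed as genuinely internal by checking that the
reporter signal's z centre of mass over the mass footprint lies below the
epithelial boundary surface.

The embryo's lateral (projected) area is segmented from a boundary-marker MIP:
threshold at mean + 2 SD, keep the largest component, fill holes; a manual
outline polygon is accepted as the alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .io import ImageStack

__all__ = [
    "MassRecord",
    "MassDetectionParams",
    "DegenerateThresholdWarning",
    "detect_masses",
    "confirm_below_epithelium",
    "masses_per_embryo",
    "embryo_lateral_area",
]


class DegenerateThresholdWarning(UserWarning):
    """The image has zero intensity variance; no threshold is definable."""


@dataclass
class MassRecord:
    """One detected internal mass on a reporter MIP."""

    embryo_id: str
    label: int
    pixel_count: int
    area_mm2: float
    centroid_yx: tuple[float, float]
    confirmed_internal: bool | None = None

    def __post_init__(self) -> None:
        if self.pixel_count <= 0:
            raise ValueError("pixel count must be positive")


@dataclass
class MassDetectionParams:
    """Threshold and size-filter parameters for mass detection."""

    k_sd: float = 4.0
    min_area_mm2: float = 0.0025
    connectivity: int = 8
    threshold_domain: str = "mip"  # mip | roi

    def __post_init__(self) -> None:
        if self.k_sd <= 0 or self.min_area_mm2 <= 0:
            raise ValueError("k_sd and min_area_mm2 must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_domain not in ("mip", "roi"):
            raise ValueError("threshold_domain must be 'mip' or 'roi'")


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def detect_masses(
    mip: np.ndarray,
    pixel_size_um: float,
    params: MassDetectionParams | None = None,
    exclusion_mask: np.ndarray | None = None,
    embryo_id: str = "",
    roi: np.ndarray | None = None,
) -> list[MassRecord]:
    """Detect internal cell masses on a reporter-channel MIP.

    Threshold tau = mean + k_sd * SD (population SD) of the MIP (or of the
    ROI when ``params.threshold_domain == "roi"``); pixels under the
    exclusion mask (annotated mis-expressing cells) are removed before
    labeling. Components with physical area >= ``min_area_mm2`` are returned,
    ordered by label.
    """
    params = params or MassDetectionParams()
    mip = np.asarray(mip, dtype=float)
    if not pixel_size_um > 0:
        raise ValueError("pixel size must be positive")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask).astype(bool)
        if exclusion_mask.shape != mip.shape:
            raise ValueError(
                f"exclusion mask shape {exclusion_mask.shape} != MIP shape {mip.shape}"
            )
    domain = mip
    if params.threshold_domain == "roi":
        if roi is None:
            raise ValueError("threshold_domain='roi' requires an ROI mask")
        roi = np.asarray(roi).astype(bool)
        if roi.shape != mip.shape:
            raise ValueError("ROI shape must match the MIP")
        domain = mip[roi]
    sd = float(np.std(domain))  # population SD
    if sd == 0:
        warnings.warn(
            "constant image: mean + k*SD threshold is degenerate; no masses",
            DegenerateThresholdWarning,
            stacklevel=2,
        )
        return []
    tau = float(np.mean(domain)) + params.k_sd * sd
    binary = mip > tau
    if exclusion_mask is not None:
        binary &= ~exclusion_mask
    labels, n = ndimage.label(binary, structure=_STRUCTS[params.connectivity])
    if n == 0:
        return []
    px_area_mm2 = (pixel_size_um / 1000.0) ** 2
    counts = np.bincount(labels.ravel())[1:]  # per label, skipping background
    centroids = ndimage.center_of_mass(binary, labels, np.arange(1, n + 1))
    records = []
    for lab, (cnt, (cy, cx)) in enumerate(zip(counts, centroids), start=1):
        area = float(cnt) * px_area_mm2
        if area < params.min_area_mm2:  # "smaller than" => equality is kept
            continue
        records.append(
            MassRecord(
                embryo_id=embryo_id, label=int(lab), pixel_count=int(cnt),
                area_mm2=area, centroid_yx=(float(cy), float(cx)),
            )
        )
    return records


def _mass_footprint(mass: MassRecord, shape: tuple[int, int]) -> np.ndarray:
    """Approximate footprint disc of a detected mass from its area/centroid."""
    r_px = np.sqrt(mass.pixel_count / np.pi)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = mass.centroid_yx
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2


def confirm_below_epithelium(
    mass: MassRecord,
    stack: ImageStack,
    surface_z_map: np.ndarray,
    footprint: np.ndarray | None = None,
) -> bool:
    """True iff the mass's reporter signal lies below the epithelial surface.

    The reporter channel's intensity-weighted z centre of mass over the mass
    footprint (in um depth) is compared with the mean surface depth there.
    If the surface map is undefined (NaN) over more than half the footprint,
    the mass is left unconfirmed with a warning.
    """
    vol = stack.channel("reporter").astype(float)
    if footprint is None:
        footprint = _mass_footprint(mass, vol.shape[1:])
    footprint = np.asarray(footprint).astype(bool)
    surface = np.asarray(surface_z_map, dtype=float)
    if surface.shape != vol.shape[1:]:
        raise ValueError("surface map shape must match the stack frame")
    defined = footprint & ~np.isnan(surface)
    if defined.sum() <= 0.5 * footprint.sum():
        warnings.warn(
            f"surface undefined over >50% of mass {mass.label} footprint; unconfirmed",
            stacklevel=2,
        )
        return False
    profile = vol[:, footprint]  # (z, n_px)
    weights = profile - profile.min()
    total = weights.sum()
    if total == 0:
        return False
    z_um = np.arange(vol.shape[0]) * stack.z_step_um
    z_com = float((weights.sum(axis=1) * z_um).sum() / total)
    return z_com > float(surface[defined].mean())


def masses_per_embryo(
    records: list[MassRecord], confirmed_only: bool = False
) -> pd.DataFrame:
    """Per-embryo mass count and mean area (NaN when an embryo has none).

    Embryos must be represented even when empty: pass records including
    zero-mass embryos via ``embryo_ids`` in the pipeline, or post-merge.
    Duplicate labels within an embryo are rejected.
    """
    by_embryo: dict[str, list[MassRecord]] = {}
    for r in records:
        by_embryo.setdefault(r.embryo_id, []).append(r)
    rows = []
    for embryo_id in sorted(by_embryo):
        group = by_embryo[embryo_id]
        labels = [r.label for r in group]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate mass labels for embryo {embryo_id}")
        if confirmed_only:
            group = [r for r in group if r.confirmed_internal]
        areas = [r.area_mm2 for r in group]
        rows.append(
            {
                "embryo_id": embryo_id,
                "mass_count": len(group),
                "mean_area_mm2": float(np.mean(areas)) if areas else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["embryo_id", "mass_count", "mean_area_mm2"])


def embryo_lateral_area(
    mip: np.ndarray,
    pixel_size_um: float,
    outline_polygon_px: np.ndarray | None = None,
    k_sd: float = 2.0,
    max_border_fraction: float = 0.75,
) -> float:
    """Projected embryo area in mm^2 from a boundary-marker MIP.

    Automatic mode thresholds at mean + k_sd * SD, keeps the largest
    connected component, fills holes and converts pixel count to mm^2. When a
    manual outline polygon (n, 2) in pixel coordinates is given, its shoelace
    area is used instead. Fails when segmentation degenerates (no foreground,
    or the component hugging most of the image border).
    """
    if outline_polygon_px is not None:
        poly = Polygon(np.asarray(outline_polygon_px, dtype=float))
        if not poly.is_valid or poly.area == 0:
            raise ValueError("invalid outline polygon")
        return float(poly.area) * (pixel_size_um / 1000.0) ** 2
    mip = np.asarray(mip, dtype=float)
    sd = float(mip.std())
    if sd == 0:
        raise ValueError("segmentation failure: constant image")
    binary = mip > mip.mean() + k_sd * sd
    labels, n = ndimage.label(binary, structure=_STRUCTS[8])
    if n == 0:
        raise ValueError("segmentation failure: nothing above threshold")
    counts = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(counts)) + 1
    comp = ndimage.binary_fill_holes(labels == biggest)
    border = np.concatenate(
        [comp[0], comp[-1], comp[:, 0], comp[:, -1]]
    )
    if border.mean() > max_border_fraction:
        raise ValueError(
            "segmentation failure: embryo component touches most of the border"
        )
    return float(comp.sum()) * (pixel_size_um / 1000.0) ** 2
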