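"""Quantitative evaluation: eFoV-restricted Jaccard conformity, per-slice
eFoV volumes and their RMSD, insert HU statistics, and HU histograms.

The eFoV region is the set of pixels farther than the sFoV radius from
the isocenter in the scan frame; couch shifts move the phantom through
that fixed annulus.  The Jaccard Conformity Index is intersection over
union of two binary masks after both are restricted to the eFoV; 1 is a
perfect match, 0 disjoint regions.  An empty union (neither mask reaches
the eFoV) is reported as 1 with a flag, since there is nothing to
disagree about.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import CTImage
from .geometry import ScanGeometry

__all__ = [
    "EmptyRegionError",
    "object_mask",
    "efov_region",
    "jaccard_efov",
    "jaccard_efov_per_slice",
    "slice_efov_volume",
    "volume_rmsd",
    "roi_hu_stats",
    "efov_hu_histogram",
    "EvalReport",
]


class EmptyRegionError(RuntimeError):
    pass


def object_mask(
    image: CTImage,
    threshold_hu: float = -400.0,
    exclude=None,
) -> np.ndarray:
    """Binary phantom mask: threshold, largest component, hole filling.

    ``exclude`` may be a predicate ``f(x, y) -> bool array`` zeroing
    regions such as a patient table (a no-op on table-free synthetic
    data).
    """
    mask = image.values > threshold_hu
    if exclude is not None:
        x, y = image.grid_coords()
        mask &= ~np.broadcast_to(exclude(x, y), mask.shape)
    if not mask.any():
        raise EmptyRegionError("no voxel above the object threshold")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return np.stack([ndimage.binary_fill_holes(sl) for sl in mask])


def efov_region(image: CTImage, geometry: ScanGeometry) -> np.ndarray:
    """Pixels outside the sFoV circle (2D, in-plane)."""
    return image.radius_map() > geometry.sfov_radius_mm


def _jaccard(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0, True
    return float(np.logical_and(a, b).sum() / union), False


def jaccard_efov(
    mask_ref: np.ndarray,
    mask_test: np.ndarray,
    grid: CTImage,
    geometry: ScanGeometry,
    return_flag: bool = False,
):
    """eFoV-restricted Jaccard Conformity Index over the whole stack."""
    if mask_ref.shape != mask_test.shape:
        raise ValueError("mask grid mismatch")
    region = efov_region(grid, geometry)
    j, empty = _jaccard(mask_ref & region, mask_test & region)
    return (j, empty) if return_flag else j


def jaccard_efov_per_slice(
    mask_ref: np.ndarray, mask_test: np.ndarray, grid: CTImage, geometry: ScanGeometry
) -> np.ndarray:
    if mask_ref.shape != mask_test.shape:
        raise ValueError("mask grid mismatch")
    region = efov_region(grid, geometry)
    return np.array(
        [_jaccard(r & region, t & region)[0] for r, t in zip(mask_ref, mask_test)]
    )


def slice_efov_volume(
    mask: np.ndarray, grid: CTImage, geometry: ScanGeometry
) -> np.ndarray:
    """Per-slice volume (cm^3) of the mask outside the sFoV circle."""
    region = efov_region(grid, geometry)
    voxel_cm3 = grid.pixel_spacing_mm**2 * grid.slice_thickness_mm / 1000.0
    return np.array([(sl & region).sum() * voxel_cm3 for sl in mask])


def volume_rmsd(ref: np.ndarray, test: np.ndarray) -> float:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((ref - test) ** 2)))


def roi_hu_stats(
    image: CTImage,
    center_mm: tuple[float, float],
    radius_mm: float = 10.0,
    n_slices: int = 5,
    start_slice: int | None = None,
) -> tuple[float, float]:
    """Mean and std of HU in a cylindrical ROI (default: 1 cm radius,
    five consecutive slices) around an insert center."""
    if start_slice is None:
        start_slice = max(0, (image.n_slices - n_slices) // 2)
    stop = start_slice + min(n_slices, image.n_slices - start_slice)
    x, y = image.grid_coords()
    inplane = np.hypot(x - center_mm[0], y - center_mm[1]) <= radius_mm
    half = image.extent_mm / 2.0
    if (
        abs(center_mm[0] - image.origin[0]) + radius_mm > half
        or abs(center_mm[1] - image.origin[1]) + radius_mm > half
    ):
        raise ValueError("ROI outside the image grid")
    vals = image.values[start_slice:stop][:, inplane]
    return float(vals.mean()), float(vals.std())


def efov_hu_histogram(
    image: CTImage,
    mask: np.ndarray,
    geometry: ScanGeometry,
    bin_width_hu: float = 10.0,
    hu_range: tuple[float, float] = (-1000.0, 1500.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HU histogram over mask ∩ eFoV: (bin_edges, counts, density)."""
    region = efov_region(image, geometry)
    sel = mask & np.broadcast_to(region, mask.shape)
    if not sel.any():
        raise EmptyRegionError("mask does not reach the eFoV")
    vals = np.clip(image.values[sel], *hu_range)
    edges = np.arange(hu_range[0], hu_range[1] + bin_width_hu, bin_width_hu)
    counts, edges = np.histogram(vals, bins=edges)
    density = counts / (counts.sum() * bin_width_hu)
    return edges, counts, density


@dataclass
class EvalReport:
    """Collected metrics of one eFoV experiment."""

    couch_offsets_mm: list = field(default_factory=list)
    jaccard_per_slice: dict = field(default_factory=dict)  # algo -> offset -> [J]
    jaccard_mean_std: dict = field(default_factory=dict)  # algo -> (mean, std)
    efov_volumes_cm3: dict = field(default_factory=dict)  # algo -> offset -> [vol]
    reference_volumes_cm3: dict = field(default_factory=dict)  # offset -> [vol]
    volume_rmsd_cm3: dict = field(default_factory=dict)  # algo -> rmsd
    insert_hu: dict = field(default_factory=dict)  # algo -> name -> (mean, std)
    histograms: dict = field(default_factory=dict)

    def finalize(self) -> None:
        for algo, by_offset in self.jaccard_per_slice.items():
            vals = np.concatenate([np.asarray(v) for v in by_offset.values()])
            self.jaccard_mean_std[algo] = (float(vals.mean()), float(vals.std()))
        for algo, by_offset in self.efov_volumes_cm3.items():
            offsets = [o for o in by_offset if o in self.reference_volumes_cm3]
            if not offsets:
                continue
            test = np.concatenate([np.asarray(by_offset[o]) for o in offsets])
            ref = np.concatenate(
                [np.asarray(self.reference_volumes_cm3[o]) for o in offsets]
            )
            self.volume_rmsd_cm3[algo] = volume_rmsd(ref, test)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "couch_offsets_mm": conv(self.couch_offsets_mm),
            "jaccard_per_slice": conv(self.jaccard_per_slice),
            "jaccard_mean_std": conv(self.jaccard_mean_std),
            "efov_volumes_cm3": conv(self.efov_volumes_cm3),
            "reference_volumes_cm3": conv(self.reference_volumes_cm3),
            "volume_rmsd_cm3": conv(self.volume_rmsd_cm3),
            "insert_hu": conv(self.insert_hu),
        }
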