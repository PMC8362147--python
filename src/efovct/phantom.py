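"""Procedural phantoms: the thorax-like evaluation phantom, couch shifts,
geometric distortions, training-corpus body slices, and the stitched
two-scan reference protocol.

Every phantom is declared as an ordered list of ellipse/circle components
with HU values.  The ground-truth object mask is always evaluated
analytically from the component parameters (union of component supports),
never thresholded from a rasterized image.

The default thorax phantom emulates a wide patient cross-section: a
560 mm x 270 mm soft-tissue ellipse (bulk ~ +100 HU, PLA-like) with two
low-density lung regions (~ -700 HU) and a row of circular
tissue-mimicking inserts.  Its width exceeds the 500 mm sFoV, so lateral
parts of the body always lie in the eFoV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .containers import CTImage, Sinogram
from .geometry import ScanGeometry

__all__ = [
    "EllipseComponent",
    "PhantomSpec",
    "InsertSet",
    "default_inserts",
    "thorax_spec",
    "make_thorax_phantom",
    "shift_couch",
    "distort_image",
    "stitched_reference",
    "random_body_spec",
]

#: nominal HU of the tissue-mimicking inserts (configuration defaults)
INSERT_HU = {
    "inhale_lung": -800.0,
    "exhale_lung": -500.0,
    "adipose": -90.0,
    "breast": -35.0,
    "solid_water": 0.0,
    "muscle": 40.0,
    "liver": 60.0,
    "inner_bone": 220.0,
    "cortical_bone": 1200.0,
}


@dataclass(frozen=True)
class EllipseComponent:
    """One ellipse (circle: equal semi-axes) painted with a constant HU."""

    center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]
    rotation_rad: float = 0.0
    hu: float = 0.0

    def inside(self, x: np.ndarray, y: np.ndarray, scale: float = 1.0) -> np.ndarray:
        cx, cy = self.center_mm
        a, b = self.semi_axes_mm
        a, b, cx, cy = a * scale, b * scale, cx * scale, cy * scale
        dx, dy = x - cx, y - cy
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def max_radius(self, scale: float = 1.0) -> float:
        """Upper bound on the distance of the component from the isocenter."""
        cx, cy = self.center_mm
        return scale * (math.hypot(cx, cy) + max(self.semi_axes_mm))

    def shifted(self, dx: float, dy: float) -> "EllipseComponent":
        cx, cy = self.center_mm
        return replace(self, center_mm=(cx + dx, cy + dy))


@dataclass(frozen=True)
class InsertSet:
    """Named circular tissue-mimicking inserts at named positions."""

    inserts: tuple[tuple[str, EllipseComponent], ...] = ()

    def components(self) -> list[EllipseComponent]:
        return [c for _, c in self.inserts]

    def center_of(self, name: str) -> tuple[float, float]:
        for n, c in self.inserts:
            if n == name:
                return c.center_mm
        raise KeyError(name)


def default_inserts(radius_mm: float = 12.0, y_mm: float = -85.0) -> InsertSet:
    """The nine inserts in a row below the lungs, inside the body outline."""
    names = list(INSERT_HU)
    xs = np.linspace(-180.0, 180.0, len(names))
    items = tuple(
        (
            name,
            EllipseComponent((float(x), y_mm), (radius_mm, radius_mm), 0.0, INSERT_HU[name]),
        )
        for name, x in zip(names, xs)
    )
    return InsertSet(items)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom: ordered components painted first-to-last.

    ``slice_scales`` gives a per-slice isotropic scaling of the whole
    layout (about the isocenter), emulating the smooth superior-inferior
    body contour.  The analytic object mask of a slice is the union of the
    scaled component supports.
    """

    components: tuple[EllipseComponent, ...]
    background_hu: float = -1000.0
    slice_scales: tuple[float, ...] = (1.0,)
    bore_radius_mm: float = 400.0

    def __post_init__(self) -> None:
        for comp in self.components:
            if comp.max_radius(max(self.slice_scales)) > self.bore_radius_mm:
                raise ValueError(
                    f"component at {comp.center_mm} exceeds the bore "
                    f"(extent {comp.max_radius(max(self.slice_scales)):.1f} mm)"
                )

    @property
    def n_slices(self) -> int:
        return len(self.slice_scales)

    def shifted(self, dx: float, dy: float) -> "PhantomSpec":
        comps = tuple(c.shifted(dx, dy) for c in self.components)
        return replace(self, components=comps)

    def mask(self, x: np.ndarray, y: np.ndarray, slice_index: int = 0) -> np.ndarray:
        """Analytic inside/outside test on arbitrary coordinates."""
        s = self.slice_scales[slice_index]
        out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        for comp in self.components:
            out |= comp.inside(x, y, s)
        return out

    def rasterize(
        self,
        pixel_spacing_mm: float,
        matrix: int,
        origin: tuple[float, float] = (0.0, 0.0),
        slice_thickness_mm: float = 3.0,
    ) -> tuple[CTImage, np.ndarray]:
        """HU image stack and the analytic object mask on the same grid."""
        ax = (np.arange(matrix) - (matrix - 1) / 2.0) * pixel_spacing_mm
        x = origin[0] + ax[None, :]
        y = origin[1] + ax[:, None]
        hu = np.full((self.n_slices, matrix, matrix), self.background_hu)
        mask = np.zeros((self.n_slices, matrix, matrix), dtype=bool)
        for k, s in enumerate(self.slice_scales):
            for comp in self.components:
                ins = comp.inside(x, y, s)
                hu[k][ins] = comp.hu
                mask[k] |= ins
        img = CTImage(hu, pixel_spacing_mm, slice_thickness_mm, origin)
        return img, mask


def _dome_profile(n_slices: int, droop: float = 0.02) -> tuple[float, ...]:
    """Per-slice outline scaling.  The default stack spans ~9 mm of a
    smoothly varying body, so adjacent slices differ by only a few mm of
    lateral extent (2% total droop)."""
    if n_slices == 1:
        return (1.0,)
    mid = (n_slices - 1) / 2.0
    return tuple(1.0 - droop * ((k - mid) / mid) ** 2 for k in range(n_slices))


def thorax_spec(
    width_mm: float = 560.0,
    height_mm: float = 270.0,
    body_hu: float = 100.0,
    lung_hu: float = -700.0,
    inserts: InsertSet | None = None,
    n_slices: int = 3,
    couch_offset_mm: float = 0.0,
) -> PhantomSpec:
    """Thorax-like phantom wider than the sFoV: body ellipse, two lungs,
    and (optionally) the tissue-insert row."""
    a, b = width_mm / 2.0, height_mm / 2.0
    comps = [
        EllipseComponent((0.0, 0.0), (a, b), 0.0, body_hu),
        EllipseComponent((-0.5 * a, 0.18 * b), (0.34 * a, 0.53 * b), 0.15, lung_hu),
        EllipseComponent((0.5 * a, 0.18 * b), (0.34 * a, 0.53 * b), -0.15, lung_hu),
    ]
    if inserts is not None:
        comps.extend(inserts.components())
    spec = PhantomSpec(tuple(comps), slice_scales=_dome_profile(n_slices))
    if couch_offset_mm:
        spec = spec.shifted(0.0, couch_offset_mm)
    return spec


def make_thorax_phantom(
    spec: PhantomSpec | None = None,
    inserts: InsertSet | None = None,
    pixel_spacing_mm: float = 800.0 / 512,
    n_slices: int = 3,
    matrix: int = 512,
) -> tuple[CTImage, np.ndarray]:
    """Rasterize the thorax phantom; returns (HU image, analytic mask)."""
    if spec is None:
        spec = thorax_spec(inserts=inserts, n_slices=n_slices)
    return spec.rasterize(pixel_spacing_mm, matrix)


def _body_extent(image: CTImage, air_hu: float = -900.0) -> float:
    """Largest distance of a non-air voxel from the isocenter."""
    nonair = image.values.max(axis=0) > air_hu
    if not nonair.any():
        return 0.0
    rad = image.radius_map()
    return float(rad[nonair].max())


def shift_couch(image: CTImage, dy_mm: float, bore_radius_mm: float = 400.0, resample: bool = False) -> CTImage:
    """Vertical couch shift: the phantom moves by ``dy_mm`` along +y.

    By default only the grid origin is updated (rigid, lossless); with
    ``resample`` the values are re-sampled onto the original grid.
    """
    shifted = CTImage(
        image.values.copy(),
        image.pixel_spacing_mm,
        image.slice_thickness_mm,
        (image.origin[0], image.origin[1] + dy_mm),
    )
    if _body_extent(shifted) > bore_radius_mm:
        raise ValueError(f"shifted phantom leaves the bore ({_body_extent(shifted):.1f} mm)")
    if not resample:
        return shifted
    vals = np.stack(
        [
            ndimage.shift(sl, (dy_mm / image.pixel_spacing_mm, 0.0), order=1, cval=-1000.0)
            for sl in image.values
        ]
    )
    return CTImage(np.clip(vals, -1000.0, None), image.pixel_spacing_mm, image.slice_thickness_mm, image.origin)


def distort_image(
    image: CTImage,
    scale: float = 1.0,
    rotation_rad: float = 0.0,
    shift_mm: tuple[float, float] = (0.0, 0.0),
    bore_radius_mm: float = 400.0,
    matrix: int = 512,
    fov_mm: float = 800.0,
    rng_seed: int | None = None,
) -> CTImage:
    """Scale/rotate/shift an image onto a centered ``fov_mm`` grid.

    The output grid is always ``fov_mm`` x ``fov_mm`` regardless of the
    input extent.  The transform parameters (and seed, if the caller drew
    them randomly) are logged in the returned image for reproducibility
    via the ``transform_log`` attribute.
    """
    sp_out = fov_mm / matrix
    c, s = math.cos(rotation_rad), math.sin(rotation_rad)
    # output pixel -> physical -> inverse transform -> input pixel
    inv_scale = 1.0 / scale
    out = np.empty((image.n_slices, matrix, matrix))
    n_in = image.matrix
    for k in range(image.n_slices):
        # affine_transform maps output coords through M to input coords
        # forward rotation acting on (y, x) is [[c, s], [-s, c]]; invert it
        m = inv_scale * np.array([[c, -s], [s, c]])
        # physical coords of output pixel p_out: (p - (matrix-1)/2)*sp_out
        # input pixel = (Minv @ (phys - shift) - origin_in)/sp_in + center_in
        mat = m * sp_out / image.pixel_spacing_mm
        center_out = (matrix - 1) / 2.0
        center_in = (n_in - 1) / 2.0
        shift_phys = np.array([shift_mm[1], shift_mm[0]])  # (row=y, col=x)
        origin_in = np.array([image.origin[1], image.origin[0]])
        offset = (m @ (-shift_phys - np.array([0.0, 0.0])) - origin_in) / image.pixel_spacing_mm
        offset = offset + center_in - mat @ np.array([center_out, center_out])
        out[k] = ndimage.affine_transform(
            image.values[k], mat, offset=offset, output_shape=(matrix, matrix), order=1, cval=-1000.0
        )
    result = CTImage(np.clip(out, -1000.0, None), sp_out, image.slice_thickness_mm, (0.0, 0.0))
    extent = _body_extent(result)
    if extent > bore_radius_mm:
        raise ValueError(f"distorted body exceeds the bore: extent {extent:.1f} mm > {bore_radius_mm} mm")
    result.transform_log = {
        "scale": scale,
        "rotation_rad": rotation_rad,
        "shift_mm": tuple(shift_mm),
        "rng_seed": rng_seed,
    }
    return result


def stitched_reference(
    image: CTImage,
    geometry: ScanGeometry,
    lateral_shift_mm: float = 60.0,
    matrix: int = 512,
    fov_mm: float = 800.0,
) -> CTImage:
    """Reference image from two laterally shifted acquisitions.

    The phantom is scanned once shifted right (+x) so its left half lies
    inside the sFoV, and once shifted left; each truncated scan is
    detruncated (mass consistency) and reconstructed, shifted back to the
    original frame, and the two lateral halves are combined with a hard
    seam at the midline.  The result contains only measured data within
    the sFoV wherever the phantom is, which is what makes it a reference.
    """
    from .detruncation import cosine_detruncate
    from .projection import fbp_reconstruct, forward_project, truncate

    extent = _body_extent(image)
    if extent - lateral_shift_mm > geometry.sfov_radius_mm:
        raise ValueError("phantom halves not covered by the sFoV after shifting")

    wide_geo, _ = geometry.widened_to(geometry.bore_radius_mm)
    sp = fov_mm / matrix
    halves = []
    for sgn in (+1.0, -1.0):
        moved = CTImage(
            image.values,
            image.pixel_spacing_mm,
            image.slice_thickness_mm,
            (image.origin[0] + sgn * lateral_shift_mm, image.origin[1]),
        )
        sino = truncate(forward_project(moved, wide_geo))
        det = cosine_detruncate(sino)
        rec = fbp_reconstruct(det.sinogram, fov_mm=fov_mm, matrix=matrix)
        back = np.stack(
            [
                ndimage.shift(sl, (0.0, -sgn * lateral_shift_mm / sp), order=1, cval=-1000.0)
                for sl in rec.values
            ]
        )
        halves.append(back)
    right_scan, left_scan = halves  # phantom shifted right -> left half measured
    out = np.where(
        (np.arange(matrix) - (matrix - 1) / 2.0)[None, None, :] * sp < 0.0,
        right_scan,
        left_scan,
    )
    return CTImage(np.clip(out, -1000.0, None), sp, image.slice_thickness_mm, (0.0, 0.0))


def random_body_spec(rng: np.random.Generator, n_slices: int = 1) -> PhantomSpec:
    """A random body-like slice for the training corpus.

    The body is an ellipse that exceeds the sFoV (part of it lies beyond
    the 250 mm circle) while fitting the bore, with a random rotation and
    center shift; inside it sit two lung-like low-density ellipses, a
    bright vertebra-like circle, and a few random soft-tissue structures.
    """
    for _ in range(200):
        a = rng.uniform(260.0, 370.0)
        b = rng.uniform(0.38, 0.75) * a
        rot = rng.uniform(-0.25, 0.25)
        cx = rng.uniform(-25.0, 25.0)
        cy = rng.uniform(-25.0, 25.0)
        body = EllipseComponent((cx, cy), (a, b), rot, rng.uniform(20.0, 120.0))
        if body.max_radius() > 396.0:
            continue
        if math.hypot(cx, cy) + a < 255.0:  # must exceed the sFoV
            continue
        break
    else:  # pragma: no cover - generous sampling bounds
        raise RuntimeError("retry budget exhausted while sampling a body")

    cr, sr = math.cos(rot), math.sin(rot)

    def in_body_frame(u: float, v: float) -> tuple[float, float]:
        return (cx + cr * u - sr * v, cy + sr * u + cr * v)

    comps = [body]
    for side in (-1.0, 1.0):
        la = rng.uniform(0.25, 0.38) * a
        lb = rng.uniform(0.4, 0.6) * b
        comps.append(
            EllipseComponent(
                in_body_frame(side * 0.5 * a, rng.uniform(0.0, 0.3) * b),
                (la, lb),
                rot + side * -0.15,
                rng.uniform(-850.0, -600.0),
            )
        )
    comps.append(
        EllipseComponent(
            in_body_frame(0.0, rng.uniform(-0.6, -0.3) * b),
            (rng.uniform(12.0, 22.0),) * 2,
            0.0,
            rng.uniform(400.0, 1100.0),
        )
    )
    for _ in range(rng.integers(2, 7)):
        u = rng.uniform(-0.6, 0.6) * a
        v = rng.uniform(-0.6, 0.6) * b
        ra = rng.uniform(10.0, 50.0)
        comps.append(
            EllipseComponent(
                in_body_frame(u, v),
                (ra, ra * rng.uniform(0.5, 1.0)),
                rng.uniform(0.0, math.pi),
                rng.uniform(-120.0, 300.0),
            )
        )
    return PhantomSpec(tuple(comps), slice_scales=(1.0,) * n_slices)
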