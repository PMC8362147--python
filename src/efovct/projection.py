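"""Forward projection, truncation, and filtered backprojection.

The projector computes line integrals of the linear attenuation
coefficient mu along fan rays by fixed-step sampling with bilinear
interpolation (default step: half the image pixel pitch).  The
reconstructor is a flat-detector fan-beam FBP: cosine pre-weighting,
band-limited ramp filtering (Ram-Lak, optional Hann apodization), and
distance-weighted backprojection over a full rotation.

``fbp_reconstruct`` supports the convolution-only extension mechanism:
an extended (bore-wide) sinogram can be supplied whose rows are used for
the filtering step only, while the backprojection reads exclusively the
measured channel block of the input.  This is how extrapolated data enter
the reconstruction without ever being backprojected.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from ._kernels import backproject_kernel, forward_kernel
from .containers import CTImage, Sinogram
from .geometry import ScanGeometry

__all__ = [
    "DEFAULT_MU_WATER",
    "hu_to_mu",
    "mu_to_hu",
    "forward_project",
    "forward_project_mu",
    "truncate",
    "pad_to_bore",
    "fbp_reconstruct",
]

#: default linear attenuation coefficient of water, per mm (~70 keV)
DEFAULT_MU_WATER = 0.02


def hu_to_mu(image: CTImage, mu_water_per_mm: float = DEFAULT_MU_WATER) -> np.ndarray:
    """Convert HU to linear attenuation: mu = mu_w * (1 + HU/1000), clipped at 0."""
    if mu_water_per_mm <= 0:
        raise ValueError("mu_water_per_mm must be > 0")
    hu = np.asarray(image.values, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite HU values")
    return np.clip(mu_water_per_mm * (1.0 + hu / 1000.0), 0.0, None)


def mu_to_hu(mu: np.ndarray, mu_water_per_mm: float = DEFAULT_MU_WATER) -> np.ndarray:
    """Inverse of :func:`hu_to_mu` on the unclipped range, floored at -1000 HU."""
    if mu_water_per_mm <= 0:
        raise ValueError("mu_water_per_mm must be > 0")
    return np.maximum((np.asarray(mu) / mu_water_per_mm - 1.0) * 1000.0, -1000.0)


def _check_coverage(geometry: ScanGeometry) -> None:
    # raises if detector does not cover the sFoV (delegated to the dataclass)
    ScanGeometry(**vars(geometry))


def forward_project(
    image: CTImage,
    geometry: ScanGeometry,
    mu_water_per_mm: float = DEFAULT_MU_WATER,
    step_mm: float | None = None,
) -> Sinogram:
    """Fan-beam forward projection of an HU image (converted internally)."""
    mu = hu_to_mu(image, mu_water_per_mm)
    return forward_project_mu(mu, image, geometry, step_mm=step_mm)


def forward_project_mu(
    mu: np.ndarray,
    grid: CTImage,
    geometry: ScanGeometry,
    step_mm: float | None = None,
) -> Sinogram:
    """Forward projection of an attenuation array on the grid of ``grid``."""
    _check_coverage(geometry)
    mu = np.asarray(mu, dtype=np.float64)
    if mu.ndim == 2:
        mu = mu[None]
    if step_mm is None:
        step_mm = 0.5 * grid.pixel_spacing_mm
    angles = geometry.angles_rad
    cosb, sinb = np.cos(angles), np.sin(angles)
    tvals = geometry.iso_channel_positions_mm()
    ox, oy = grid.origin
    # circle (centered on the grid) guaranteed to contain all pixels
    rclip = 0.5 * np.sqrt(2.0) * grid.extent_mm + grid.pixel_spacing_mm
    out = np.empty((mu.shape[0], geometry.n_angles, geometry.n_channels))
    buf = np.empty((geometry.n_angles, geometry.n_channels))
    for k in range(mu.shape[0]):
        forward_kernel(
            np.ascontiguousarray(mu[k]),
            grid.pixel_spacing_mm,
            ox,
            oy,
            cosb,
            sinb,
            geometry.source_to_isocenter_mm,
            tvals,
            step_mm,
            rclip,
            buf,
        )
        out[k] = buf
    return Sinogram(out, geometry)


def truncate(sino: Sinogram, n_channels: int | None = None) -> Sinogram:
    """Restrict a wide sinogram to the physical detector's channel block.

    Channels beyond the physical detector (default: the 512-channel
    sFoV-covering detector of the geometry's ``required_channels_for_radius``
    of the sFoV) are removed; retained values are bit-exact.
    """
    geo = sino.geometry
    if n_channels is None:
        n_channels = geo.required_channels_for_radius(geo.sfov_radius_mm)
    if n_channels > geo.n_channels:
        raise ValueError("cannot truncate to more channels than present")
    pad = (geo.n_channels - n_channels) // 2
    from dataclasses import replace

    new_geo = replace(geo, n_channels=n_channels)
    values = sino.values[:, :, pad : pad + n_channels]
    return Sinogram(values.copy(), new_geo)


def pad_to_bore(sino: Sinogram) -> Sinogram:
    """Zero-pad a sinogram onto the bore-covering channel grid.

    The measured flag marks the original central block; padded channels
    are unmeasured.
    """
    geo = sino.geometry
    wide_geo, pad = geo.widened_to(geo.bore_radius_mm)
    if pad == 0:
        return sino.copy()
    ns, na, nc = sino.values.shape
    values = np.zeros((ns, na, wide_geo.n_channels))
    values[:, :, pad : pad + nc] = sino.values
    i0, i1 = sino.measured_range
    measured = np.zeros(wide_geo.n_channels, dtype=bool)
    measured[pad + i0 : pad + i1] = True
    return Sinogram(values, wide_geo, measured)


def _ramp_kernel(nc: int, dt: float, filter_name: str) -> np.ndarray:
    """Spatial band-limited ramp kernel over lags -(nc-1)..(nc-1)."""
    k = np.arange(-(nc - 1), nc)
    h = np.zeros(k.shape)
    h[k == 0] = 1.0 / (4.0 * dt * dt)
    odd = k % 2 != 0
    h[odd] = -1.0 / (np.pi * k[odd] * dt) ** 2
    if filter_name == "ramp":
        return h
    if filter_name == "hann":
        # apodize in frequency domain: H(f) *= 0.5 (1 + cos(pi f / f_N))
        nfft = int(2 ** np.ceil(np.log2(2 * h.size)))
        hf = np.fft.rfft(h, nfft)
        f = np.fft.rfftfreq(nfft, d=dt)
        window = 0.5 * (1.0 + np.cos(np.pi * f / f[-1]))
        hw = np.fft.irfft(hf * window, nfft)
        return np.concatenate([hw[-(nc - 1):], hw[:nc]])
    raise ValueError(f"unknown filter {filter_name!r}")


def filter_rows(values: np.ndarray, geometry: ScanGeometry, filter_name: str = "ramp") -> np.ndarray:
    """Cosine-weight and ramp-filter sinogram rows (any leading shape)."""
    dt = geometry.iso_spacing_mm
    w = geometry.fan_weights()  # == RF/sqrt(RF^2 + t_iso^2)
    h = _ramp_kernel(geometry.n_channels, dt, filter_name)
    pw = values * w
    # factor 1/2: full-rotation fan-beam FBP counts every ray twice
    q = fftconvolve(pw, h[(None,) * (values.ndim - 1) + (slice(None),)], mode="same", axes=-1)
    return q * (0.5 * dt)


def fbp_reconstruct(
    sino: Sinogram,
    fov_mm: float = 800.0,
    matrix: int = 512,
    origin: tuple[float, float] = (0.0, 0.0),
    filter_name: str = "ramp",
    conv_only_extension: Sinogram | None = None,
    backproject_measured_only: bool = False,
    mu_water_per_mm: float = DEFAULT_MU_WATER,
    slice_thickness_mm: float | None = None,
) -> CTImage:
    """Flat-detector fan-beam filtered backprojection.

    Parameters
    ----------
    conv_only_extension :
        Optional extended (wider-detector) sinogram whose rows replace the
        input during cosine weighting and filtering; only the channels of
        ``sino`` (which must form the central block of the extension, with
        identical values where measured) are backprojected.  This
        implements extrapolation that acts on the convolution step only.
    backproject_measured_only :
        Restrict backprojection to the measured channel block of ``sino``
        (the default when a conv-only extension is given).
    """
    geometry = sino.geometry
    if matrix < 32:
        raise ValueError("matrix must be >= 32")
    if fov_mm > 2.0 * geometry.bore_radius_mm:
        raise ValueError("fov_mm must not exceed the bore diameter")
    angles = geometry.angles_rad
    span = angles[-1] - angles[0] + (angles[1] - angles[0])
    if span < 2.0 * np.pi - 1e-9:
        raise ValueError("angle coverage below a full rotation")

    if conv_only_extension is not None:
        ext = conv_only_extension
        if ext.values.shape[:2] != sino.values.shape[:2]:
            raise ValueError("extension slice/angle shape mismatch")
        if ext.geometry.n_channels < geometry.n_channels:
            raise ValueError("extension must be at least as wide as the input")
        filt_sino, filt_geo = ext, ext.geometry
        pad = (ext.geometry.n_channels - geometry.n_channels) // 2
        i0, i1 = sino.measured_range
        ilo, ihi = pad + i0, pad + i1 - 1
    else:
        filt_sino, filt_geo = sino, geometry
        if backproject_measured_only:
            i0, i1 = sino.measured_range
            ilo, ihi = i0, i1 - 1
        else:
            ilo, ihi = 0, geometry.n_channels - 1

    q = filter_rows(filt_sino.values, filt_geo, filter_name)

    dt = filt_geo.iso_spacing_mm
    tvals = filt_geo.iso_channel_positions_mm()
    t0 = tvals[0]
    cosb, sinb = np.cos(angles), np.sin(angles)
    dbeta = 2.0 * np.pi / geometry.n_angles
    spacing = fov_mm / matrix
    ns = sino.n_slices
    out = np.empty((ns, matrix, matrix))
    buf = np.empty((matrix, matrix))
    for k in range(ns):
        backproject_kernel(
            np.ascontiguousarray(q[k]),
            cosb,
            sinb,
            geometry.source_to_isocenter_mm,
            t0,
            dt,
            spacing,
            origin[0],
            origin[1],
            matrix,
            float(ilo),
            float(ihi),
            dbeta,
            buf,
        )
        out[k] = buf
    hu = mu_to_hu(out, mu_water_per_mm)
    return CTImage(
        hu,
        pixel_spacing_mm=spacing,
        slice_thickness_mm=slice_thickness_mm or 3.0,
        origin=origin,
    )
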