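"""Projection-domain detruncation and the HDFoV reconstruction pipeline.

Mass consistency: for parallel-equivalent data the weighted integral of a
projection row (its "mass") is the same at every angle; truncation only
removes mass, so the per-angle mass of a truncated sinogram drops below
the maximum over angles.  ``cosine_detruncate`` restores consistency by
extending every truncated row edge with a cos^2-shaped tail whose width
is solved per angle so that the added weighted mass equals that angle's
deficit.  The measured channels are never touched.

``linear_cos2_detruncate`` implements the slope-matched linear x cos^2
extrapolation intended for convolution-only use: the extension covers the
full channel range out to the bore projection and is consumed by
``fbp_reconstruct(..., conv_only_extension=...)`` which filters the
extended rows but backprojects measured channels only.

The HDFoV pipeline is the classical two-step method: reconstruct a first
estimate from mass-consistent data, smooth and binarize it to an object
mask, forward-project the water-filled mask, replace the extrapolated
channels by those simulated projections, and reconstruct the final image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import CTImage, Sinogram
from .geometry import ScanGeometry
from .projection import (
    DEFAULT_MU_WATER,
    fbp_reconstruct,
    forward_project_mu,
    pad_to_bore,
)

__all__ = [
    "MassProfile",
    "DetruncationResult",
    "EmptyMaskError",
    "projection_mass",
    "cosine_detruncate",
    "linear_cos2_detruncate",
    "binarize_object",
    "mask_to_sinogram",
    "merge_sinograms",
    "hdfov_reconstruct",
]

log = logging.getLogger(__name__)


class EmptyMaskError(RuntimeError):
    """No voxel above the binarization threshold."""


@dataclass
class MassProfile:
    """Per-angle fan-weighted projection mass, per slice."""

    mass: np.ndarray  # (n_slices, n_angles)
    reference: np.ndarray  # (n_slices,)

    @property
    def normalized(self) -> np.ndarray:
        return self.mass / self.reference[:, None]


@dataclass
class DetruncationResult:
    sinogram: Sinogram  # bore-wide channel grid
    added_mass: np.ndarray  # (n_slices, n_angles)
    amplitude_corrections: list = field(default_factory=list)


def _channel_fan_angles(geometry: ScanGeometry) -> np.ndarray:
    """Fan angle gamma of each channel (atan(t_iso / RF))."""
    t = geometry.iso_channel_positions_mm()
    return np.arctan2(t, geometry.source_to_isocenter_mm)


def _mass_weights(geometry: ScanGeometry) -> np.ndarray:
    """Parallel-equivalent ray measure per channel: cos^3(gamma) * dt_iso.

    cos(gamma) is the fan weight RFD/sqrt(RFD^2+u^2); the extra cos^2
    factor is the Jacobian ds/dt of the fan-to-parallel impact-parameter
    map s = RF sin(gamma), so that sum(p * w) equals the parallel-beam
    row integral (= the area integral of mu) for complete data.
    """
    gamma = _channel_fan_angles(geometry)
    return np.cos(gamma) ** 3 * geometry.iso_spacing_mm


def _angle_gather(values: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """out[s, j, i] = values[s, (j + shift[i]) mod n_angles, i].

    Fractional shifts use periodic linear interpolation over the angle
    axis; the full rotation makes the wrap exact.
    """
    ns, na, nc = values.shape
    pos = (np.arange(na)[:, None] + shift[None, :]) % na  # (na, nc)
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    i1 = (i0 + 1) % na
    idx0 = np.broadcast_to(i0[None], (ns, na, nc))
    idx1 = np.broadcast_to(i1[None], (ns, na, nc))
    return np.take_along_axis(values, idx0, axis=1) * (1.0 - frac) + np.take_along_axis(
        values, idx1, axis=1
    ) * frac


def rebin_to_parallel(sino: Sinogram) -> np.ndarray:
    """Gather each channel's parallel-equivalent view: the fan ray
    (beta, channel i) belongs to the parallel view theta = beta - gamma_i,
    so parallel view j reads fan view j + gamma_i/dbeta per channel."""
    dbeta = 2.0 * np.pi / sino.geometry.n_angles
    delta = _channel_fan_angles(sino.geometry) / dbeta
    return _angle_gather(sino.values, delta)


def scatter_from_parallel(par: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Inverse indexing of :func:`rebin_to_parallel` (fan view a reads
    parallel view a - gamma_i/dbeta per channel)."""
    dbeta = 2.0 * np.pi / geometry.n_angles
    delta = _channel_fan_angles(geometry) / dbeta
    return _angle_gather(par, -delta)


def projection_mass(sino: Sinogram) -> MassProfile:
    """Per-view projection mass in the parallel-equivalent sense.

    Rows are rebinned channel-wise to parallel views and integrated with
    the parallel ray measure; for complete (untruncated) data the result
    is constant over views and equals the area integral of mu.  The
    reference is the maximum over views, since truncation only removes
    mass; ``normalized`` drops below 1 wherever data are truncated.
    """
    par = rebin_to_parallel(sino)
    w = _mass_weights(sino.geometry)
    mass = np.einsum("sac,c->sa", par, w)
    reference = mass.max(axis=1)
    if np.any(reference <= 0):
        raise ValueError("all-zero sinogram: projection-mass reference undefined")
    return MassProfile(mass, reference)


def _edge_mass(p_edge: float, w: np.ndarray, du: float, x: np.ndarray, width: float) -> np.ndarray:
    """Weighted mass of the cos^2 tail p_edge*cos^2(pi/2 * x/width)."""
    vals = np.where(x < width, p_edge * np.cos(0.5 * np.pi * np.minimum(x / width, 1.0)) ** 2, 0.0)
    return vals * w * du


def _solve_cos2_extension(
    p_edge: float,
    target: float,
    x: np.ndarray,
    w: np.ndarray,
    du: float,
) -> tuple[np.ndarray, float | None]:
    """Find tail width W so the added weighted mass hits ``target``.

    Returns the extension values on the channels at distances ``x`` from
    the edge and the amplitude-correction factor (None if not needed).
    """
    if p_edge <= 0 or target <= 0 or x.size == 0:
        return np.zeros_like(x), None
    w_max = float(x.max() + (x[1] - x[0] if x.size > 1 else du))
    full = _edge_mass(p_edge, w, du, x, w_max).sum()
    if full < target:
        corr = target / full
        vals = np.where(x < w_max, p_edge * np.cos(0.5 * np.pi * x / w_max) ** 2, 0.0)
        return corr * vals, float(corr)
    lo, hi = 0.0, w_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _edge_mass(p_edge, w, du, x, mid).sum() < target:
            lo = mid
        else:
            hi = mid
    width = 0.5 * (lo + hi)
    return (
        np.where(x < width, p_edge * np.cos(0.5 * np.pi * np.minimum(x / width, 1.0)) ** 2, 0.0),
        None,
    )


def cosine_detruncate(sino: Sinogram, tolerance: float = 1e-3) -> DetruncationResult:
    """Mass-consistency detruncation with cos^2-shaped edge extensions.

    Each truncated row is extended on the bore-wide channel grid so its
    fan-weighted mass reaches the reference (max over angles); the deficit
    is split between the two edges proportionally to the edge values.
    Rows whose edges carry no signal (untruncated) are returned unchanged.
    """
    wide = pad_to_bore(sino)
    i0, i1 = wide.measured_range
    geo = wide.geometry
    ns, na, nc = wide.values.shape

    # solve in the parallel-rebinned domain, where mass is angle-invariant
    par = rebin_to_parallel(wide)
    w = _mass_weights(geo)
    mass = np.einsum("sac,c->sa", par[:, :, i0:i1], w[i0:i1])
    reference = mass.max(axis=1)
    if np.any(reference <= 0):
        raise ValueError("all-zero sinogram: projection-mass reference undefined")

    du = geo.iso_spacing_mm
    x_left = (np.arange(i0)[::-1] + 1) * du  # distances of pad channels from the edge
    x_right = (np.arange(nc - i1) + 1) * du
    w_left = w[:i0] / du
    w_right = w[i1:] / du

    par_ext = np.zeros_like(par)
    added = np.zeros((ns, na))
    corrections: list = []
    for s in range(ns):
        ref = reference[s]
        for a in range(na):
            deficit = ref - mass[s, a]
            if deficit < -1e-6 * ref:
                raise ValueError("negative mass deficit: reference mis-selected")
            if deficit <= 0.1 * tolerance * ref:
                continue
            p_l = max(par[s, a, i0], 0.0)
            p_r = max(par[s, a, i1 - 1], 0.0)
            if p_l + p_r <= 0.0:
                continue  # no signal at the edges: nothing to extend
            d_l = deficit * p_l / (p_l + p_r)
            d_r = deficit * p_r / (p_l + p_r)
            ext_l, corr_l = _solve_cos2_extension(p_l, d_l, x_left, w_left, du)
            ext_r, corr_r = _solve_cos2_extension(p_r, d_r, x_right, w_right, du)
            par_ext[s, a, :i0] = ext_l
            par_ext[s, a, i1:] = ext_r
            added[s, a] = (ext_l * w_left).sum() * du + (ext_r * w_right).sum() * du
            for side, corr in (("left", corr_l), ("right", corr_r)):
                if corr is not None:
                    corrections.append((s, a, side, corr))
                    log.warning(
                        "slice %d view %d: %s deficit not absorbable within the bore; "
                        "amplitude boosted by %.3f",
                        s,
                        a,
                        side,
                        corr,
                    )
    # map the extensions back onto fan rows; measured channels untouched
    fan_ext = scatter_from_parallel(par_ext, geo)
    values = wide.values.copy()
    values[:, :, :i0] = fan_ext[:, :, :i0]
    values[:, :, i1:] = fan_ext[:, :, i1:]
    out = Sinogram(values, geo, wide.measured.copy())
    return DetruncationResult(out, added, corrections)


def linear_cos2_detruncate(sino: Sinogram) -> DetruncationResult:
    """Slope-matched linear x cos^2 extrapolation out to the bore.

    p(u) = max(0, p_edge + s*(u - u_edge)) * cos^2(pi/2 * (u-u_edge)/W),
    with s the one-sided finite-difference slope at the edge channel and W
    the channel distance from the edge to the bore projection.  Intended
    as a convolution-only extension (filtering, never backprojection).
    """
    wide = pad_to_bore(sino)
    i0, i1 = wide.measured_range
    geo = wide.geometry
    du = geo.channel_spacing_mm
    ns, na, nc = wide.values.shape
    values = wide.values.copy()
    added = np.zeros((ns, na))
    w = geo.fan_weights()

    x_left = (np.arange(i0)[::-1] + 1) * du
    x_right = (np.arange(nc - i1) + 1) * du
    w_bore_left = (i0 + 0.5) * du
    w_bore_right = (nc - i1 + 0.5) * du

    def tail(p_edge: float, slope_out: float, x: np.ndarray, w_bore: float) -> np.ndarray:
        lin = np.maximum(p_edge + slope_out * x, 0.0)
        return lin * np.cos(0.5 * np.pi * np.minimum(x / w_bore, 1.0)) ** 2

    for s in range(ns):
        for a in range(na):
            row = values[s, a]
            p_l, p_r = row[i0], row[i1 - 1]
            # one-sided slopes continued outward (x grows away from the edge)
            slope_l = (row[i0] - row[i0 + 1]) / du
            slope_r = (row[i1 - 1] - row[i1 - 2]) / du
            if i0 > 0 and p_l > 0:
                row[:i0] = tail(p_l, slope_l, x_left, w_bore_left)
            if i1 < nc and p_r > 0:
                row[i1:] = tail(p_r, slope_r, x_right, w_bore_right)
            added[s, a] = (row[:i0] * w[:i0]).sum() * du + (row[i1:] * w[i1:]).sum() * du
    out = Sinogram(values, geo, wide.measured.copy())
    return DetruncationResult(out, added)


def binarize_object(
    image: CTImage,
    sigma_mm: float = 5.0,
    sigma_slices: float = 1.0,
    threshold_hu: float = -400.0,
) -> np.ndarray:
    """Gaussian-smoothed threshold mask of the scanned object.

    3D Gaussian low-pass (in-plane ``sigma_mm``, across slices
    ``sigma_slices``, in slices), threshold, keep the largest connected
    component, fill in-plane holes (internal air such as lungs belongs to
    the body outline).
    """
    if sigma_mm < 0 or sigma_slices < 0:
        raise ValueError("sigma must be >= 0")
    sig_px = sigma_mm / image.pixel_spacing_mm
    smooth = ndimage.gaussian_filter(image.values, (sigma_slices, sig_px, sig_px))
    mask = smooth > threshold_hu
    if not mask.any():
        raise EmptyMaskError("no voxel above the binarization threshold")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = np.stack([ndimage.binary_fill_holes(sl) for sl in mask])
    return mask


def mask_to_sinogram(
    mask: np.ndarray,
    grid: CTImage,
    geometry: ScanGeometry,
    mu_water_per_mm: float = DEFAULT_MU_WATER,
) -> Sinogram:
    """Forward-project a water-filled binary mask on the given geometry."""
    mu = np.asarray(mask, dtype=np.float64) * mu_water_per_mm
    return forward_project_mu(mu, grid, geometry)


def merge_sinograms(measured: Sinogram, simulated: Sinogram, fade_channels: int = 3) -> Sinogram:
    """Measured data inside the sFoV, simulated data beyond.

    The output equals the measured sinogram bit-exactly on its measured
    channels; simulated values fill the rest.  The junction discrepancy
    (measured minus simulated at the edge channel) is feathered linearly
    over ``fade_channels`` channels on the simulated side, so a simulated
    sinogram that already agrees with the measurement passes through
    untouched.
    """
    wide = pad_to_bore(measured)
    if simulated.values.shape != wide.values.shape:
        raise ValueError("simulated sinogram does not match the bore-wide grid")
    if simulated.geometry.n_channels != wide.geometry.n_channels:
        raise ValueError("channel grid mismatch")
    i0, i1 = wide.measured_range
    out = simulated.values.copy()
    out[:, :, i0:i1] = wide.values[:, :, i0:i1]
    nc = out.shape[2]
    jump_l = wide.values[:, :, i0] - simulated.values[:, :, i0]
    jump_r = wide.values[:, :, i1 - 1] - simulated.values[:, :, i1 - 1]
    for k in range(1, fade_channels + 1):
        w = 1.0 - k / (fade_channels + 1.0)
        if i0 - k >= 0:
            out[:, :, i0 - k] = simulated.values[:, :, i0 - k] + w * jump_l
        if i1 - 1 + k < nc:
            out[:, :, i1 - 1 + k] = simulated.values[:, :, i1 - 1 + k] + w * jump_r
    return Sinogram(out, wide.geometry, wide.measured.copy())


@dataclass
class HDFoVConfig:
    fov_mm: float = 800.0
    matrix: int = 512
    first_pass_matrix: int = 256
    sigma_mm: float = 5.0
    sigma_slices: float = 1.0
    threshold_hu: float = -400.0
    fade_channels: int = 3
    filter_name: str = "ramp"
    mu_water_per_mm: float = DEFAULT_MU_WATER


def hdfov_reconstruct(
    measured: Sinogram,
    config: HDFoVConfig | None = None,
    return_intermediates: bool = False,
):
    """Two-step mass-consistency eFoV reconstruction (HDFoV).

    cosine detruncation -> bore-wide first-pass FBP -> Gaussian smoothing
    and binarization -> forward projection of the water-filled mask ->
    projection-domain merge (measured data preserved bit-exactly) ->
    final FBP.
    """
    cfg = config or HDFoVConfig()
    det = cosine_detruncate(measured)
    first = fbp_reconstruct(
        det.sinogram,
        fov_mm=2.0 * measured.geometry.bore_radius_mm,
        matrix=cfg.first_pass_matrix,
        filter_name=cfg.filter_name,
        mu_water_per_mm=cfg.mu_water_per_mm,
    )
    try:
        mask = binarize_object(first, cfg.sigma_mm, cfg.sigma_slices, cfg.threshold_hu)
    except EmptyMaskError:
        log.warning("empty first-pass mask; falling back to the detruncated reconstruction")
        final = fbp_reconstruct(
            det.sinogram,
            fov_mm=cfg.fov_mm,
            matrix=cfg.matrix,
            filter_name=cfg.filter_name,
            mu_water_per_mm=cfg.mu_water_per_mm,
        )
        return (final, {"detruncated": det, "first_pass": first}) if return_intermediates else final
    simulated = mask_to_sinogram(mask, first, det.sinogram.geometry, cfg.mu_water_per_mm)
    merged = merge_sinograms(measured, simulated, cfg.fade_channels)
    final = fbp_reconstruct(
        merged,
        fov_mm=cfg.fov_mm,
        matrix=cfg.matrix,
        filter_name=cfg.filter_name,
        mu_water_per_mm=cfg.mu_water_per_mm,
    )
    if return_intermediates:
        return final, {
            "detruncated": det,
            "first_pass": first,
            "mask": mask,
            "simulated": simulated,
            "merged": merged,
        }
    return final
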