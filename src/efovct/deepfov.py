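"""Projection-domain network-fusion eFoV reconstruction (HDeepFoV).

Instead of binarizing a mass-consistency reconstruction, this pipeline
asks an image-domain estimator for a full-FoV estimate of the object,
forward-projects that estimate on the bore-wide channel grid, and fuses
it with the measured data in the projection domain: measured channels are
kept bit-exactly, simulated channels fill the eFoV, and the final image
is reconstructed by ordinary FBP at full resolution.  Because the
estimate only ever enters through the projector, the final image is a
genuine 512^2 reconstruction, never an upsampled network output, and the
noise/resolution character inside the sFoV matches a plain FBP.

The estimator contract is deliberately small: a callable mapping a
256 x 256, 800 mm FoV HU image stack to an image on the identical grid,
with output clipped to [-1000, 3000] HU.  Three implementations are
provided: an oracle (returns the known ground truth; upper bound), the
identity (returns its input; lower bound requiring no training), and the
trained network from :mod:`efovct.training`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CTImage, Sinogram
from .detruncation import linear_cos2_detruncate, merge_sinograms
from .projection import (
    DEFAULT_MU_WATER,
    fbp_reconstruct,
    forward_project,
)

__all__ = [
    "Estimator",
    "OracleEstimator",
    "IdentityEstimator",
    "prepare_network_input",
    "hdeepfov_reconstruct",
    "HDeepFoVConfig",
    "downsample_image",
]

NETWORK_MATRIX = 256
NETWORK_FOV_MM = 800.0
HU_MIN, HU_MAX = -1000.0, 3000.0


def downsample_image(image: CTImage, factor: int) -> CTImage:
    """Area-averaging downsample by an integer factor."""
    n = image.matrix
    if n % factor:
        raise ValueError("matrix not divisible by downsampling factor")
    m = n // factor
    vals = image.values.reshape(image.n_slices, m, factor, m, factor).mean(axis=(2, 4))
    return CTImage(vals, image.pixel_spacing_mm * factor, image.slice_thickness_mm, image.origin)


class Estimator:
    """Callable contract for eFoV image estimators.

    ``kind`` is one of {"oracle", "identity", "trained"}.  Implementations
    must return an image on the same 256^2 / 800 mm grid as the input,
    clipped to [-1000, 3000] HU.
    """

    kind: str = "abstract"

    def __call__(self, image: CTImage) -> CTImage:  # pragma: no cover - interface
        raise NotImplementedError

    @staticmethod
    def _validate_grid(image: CTImage) -> None:
        if image.matrix != NETWORK_MATRIX:
            raise ValueError(f"estimator grid must be {NETWORK_MATRIX}^2, got {image.matrix}^2")


class OracleEstimator(Estimator):
    """Returns the known ground-truth image (downsampled to the network
    grid); the upper bound of what any estimator could achieve."""

    kind = "oracle"

    def __init__(self, ground_truth: CTImage):
        if ground_truth.matrix % NETWORK_MATRIX:
            raise ValueError("ground truth matrix must be divisible by 256")
        factor = ground_truth.matrix // NETWORK_MATRIX
        self._truth = downsample_image(ground_truth, factor) if factor > 1 else ground_truth

    def __call__(self, image: CTImage) -> CTImage:
        self._validate_grid(image)
        if self._truth.n_slices != image.n_slices:
            raise ValueError("oracle slice count mismatch")
        vals = np.clip(self._truth.values, HU_MIN, HU_MAX)
        return CTImage(vals, image.pixel_spacing_mm, image.slice_thickness_mm, image.origin)


class IdentityEstimator(Estimator):
    """Passes the network input through unchanged (clipped)."""

    kind = "identity"

    def __call__(self, image: CTImage) -> CTImage:
        self._validate_grid(image)
        vals = np.clip(image.values, HU_MIN, HU_MAX)
        return CTImage(vals, image.pixel_spacing_mm, image.slice_thickness_mm, image.origin)


def prepare_network_input(
    measured: Sinogram,
    recon_matrix: int = 512,
    filter_name: str = "ramp",
    mu_water_per_mm: float = DEFAULT_MU_WATER,
) -> CTImage:
    """Standardized estimator input reconstruction.

    The measured sinogram is extrapolated with the slope-matched
    linear x cos^2 tail, which is used during the convolution step only
    (backprojection reads measured channels exclusively); the 800 mm FoV
    reconstruction is then area-averaged down to the 256^2 network grid.
    Training and inference share this exact procedure.
    """
    ext = linear_cos2_detruncate(measured)
    rec = fbp_reconstruct(
        measured,
        fov_mm=NETWORK_FOV_MM,
        matrix=recon_matrix,
        filter_name=filter_name,
        conv_only_extension=ext.sinogram,
        mu_water_per_mm=mu_water_per_mm,
    )
    if recon_matrix == NETWORK_MATRIX:
        return rec
    return downsample_image(rec, recon_matrix // NETWORK_MATRIX)


@dataclass
class HDeepFoVConfig:
    fov_mm: float = 800.0
    matrix: int = 512
    input_matrix: int = 512
    fade_channels: int = 3
    filter_name: str = "ramp"
    mu_water_per_mm: float = DEFAULT_MU_WATER


def hdeepfov_reconstruct(
    measured: Sinogram,
    estimator: Estimator,
    config: HDeepFoVConfig | None = None,
    return_intermediates: bool = False,
):
    """Network-fusion eFoV reconstruction.

    prepare input -> estimator -> forward projection of the estimate on
    the bore-wide grid -> projection-domain merge (measured data
    preserved bit-exactly) -> final full-resolution FBP.  No image-domain
    blending or empirical scaling is involved.
    """
    cfg = config or HDeepFoVConfig()
    net_in = prepare_network_input(
        measured, cfg.input_matrix, cfg.filter_name, cfg.mu_water_per_mm
    )
    estimate = estimator(net_in)
    if estimate.matrix != net_in.matrix or estimate.n_slices != net_in.n_slices:
        raise ValueError("estimator output grid mismatch")
    wide_geo, _ = measured.geometry.widened_to(measured.geometry.bore_radius_mm)
    simulated = forward_project(estimate, wide_geo, cfg.mu_water_per_mm)
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
            "network_input": net_in,
            "estimate": estimate,
            "simulated": simulated,
            "merged": merged,
        }
    return final
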