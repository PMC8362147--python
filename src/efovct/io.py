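"""Container file format and run configuration.

Sinograms and CT images are stored in HDF5: one dataset ``values`` plus
scalar attributes for every metadata field, and (for sinograms) a
``measured`` dataset and a ``geometry`` attribute group.  Round trips
are bit-exact.  Configurations are YAML documents validated by pydantic
models with unknown keys rejected.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .containers import CTImage, Sinogram
from .geometry import ScanGeometry

__all__ = [
    "write_image",
    "read_image",
    "write_sinogram",
    "read_sinogram",
    "GeometryConfig",
    "PhantomConfig",
    "ReconstructionConfig",
    "TrainingBlock",
    "EvaluationConfig",
    "RunConfig",
    "load_config",
    "dump_config",
]

_GEO_FIELDS = [
    "source_to_isocenter_mm",
    "source_to_detector_mm",
    "n_channels",
    "channel_spacing_mm",
    "n_angles",
    "sfov_radius_mm",
    "bore_radius_mm",
]


def _write_geometry(grp: h5py.Group, geo: ScanGeometry) -> None:
    g = grp.create_group("geometry")
    for name in _GEO_FIELDS:
        g.attrs[name] = getattr(geo, name)


def _read_geometry(grp: h5py.Group) -> ScanGeometry:
    attrs = grp["geometry"].attrs
    kwargs = {name: attrs[name] for name in _GEO_FIELDS}
    kwargs["n_channels"] = int(kwargs["n_channels"])
    kwargs["n_angles"] = int(kwargs["n_angles"])
    return ScanGeometry(**kwargs)


def write_image(path: str | Path, image: CTImage) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=image.values)
        d.attrs["units"] = "HU"
        f.attrs["kind"] = "ct_image"
        f.attrs["pixel_spacing_mm"] = image.pixel_spacing_mm
        f.attrs["slice_thickness_mm"] = image.slice_thickness_mm
        f.attrs["origin_mm"] = image.origin


def read_image(path: str | Path) -> CTImage:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "ct_image":
            raise ValueError(f"{path} is not a CT image container")
        return CTImage(
            f["values"][()],
            float(f.attrs["pixel_spacing_mm"]),
            float(f.attrs["slice_thickness_mm"]),
            tuple(f.attrs["origin_mm"]),
        )


def write_sinogram(path: str | Path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=sino.values)
        d.attrs["units"] = "line integral of mu (dimensionless)"
        f.attrs["kind"] = "sinogram"
        f.create_dataset("measured", data=sino.measured)
        _write_geometry(f, sino.geometry)


def read_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "sinogram":
            raise ValueError(f"{path} is not a sinogram container")
        return Sinogram(f["values"][()], _read_geometry(f), f["measured"][()])


def export_png(path: str | Path, image: CTImage, window: tuple[float, float] = (-1000.0, 1000.0)) -> None:
    """Optional lossless raster export of the middle slice for inspection."""
    import imageio.v3 as iio

    lo, hi = window
    sl = image.values[image.n_slices // 2]
    arr = np.clip((sl - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 65535).astype(np.uint16))


# ----------------------------------------------------------------------
class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    source_to_isocenter_mm: float = 595.0
    source_to_detector_mm: float = 1086.0
    n_channels: int = 512
    channel_spacing_mm: float = 2.0
    n_angles: int = 720
    sfov_radius_mm: float = 250.0
    bore_radius_mm: float = 400.0

    def build(self) -> ScanGeometry:
        return ScanGeometry(**self.model_dump())


class PhantomConfig(_Strict):
    width_mm: float = 560.0
    height_mm: float = 270.0
    body_hu: float = 100.0
    lung_hu: float = -700.0
    n_slices: int = 3
    with_inserts: bool = True
    raster_matrix: int = 512
    exclude_table: bool = False  # interface parity; synthetic data has no table


class ReconstructionConfig(_Strict):
    algorithm: str = "hdfov"  # hdfov | hdeepfov | naive
    matrix: int = 512
    fov_mm: float = 800.0
    filter_name: str = "ramp"
    estimator: str = "oracle"  # oracle | identity | model:<path>
    first_pass_matrix: int = 256
    sigma_mm: float = 5.0
    sigma_slices: float = 1.0
    threshold_hu: float = -400.0
    fade_channels: int = 3


class TrainingBlock(_Strict):
    n_pairs: int = 500
    n_angles: int = 360
    depth: int = 3
    base_channels: int = 8
    leaky_slope: float = 0.01
    stem_pool: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 30
    validation_fraction: float = 0.2


class EvaluationConfig(_Strict):
    threshold_hu: float = -400.0
    bin_width_hu: float = 10.0
    couch_offsets_mm: list[float] = Field(default_factory=lambda: [0.0, 90.0, 120.0])
    stitch_lateral_shift_mm: float = 60.0


class RunConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)
    training: TrainingBlock = Field(default_factory=TrainingBlock)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    seed: int = 0
    output_dir: str = "efovct_out"


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (all defaults materialized)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
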