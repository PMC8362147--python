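"""Fan-beam scan geometry.

The scanner model is a third-generation fan-beam CT: an x-ray source
rotating on a circle of radius ``source_to_isocenter_mm`` (RF) around the
isocenter, with a flat equally-spaced detector at distance
``source_to_detector_mm`` (RFD) from the source.  The central circular
region that is seen by the detector at every angle is the scan
field-of-view (sFoV); the physical opening of the scanner is the bore.
Objects may extend beyond the sFoV (into the extended FoV, eFoV) but must
fit inside the bore.

Channel centers sit at ``(i - (n_channels - 1) / 2) * channel_spacing_mm``
on the physical detector (0-based index ``i``).  Internally most math uses
the *virtual detector at the isocenter*: the detector coordinates scaled by
``RF / RFD``, which makes the impact parameter of a ray a simple function
of its channel coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ScanGeometry", "default_geometry"]


@dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam acquisition description.

    Parameters
    ----------
    source_to_isocenter_mm :
        Focus-to-isocenter distance RF.
    source_to_detector_mm :
        Focus-to-detector distance RFD (flat detector).
    n_channels :
        Number of detector channels.
    channel_spacing_mm :
        Channel pitch measured at the detector.
    n_angles :
        Number of projection angles, evenly spaced over a full rotation.
    sfov_radius_mm :
        Radius of the scan field-of-view (fully measured region).
    bore_radius_mm :
        Radius of the scanner opening; outer limit of any object.
    """

    source_to_isocenter_mm: float = 595.0
    source_to_detector_mm: float = 1086.0
    n_channels: int = 512
    channel_spacing_mm: float = 2.0
    n_angles: int = 720
    sfov_radius_mm: float = 250.0
    bore_radius_mm: float = 400.0

    def __post_init__(self) -> None:
        rf = self.source_to_isocenter_mm
        rfd = self.source_to_detector_mm
        if not (0 < rf < rfd):
            raise ValueError(f"need 0 < RF < RFD, got RF={rf}, RFD={rfd}")
        if self.channel_spacing_mm <= 0:
            raise ValueError("channel_spacing_mm must be > 0")
        if self.n_channels < 2 or self.n_angles < 2:
            raise ValueError("n_channels and n_angles must be >= 2")
        if not (0 < self.sfov_radius_mm <= self.bore_radius_mm):
            raise ValueError("need 0 < sfov_radius_mm <= bore_radius_mm")
        if self.bore_radius_mm >= rf:
            raise ValueError("bore must lie strictly inside the source orbit")
        # measured half-fan must cover the sFoV circle
        if math.asin(self.sfov_radius_mm / rf) > math.atan(self.half_detector_width_mm / rfd) + 1e-12:
            raise ValueError(
                "detector half-width does not cover the sFoV: "
                f"asin(sfov/RF)={math.asin(self.sfov_radius_mm / rf):.4f} > "
                f"atan(halfw/RFD)={math.atan(self.half_detector_width_mm / rfd):.4f}"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def half_detector_width_mm(self) -> float:
        """Physical half-width of the detector (to the outer channel edge)."""
        return 0.5 * self.n_channels * self.channel_spacing_mm

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_isocenter_mm

    @property
    def iso_spacing_mm(self) -> float:
        """Channel pitch on the virtual detector at the isocenter."""
        return self.channel_spacing_mm / self.magnification

    @property
    def angles_rad(self) -> np.ndarray:
        return np.linspace(0.0, 2.0 * np.pi, self.n_angles, endpoint=False)

    def channel_positions_mm(self) -> np.ndarray:
        """Channel center coordinates on the physical detector."""
        i = np.arange(self.n_channels)
        return (i - (self.n_channels - 1) / 2.0) * self.channel_spacing_mm

    def iso_channel_positions_mm(self) -> np.ndarray:
        """Channel center coordinates on the virtual detector at isocenter."""
        return self.channel_positions_mm() / self.magnification

    def fan_weights(self) -> np.ndarray:
        """Parallel-equivalent channel weight RFD / sqrt(RFD^2 + u^2).

        Equals cos(gamma) of the fan angle of each channel; used both for
        projection-mass bookkeeping and as the FBP cosine pre-weight.
        """
        u = self.channel_positions_mm()
        rfd = self.source_to_detector_mm
        return rfd / np.sqrt(rfd * rfd + u * u)

    def required_channels_for_radius(self, radius_mm: float) -> int:
        """Smallest even channel count whose fan covers a centered circle."""
        rf = self.source_to_isocenter_mm
        rfd = self.source_to_detector_mm
        if radius_mm >= rf:
            raise ValueError("radius must be smaller than RF")
        half_w = rfd * math.tan(math.asin(radius_mm / rf))
        n = int(math.ceil(2.0 * half_w / self.channel_spacing_mm))
        return n + (n % 2)

    def widened_to(self, radius_mm: float) -> tuple["ScanGeometry", int]:
        """Geometry with the detector symmetrically widened to cover
        a centered circle of ``radius_mm``.

        Returns the widened geometry and the per-side channel padding.
        """
        n_req = self.required_channels_for_radius(radius_mm)
        pad = max(0, (n_req - self.n_channels + 1) // 2)
        geo = replace(self, n_channels=self.n_channels + 2 * pad)
        return geo, pad

    def with_angles(self, n_angles: int) -> "ScanGeometry":
        return replace(self, n_angles=n_angles)


def default_geometry(n_angles: int = 720) -> ScanGeometry:
    """The desk-scale scanner: RF 595 mm, RFD 1086 mm, 500 mm sFoV,
    800 mm bore, 512 channels of 2 mm pitch."""
    return ScanGeometry(n_angles=n_angles)
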