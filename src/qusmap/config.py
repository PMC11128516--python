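"""Acquisition geometry and phantom descriptions.

The default :class:`AcquisitionConfig` mirrors a 7.5-MHz linear-array
acquisition sampled at 30 MHz: 1558 axial samples x 256 scan lines over a
40 mm x 40 mm field of view, with a 0.7 mm pulse length.  All physical
quantities are SI except where a field name says otherwise (mm).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ParameterError(ValueError):
    """Invalid physical/algorithmic parameter value."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Pulse-echo acquisition geometry of one RF frame.

    Attributes
    ----------
    center_frequency : float
        Transmit center frequency in Hz.
    sampling_frequency : float
        RF sampling rate in Hz.
    sound_speed : float
        Assumed speed of sound in m/s.
    n_samples, n_lines : int
        Axial samples per line and number of scan lines.
    lateral_extent_mm : float
        Lateral width of the imaged field in mm.
    pulse_periods : float
        Number of carrier periods in the Gaussian excitation pulse.
    axial_fwhm_target_mm, lateral_fwhm_target_mm : float
        Point-spread-function envelope FWHMs the simulator is calibrated to.
    pulse_length_mm : float
        Transducer pulse length (PL); sliding-window sides are multiples of it.
    """

    center_frequency: float = 7.5e6
    sampling_frequency: float = 30e6
    sound_speed: float = 1540.0
    n_samples: int = 1558
    n_lines: int = 256
    lateral_extent_mm: float = 40.0
    pulse_periods: float = 3.5
    axial_fwhm_target_mm: float = 0.7175
    lateral_fwhm_target_mm: float = 0.7194
    pulse_length_mm: float = 0.7

    def __post_init__(self) -> None:
        if self.sampling_frequency <= 0 or self.sound_speed <= 0:
            raise ParameterError("sampling_frequency and sound_speed must be positive")
        if self.n_samples < 2 or self.n_lines < 2:
            raise ParameterError("frame must have at least 2 samples and 2 lines")
        if self.lateral_extent_mm <= 0 or self.pulse_length_mm <= 0:
            raise ParameterError("lateral_extent_mm and pulse_length_mm must be positive")

    @property
    def axial_spacing_mm(self) -> float:
        """Axial sample spacing c/(2 fs) in mm."""
        return self.sound_speed / (2.0 * self.sampling_frequency) * 1e3

    @property
    def lateral_pitch_mm(self) -> float:
        """Scan-line pitch in mm."""
        return self.lateral_extent_mm / self.n_lines

    @property
    def depth_mm(self) -> float:
        """Imaged depth n_samples * axial spacing in mm."""
        return self.n_samples * self.axial_spacing_mm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)


@dataclass(frozen=True)
class ResolutionCell:
    """PSF-FWHM resolution cell; volume is the product of the three FWHMs."""

    axial_fwhm_mm: float
    lateral_fwhm_mm: float
    elevational_fwhm_mm: float

    @property
    def volume_mm3(self) -> float:
        return self.axial_fwhm_mm * self.lateral_fwhm_mm * self.elevational_fwhm_mm

    @property
    def area_mm2(self) -> float:
        """In-plane (axial x lateral) cell area used for 2-D densities."""
        return self.axial_fwhm_mm * self.lateral_fwhm_mm


@dataclass(frozen=True)
class PhantomSpec:
    """A scattering phantom: uniform background plus one denser disk inclusion.

    Densities are scatterers per (2-D, axial x lateral) resolution cell.
    ``inclusion_density`` is the total density inside the disk and must be at
    least ``background_density``; set them equal (or ``inclusion_diameter_mm``
    to 0) for a homogeneous phantom.

    ``amplitude_distribution`` controls per-scatterer reflectivity:
    ``"normal"`` (standard normal, the Field II phantom convention — random
    reflectivities lower the *effective* scatterer number per cell by the
    amplitude-kurtosis factor 3) or ``"unit"`` (all ones).
    """

    field_width_mm: float = 40.0
    field_depth_mm: float = 40.0
    background_density: float = 2.0
    inclusion_density: float = 16.0
    inclusion_center_mm: tuple[float, float] = (20.0, 20.0)  # (lateral, axial)
    inclusion_diameter_mm: float = 10.0
    resolution_cell: ResolutionCell = field(
        default_factory=lambda: ResolutionCell(0.7175, 0.7194, 0.7194)
    )
    amplitude_distribution: str = "normal"

    def __post_init__(self) -> None:
        if self.amplitude_distribution not in ("normal", "unit"):
            raise ParameterError("amplitude_distribution must be 'normal' or 'unit'")
        if self.field_width_mm <= 0 or self.field_depth_mm <= 0:
            raise ParameterError("field dimensions must be positive")
        if self.background_density <= 0 or self.inclusion_density <= 0:
            raise ParameterError("scatterer densities must be positive")
        if self.inclusion_diameter_mm < 0:
            raise ParameterError("inclusion diameter must be nonnegative")
        if (
            self.inclusion_diameter_mm > 0
            and self.inclusion_density < self.background_density
        ):
            raise ParameterError(
                "inclusion_density must be >= background_density "
                "(the inclusion is modeled as background plus extra scatterers)"
            )

    @classmethod
    def homogeneous(cls, density: float, **kwargs) -> "PhantomSpec":
        return cls(
            background_density=density,
            inclusion_density=density,
            inclusion_diameter_mm=0.0,
            **kwargs,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inclusion_center_mm"] = list(self.inclusion_center_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "resolution_cell" in d and isinstance(d["resolution_cell"], dict):
            d["resolution_cell"] = ResolutionCell(**d["resolution_cell"])
        if "inclusion_center_mm" in d:
            d["inclusion_center_mm"] = tuple(d["inclusion_center_mm"])
        return cls(**d)


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON key-value config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(obj: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2))
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
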