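"""Configuration objects shared across the pipeline.

All physical quantities carry explicit units in their field names or
docstrings: lengths in nm or µm as stated, times in seconds or minutes,
intensities in arbitrary fluorescence units (a.u.).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["NoiseModel", "SimConfig", "PipelineConfig", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    """Raised when a configuration or simulation parameter is out of range."""


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian camera noise model.

    gaussian_sigma
        Additive read-noise standard deviation, a.u.
    poisson_gain
        a.u. per photon for shot noise; 0 disables the Poisson component.
    """

    gaussian_sigma: float = 3.0
    poisson_gain: float = 0.5

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.poisson_gain < 0:
            raise InvalidParameterError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Imaging conditions for the synthetic generators.

    pixel_size : nm per pixel (default 80, a typical 63x confocal pitch).
    psf_sigma  : Gaussian PSF standard deviation in nm (default 110).
    image_shape: (rows, cols) in pixels.
    Identical seeds give bit-identical output from every generator.
    """

    seed: int = 0
    pixel_size: float = 80.0
    psf_sigma: float = 110.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.psf_sigma < 0:
            raise InvalidParameterError("psf_sigma must be >= 0")
        if len(self.image_shape) != 2 or any(int(s) <= 0 for s in self.image_shape):
            raise InvalidParameterError("image_shape must be two positive integers")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-side defaults for every pipeline stage.

    Channel roles map color names to 0-based channel indices of the input
    TIFF. Unknown keys in a mapping/YAML file are rejected rather than
    silently ignored.
    """

    # channel roles: 0-based indices into the channel axis
    green: int = 0
    red: int = 1
    blue: int = 2
    pixel_size: float = 80.0  # nm/px
    seed: int = 0
    # snapshot segmentation
    nucleus_min_separation: float = 10.0  # µm, minimum seed spacing
    smoothing_sigma: float = 1.0  # µm, channel pre-smoothing
    small_object_area: float = 0.5  # µm², accumulation-mask cleanup
    interface_assignment_radius: float = 1.5  # µm, dual-lattice capture radius
    min_interface_length: float = 2.0  # µm, contact below this is never flagged
    # FRAP
    strip_width: int = 9  # px, normal max-projection strip
    # accumulation statistics
    log_bins: int = 50
    intensity_floor: float = 10.0  # a.u., dimmest-cell value after shifting
    # rainbow / polarity
    normal_halfwidth: float = 12.0  # px, straightening half-width
    gradient_box: float = 3.0  # µm, cytoplasmic measurement box side
    gradient_standoff: float = 1.5  # µm, box standoff from the boundary
    vesicle_percentile: float = 99.0  # per-cell vesicle exclusion threshold
    np_gap_threshold: float = 30.0  # nm, |mean gap| below which p = 0
    min_gap_positions: int = 5  # minimum quality-passing positions for polarity

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.strip_width < 1 or self.strip_width % 2 == 0:
            raise InvalidParameterError("strip_width must be odd and >= 1")
        if self.log_bins < 2:
            raise InvalidParameterError("log_bins must be >= 2")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown configuration keys: {sorted(unknown)}"
            )
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise InvalidParameterError(f"{path} does not contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return asdict(self)
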