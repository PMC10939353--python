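"""Configuration objects for the f2f pipeline.

The optical configuration is the single source every default length scale is
derived from: the physical pixel size converts pixels to nanometres, and the
diffraction limit (in pixels) parameterizes the spot-detection window and all
selection radii.  With the reference setup (×100 / 1.49 NA objective, 6.45 µm
sensor pixels → 64.5 nm per pixel, diffraction limit ≈ 5.5 px) the derived
defaults are the recommended ones: an 11 px detection/median window, a 10 px
closest-neighbour radius and a 13 px cell-contour radius.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ParameterError

#: Gaussian FWHM in units of sigma.
_FWHM = 2.355


@dataclass(frozen=True)
class OpticalConfig:
    """Physical description of the microscope and camera.

    Parameters
    ----------
    pixel_size_nm:
        Sample-plane pixel size in nanometres (default 64.5 nm: a 6.45 µm
        sensor pixel behind a ×100 objective).
    diffraction_limit_px:
        Diffraction limit of the optics expressed in pixels.  The default of
        5.5 px makes "twice the diffraction limit" an 11 px window.
    psf_sigma_px:
        Standard deviation of the Gaussian point-spread function in pixels.
        If ``None`` it is derived as ``diffraction_limit_px / 2.355`` so the
        PSF FWHM matches the diffraction limit.
    image_shape:
        Frame size as (rows, cols).
    """

    pixel_size_nm: float = 64.5
    diffraction_limit_px: float = 5.5
    psf_sigma_px: float | None = None
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be > 0")
        if self.diffraction_limit_px <= 0:
            raise ParameterError("diffraction_limit_px must be > 0")
        if self.psf_sigma_px is not None and self.psf_sigma_px <= 0:
            raise ParameterError("psf_sigma_px must be > 0")
        if len(self.image_shape) != 2 or min(self.image_shape) < 16:
            raise ParameterError("image_shape must be (rows, cols), each >= 16")

    @property
    def sigma_px(self) -> float:
        """Effective PSF sigma in pixels."""
        if self.psf_sigma_px is not None:
            return self.psf_sigma_px
        return self.diffraction_limit_px / _FWHM

    @property
    def median_diameter_px(self) -> int:
        """Twice the diffraction limit, rounded to the nearest odd integer."""
        d = int(round(2.0 * self.diffraction_limit_px))
        return d if d % 2 == 1 else d + 1

    @property
    def max_closest_neighbour_px(self) -> float:
        """Default isolation radius: twice the diffraction limit minus 1 px."""
        return float(self.median_diameter_px - 1)

    @property
    def max_contour_dist_px(self) -> float:
        """Default contour-distance radius: twice the diffraction limit plus 2 px."""
        return float(self.median_diameter_px + 2)

    def nm_to_px(self, nm: float) -> float:
        return nm / self.pixel_size_nm

    def px_to_nm(self, px: float) -> float:
        return px * self.pixel_size_nm


@dataclass(frozen=True)
class PreprocessConfig:
    """Background-subtraction parameters.

    ``rolling_ball_radius_px`` should be slightly larger than the cell
    radius; ``median_diameter_px`` is twice the diffraction limit (odd).
    """

    rolling_ball_radius_px: float = 70.0
    median_diameter_px: int = 11

    def __post_init__(self) -> None:
        if self.rolling_ball_radius_px <= 0:
            raise ParameterError("rolling_ball_radius_px must be > 0")
        if self.median_diameter_px < 3 or self.median_diameter_px % 2 == 0:
            raise ParameterError("median_diameter_px must be odd and >= 3")

    @classmethod
    def from_optical(cls, optical: OpticalConfig,
                     rolling_ball_radius_px: float = 70.0) -> "PreprocessConfig":
        return cls(rolling_ball_radius_px=rolling_ball_radius_px,
                   median_diameter_px=optical.median_diameter_px)


@dataclass(frozen=True)
class DetectionConfig:
    """Spot detection and cross-channel linking parameters."""

    diameter_px: int = 11
    percentile: float = 99.0
    min_mass: float = 1000.0
    max_sep_px: float = 2.0          # 2 px intra-assembly, 3 px inter-assembly
    link_mode: str = "mutual"        # "mutual" | "greedy"

    def __post_init__(self) -> None:
        if self.diameter_px < 3 or self.diameter_px % 2 == 0:
            raise ParameterError("diameter_px must be odd and >= 3")
        if not 0 <= self.percentile < 100:
            raise ParameterError("percentile must be in [0, 100)")
        if self.max_sep_px <= 0:
            raise ParameterError("max_sep_px must be > 0")
        if self.link_mode not in ("mutual", "greedy"):
            raise ParameterError("link_mode must be 'mutual' or 'greedy'")


@dataclass(frozen=True)
class SelectionConfig:
    """Spot-pair quality cascade thresholds."""

    max_closest_neighbour_px: float = 10.0
    max_contour_dist_px: float = 13.0
    density_cutoff: float = 0.5
    density_min_pairs: int = 20
    r2_threshold: float = 0.35
    segmentation_backend: str = "threshold"   # "threshold" | "external_mask"

    def __post_init__(self) -> None:
        if not 0 < self.density_cutoff < 1:
            raise ParameterError("density_cutoff must be in (0, 1)")
        if not 0 <= self.r2_threshold <= 1:
            raise ParameterError("r2_threshold must be in [0, 1]")
        if self.segmentation_backend not in ("threshold", "external_mask"):
            raise ParameterError(
                "segmentation_backend must be 'threshold' or 'external_mask'")

    @classmethod
    def from_optical(cls, optical: OpticalConfig, **kw) -> "SelectionConfig":
        return cls(max_closest_neighbour_px=optical.max_closest_neighbour_px,
                   max_contour_dist_px=optical.max_contour_dist_px, **kw)


def default_trim_grid() -> tuple[float, ...]:
    """Candidate upper-tail trim fractions: 0%, 2.5%, ..., 30%."""
    return tuple(round(0.025 * k, 4) for k in range(13))


@dataclass(frozen=True)
class EstimationConfig:
    """Rician MLE and bootstrap outlier-rejection parameters."""

    n_boot: int = 100
    trim_grid: tuple[float, ...] = field(default_factory=default_trim_grid)
    seed: int = 0
    min_n_reject: int = 10

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ParameterError("n_boot must be >= 1")
        if any(not 0 <= f < 1 for f in self.trim_grid):
            raise ParameterError("trim fractions must be in [0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Full workflow configuration (a serialized RunConfig plus the input
    files fully determines a run)."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    seed: int = 0
    match_tol_px: float = 2.0
    tre_gate_nm: float = 1.0
    enforce_tre_gate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(t, key):
            sub = dict(d.get(key, {}))
            if key == "optical" and "image_shape" in sub:
                sub["image_shape"] = tuple(sub["image_shape"])
            if key == "estimation" and "trim_grid" in sub:
                sub["trim_grid"] = tuple(sub["trim_grid"])
            return t(**sub)

        top = {k: d[k] for k in
               ("seed", "match_tol_px", "tre_gate_nm", "enforce_tre_gate")
               if k in d}
        return cls(optical=build(OpticalConfig, "optical"),
                   preprocess=build(PreprocessConfig, "preprocess"),
                   detection=build(DetectionConfig, "detection"),
                   selection=build(SelectionConfig, "selection"),
                   estimation=build(EstimationConfig, "estimation"),
                   **top)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
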