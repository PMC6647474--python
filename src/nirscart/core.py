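"""Core spectral containers: wavelength grids and spectrum records.

The instrument pairs two diffuse-reflectance spectrometers sharing one probe:
detector A covers the visible/short-NIR range (0.35-1.1 um, 0.6 nm steps) and
detector B the NIR range (1.0-2.5 um, 6.4 nm steps).  A measurement is one
intensity vector per detector segment plus acquisition metadata (animal, leg,
anatomical site line, location index, repeat, modality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

SEGMENT_A = "A"
SEGMENT_B = "B"

#: default grid constants, in micrometres
DETECTOR_A_RANGE = (0.35, 1.10)
DETECTOR_A_STEP = 0.0006
DETECTOR_B_RANGE = (1.00, 2.50)
DETECTOR_B_STEP = 0.0064


class NirscartError(Exception):
    """Base class for package errors."""


class ConfigurationError(NirscartError, ValueError):
    pass


class AlignmentError(NirscartError, ValueError):
    pass


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniformly spaced wavelength axis of one detector segment, in um."""

    label: str
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ConfigurationError("grid needs at least two wavelengths")
        d = np.diff(w)
        if np.any(d <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ConfigurationError("grid spacing must be uniform")
        object.__setattr__(self, "wavelengths", w)

    @property
    def spacing(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other) -> bool:  # value semantics
        return (
            isinstance(other, WavelengthGrid)
            and self.label == other.label
            and self.wavelengths.shape == other.wavelengths.shape
            and bool(np.array_equal(self.wavelengths, other.wavelengths))
        )


def _uniform_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def detector_a_grid() -> WavelengthGrid:
    """Visible/short-NIR segment: 0.35-1.1 um at 0.6 nm."""
    return WavelengthGrid(SEGMENT_A, _uniform_grid(*DETECTOR_A_RANGE, DETECTOR_A_STEP))


def detector_b_grid() -> WavelengthGrid:
    """NIR segment: 1.0-2.5 um at 6.4 nm."""
    return WavelengthGrid(SEGMENT_B, _uniform_grid(*DETECTOR_B_RANGE, DETECTOR_B_STEP))


@dataclass
class RawSpectrum:
    """Two-segment intensity record with acquisition metadata.

    ``intensity`` maps segment label -> intensity vector (arbitrary
    reflectance units) matching the corresponding grid length.
    """

    grids: Mapping[str, WavelengthGrid]
    intensity: Mapping[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, grid in self.grids.items():
            y = np.asarray(self.intensity[label], dtype=float)
            if y.shape != (len(grid),):
                raise AlignmentError(
                    f"segment {label}: intensity length {y.shape} != grid {len(grid)}"
                )
            if not np.all(np.isfinite(y)):
                raise ValueError(f"segment {label}: non-finite intensity values")
            self.intensity[label] = y  # type: ignore[index]

    def copy(self) -> "RawSpectrum":
        return RawSpectrum(
            grids=dict(self.grids),
            intensity={k: v.copy() for k, v in self.intensity.items()},
            meta=dict(self.meta),
        )


@dataclass
class AnalysisSpectrum:
    """Preprocessed first-derivative spectrum on the cropped analysis grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise AlignmentError("wavelengths and values differ in length")


def replace_meta(spec: AnalysisSpectrum, **kw) -> AnalysisSpectrum:
    meta = dict(spec.meta)
    meta.update(kw)
    return AnalysisSpectrum(spec.wavelengths, spec.values, meta)
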