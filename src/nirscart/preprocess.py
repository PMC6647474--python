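"""Savitzky-Golay derivative preprocessing of dual-detector spectra.

Each detector segment is filtered separately with a 3rd-degree Savitzky-Golay
first-derivative filter whose window matches that detector's resolution
(139 points ~ 0.08 um on detector A, 41 points ~ 0.26 um on detector B).
Derivatives are scaled by the segment's wavelength spacing so both segments
are in common d/dlambda units.  Output is restricted to positions with a full
centered window (no padded extrapolation), cropped to the analysis region
(default 0.80-1.90 um), and the two segments are concatenated with detector A
used below a configurable boundary wavelength and detector B above it.

Because detector B starts at 1.0 um and its 41-point half-window spans
0.128 um, the first full-window B position is 1.128 um; with the default
boundary at 1.0 um the concatenated analysis grid therefore has a small
uncovered interval (1.0-1.128 um) rather than extrapolated boundary values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    SEGMENT_A,
    SEGMENT_B,
    AlignmentError,
    AnalysisSpectrum,
    ConfigurationError,
    RawSpectrum,
    WavelengthGrid,
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Savitzky-Golay and cropping parameters.

    window_a/window_b are filter window lengths in points for the two
    detector segments; crop is the analysis wavelength interval in um;
    boundary is the wavelength at which detector A hands over to detector B.
    """

    window_a: int = 139
    window_b: int = 41
    poly_degree: int = 3
    derivative_order: int = 1
    crop: tuple[float, float] = (0.80, 1.90)
    boundary: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.window_a, self.window_b):
            if w % 2 == 0 or w <= self.poly_degree:
                raise ConfigurationError(
                    "windows must be odd and greater than the polynomial degree"
                )
        if self.derivative_order > self.poly_degree:
            raise ConfigurationError("derivative order must not exceed degree")
        if self.crop[0] >= self.crop[1]:
            raise ConfigurationError("crop interval must be non-empty")

    def window_for(self, label: str) -> int:
        return self.window_a if label == SEGMENT_A else self.window_b


def savgol(
    values: np.ndarray,
    window: int,
    degree: int,
    deriv_order: int,
    spacing: float,
) -> np.ndarray:
    """Savitzky-Golay filter restricted to full-window (interior) positions.

    Each output point is the ``deriv_order``-th derivative of the local
    least-squares polynomial of the given degree over the centered window,
    scaled by ``spacing**-deriv_order``.  The returned series is shorter than
    the input by ``window - 1`` points (half a window at each end).
    """
    y = np.atleast_2d(np.asarray(values, dtype=float))
    if window % 2 == 0 or window <= degree:
        raise ConfigurationError("window must be odd and greater than degree")
    if y.shape[-1] < window:
        raise ValueError(
            f"series length {y.shape[-1]} shorter than window {window}"
        )
    half = window // 2
    out = savgol_filter(
        y, window, degree, deriv=deriv_order, delta=spacing, axis=-1
    )[..., half:-half]
    if np.asarray(values).ndim == 1:
        return out[0]
    return out


def _segment_selection(
    grid: WavelengthGrid, config: PreprocessConfig, label: str
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into the valid filtered series) and wavelengths kept for a segment."""
    half = config.window_for(label) // 2
    valid_w = grid.wavelengths[half : len(grid) - half]
    lo, hi = config.crop
    keep = (valid_w >= lo - 1e-12) & (valid_w <= hi + 1e-12)
    if label == SEGMENT_A:
        keep &= valid_w < config.boundary - 1e-12
    else:
        keep &= valid_w >= config.boundary - 1e-12
    return np.flatnonzero(keep), valid_w[keep]


def analysis_wavelengths(
    grids: dict[str, WavelengthGrid], config: PreprocessConfig
) -> np.ndarray:
    """The concatenated analysis grid implied by grids + config (a pure
    function of the configuration, identical for every spectrum in a run)."""
    parts = []
    for label in (SEGMENT_A, SEGMENT_B):
        _, w = _segment_selection(grids[label], config, label)
        parts.append(w)
    out = np.concatenate(parts)
    if out.size == 0:
        raise ConfigurationError("crop interval excludes every grid point")
    return out


def preprocess_matrix(
    intensities: dict[str, np.ndarray],
    grids: dict[str, WavelengthGrid],
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized preprocessing of stacked spectra.

    ``intensities`` maps segment label -> (n, grid length) matrix.  Returns
    (wavelengths, values) with values of shape (n, n_analysis_points).
    """
    blocks = []
    waves = []
    for label in (SEGMENT_A, SEGMENT_B):
        grid = grids[label]
        y = np.atleast_2d(intensities[label])
        if y.shape[1] != len(grid):
            raise AlignmentError(
                f"segment {label}: {y.shape[1]} columns vs grid {len(grid)}"
            )
        filt = savgol(
            y,
            config.window_for(label),
            config.poly_degree,
            config.derivative_order,
            grid.spacing,
        )
        idx, w = _segment_selection(grid, config, label)
        blocks.append(filt[:, idx])
        waves.append(w)
    out_w = np.concatenate(waves)
    if out_w.size == 0:
        raise ConfigurationError("crop interval excludes every grid point")
    return out_w, np.concatenate(blocks, axis=1)


def preprocess(
    raw: RawSpectrum, config: PreprocessConfig = PreprocessConfig()
) -> AnalysisSpectrum:
    """Preprocess one two-segment spectrum into an AnalysisSpectrum."""
    w, v = preprocess_matrix(
        {k: raw.intensity[k][None, :] for k in raw.grids},
        dict(raw.grids),
        config,
    )
    return AnalysisSpectrum(w, v[0], dict(raw.meta))


def average_repeats(spectra: Sequence[AnalysisSpectrum]) -> AnalysisSpectrum:
    """Pointwise mean of repeat spectra sharing one analysis grid.

    Metadata keeps fields shared by all repeats; the repeat index is cleared.
    """
    if not spectra:
        raise AlignmentError("cannot average an empty spectrum list")
    w0 = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != w0.shape or not np.allclose(
            s.wavelengths, w0, rtol=0, atol=1e-12
        ):
            raise AlignmentError("repeat spectra are on different grids")
    values = np.mean([s.values for s in spectra], axis=0)
    meta: dict = {}
    keys = set().union(*(s.meta.keys() for s in spectra))
    for k in keys:
        vals = {repr(s.meta.get(k, None)) for s in spectra}
        if len(vals) == 1:
            meta[k] = spectra[0].meta.get(k)
    meta.pop("repeat", None)
    return AnalysisSpectrum(w0, values, meta)
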