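"""Synthetic study cohort: latent cartilage state, forward-modelled spectra.

The generator emulates the design of the equine study the pipeline is built
for: 7 experimental ponies carrying surgically created chondral lesions and 3
healthy controls, two legs per pony, three anatomical measurement lines
(proximal/central/distal) with four locations at increasing distance from the
lesion, 3 in-vitro and 15 in-vivo repeat spectra per location, and a small
fraction (default 3.1%) of in-vivo repeats corrupted by poor probe contact
and arthroscopic light-source leakage.

Each location carries latent cartilage properties (thickness, proteoglycan
amplitude, a degeneration factor that decreases with distance from the
lesion, and the shape of the collagen orientation transition).  Latents map
to 500-point depth profiles, from which the five regression targets are
extracted; spectra are produced by a deliberately simple forward model -- a
power-law scattering baseline minus Gaussian absorption bands whose depths
are affine in the targets -- plus instrument noise and per-repeat gain
variation.  The model makes no claim about real cartilage optics; it is the
simplest construction under which the spectra carry recoverable information
about all five targets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    SEGMENT_A,
    SEGMENT_B,
    ConfigurationError,
    RawSpectrum,
    WavelengthGrid,
    detector_a_grid,
    detector_b_grid,
)
from .profiles import DepthProfile, DEPTH_GRID, extract_references

EXPERIMENTAL = "experimental"
CONTROL = "control"


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the virtual cohort."""

    n_experimental: int = 7
    n_control: int = 3
    site_lines: tuple[str, ...] = ("proximal", "central", "distal")
    locations_per_line: int = 4
    legs: tuple[str, ...] = ("L", "R")
    in_vitro_repeats: int = 3
    in_vivo_repeats: int = 15
    contamination_rate: float = 0.031
    noise_sd: float = 0.01
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_experimental", "n_control", "locations_per_line",
                     "in_vitro_repeats", "in_vivo_repeats"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.site_lines or not self.legs:
            raise ConfigurationError("need at least one site line and one leg")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ConfigurationError("contamination_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    @property
    def n_ponies(self) -> int:
        return self.n_experimental + self.n_control

    def pony_ids(self) -> list[str]:
        return [f"E{i + 1}" for i in range(self.n_experimental)] + [
            f"C{i + 1}" for i in range(self.n_control)
        ]


@dataclass(frozen=True)
class LatentProperties:
    """Latent cartilage state of one measurement location.

    thickness in mm; pg_amplitude scales the proteoglycan optical-density
    profile; degeneration in [0, 1] (0 for controls) drives proteoglycan
    depletion and collagen disruption; angle_steepness in [0, 1] sets how
    early and sharply the collagen orientation turns from surface-parallel
    to perpendicular.
    """

    thickness: float
    pg_amplitude: float
    degeneration: float
    angle_steepness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.pg_amplitude <= 0:
            raise ConfigurationError("thickness and pg_amplitude must be positive")
        if not 0.0 <= self.degeneration <= 1.0:
            raise ConfigurationError("degeneration must lie in [0, 1]")
        if not 0.0 <= self.angle_steepness <= 1.0:
            raise ConfigurationError("angle_steepness must lie in [0, 1]")


#: proteoglycan depth curve: smoothstep rise from 0.35 at the surface to 1 at
#: the subchondral interface, before amplitude scaling and depletion
_PG_SURFACE = 0.35
#: depletion mixes a uniform full-thickness loss with a surface-weighted term
_DEPLETION_UNIFORM = 0.25
_DEPLETION_SURFACE = 0.45
_DEPLETION_SCALE = 0.35
#: collagen transition: logistic in depth, midpoint/width set by steepness
_ANGLE_DROP = 8.0  # degrees removed from the deep zone at full degeneration


def pg_curve(depth: np.ndarray, latent: LatentProperties) -> np.ndarray:
    """Closed-form proteoglycan optical-density curve of one location."""
    d = np.asarray(depth, dtype=float)
    base = _PG_SURFACE + (1.0 - _PG_SURFACE) * (3 * d**2 - 2 * d**3)
    depletion = 1.0 - latent.degeneration * (
        _DEPLETION_UNIFORM + _DEPLETION_SURFACE * np.exp(-d / _DEPLETION_SCALE)
    )
    return latent.pg_amplitude * base * depletion


def angle_curve(depth: np.ndarray, latent: LatentProperties) -> np.ndarray:
    """Closed-form collagen orientation-angle curve (degrees) of one location."""
    d = np.asarray(depth, dtype=float)
    s = latent.angle_steepness
    midpoint = 0.45 - 0.25 * s
    width = 0.12 - 0.07 * s
    deep = 90.0 - _ANGLE_DROP * latent.degeneration
    return deep / (1.0 + np.exp(-(d - midpoint) / width))


def latent_to_profiles(latent: LatentProperties) -> tuple[DepthProfile, DepthProfile]:
    """Sample the closed-form curves on the 500-point depth grid."""
    return (
        DepthProfile(pg_curve(DEPTH_GRID, latent), kind="pg"),
        DepthProfile(angle_curve(DEPTH_GRID, latent), kind="angle"),
    )


@dataclass(frozen=True)
class SpectralForwardParams:
    """Forward-model constants linking latent targets to spectra.

    Band centers/widths in um; ``band_links`` has one row per band giving the
    affine coefficients of its absorption depth on
    (1, pg_full, pg_sup, angle_full/90, angle_sup/90, thickness).
    Artifact parameters describe arthroscopic light-source leakage in the
    visible region and loss of probe-tissue contact.
    """

    band_centers: tuple[float, ...] = (0.92, 0.97, 1.21, 1.45, 1.58, 1.73)
    band_widths: tuple[float, ...] = (0.035, 0.04, 0.05, 0.06, 0.045, 0.05)
    band_links: tuple[tuple[float, ...], ...] = (
        (0.05, 0.02, 0.03, 0.01, 0.02, 0.12),
        (0.10, 0.05, 0.02, 0.02, 0.01, 0.08),
        (0.05, 0.15, 0.08, 0.03, 0.02, 0.03),
        (0.12, 0.08, 0.14, 0.02, 0.04, 0.02),
        (0.04, 0.03, 0.02, 0.14, 0.06, 0.02),
        (0.05, 0.02, 0.04, 0.05, 0.12, 0.01),
    )
    scatter_amplitude: float = 1.0
    scatter_exponent: float = 1.3
    scatter_jitter_sd: float = 0.12     # per-location log-normal baseline jitter
    gain_sd_vitro: float = 0.015        # per-repeat multiplicative gain sd
    gain_sd_vivo: float = 0.015
    vivo_noise_factor: float = 2.5      # in-vivo additive noise inflation
    leak_center: float = 0.55           # um, within the 0.40-0.75 visible band
    leak_width: float = 0.05
    leak_amplitude: float = 12.0
    contact_loss_range: tuple[float, float] = (0.25, 0.65)
    tilt_range: tuple[float, float] = (-0.2, 0.2)  # intensity per um

    def __post_init__(self) -> None:
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_links)):
            raise ConfigurationError("band parameter lengths disagree")
        if not all(0.35 <= c <= 2.5 for c in self.band_centers):
            raise ConfigurationError("band centers must lie within the detector grids")
        if not 0.40 <= self.leak_center <= 0.75:
            raise ConfigurationError("leak center must lie within 0.40-0.75 um")


def _band_matrix(wavelengths: np.ndarray, params: SpectralForwardParams) -> np.ndarray:
    c = np.asarray(params.band_centers)[:, None]
    w = np.asarray(params.band_widths)[:, None]
    return np.exp(-0.5 * ((wavelengths[None, :] - c) / w) ** 2)


def _driver_vector(latent: LatentProperties) -> np.ndarray:
    pg, angle = latent_to_profiles(latent)
    ref = extract_references(pg, angle, latent.thickness)
    return np.array(
        [
            1.0,
            ref.pg_full,
            ref.pg_sup,
            ref.angle_full / 90.0,
            ref.angle_sup / 90.0,
            ref.thickness,
        ]
    )


def clean_intensity(
    latent: LatentProperties,
    params: SpectralForwardParams,
    wavelengths: np.ndarray,
    scatter_amplitude: float | None = None,
) -> np.ndarray:
    """Noiseless intensity on one wavelength axis: baseline minus bands."""
    amp = params.scatter_amplitude if scatter_amplitude is None else scatter_amplitude
    baseline = amp * wavelengths ** (-params.scatter_exponent)
    depths = np.asarray(params.band_links) @ _driver_vector(latent)
    return baseline - depths @ _band_matrix(wavelengths, params)


def forward_spectrum(
    latent: LatentProperties,
    params: SpectralForwardParams,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    gain_sd: float = 0.0,
    scatter_amplitude: float | None = None,
    meta: dict | None = None,
) -> RawSpectrum:
    """One noisy two-segment spectrum for a location's latent state."""
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    grids = {SEGMENT_A: detector_a_grid(), SEGMENT_B: detector_b_grid()}
    gain = 1.0 + gain_sd * rng.standard_normal() if gain_sd > 0 else 1.0
    intensity = {}
    for label, grid in grids.items():
        y = gain * clean_intensity(latent, params, grid.wavelengths, scatter_amplitude)
        if noise_sd > 0:
            y = y + noise_sd * rng.standard_normal(len(grid))
        intensity[label] = y
    return RawSpectrum(grids, intensity, dict(meta or {}, artifact=False))


def inject_artifact(
    spectrum: RawSpectrum,
    params: SpectralForwardParams,
    rng: np.random.Generator,
) -> RawSpectrum:
    """Corrupt a clean spectrum with a non-contact measurement artifact.

    Adds a Gaussian light-source leak in the visible region, multiplies the
    NIR region (>= 0.75 um) by a contact-loss factor drawn from the
    configured range, and tilts the baseline; the record is flagged as an
    artifact in its metadata.
    """
    out = spectrum.copy()
    contact = rng.uniform(*params.contact_loss_range)
    tilt = rng.uniform(*params.tilt_range)
    for label, grid in out.grids.items():
        w = grid.wavelengths
        y = out.intensity[label]
        nir = w >= 0.75
        y = np.where(nir, y * contact, y)
        y = y + params.leak_amplitude * np.exp(
            -0.5 * ((w - params.leak_center) / params.leak_width) ** 2
        )
        y = y + tilt * (w - 1.0)
        out.intensity[label] = y  # type: ignore[index]
    out.meta["artifact"] = True
    return out


@dataclass
class CohortDataset:
    """Spectra, latent truth, and metadata of one generated cohort."""

    config: CohortConfig
    params: SpectralForwardParams
    grids: dict[str, WavelengthGrid]
    latent: pd.DataFrame        # one row per location: keys + latents + targets
    in_vitro_meta: pd.DataFrame  # keys + repeat + artifact flag
    in_vivo_meta: pd.DataFrame
    in_vitro: dict[str, np.ndarray]  # segment label -> (n_rows, grid length)
    in_vivo: dict[str, np.ndarray]

    KEY_COLS = ["pony_id", "group", "leg", "site", "location"]

    def location_index(self) -> pd.DataFrame:
        return self.latent[self.KEY_COLS]


def _sample_latent(
    rng: np.random.Generator, group: str, location: int, n_locations: int
) -> LatentProperties:
    def truncated_normal(mean, sd, lo, hi):
        for _ in range(100):
            x = mean + sd * rng.standard_normal()
            if lo <= x <= hi:
                return x
        return float(np.clip(x, lo, hi))

    thickness = truncated_normal(0.8, 0.28, 0.2, 1.4)
    pg_amplitude = truncated_normal(0.95, 0.35, 0.15, 1.7)
    if group == EXPERIMENTAL:
        gradient = (n_locations - location) / max(n_locations - 1, 1)
        degeneration = float(
            np.clip(0.6 * gradient + rng.uniform(-0.08, 0.08), 0.0, 1.0)
        )
    else:
        degeneration = 0.0
    steepness = float(
        np.clip(rng.uniform(0.15, 0.95) - 0.3 * degeneration, 0.02, 1.0)
    )
    return LatentProperties(thickness, pg_amplitude, degeneration, steepness)


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    params: SpectralForwardParams = SpectralForwardParams(),
) -> CohortDataset:
    """Generate the full virtual cohort, deterministically under the seed.

    Per pony x leg x site x location: one latent state with its depth
    profiles and reference targets, ``in_vitro_repeats`` clean in-vitro
    spectra, and ``in_vivo_repeats`` in-vivo spectra of which each is
    independently an artifact with probability ``contamination_rate``
    (recorded as ground truth).
    """
    rng = np.random.default_rng(config.seed)
    grids = {SEGMENT_A: detector_a_grid(), SEGMENT_B: detector_b_grid()}
    wl = {k: g.wavelengths for k, g in grids.items()}

    latent_rows = []
    vitro_meta, vivo_meta = [], []
    vitro_spec = {SEGMENT_A: [], SEGMENT_B: []}
    vivo_spec = {SEGMENT_A: [], SEGMENT_B: []}

    groups = [EXPERIMENTAL] * config.n_experimental + [CONTROL] * config.n_control
    for pony_id, group in zip(config.pony_ids(), groups):
        for leg in config.legs:
            for site in config.site_lines:
                for location in range(1, config.locations_per_line + 1):
                    latent = _sample_latent(
                        rng, group, location, config.locations_per_line
                    )
                    pg_prof, angle_prof = latent_to_profiles(latent)
                    ref = extract_references(pg_prof, angle_prof, latent.thickness)
                    key = dict(
                        pony_id=pony_id, group=group, leg=leg,
                        site=site, location=location,
                    )
                    latent_rows.append(
                        key
                        | dict(
                            pg_amplitude=latent.pg_amplitude,
                            degeneration=latent.degeneration,
                            angle_steepness=latent.angle_steepness,
                        )
                        | ref.as_dict()
                    )
                    scatter_amp = params.scatter_amplitude * float(
                        np.exp(params.scatter_jitter_sd * rng.standard_normal())
                    )
                    clean = {
                        k: clean_intensity(latent, params, wl[k], scatter_amp)
                        for k in grids
                    }
                    for repeat in range(1, config.in_vitro_repeats + 1):
                        gain = 1.0 + params.gain_sd_vitro * rng.standard_normal()
                        for k in grids:
                            y = gain * clean[k]
                            if config.noise_sd > 0:
                                y = y + config.noise_sd * rng.standard_normal(y.size)
                            vitro_spec[k].append(y)
                        vitro_meta.append(key | dict(repeat=repeat, artifact=False))
                    vivo_noise = config.noise_sd * params.vivo_noise_factor
                    for repeat in range(1, config.in_vivo_repeats + 1):
                        gain = 1.0 + params.gain_sd_vivo * rng.standard_normal()
                        seg = {}
                        for k in grids:
                            y = gain * clean[k]
                            if vivo_noise > 0:
                                y = y + vivo_noise * rng.standard_normal(y.size)
                            seg[k] = y
                        is_artifact = bool(rng.random() < config.contamination_rate)
                        if is_artifact:
                            raw = inject_artifact(
                                RawSpectrum(grids, seg, dict(key)), params, rng
                            )
                            seg = raw.intensity
                        for k in grids:
                            vivo_spec[k].append(seg[k])
                        vivo_meta.append(key | dict(repeat=repeat, artifact=is_artifact))

    return CohortDataset(
        config=config,
        params=params,
        grids=grids,
        latent=pd.DataFrame(latent_rows),
        in_vitro_meta=pd.DataFrame(vitro_meta),
        in_vivo_meta=pd.DataFrame(vivo_meta),
        in_vitro={k: np.array(v) for k, v in vitro_spec.items()},
        in_vivo={k: np.array(v) for k, v in vivo_spec.items()},
    )


# ---------------------------------------------------------------------------
# serialization: one CSV per modality, latent truth CSV, JSON metadata

def _spectra_frame(meta: pd.DataFrame, spec: dict[str, np.ndarray],
                   grids: dict[str, WavelengthGrid]) -> pd.DataFrame:
    cols = {}
    for label in (SEGMENT_A, SEGMENT_B):
        for j, w in enumerate(grids[label].wavelengths):
            cols[f"{label}_{w:.4f}"] = spec[label][:, j]
    return pd.concat([meta.reset_index(drop=True), pd.DataFrame(cols)], axis=1)


def save_cohort(ds: CohortDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _spectra_frame(ds.in_vitro_meta, ds.in_vitro, ds.grids).to_csv(
        directory / "in_vitro.csv", index=False, float_format="%.6g"
    )
    _spectra_frame(ds.in_vivo_meta, ds.in_vivo, ds.grids).to_csv(
        directory / "in_vivo.csv", index=False, float_format="%.6g"
    )
    ds.latent.to_csv(directory / "latent.csv", index=False)
    meta = {
        "config": asdict(ds.config),
        "params": asdict(ds.params),
        "grids": {k: {"label": g.label, "start": g.wavelengths[0],
                      "step": g.spacing, "n": len(g)} for k, g in ds.grids.items()},
    }
    (directory / "cohort.json").write_text(json.dumps(meta, indent=2, default=list))
    return directory


def load_cohort(directory: str | Path) -> CohortDataset:
    directory = Path(directory)
    meta = json.loads((directory / "cohort.json").read_text())
    cfg_raw = meta["config"]
    for k in ("site_lines", "legs"):
        cfg_raw[k] = tuple(cfg_raw[k])
    config = CohortConfig(**cfg_raw)
    p_raw = meta["params"]
    for k in ("band_centers", "band_widths", "contact_loss_range", "tilt_range"):
        p_raw[k] = tuple(p_raw[k])
    p_raw["band_links"] = tuple(tuple(r) for r in p_raw["band_links"])
    params = SpectralForwardParams(**p_raw)
    grids = {
        k: WavelengthGrid(g["label"], g["start"] + g["step"] * np.arange(g["n"]))
        for k, g in meta["grids"].items()
    }

    def split(path: Path):
        df = pd.read_csv(path)
        meta_cols = [c for c in df.columns if not c[:2] in ("A_", "B_")]
        spec = {}
        for label in (SEGMENT_A, SEGMENT_B):
            cols = [c for c in df.columns if c.startswith(label + "_")]
            spec[label] = df[cols].to_numpy(dtype=float)
        return df[meta_cols], spec

    vitro_meta, vitro = split(directory / "in_vitro.csv")
    vivo_meta, vivo = split(directory / "in_vivo.csv")
    return CohortDataset(
        config=config,
        params=params,
        grids=grids,
        latent=pd.read_csv(directory / "latent.csv"),
        in_vitro_meta=vitro_meta,
        in_vivo_meta=vivo_meta,
        in_vitro=vitro,
        in_vivo=vivo,
    )
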