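"""Synthetic tumor-section and efficacy-cohort generators with known ground truth.

The section generator emulates a three-channel fluorescence image of a frozen
tumor section: a compact nuclei-dense tumor region on a dark background,
sparse perfused vessels inside it, and an antibody channel whose intensity
decays exponentially with distance from the tumor edge and from the nearest
vessel wall:

    I(x) = background + A_e * exp(-d_edge(x) / lambda_e)
                      + A_v * exp(-d_vessel(x) / lambda_v)    inside the tumor,
    I(x) ~ 0                                                  outside.

Distances are measured from the mask *surface* (tumor boundary, vessel wall),
not from centroids.  The exponential field is a phenomenological stand-in for
antibody penetration; it is not a diffusion/binding PK model.

Distance convention: ``d = (EDT - 0.5) * pixel_size``, where EDT is the
Euclidean distance transform to the nearest background (resp. vessel) pixel
center.  With this convention a pixel center sitting at true depth ``0.5 px``
behind the sub-pixel 0.5-level boundary gets exactly that distance, so the
discrete field agrees with the continuous closed form at pixel centers.

The cohort generator emulates the two-arm efficacy study: per-animal tumor
volumes follow exponential growth from a randomized enrollment volume of
about 200 +/- 20 mm^3, recorded over a 30-day follow-up; an event (death) is
recorded at the first measurement where the volume exceeds a size threshold,
otherwise the animal is censored at follow-up.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .efficacy import GrowthRecord, SurvivalRecord
from .exceptions import ParameterError
from .io import SectionImage

NOISE_MODELS = ("none", "gaussian", "poisson-gaussian")
GROUPS = ("SD", "FD")


@dataclass
class SyntheticSectionParams:
    """Parameters of one synthetic section.

    Amplitudes and ``background`` are in arbitrary fluorescence units (a.u.);
    decay lengths, radii and ``pixel_size`` in µm.  ``boundary_roughness`` is
    the relative amplitude of low-frequency radial perturbation of the tumor
    outline (0 gives a circle).
    """

    image_shape: tuple[int, int] = (320, 320)
    pixel_size: float = 1.3           # µm / pixel
    tumor_radius: float = 150.0       # µm
    boundary_roughness: float = 0.08
    n_vessels: int = 8
    vessel_radius: float = 6.0        # µm
    edge_amplitude: float = 1.0       # A_e, a.u.
    edge_decay: float = 20.0          # lambda_e, µm
    vessel_amplitude: float = 1.0     # A_v, a.u.
    vessel_decay: float = 15.0        # lambda_v, µm
    background: float = 0.05          # a.u., inside-tumor baseline
    noise_model: str = "poisson-gaussian"
    noise_scale: float = 0.01         # a.u.; photon gain / read-noise scale
    seed: int = 0

    def validate(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ParameterError(f"noise_model must be one of {NOISE_MODELS}")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.boundary_roughness < 0 or self.n_vessels < 0:
            raise ParameterError("boundary_roughness and n_vessels must be >= 0")
        if self.background < 0 or self.noise_scale < 0:
            raise ParameterError("background and noise_scale must be >= 0")
        for name in ("edge_amplitude", "vessel_amplitude"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("edge_decay", "vessel_decay", "tumor_radius", "vessel_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        # tumor (incl. roughness excursion) must fit with a 10-pixel margin
        r_max_px = self.tumor_radius * (1.0 + 3.0 * self.boundary_roughness) / self.pixel_size
        if r_max_px + 10 > min(self.image_shape) / 2:
            raise ParameterError(
                f"tumor of radius {self.tumor_radius} µm does not fit in "
                f"{self.image_shape} at {self.pixel_size} µm/px with a 10-pixel margin")

    def replace(self, **kw) -> "SyntheticSectionParams":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Generator-side truth for one section: masks, decays, clean field."""

    tumor_mask: np.ndarray
    vessel_mask: np.ndarray
    edge_decay: float
    vessel_decay: float
    antibody_clean: np.ndarray      # noiseless antibody field
    edge_distance_um: np.ndarray    # d_edge inside tumor (µm); 0 outside
    vessel_distance_um: np.ndarray  # d to nearest vessel wall (µm); inf if no vessels
    vessel_centers: np.ndarray      # (n, 2) float, (row, col) in pixels
    params: SyntheticSectionParams = field(repr=False, default=None)


def _radial_perturbation(theta: np.ndarray, roughness: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Low-frequency (harmonics 2..5) relative radius perturbation."""
    if roughness == 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    for k in range(2, 6):
        amp = rng.normal() / k
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(k * theta + phase)
    return roughness * out


def _tumor_mask(params: SyntheticSectionParams, rng: np.random.Generator) -> np.ndarray:
    nr, nc = params.image_shape
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    rows, cols = np.mgrid[0:nr, 0:nc]
    dy, dx = rows - cy, cols - cx
    theta = np.arctan2(dy, dx)
    radius_px = params.tumor_radius / params.pixel_size
    r_theta = radius_px * (1.0 + np.clip(_radial_perturbation(theta, params.boundary_roughness, rng),
                                         -3 * params.boundary_roughness,
                                         3 * params.boundary_roughness))
    return dx ** 2 + dy ** 2 <= r_theta ** 2


def _place_vessels(params: SyntheticSectionParams, tumor: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random vessel disks fully inside the tumor, wall gap >= 2*vessel_radius."""
    nr, nc = tumor.shape
    r_px = params.vessel_radius / params.pixel_size
    # candidate centers must be at least one vessel radius (plus a pixel) inside
    interior_um = np.maximum(ndi.distance_transform_edt(tumor) - 0.5, 0) * params.pixel_size
    allowed = interior_um >= params.vessel_radius + params.pixel_size
    idx = np.argwhere(allowed)
    if params.n_vessels > 0 and len(idx) == 0:
        raise ParameterError("tumor too small to contain any vessel")
    centers: list[np.ndarray] = []
    min_center_dist = 4.0 * r_px  # wall-to-wall gap of 2*vessel_radius
    max_tries = 2000
    for _ in range(max_tries):
        if len(centers) == params.n_vessels:
            break
        cand = idx[rng.integers(len(idx))].astype(float)
        if all(np.linalg.norm(cand - c) >= min_center_dist for c in centers):
            centers.append(cand)
    else:
        if len(centers) < params.n_vessels:
            raise ParameterError(
                f"could not place {params.n_vessels} vessels with the required separation")
    mask = np.zeros_like(tumor)
    if centers:
        rows, cols = np.mgrid[0:nr, 0:nc]
        for cy, cx in centers:
            mask |= (rows - cy) ** 2 + (cols - cx) ** 2 <= r_px ** 2
        mask &= tumor
    return mask, np.array(centers, dtype=float).reshape(-1, 2)


def surface_distance_um(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Distance (µm) from each foreground pixel center to the mask surface.

    Uses ``(EDT - 0.5) * pixel_size`` so distances are measured to the
    sub-pixel boundary halfway between foreground and background centers.
    """
    return np.maximum(ndi.distance_transform_edt(mask) - 0.5, 0.0) * pixel_size


def _apply_noise(img: np.ndarray, model: str, scale: float,
                 rng: np.random.Generator) -> np.ndarray:
    if model == "none" or scale == 0:
        return img
    if model == "gaussian":
        noisy = img + rng.normal(0.0, scale, img.shape)
    elif model == "poisson-gaussian":
        # shot noise (variance proportional to signal, gain = scale) + read noise
        noisy = scale * rng.poisson(np.maximum(img, 0) / scale) + rng.normal(0.0, scale, img.shape)
    else:  # pragma: no cover - validated upstream
        raise ParameterError(f"unknown noise model {model!r}")
    return np.clip(noisy, 0.0, None)


def generate_section(params: SyntheticSectionParams,
                     section_id: str = "", tumor_id: str = "",
                     group: str = "") -> tuple[SectionImage, GroundTruth]:
    """Generate one synthetic section and its ground truth.

    Deterministic: identical ``params`` (including ``seed``) give bit-identical
    output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    tumor = _tumor_mask(params, rng)
    vessels, centers = _place_vessels(params, tumor, rng)

    d_edge = surface_distance_um(tumor, params.pixel_size)
    if vessels.any():
        d_vessel = np.maximum(ndi.distance_transform_edt(~vessels) - 0.5, 0.0) * params.pixel_size
    else:
        d_vessel = np.full(tumor.shape, np.inf)

    with np.errstate(over="ignore"):
        clean = np.where(
            tumor,
            params.background
            + params.edge_amplitude * np.exp(-d_edge / params.edge_decay)
            + params.vessel_amplitude * np.exp(-np.minimum(d_vessel, 1e9) / params.vessel_decay),
            0.0,
        )

    nuclei = np.where(tumor, 1.0, 0.1)
    vessel_ch = np.where(vessels, 1.0, 0.02)

    antibody = _apply_noise(clean, params.noise_model, params.noise_scale, rng)
    nuclei = _apply_noise(nuclei, params.noise_model, params.noise_scale, rng)
    vessel_ch = _apply_noise(vessel_ch, params.noise_model, params.noise_scale, rng)

    section = SectionImage(nuclei=nuclei, antibody=antibody, vessel=vessel_ch,
                           pixel_size=params.pixel_size,
                           section_id=section_id, tumor_id=tumor_id, group=group)
    truth = GroundTruth(tumor_mask=tumor, vessel_mask=vessels,
                        edge_decay=params.edge_decay, vessel_decay=params.vessel_decay,
                        antibody_clean=clean, edge_distance_um=np.where(tumor, d_edge, 0.0),
                        vessel_distance_um=d_vessel, vessel_centers=centers, params=params)
    return section, truth


def analytic_profile(params: SyntheticSectionParams, source: str,
                     depth_grid: np.ndarray) -> np.ndarray:
    """Expected intensity ``background + A * exp(-d/lambda)`` for one source.

    Ignores the other source's contribution, so it is exact only when the
    other amplitude is 0.
    """
    d = np.asarray(depth_grid, dtype=float)
    if d.ndim != 1 or len(d) == 0 or np.any(d < 0) or np.any(np.diff(d) < 0):
        raise ParameterError("depth_grid must be nonnegative and ascending")
    if source == "edge":
        amp, lam = params.edge_amplitude, params.edge_decay
    elif source == "vessel":
        amp, lam = params.vessel_amplitude, params.vessel_decay
    else:
        raise ParameterError("source must be 'edge' or 'vessel'")
    return params.background + amp * np.exp(-d / lam)


# ---------------------------------------------------------------------------
# Efficacy cohorts

@dataclass
class SyntheticCohortParams:
    """Two-arm growth/survival cohort.

    Volumes in mm³, rates in 1/day.  ``growth_rate`` maps group name to rate;
    equal rates give the null (no-regimen-effect) regime.  An animal dies at
    the first measurement where its recorded volume exceeds
    ``death_threshold``; otherwise it is censored at ``follow_up`` days.
    """

    n_per_group: int = 10
    start_volume_mean: float = 200.0
    start_volume_sd: float = 20.0
    growth_rate: dict[str, float] = field(default_factory=lambda: {"SD": 0.08, "FD": 0.08})
    volume_noise_sd: float = 15.0
    death_threshold: float = 2000.0
    follow_up: int = 30
    measurement_interval: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ParameterError("n_per_group must be >= 1")
        if self.start_volume_mean <= 0 or self.follow_up <= 0:
            raise ParameterError("start_volume_mean and follow_up must be > 0")
        if self.measurement_interval <= 0:
            raise ParameterError("measurement_interval must be > 0")
        if not self.growth_rate:
            raise ParameterError("growth_rate must name at least one group")

    def replace(self, **kw) -> "SyntheticCohortParams":
        return dataclasses.replace(self, **kw)


def generate_cohort(params: SyntheticCohortParams
                    ) -> tuple[list[GrowthRecord], list[SurvivalRecord]]:
    """Generate per-animal growth curves and survival records for each group."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    days = np.arange(0, params.follow_up + 1, params.measurement_interval)
    if days[-1] != params.follow_up:
        days = np.append(days, params.follow_up)

    growth: list[GrowthRecord] = []
    survival: list[SurvivalRecord] = []
    for group in sorted(params.growth_rate):
        rate = params.growth_rate[group]
        for i in range(params.n_per_group):
            animal = f"{group}-{i + 1:02d}"
            v0 = max(rng.normal(params.start_volume_mean, params.start_volume_sd), 1.0)
            event_time: float | None = None
            for day in days:
                vol = v0 * np.exp(rate * day)
                if params.volume_noise_sd > 0:
                    vol = max(vol + rng.normal(0.0, params.volume_noise_sd), 1.0)
                growth.append(GrowthRecord(animal_id=animal, group=group,
                                           day=int(day), volume=float(vol)))
                if vol > params.death_threshold:
                    event_time = float(day)
                    break
            if event_time is not None:
                survival.append(SurvivalRecord(animal_id=animal, group=group,
                                               time=max(event_time, 0.5), event=True))
            else:
                survival.append(SurvivalRecord(animal_id=animal, group=group,
                                               time=float(params.follow_up), event=False))
    return growth, survival
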