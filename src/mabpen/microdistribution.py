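"""Penetration profiles, AUC summaries and whole-tumor accumulation.

Two complementary geometries quantify antibody microdistribution:

* **Edge profiles** — intensity sampled along lines directed perpendicular
  from the tumor boundary toward the center, out to 80 µm by default.
  Anchors are spaced uniformly along the boundary contour; the inward normal
  is estimated from a smoothed contour tangent (central differences over
  ±k vertices) and oriented toward the mask interior.  Sampling is bilinear
  at ``bin_width`` steps; before sampling, pixels outside the tumor are
  filled with their nearest in-tumor value so interpolation at the boundary
  does not mix in the dark exterior.

* **Vessel profiles** — per vessel component, tumor pixels are binned by
  Euclidean distance to that component's wall (distance-map mode, the
  default), each pixel assigned to its nearest vessel.  The recorded
  distance of each bin is the mean distance of the pixels it contains.
  Components are labeled peripheral/central by whether their centroid lies
  within the outer 25% of edge distances.

Profiles are aggregated into per-bin mean ± sd curves and summarized by
trapezoidal AUC.  ``auc_raw`` (a.u.·µm) integrates the curve as measured;
the normalized ``auc`` rescales intensity to max 1 and distance to the
profiling depth, giving a unitless shape index in [0, 1].  Whole-tumor
accumulation is total antibody intensity inside the tumor divided by tumor
area (a.u./µm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .exceptions import FitError, ProfilingError, UsageError
from .io import BoundaryContour, Mask, SectionImage
from .synthetic import surface_distance_um


@dataclass
class ProfileParams:
    max_depth_edge: float = 80.0       # µm
    max_depth_vessel: float = 80.0     # µm
    bin_width: float | None = None     # µm; None -> pixel_size
    n_lines_per_section: int = 36
    mode: str = "line"                 # {"line", "distance_map"}
    normalization: str = "none"        # {"none", "max1", "background_subtracted"}
    # normal estimation: the contour is smoothed with a circular moving
    # average before the tangent is taken by central differences.  A binary
    # boundary has flat runs of ~sqrt(2R) px near low-curvature poles, so
    # both the window and the baseline must span several such runs.
    tangent_halfspan: int = 10         # contour vertices each side for the tangent
    contour_smoothing_window: int = 41  # vertices, circular moving average

    def validate(self) -> None:
        if self.max_depth_edge <= 0 or self.max_depth_vessel <= 0:
            raise UsageError("max depths must be > 0")
        if self.bin_width is not None and self.bin_width <= 0:
            raise UsageError("bin_width must be > 0")
        if self.n_lines_per_section < 1:
            raise UsageError("n_lines_per_section must be >= 1")
        if self.mode not in ("line", "distance_map"):
            raise UsageError("mode must be 'line' or 'distance_map'")
        if self.normalization not in ("none", "max1", "background_subtracted"):
            raise UsageError("unknown normalization")

    def resolved_bin_width(self, pixel_size: float) -> float:
        return self.bin_width if self.bin_width is not None else pixel_size


@dataclass
class LineProfile:
    """One intensity-vs-distance trace (µm, a.u.)."""

    distances: np.ndarray
    intensities: np.ndarray
    source: str                      # {"edge", "vessel"}
    section_id: str = ""
    anchor: tuple[float, float] = (0.0, 0.0)   # (row, col) start point
    region: str = ""                 # vessel profiles: {"peripheral", "central"}

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.distances.shape != self.intensities.shape:
            raise UsageError("distances and intensities must have equal length")


@dataclass
class MeanProfile:
    """Per-bin mean ± sd over a set of profiles."""

    bin_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    source: str
    group: str = ""


@dataclass
class AUCResult:
    auc: float          # normalized (intensity max 1, distance scaled to depth)
    auc_raw: float      # a.u.·µm
    source: str
    group: str = ""
    n_profiles: int = 1


@dataclass
class AccumulationResult:
    """Whole-tumor antibody accumulation: total intensity / tumor area."""

    total_intensity: float   # a.u. (sum over tumor pixels)
    tumor_area: float        # µm²
    accumulation: float      # a.u./µm²
    section_id: str = ""
    group: str = ""


# ---------------------------------------------------------------------------
# sampling helpers

def _fill_outside(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace outside-mask pixels by their nearest inside-mask value."""
    if mask.all():
        return img
    _, (ir, ic) = ndi.distance_transform_edt(~mask, return_indices=True)
    return img[ir, ic]


def _bilinear(img: np.ndarray, points: np.ndarray) -> np.ndarray:
    return ndi.map_coordinates(img, points.T, order=1, mode="nearest")


def _inward_normals(contour: BoundaryContour, mask: np.ndarray,
                    anchor_idx: np.ndarray, halfspan: int,
                    smoothing_window: int = 41) -> tuple[np.ndarray, np.ndarray]:
    """Unit inward normals at the given contour vertex indices.

    The contour coordinates are smoothed with a circular moving average, the
    tangent is a central difference over ±halfspan smoothed vertices, and
    the normal sign is chosen so a short step lands inside the mask.
    Anchors where neither side is inside are dropped.
    """
    coords = contour.coords[:-1]  # open form
    m = len(coords)
    w = min(smoothing_window, max(1, (m // 4) * 2 + 1))
    if w > 1:
        smoothed = np.column_stack(
            [ndi.uniform_filter1d(coords[:, j], w, mode="wrap") for j in (0, 1)])
    else:
        smoothed = coords
    anchors, normals = [], []
    for i in anchor_idx:
        t = smoothed[(i + halfspan) % m] - smoothed[(i - halfspan) % m]
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t = t / norm
        n = np.array([-t[1], t[0]])
        a = coords[i]
        step = 2.0
        inside_pos = _point_in_mask(mask, a + step * n)
        inside_neg = _point_in_mask(mask, a - step * n)
        if inside_pos and not inside_neg:
            pass
        elif inside_neg and not inside_pos:
            n = -n
        elif inside_pos and inside_neg:
            pass  # thin structure; keep the positive convention
        else:
            continue
        anchors.append(a)
        normals.append(n)
    return np.array(anchors).reshape(-1, 2), np.array(normals).reshape(-1, 2)


def _point_in_mask(mask: np.ndarray, point: np.ndarray) -> bool:
    r = int(round(point[0]))
    c = int(round(point[1]))
    if r < 0 or c < 0 or r >= mask.shape[0] or c >= mask.shape[1]:
        return False
    return bool(mask[r, c])


def _background_level(section: SectionImage, tumor: Mask) -> float:
    outside = section.antibody[~tumor.pixels]
    return float(np.median(outside)) if outside.size else 0.0


# ---------------------------------------------------------------------------
# edge profiles

def edge_profiles(section: SectionImage, tumor: Mask, contour: BoundaryContour,
                  params: ProfileParams | None = None) -> list[LineProfile]:
    """Line profiles perpendicular from the tumor edge toward the center.

    Anchors are spaced uniformly by arclength along the contour.  Lines
    leaving the tumor mask before ``max_depth_edge`` are truncated at exit.
    """
    params = params or ProfileParams()
    params.validate()
    bw = params.resolved_bin_width(section.pixel_size)
    depths = np.arange(0.0, params.max_depth_edge + bw / 2, bw)

    arclen = contour.arclength()
    total = arclen[-1]
    targets = np.linspace(0, total, params.n_lines_per_section, endpoint=False)
    anchor_idx = np.unique(np.searchsorted(arclen, targets))
    anchor_idx = anchor_idx[anchor_idx < len(contour.coords) - 1]

    anchors, normals = _inward_normals(contour, tumor.pixels, anchor_idx,
                                       params.tangent_halfspan,
                                       params.contour_smoothing_window)
    field_img = _fill_outside(section.antibody, tumor.pixels)
    offset = 0.0
    if params.normalization == "background_subtracted":
        offset = _background_level(section, tumor)
    mask_f = tumor.pixels.astype(float)

    profiles: list[LineProfile] = []
    for a, n in zip(anchors, normals):
        pts = a[None, :] + (depths / section.pixel_size)[:, None] * n[None, :]
        inside = _bilinear(mask_f, pts) >= 0.5
        # truncate at first exit (the 0-µm anchor sits on the boundary itself)
        k = len(depths)
        exits = np.flatnonzero(~inside[1:])
        if exits.size:
            k = exits[0] + 1
        if k < 1:
            continue
        vals = _bilinear(field_img, pts[:k])
        if offset:
            vals = np.clip(vals - offset, 0.0, None)
        profiles.append(LineProfile(distances=depths[:k], intensities=vals,
                                    source="edge", section_id=section.section_id,
                                    anchor=(float(a[0]), float(a[1]))))
    if not any(len(p.distances) >= 2 for p in profiles):
        raise ProfilingError("tumor thinner than one bin everywhere; no edge profile")
    return profiles


def edge_profile_distance_map(section: SectionImage, tumor: Mask,
                              params: ProfileParams | None = None) -> MeanProfile:
    """Edge profile by binning tumor pixels on the edge-distance map.

    Independent route to the same quantity as the mean of dense line
    profiles; the recorded distance per bin is the mean pixel distance.
    """
    params = params or ProfileParams()
    params.validate()
    bw = params.resolved_bin_width(section.pixel_size)
    d = surface_distance_um(tumor.pixels, section.pixel_size)
    valid = tumor.pixels & (d <= params.max_depth_edge)
    if not valid.any():
        raise ProfilingError("empty tumor mask")
    offset = _background_level(section, tumor) if params.normalization == "background_subtracted" else 0.0
    centers, mean, sd, n = _bin_by_distance(d[valid], section.antibody[valid] - offset, bw)
    return MeanProfile(bin_centers=centers, mean=np.clip(mean, 0 if offset else -np.inf, None),
                       sd=sd, n=n, source="edge", group=section.group)


# ---------------------------------------------------------------------------
# vessel profiles

def _bin_by_distance(d: np.ndarray, v: np.ndarray, bw: float
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    idx = np.floor(d / bw).astype(int)
    nb = idx.max() + 1
    n = np.bincount(idx, minlength=nb)
    keep = n > 0
    sum_v = np.bincount(idx, weights=v, minlength=nb)
    sum_d = np.bincount(idx, weights=d, minlength=nb)
    sum_v2 = np.bincount(idx, weights=v * v, minlength=nb)
    mean = sum_v[keep] / n[keep]
    centers = sum_d[keep] / n[keep]
    with np.errstate(invalid="ignore"):
        var = (sum_v2[keep] - n[keep] * mean ** 2) / np.maximum(n[keep] - 1, 1)
    sd = np.sqrt(np.clip(var, 0, None))
    sd[n[keep] < 2] = 0.0
    return centers, mean, sd, n[keep]


def vessel_profiles(section: SectionImage, tumor: Mask, vessels: Mask,
                    params: ProfileParams | None = None) -> list[LineProfile]:
    """Per-vessel intensity-vs-distance-from-wall profiles (distance-map mode).

    Tumor pixels are assigned to their nearest vessel component (Euclidean;
    exact ties go to the lower component label) and binned by distance to
    that component's wall.  Requires a nonempty vessel mask.
    """
    params = params or ProfileParams()
    params.validate()
    if not vessels.pixels.any():
        raise ProfilingError(
            "vessel mask is empty (segmentation warned); vessel profiling unavailable")
    bw = params.resolved_bin_width(section.pixel_size)
    labels, n_comp = ndi.label(vessels.pixels, structure=np.ones((3, 3), dtype=int))

    edt, (ir, ic) = ndi.distance_transform_edt(~vessels.pixels, return_indices=True)
    owner = labels[ir, ic]                      # nearest vessel component per pixel
    d_um = np.maximum(edt - 0.5, 0.0) * section.pixel_size

    valid = tumor.pixels & ~vessels.pixels & (d_um <= params.max_depth_vessel)
    offset = _background_level(section, tumor) if params.normalization == "background_subtracted" else 0.0

    d_edge = surface_distance_um(tumor.pixels, section.pixel_size)
    outer_band = 0.25 * d_edge.max()

    profiles: list[LineProfile] = []
    centroids = ndi.center_of_mass(vessels.pixels, labels, index=range(1, n_comp + 1))
    for comp, cen in zip(range(1, n_comp + 1), centroids):
        sel = valid & (owner == comp)
        if not sel.any():
            continue
        centers, mean, _, _ = _bin_by_distance(d_um[sel], section.antibody[sel] - offset, bw)
        cen_px = (int(round(cen[0])), int(round(cen[1])))
        region = "peripheral" if d_edge[cen_px] <= outer_band else "central"
        profiles.append(LineProfile(distances=centers, intensities=np.clip(mean, 0 if offset else -np.inf, None),
                                    source="vessel", section_id=section.section_id,
                                    anchor=(float(cen[0]), float(cen[1])), region=region))
    if not profiles:
        raise ProfilingError("no tumor pixels within profiling depth of any vessel")
    return profiles


# ---------------------------------------------------------------------------
# aggregation, AUC, decay fit, accumulation

def aggregate_profiles(profiles: list[LineProfile],
                       params: ProfileParams | None = None,
                       group: str = "") -> MeanProfile:
    """Per-bin mean, sample sd (n−1; sd = 0 when n = 1) and n over profiles.

    Profiles must share one source; bins covered by no profile are omitted.
    Distances are grouped on the common bin grid (rounded to 1e-6 µm).
    """
    if not profiles:
        raise UsageError("aggregate_profiles: no profiles")
    sources = {p.source for p in profiles}
    if len(sources) != 1:
        raise UsageError(f"aggregate_profiles: mixed sources {sources}")
    d_all = np.concatenate([p.distances for p in profiles])
    v_all = np.concatenate([p.intensities for p in profiles])
    params = params or ProfileParams()
    bw = params.bin_width
    if bw is None:
        # infer the grid pitch from the data
        uniq = np.unique(np.round(d_all, 6))
        bw = float(np.min(np.diff(uniq))) if len(uniq) > 1 else 1.0
    # line-profile distances sit on the grid i*bw; distance-map distances are
    # in-bin means — floor with a small nudge maps both to a stable bin index
    idx = np.floor(d_all / bw + 1e-6).astype(int)
    order = np.argsort(idx, kind="stable")
    idx, d_all, v_all = idx[order], d_all[order], v_all[order]
    bins, starts = np.unique(idx, return_index=True)
    splits_v = np.split(v_all, starts[1:])
    splits_d = np.split(d_all, starts[1:])
    centers = np.array([d.mean() for d in splits_d])
    mean = np.array([v.mean() for v in splits_v])
    sd = np.array([v.std(ddof=1) if len(v) > 1 else 0.0 for v in splits_v])
    n = np.array([len(v) for v in splits_v])
    return MeanProfile(bin_centers=centers, mean=mean, sd=sd, n=n,
                       source=profiles[0].source, group=group)


def profile_auc(mean_profile: MeanProfile,
                params: ProfileParams | None = None) -> AUCResult:
    """Trapezoidal AUC of a mean profile.

    ``auc_raw`` integrates intensity (a.u.) over distance (µm).  ``auc``
    integrates after scaling intensity to max 1 and distance to the profile
    span, yielding a unitless penetration-shape index in [0, 1].
    """
    x = np.asarray(mean_profile.bin_centers, dtype=float)
    y = np.asarray(mean_profile.mean, dtype=float)
    if len(x) < 2:
        raise UsageError("profile_auc: need >= 2 bins")
    auc_raw = float(np.trapezoid(y, x))
    span = x.max() - x.min()
    ymax = y.max()
    if ymax > 0 and span > 0:
        auc_norm = float(np.trapezoid(y / ymax, (x - x.min()) / span))
    else:
        auc_norm = 0.0
    n_prof = int(np.max(mean_profile.n)) if np.size(mean_profile.n) else 1
    return AUCResult(auc=auc_norm, auc_raw=auc_raw, source=mean_profile.source,
                     group=mean_profile.group, n_profiles=n_prof)


@dataclass
class DecayFit:
    amplitude: float     # a.u.
    decay_length: float  # µm
    background: float    # a.u.
    residual_norm: float


def fit_decay(mean_profile: MeanProfile) -> DecayFit:
    """Least-squares fit of ``A·exp(−d/λ) + b`` to a mean profile.

    Raises :class:`FitError` when the profile is flat (λ unidentifiable) or
    the optimizer fails to converge.
    """
    x = np.asarray(mean_profile.bin_centers, dtype=float)
    y = np.asarray(mean_profile.mean, dtype=float)
    if len(x) < 4:
        raise FitError("fit_decay: need >= 4 bins")
    span = x.max() - x.min()
    if np.ptp(y) < 1e-12 * max(1.0, abs(y).max()) or span == 0:
        raise FitError("fit_decay: profile is constant; decay length unidentifiable")

    def model(d, a, lam, b):
        return a * np.exp(-d / lam) + b

    b0 = float(y.min())
    a0 = float(y.max() - y.min())
    # first depth where the excess over baseline drops by 1/e
    drop = y - b0 <= a0 / np.e
    lam0 = float(x[np.argmax(drop)]) if drop.any() and x[np.argmax(drop)] > 0 else span / 3
    try:
        popt, _ = curve_fit(model, x, y, p0=(a0, lam0, b0),
                            bounds=([0, 1e-3, 0], [np.inf, 1e6, np.inf]),
                            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"fit_decay: optimizer failed ({exc})") from exc
    resid = float(np.linalg.norm(model(x, *popt) - y))
    return DecayFit(amplitude=float(popt[0]), decay_length=float(popt[1]),
                    background=float(popt[2]), residual_norm=resid)


def total_accumulation(section: SectionImage, tumor: Mask) -> AccumulationResult:
    """Whole-tumor accumulation: antibody intensity summed over the tumor
    divided by tumor area (a.u./µm²)."""
    if not tumor.pixels.any():
        raise UsageError("total_accumulation: empty tumor mask")
    total = float(np.sum(section.antibody[tumor.pixels]))
    area = tumor.area_um2(section.pixel_size)
    return AccumulationResult(total_intensity=total, tumor_area=area,
                              accumulation=total / area,
                              section_id=section.section_id, group=section.group)
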