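"""The 226-dimensional TLS spatial feature vector (spatial-branch input).

Every connected TLS domain on a post-processed heatmap is summarized by its
maturity subtype (Agg / FL-1 / FL-2), its area in mm^2, and the signed
Euclidean distance from its centroid to the nearest tumor-margin pixel
(negative when the centroid lies inside tumor).  Distances and areas are then
discretized into seven bins each:

    distance (mm):  <=0, (0,0.4], (0.4,1.0], (1.0,2.2], (2.2,4.5], (4.5,6.4], >6.4
    area (mm^2):    (0,0.03], (0.03,0.05], (0.05,0.07], (0.07,0.10],
                    (0.10,0.15], (0.15,0.28], >0.28

and pooled over all slides of a case into a fixed named registry of exactly
226 features:

    7 distance bins x 3 subtypes x {count, total area, mean area}   =  63
    7 area bins     x 3 subtypes x {count, total area, mean area}   =  63
    7 distance bins x 7 area bins x {count, total area}             =  98
    tumor: total area (mm^2), mean area per slide (mm^2)            =   2
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from tlsview.heatmap_core import (
    SUBTYPE_AGG,
    SUBTYPE_FL1,
    SUBTYPE_FL2,
    TLS,
    TUMOR,
    ConnectedComponent,
    TissueHeatmap,
    find_components,
)

#: right edges of the interior distance bins (mm); bin 0 is (-inf, 0], bin 6 is (6.4, inf)
DISTANCE_BIN_EDGES_MM = (0.0, 0.4, 1.0, 2.2, 4.5, 6.4)
#: right edges of the interior area bins (mm^2); bin 6 is (0.28, inf)
AREA_BIN_EDGES_MM2 = (0.03, 0.05, 0.07, 0.10, 0.15, 0.28)

N_BINS = 7
SUBTYPE_TAGS = ("Agg", "FL1", "FL2")  # registry-name-safe spellings
_SUBTYPE_INDEX = {SUBTYPE_AGG: 0, SUBTYPE_FL1: 1, SUBTYPE_FL2: 2}

REGISTRY_VERSION = "tlsview-226-v1"
N_FEATURES = 226


def bin_distance(d_mm: float) -> int:
    """Index (0..6) of the signed margin-distance bin holding ``d_mm``."""
    if not np.isfinite(d_mm):
        raise ValueError("distance must be finite")
    for i, edge in enumerate(DISTANCE_BIN_EDGES_MM):
        if d_mm <= edge:
            return i
    return N_BINS - 1


def bin_area(a_mm2: float) -> int:
    """Index (0..6) of the area bin holding ``a_mm2`` (strictly positive)."""
    if not a_mm2 > 0:
        raise ValueError("area must be positive")
    for i, edge in enumerate(AREA_BIN_EDGES_MM2):
        if a_mm2 <= edge:
            return i
    return N_BINS - 1


def registry_names() -> list[str]:
    """The canonical ordered names of the 226 spatial features."""
    names: list[str] = []
    for s in SUBTYPE_TAGS:
        for b in range(N_BINS):
            for stat in ("count", "area_total", "area_mean"):
                names.append(f"dist{b}_{s}_{stat}")
    for s in SUBTYPE_TAGS:
        for b in range(N_BINS):
            for stat in ("count", "area_total", "area_mean"):
                names.append(f"area{b}_{s}_{stat}")
    for d in range(N_BINS):
        for a in range(N_BINS):
            names.append(f"joint_d{d}_a{a}_count")
    for d in range(N_BINS):
        for a in range(N_BINS):
            names.append(f"joint_d{d}_a{a}_area_total")
    names.append("tumor_area_total_mm2")
    names.append("tumor_area_mean_per_slide_mm2")
    assert len(names) == N_FEATURES
    return names


def shipped_registry() -> dict:
    """The registry JSON shipped with the package (names + bin edges)."""
    with resources.files("tlsview.data").joinpath("feature_registry.json").open() as fh:
        return json.load(fh)


@dataclass
class TLSComponent:
    """One connected TLS domain with its subtype and signed margin distance."""

    component: ConnectedComponent
    subtype: int  # SUBTYPE_AGG / SUBTYPE_FL1 / SUBTYPE_FL2
    signed_margin_distance_mm: float
    slide_id: str = ""

    @property
    def area_mm2(self) -> float:
        return self.component.area_mm2


@dataclass
class SpatialFeatureVector:
    """Named, ordered 226-dimensional spatial feature vector for one case."""

    values: np.ndarray
    names: list[str]
    registry_version: str = REGISTRY_VERSION
    case_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if len(self.names) != N_FEATURES:
            raise ValueError("names must match feature count")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def subtype_of(c: ConnectedComponent, h: TissueHeatmap) -> int:
    """Majority subtype over a TLS component; ties go to the more mature class."""
    sub = h.subtypes[c.pixel_coords[:, 0], c.pixel_coords[:, 1]]
    sub = sub[sub > 0]
    if sub.size == 0:
        raise ValueError("component has no subtype-labelled pixels")
    counts = np.bincount(sub, minlength=4)[1:4]
    best = counts.max()
    # candidates tied at the max count: prefer FL-2 > FL-1 > Agg
    for st in (SUBTYPE_FL2, SUBTYPE_FL1, SUBTYPE_AGG):
        if counts[_SUBTYPE_INDEX[st]] == best:
            return st
    raise AssertionError("unreachable")


def tumor_region_mask(h: TissueHeatmap) -> np.ndarray:
    """The tumor region with interior enclaves (e.g. embedded TLS) filled in.

    Margin distances are measured to the invasive margin of this region, so
    a TLS fully surrounded by tumor counts as inside the tumor rather than as
    sitting next to an internal rim.
    """
    from scipy import ndimage

    return ndimage.binary_fill_holes(h.labels == TUMOR)


def tumor_boundary_mask(h: TissueHeatmap) -> np.ndarray:
    """Margin pixels: tumor-region pixels with a 4-neighbor (or grid edge) outside."""
    region = tumor_region_mask(h)
    if not region.any():
        return region
    interior = (
        np.roll(region, 1, 0) & np.roll(region, -1, 0)
        & np.roll(region, 1, 1) & np.roll(region, -1, 1)
    )
    # np.roll wraps; pixels on the grid edge are boundary by construction
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    return region & ~interior


def signed_margin_distance(c: ConnectedComponent, h: TissueHeatmap) -> float:
    """Signed distance (mm) from the component centroid to the tumor margin.

    The magnitude is the Euclidean distance from the real-valued centroid to
    the nearest tumor-margin pixel center; the sign is negative when the
    centroid's nearest integer pixel lies inside the (hole-filled) tumor
    region.
    """
    boundary = tumor_boundary_mask(h)
    if not boundary.any():
        raise ValueError(f"slide {h.slide_id!r} has no tumor pixels")
    pts = np.argwhere(boundary).astype(np.float64)
    cr, cc = c.centroid
    dist_px = float(cKDTree(pts).query([cr, cc])[0])
    ir = int(np.clip(round(cr), 0, h.shape[0] - 1))
    ic = int(np.clip(round(cc), 0, h.shape[1] - 1))
    sign = -1.0 if tumor_region_mask(h)[ir, ic] else 1.0
    return sign * dist_px * h.pixel_pitch_mm


def extract_tls_components(h: TissueHeatmap) -> list[TLSComponent]:
    """All TLS components of a post-processed heatmap, with subtype and distance."""
    out = []
    for comp in find_components(h, TLS):
        out.append(
            TLSComponent(
                component=comp,
                subtype=subtype_of(comp, h),
                signed_margin_distance_mm=signed_margin_distance(comp, h),
                slide_id=h.slide_id,
            )
        )
    return out


def build_spatial_features(
    components: list[TLSComponent],
    heatmaps: list[TissueHeatmap],
    case_id: str = "",
) -> SpatialFeatureVector:
    """Pool a case's TLS components and tumor areas into the 226-feature vector.

    Counts and areas are summed over all slides of the case; mean-area entries
    are zero where the corresponding count is zero.  Tumor global features are
    the total tumor area over the case and its mean per slide.
    """
    if not heatmaps:
        raise ValueError("a case needs at least one heatmap")

    dist_count = np.zeros((N_BINS, 3))
    dist_area = np.zeros((N_BINS, 3))
    area_count = np.zeros((N_BINS, 3))
    area_area = np.zeros((N_BINS, 3))
    joint_count = np.zeros((N_BINS, N_BINS))
    joint_area = np.zeros((N_BINS, N_BINS))

    for tc in components:
        s = _SUBTYPE_INDEX[tc.subtype]
        d = bin_distance(tc.signed_margin_distance_mm)
        a = bin_area(tc.area_mm2)
        mm2 = tc.area_mm2
        dist_count[d, s] += 1
        dist_area[d, s] += mm2
        area_count[a, s] += 1
        area_area[a, s] += mm2
        joint_count[d, a] += 1
        joint_area[d, a] += mm2

    def _mean(total: np.ndarray, count: np.ndarray) -> np.ndarray:
        return np.divide(total, count, out=np.zeros_like(total), where=count > 0)

    dist_mean = _mean(dist_area, dist_count)
    area_mean = _mean(area_area, area_count)

    tumor_total = sum(
        sum(comp.area_mm2 for comp in find_components(h, TUMOR)) for h in heatmaps
    )
    tumor_mean_per_slide = tumor_total / len(heatmaps)

    values: list[float] = []
    for s in range(3):
        for b in range(N_BINS):
            values += [dist_count[b, s], dist_area[b, s], dist_mean[b, s]]
    for s in range(3):
        for b in range(N_BINS):
            values += [area_count[b, s], area_area[b, s], area_mean[b, s]]
    for d in range(N_BINS):
        for a in range(N_BINS):
            values.append(joint_count[d, a])
    for d in range(N_BINS):
        for a in range(N_BINS):
            values.append(joint_area[d, a])
    values += [tumor_total, tumor_mean_per_slide]

    return SpatialFeatureVector(np.array(values), registry_names(), case_id=case_id)


def case_features(heatmaps: list[TissueHeatmap], case_id: str = "") -> SpatialFeatureVector:
    """Convenience: extract components from post-processed heatmaps and pool."""
    comps: list[TLSComponent] = []
    for h in heatmaps:
        comps.extend(extract_tls_components(h))
    return build_spatial_features(comps, heatmaps, case_id=case_id)
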