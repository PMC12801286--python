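"""Tissue label heatmaps: representation, post-processing, SSIM audit.

A heatmap is a coarse label image in which each pixel corresponds to one
256-px tile of the source whole-slide image scanned at 0.25 um/px, i.e. an
edge length of 0.064 mm per heatmap pixel.  Labels: 0 background, 1 normal,
2 tumor, 3 TLS.  A parallel subtype grid refines TLS pixels by maturity:
1 Agg (lymphoid aggregate), 2 FL-1 (primary follicle), 3 FL-2 (secondary
follicle).

Post-processing removes segmentation noise before any spatial statistics are
computed: normal tissue is dropped, single-pixel specks and sub-threshold
tumor domains (default 20 px) are erased, and interior holes of the surviving
tumor/TLS domains are filled.  The structural-similarity index (SSIM) between
the raw and cleaned heatmap audits that this denoising preserves the slide's
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

# tissue classes
BACKGROUND = 0
NORMAL = 1
TUMOR = 2
TLS = 3
TISSUE_CLASSES = (BACKGROUND, NORMAL, TUMOR, TLS)

# TLS maturity subtypes (subtype grid values)
SUBTYPE_NONE = 0
SUBTYPE_AGG = 1
SUBTYPE_FL1 = 2
SUBTYPE_FL2 = 3
SUBTYPE_NAMES = {SUBTYPE_AGG: "Agg", SUBTYPE_FL1: "FL-1", SUBTYPE_FL2: "FL-2"}

#: default physical pitch of one heatmap pixel (one 256-px tile at 0.25 um/px)
DEFAULT_PIXEL_PITCH_MM = 0.064

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class TissueHeatmap:
    """A per-slide multi-class tissue label grid with physical scale.

    Parameters
    ----------
    labels : 2-D int array with values in {0, 1, 2, 3}.
    subtypes : 2-D int array, same shape; nonzero exactly where ``labels == 3``.
    pixel_pitch_mm : physical edge length of one heatmap pixel, in mm.
    slide_id : identifier of the source slide.
    """

    labels: np.ndarray
    subtypes: np.ndarray | None = None
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.subtypes is None:
            self.subtypes = np.zeros_like(self.labels)
        self.subtypes = np.asarray(self.subtypes, dtype=np.int16)
        if self.subtypes.shape != self.labels.shape:
            raise ValueError("labels and subtypes must share a shape")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        self.validate()

    def validate(self) -> None:
        if not np.isin(self.labels, TISSUE_CLASSES).all():
            raise ValueError("labels must lie in {0,1,2,3}")
        tls = self.labels == TLS
        if (self.subtypes[~tls] != SUBTYPE_NONE).any():
            raise ValueError("subtypes must be 0 outside TLS pixels")
        if (self.subtypes[tls] == SUBTYPE_NONE).any():
            raise ValueError("every TLS pixel needs a nonzero subtype")
        if not np.isin(self.subtypes, (0, 1, 2, 3)).all():
            raise ValueError("subtypes must lie in {0,1,2,3}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "TissueHeatmap":
        return TissueHeatmap(
            self.labels.copy(), self.subtypes.copy(), self.pixel_pitch_mm, self.slide_id
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TissueHeatmap):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subtypes, other.subtypes)
            and self.pixel_pitch_mm == other.pixel_pitch_mm
        )


@dataclass
class ConnectedComponent:
    """One 8-connected domain of a single tissue class."""

    label_class: int
    pixel_coords: np.ndarray  # (n, 2) array of (row, col)
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    slide_id: str = ""

    @property
    def area_px(self) -> int:
        return int(self.pixel_coords.shape[0])

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.pixel_pitch_mm**2

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixel_coords.mean(axis=0)
        return float(r), float(c)

    def mask_on(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixel_coords[:, 0], self.pixel_coords[:, 1]] = True
        return m


def find_components(h: TissueHeatmap, tissue_class: int) -> list[ConnectedComponent]:
    """Partition all pixels of ``tissue_class`` into 8-connected components.

    Components are returned in deterministic order, sorted by their
    (min row, min col) corner.
    """
    if tissue_class not in TISSUE_CLASSES:
        raise ValueError(f"unknown tissue class {tissue_class!r}")
    mask = h.labels == tissue_class
    lab, n = ndimage.label(mask, structure=_EIGHT_CONN)
    comps = []
    for idx in range(1, n + 1):
        coords = np.argwhere(lab == idx)
        comps.append(
            ConnectedComponent(tissue_class, coords, h.pixel_pitch_mm, h.slide_id)
        )
    comps.sort(key=lambda c: (int(c.pixel_coords[:, 0].min()), int(c.pixel_coords[:, 1].min())))
    return comps


def _remove_small(labels: np.ndarray, tissue_class: int, min_px: int) -> None:
    """Erase (to background, in place) components of a class below min_px."""
    mask = labels == tissue_class
    lab, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    kill = np.flatnonzero(sizes < min_px) + 1
    if kill.size:
        labels[np.isin(lab, kill)] = BACKGROUND


def postprocess(h: TissueHeatmap, min_tumor_px: int = 20) -> TissueHeatmap:
    """Denoise a heatmap: drop normal tissue, specks, small tumor domains; fill holes.

    Steps, in order:

    1. normal pixels -> background;
    2. single-pixel components of any remaining class -> background;
    3. tumor components with fewer than ``min_tumor_px`` pixels -> background;
    4. interior background holes of remaining tumor and TLS components are
       filled with the enclosing component's class (TLS fill applied last so
       the innermost enclosing structure wins).  New TLS pixels inherit the
       subtype of the nearest original TLS pixel.

    The operation is idempotent and never mutates its input.
    """
    if min_tumor_px < 1:
        raise ValueError("min_tumor_px must be >= 1")
    labels = h.labels.copy()
    labels[labels == NORMAL] = BACKGROUND
    _remove_small(labels, TUMOR, max(2, min_tumor_px))
    _remove_small(labels, TLS, 2)

    pre_fill_bg = labels == BACKGROUND
    for cls in (TUMOR, TLS):
        filled = ndimage.binary_fill_holes(labels == cls)
        labels[filled & pre_fill_bg] = cls

    subtypes = np.where(labels == TLS, h.subtypes, SUBTYPE_NONE).astype(np.int16)
    new_tls = (labels == TLS) & (subtypes == SUBTYPE_NONE)
    if new_tls.any():
        # propagate the nearest original subtype into hole-filled TLS pixels
        had = h.subtypes > 0
        if not had.any():
            raise ValueError("TLS pixels present without any subtype source")
        _, (ir, ic) = ndimage.distance_transform_edt(~had, return_indices=True)
        subtypes[new_tls] = h.subtypes[ir[new_tls], ic[new_tls]]
    return TissueHeatmap(labels, subtypes, h.pixel_pitch_mm, h.slide_id)


def ssim(a: TissueHeatmap, b: TissueHeatmap) -> float:
    """Structural similarity of two label grids treated as intensity images.

    Uses a 7x7 uniform window and the standard stabilizing constants, with the
    data range set to the maximum label value present (at least 1).  Only the
    class-label grid enters the comparison; the subtype channel does not.
    """
    if a.shape != b.shape:
        raise ValueError("heatmaps must share a shape")
    data_range = float(max(a.labels.max(), b.labels.max(), 1))
    return float(
        structural_similarity(
            a.labels.astype(np.float64),
            b.labels.astype(np.float64),
            win_size=7,
            data_range=data_range,
        )
    )
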