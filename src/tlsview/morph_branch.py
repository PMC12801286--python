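"""Morphological branch: TLS embeddings, per-case 7-center clustering,
gated-attention aggregation.

In the full framework each TLS region is embedded by a trained follicle
subtype network.  The embedding is a pluggable contract here — any callable
``(component, heatmap) -> vector`` of fixed width works.  The shipped
``toy_encoder`` is a deterministic handcrafted descriptor (area, perimeter,
circularity, maturity one-hot, margin distance) pushed through a fixed random
projection, so the whole pipeline runs without any trained weights.

Per case the embeddings are k-means-clustered into exactly 7 centers (cases
with fewer than 7 TLSs are padded by cyclic repetition), giving every case an
identical 7 x d_m representation so fusion models can train in full batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from tlsview import nn
from tlsview.fusion_nets import GatedAttention
from tlsview.heatmap_core import TissueHeatmap
from tlsview.spatial_branch import TLSComponent, _SUBTYPE_INDEX

N_MORPH_CLUSTERS = 7
DEFAULT_EMBED_DIM = 64

_PROJECTION_SEED = 715517  # fixed: the toy encoder must be deterministic


@dataclass
class TLSEmbedding:
    vector: np.ndarray
    component_id: str = ""

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.isfinite(self.vector).all():
            raise ValueError("embedding contains non-finite values")


@dataclass
class MorphBag:
    """Exactly 7 cluster centers (7 x d_m) representing one case's TLSs."""

    centers: np.ndarray
    case_id: str = ""
    empty: bool = False  # True when the case had no TLS at all

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2 or self.centers.shape[0] != N_MORPH_CLUSTERS:
            raise ValueError(f"MorphBag needs exactly {N_MORPH_CLUSTERS} centers")


def component_perimeter_px(mask: np.ndarray) -> int:
    """Perimeter as the count of exposed 4-neighbor pixel edges."""
    m = mask.astype(int)
    per = 0
    padded = np.pad(m, 1)
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        per += int((np.roll(padded, shift, axis=ax) < padded).sum())
    return per


def toy_encoder(c: TLSComponent, h: TissueHeatmap, d_m: int = DEFAULT_EMBED_DIM) -> TLSEmbedding:
    """Deterministic shape/subtype descriptor with a fixed random projection.

    The base descriptor is translation-invariant: area (mm^2 and log px),
    perimeter (mm), circularity 4*pi*A/P^2, a maturity one-hot, and the
    signed margin distance.  A fixed Gaussian projection lifts it to d_m
    dimensions with a tanh squash.
    """
    comp = c.component
    mask = comp.mask_on(h.shape)
    area_px = comp.area_px
    per_px = component_perimeter_px(mask)
    pitch = h.pixel_pitch_mm
    circ = 4.0 * np.pi * area_px / per_px**2 if per_px > 0 else 0.0
    onehot = np.zeros(3)
    onehot[_SUBTYPE_INDEX[c.subtype]] = 1.0
    base = np.array([
        comp.area_mm2,
        np.log1p(area_px),
        per_px * pitch,
        circ,
        *onehot,
        c.signed_margin_distance_mm,
    ])
    rng = np.random.default_rng(_PROJECTION_SEED)
    proj = rng.normal(size=(base.size, d_m)) / np.sqrt(base.size)
    return TLSEmbedding(np.tanh(base @ proj), component_id=f"{c.slide_id}")


def cluster_case(
    embeddings: list[TLSEmbedding],
    k: int = N_MORPH_CLUSTERS,
    seed: int = 0,
    case_id: str = "",
    d_m: int = DEFAULT_EMBED_DIM,
) -> MorphBag:
    """k-means the case's TLS embeddings into exactly k representative centers.

    Fewer than k embeddings are padded to k rows by cyclic repetition; an
    empty case yields an all-zero bag flagged ``empty``.
    """
    if not embeddings:
        return MorphBag(np.zeros((k, d_m)), case_id=case_id, empty=True)
    x = np.stack([e.vector for e in embeddings])
    if x.shape[0] < k:
        idx = np.arange(k) % x.shape[0]
        return MorphBag(x[idx], case_id=case_id)
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-6,
                random_state=seed)
    km.fit(x)
    # deterministic center order, independent of k-means internals
    centers = km.cluster_centers_
    order = np.lexsort(centers.T[::-1])
    return MorphBag(centers[order], case_id=case_id)


def aggregate_morph(bag: MorphBag, params: GatedAttention) -> np.ndarray:
    """Gated-attention pooling of the 7 centers into the case vector r̂_M."""
    if bag.centers.shape[1] != params.embed1.W.data.shape[0]:
        raise ValueError("embedding dimension does not match attention params")
    _, pooled = params(nn.Tensor(bag.centers))
    return pooled.data


def case_morph_bag(
    components: list[TLSComponent],
    heatmaps_by_slide: dict[str, TissueHeatmap],
    seed: int = 0,
    case_id: str = "",
    d_m: int = DEFAULT_EMBED_DIM,
    encoder=toy_encoder,
) -> MorphBag:
    """Encode and cluster all of a case's TLS components into its MorphBag."""
    embs = [encoder(c, heatmaps_by_slide[c.slide_id], d_m) for c in components]
    return cluster_case(embs, seed=seed, case_id=case_id, d_m=d_m)
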