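"""The framework's network heads: gated-attention MIL, the spatial-branch MLP,
two-branch multi-view fusion, and multimodal clinical fusion.

Equations implemented here:

*Gated attention* over a bag of instance features f_1..f_N (each produced by
two fully connected layers from the raw instance vector r_i):

    S_i = softmax_i( W · (tanh(W_a f_i) ⊙ σ(W_b f_i)) ),   pooled = Σ_i S_i f_i

*Case-level MIL head*:  p = softmax( W_out · pooled ).

*Two-branch fusion* of the spatial vector r_S and the morphological vector
r̂_M, with r_mv = concat(r_S, r̂_M):

    f_fusion = concat( W_fusion·(f_S ⊙ f_mvS),  W_fusion·(f_M ⊙ f_mvM) )

where f_S, f_M are linear maps of r_S, r̂_M and f_mvS, f_mvM are two separate
linear maps of r_mv; f_fusion (width 32) is the penultimate representation,
followed by a linear two-class head.

*Multimodal fusion*: a 14-covariate clinical vector passes through four
FC+BatchNorm+ReLU layers (14→64→64→64→32); the 32-wide clinical embedding is
concatenated with the 32-wide fusion penultimate into a 64-wide vector and a
final linear layer produces the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tlsview import nn
from tlsview.nn import Tensor

N_CLINICAL = 14


@dataclass
class PatchFeatureBag:
    """Instance feature matrix (N x d_p) for one case's MIL bag."""

    case_id: str
    matrix: np.ndarray
    slide_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("bag must be a non-empty N x d matrix")
        if not np.isfinite(self.matrix).all():
            raise ValueError("bag contains non-finite values")
        if self.slide_index is None:
            self.slide_index = np.zeros(self.matrix.shape[0], dtype=int)


class GatedAttention(nn.Module):
    """Instance embedding (two FC+ReLU layers) plus gated-attention pooling."""

    def __init__(self, d_in: int, h: int, a: int, rng: np.random.Generator):
        self.embed1 = nn.Linear(d_in, h, rng)
        self.embed2 = nn.Linear(h, h, rng)
        self.W_a = nn.Linear(h, a, rng, bias=False)
        self.W_b = nn.Linear(h, a, rng, bias=False)
        self.W = nn.Linear(a, 1, rng, bias=False)

    def instance_features(self, x: Tensor) -> Tensor:
        return self.embed2(self.embed1(x).relu()).relu()

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: (..., N, d_in) -> (scores (..., N, 1), pooled (..., h))."""
        f = self.instance_features(x)
        logits = self.W(self.embed_gate(f))
        scores = nn.softmax(logits, axis=-2)
        pooled = (scores * f).sum(axis=-2)
        return scores, pooled

    def embed_gate(self, f: Tensor) -> Tensor:
        return self.W_a(f).tanh() * self.W_b(f).sigmoid()


def gated_attention(bag: PatchFeatureBag, params: GatedAttention) -> tuple[np.ndarray, np.ndarray]:
    """Attention scores (probability vector over instances) and pooled vector."""
    scores, pooled = params(Tensor(bag.matrix))
    return scores.data[:, 0], pooled.data


class WSINet(nn.Module):
    """Case-level MIL prognosis model over patch-feature bags."""

    def __init__(self, d_in: int = 768, h: int = 256, a: int = 128,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.attention = GatedAttention(d_in, h, a, rng)
        self.head = nn.Linear(h, 2, rng)

    def forward_bag(self, bag: PatchFeatureBag) -> tuple[Tensor, Tensor]:
        scores, pooled = self.attention(Tensor(bag.matrix))
        logits = self.head(pooled.reshape(1, -1))
        return scores, logits

    def predict_proba(self, bag: PatchFeatureBag) -> np.ndarray:
        _, logits = self.forward_bag(bag)
        return nn.softmax(logits, axis=-1).data[0]


def wsinet_forward(bag: PatchFeatureBag, model: WSINet) -> np.ndarray:
    """Two-class probabilities for one bag (softmax over the linear head)."""
    return model.predict_proba(bag)


class SpBMLP(nn.Module):
    """Spatial-branch encoder: 226 -> 128 -> 64 -> 32 MLP with ReLU."""

    def __init__(self, d_in: int = 226, widths=(128, 64, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.mlp = nn.MLP([d_in, *widths], rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.mlp(x)


def spb_forward(x: np.ndarray, model: SpBMLP) -> np.ndarray:
    """Spatial representation r_S (width 32) for standardized feature rows."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if not np.isfinite(x).all():
        raise ValueError("non-finite spatial features")
    return model(Tensor(x)).data


class MorphAttention(nn.Module):
    """Simplified gated attention over the 7 morphological cluster centers."""

    def __init__(self, d_m: int = 64, h: int = 64, a: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.attention = GatedAttention(d_m, h, a, rng)

    def __call__(self, centers: Tensor) -> tuple[Tensor, Tensor]:
        return self.attention(centers)


class MVNet(nn.Module):
    """Two-branch multi-view fusion network.

    Consumes the 226-wide spatial vector (through SpBMLP) and a case's 7 x d_m
    morphological cluster-center matrix (through MorphAttention), fuses the
    branch representations via the shared-weight gated fusion equation, and
    classifies relapse with a linear head on the 32-wide f_fusion.
    """

    WIDTH = 32  # width of each branch representation; f_fusion is 32 = 2 x 16

    def __init__(self, d_spatial: int = 226, d_m: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spb = SpBMLP(d_spatial, seed=seed + 1)
        self.mpb = MorphAttention(d_m, seed=seed + 2)
        h_m = 64  # morph pooled width
        w = self.WIDTH
        self.map_S = nn.Linear(w, w, rng)        # f_S from r_S
        self.map_M = nn.Linear(h_m, w, rng)      # f_M from r̂_M
        self.map_mvS = nn.Linear(w + h_m, w, rng)  # f_mvS from r_mv
        self.map_mvM = nn.Linear(w + h_m, w, rng)  # f_mvM from r_mv
        self.W_fusion = nn.Linear(w, w // 2, rng, bias=False)
        self.head = nn.Linear(w, 2, rng)

    def branch_representations(self, spatial: Tensor, centers: Tensor) -> tuple[Tensor, Tensor]:
        r_s = self.spb(spatial)
        _, r_m = self.mpb(centers)
        return r_s, r_m

    def fuse(self, r_s: Tensor, r_m: Tensor) -> Tensor:
        """f_fusion (the 32-wide penultimate representation)."""
        r_mv = nn.concat([r_s, r_m], axis=-1)
        f_s = self.map_S(r_s)
        f_m = self.map_M(r_m)
        f_mvs = self.map_mvS(r_mv)
        f_mvm = self.map_mvM(r_mv)
        return nn.concat(
            [self.W_fusion(f_s * f_mvs), self.W_fusion(f_m * f_mvm)], axis=-1
        )

    def forward(self, spatial: Tensor, centers: Tensor) -> tuple[Tensor, Tensor]:
        r_s, r_m = self.branch_representations(spatial, centers)
        f_fusion = self.fuse(r_s, r_m)
        return f_fusion, self.head(f_fusion)

    def predict_proba(self, spatial: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """Relapse probabilities, rows aligned with input cases."""
        _, logits = self.forward(Tensor(np.atleast_2d(spatial)), Tensor(centers))
        return nn.softmax(logits, axis=-1).data

    def penultimate(self, spatial: np.ndarray, centers: np.ndarray) -> np.ndarray:
        f_fusion, _ = self.forward(Tensor(np.atleast_2d(spatial)), Tensor(centers))
        return f_fusion.data


def mvnet_fuse(r_s: np.ndarray, r_m: np.ndarray, model: MVNet) -> tuple[np.ndarray, np.ndarray]:
    """Apply the fusion equation to precomputed branch representations.

    Returns (f_fusion, class probabilities).
    """
    r_s = np.atleast_2d(np.asarray(r_s, dtype=np.float64))
    r_m = np.atleast_2d(np.asarray(r_m, dtype=np.float64))
    f_fusion = model.fuse(Tensor(r_s), Tensor(r_m))
    probs = nn.softmax(model.head(f_fusion), axis=-1)
    return f_fusion.data, probs.data


class ClinicalTower(nn.Module):
    """Clinical embedding tower: 14 -> 64 -> 64 -> 64 -> 32, FC+BN+ReLU each."""

    def __init__(self, d_in: int = N_CLINICAL, seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = [d_in, 64, 64, 64, 32]
        self.fcs = [nn.Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.bns = [nn.BatchNorm1d(b) for b in widths[1:]]

    def set_training(self, training: bool) -> None:
        for bn in self.bns:
            bn.training = training

    def __call__(self, x: Tensor) -> Tensor:
        for fc, bn in zip(self.fcs, self.bns):
            x = bn(fc(x)).relu()
        return x


class MMF(nn.Module):
    """Multimodal fusion: clinical embedding + fusion penultimate -> prediction."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.clinical = ClinicalTower(seed=seed + 1)
        self.head = nn.Linear(64, 2, rng)

    def set_training(self, training: bool) -> None:
        self.clinical.set_training(training)

    def forward(self, clinical: Tensor, penultimate: Tensor) -> Tensor:
        emb = self.clinical(clinical)
        fused = nn.concat([emb, penultimate], axis=-1)
        return self.head(fused)

    def predict_proba(self, clinical: np.ndarray, penultimate: np.ndarray) -> np.ndarray:
        clinical = np.atleast_2d(np.asarray(clinical, dtype=np.float64))
        if clinical.shape[1] != N_CLINICAL:
            raise ValueError(f"clinical vector must have {N_CLINICAL} covariates")
        self.set_training(False)
        logits = self.forward(Tensor(clinical), Tensor(np.atleast_2d(penultimate)))
        return nn.softmax(logits, axis=-1).data


def mmf_forward(clinical: np.ndarray, mvnet_penultimate: np.ndarray, model: MMF) -> np.ndarray:
    """Relapse probability rows from clinical covariates + fusion penultimate."""
    return model.predict_proba(clinical, mvnet_penultimate)


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics frozen on the training fold."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(1))
    std: np.ndarray = field(default_factory=lambda: np.ones(1))

    @classmethod
    def fit(cls, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=np.float64)
        std = x.std(axis=0)
        std[std < 1e-12] = 1.0
        return cls(mean=x.mean(axis=0), std=std)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.std
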