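"""Training and evaluation protocol: class-weighted loss, stratified 5-fold
case-level cross-validation, cross-fold ensemble averaging, Equal-Error-Rate
thresholding, and the evaluation statistics (AUROC, DeLong's paired test,
Kaplan-Meier / log-rank).

Protocol constants follow the development recipe the framework was built
with: relapse classification with class weights 0.5 (no relapse) / 1.2
(relapse), Adam at 1e-3 with inverse-time decay (rate 9e-3) and full-cohort
batches for the fusion models, 500 training epochs for prognostic models, and
out-of-fold concatenation for internal evaluation.  External-style evaluation
averages the five fold models' probabilities and binarizes only the ensemble,
at a dataset-specific EER threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from tlsview import nn
from tlsview.fusion_nets import MMF, MVNet, N_CLINICAL, SpBMLP, Standardizer
from tlsview.nn import Tensor

N_FOLDS = 5
CLASS_WEIGHTS = (0.5, 1.2)  # (no relapse, relapse)
EPOCHS_PROGNOSTIC = 500
EPOCHS_PREDICTIVE = 100
LR0 = 1e-3
INV_TIME_DECAY = 9e-3


@dataclass
class CaseRecord:
    """One case: identity, relapse outcome, survival follow-up, clinical row."""

    case_id: str
    relapse_label: int
    rfs_time_months: float
    event: int
    act_flag: int
    clinical: np.ndarray

    def __post_init__(self) -> None:
        self.clinical = np.asarray(self.clinical, dtype=np.float64)
        if self.clinical.shape != (N_CLINICAL,):
            raise ValueError(f"clinical vector must have {N_CLINICAL} entries")
        if self.rfs_time_months <= 0:
            raise ValueError("rfs_time_months must be positive")
        if self.relapse_label not in (0, 1) or self.event not in (0, 1):
            raise ValueError("labels must be 0/1")


@dataclass
class FoldSplit:
    """Disjoint case-id lists partitioning the cohort at case level."""

    folds: list[list[str]]

    def __post_init__(self) -> None:
        flat = [c for f in self.folds for c in f]
        if len(flat) != len(set(flat)):
            raise ValueError("folds overlap")

    @classmethod
    def stratified(cls, case_ids: list[str], labels: np.ndarray, seed: int,
                   n_folds: int = N_FOLDS) -> "FoldSplit":
        labels = np.asarray(labels)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [[case_ids[i] for i in test] for _, test in skf.split(labels, labels)]
        for f in folds:
            fl = labels[[case_ids.index(c) for c in f]]
            if len(set(fl.tolist())) < 2:
                raise ValueError("a fold contains a single class; enlarge the cohort")
        return cls(folds)


@dataclass
class RiskPrediction:
    case_id: str
    probability: float
    risk_class: int
    threshold: float
    fold: int = -1

    def __post_init__(self) -> None:
        assert self.risk_class == int(self.probability >= self.threshold)


# -- loss --------------------------------------------------------------------

def weighted_ce_loss(probs: np.ndarray, labels: np.ndarray,
                     w0: float = CLASS_WEIGHTS[0], w1: float = CLASS_WEIGHTS[1]) -> float:
    """Mean class-weighted cross-entropy: mean_i of -w_{y_i} log p_i[y_i].

    ``probs`` is (n, 2) class probabilities (or (n,) probability of class 1).
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim == 1:
        probs = np.column_stack([1.0 - probs, probs])
    p_true = probs[np.arange(len(labels)), labels]
    if (p_true <= 0).any():
        warnings.warn("zero predicted probability clipped at 1e-12")
        p_true = np.clip(p_true, 1e-12, None)
    w = np.where(labels == 1, w1, w0)
    return float(np.mean(-w * np.log(p_true)))


def _weighted_ce_tensor(logits: Tensor, labels: np.ndarray,
                        w0: float = CLASS_WEIGHTS[0], w1: float = CLASS_WEIGHTS[1]) -> Tensor:
    """Differentiable class-weighted cross-entropy on 2-class logits."""
    logp = nn.softmax(logits, axis=-1).log()
    n = len(labels)
    picked = logp[np.arange(n), labels]
    w = np.where(np.asarray(labels) == 1, w1, w0)
    return (picked * Tensor(-w)).mean()


# -- model specs and single-fold training -------------------------------------

@dataclass
class ModelSpec:
    """What to train: 'spb', 'mvnet', or 'mmf', plus sizes and schedule."""

    kind: str = "mvnet"
    d_spatial: int = 226
    d_m: int = 64
    epochs: int = EPOCHS_PROGNOSTIC
    lr0: float = LR0
    decay: float = INV_TIME_DECAY
    pretrain_epochs: int = 100
    l2_penalty: float = 3e-2
    class_weights: tuple[float, float] = CLASS_WEIGHTS


@dataclass
class TrainedModel:
    """A fold model together with its frozen standardization statistics."""

    spec: ModelSpec
    net: nn.Module
    standardizer: Standardizer
    lr_trace: list[float] = field(default_factory=list)

    def predict_proba(self, spatial: np.ndarray, centers: np.ndarray | None = None,
                      clinical: np.ndarray | None = None) -> np.ndarray:
        """Relapse (class-1) probability per case."""
        z = self.standardizer.transform(np.atleast_2d(spatial))
        if self.spec.kind == "spb":
            logits = self.net.head(self.net.spb(Tensor(z)))
            return nn.softmax(logits, axis=-1).data[:, 1]
        if self.spec.kind == "mvnet":
            return self.net.predict_proba(z, centers)[:, 1]
        if self.spec.kind == "mmf":
            pen = self.net.mvnet.penultimate(z, centers)
            return self.net.mmf.predict_proba(clinical, pen)[:, 1]
        raise ValueError(f"unknown model kind {self.spec.kind!r}")


class _SpBClassifier(nn.Module):
    def __init__(self, d_spatial: int, seed: int):
        rng = np.random.default_rng(seed)
        self.spb = SpBMLP(d_spatial, seed=seed + 1)
        self.head = nn.Linear(32, 2, rng)


class _MMFStack(nn.Module):
    """A trained (frozen) MVNet plus the multimodal head trained on top."""

    def __init__(self, mvnet: MVNet, seed: int):
        self.mvnet = mvnet
        self.mmf = MMF(seed=seed)

    def parameters(self):
        return self.mmf.parameters()  # the fusion trunk stays frozen


def _l2_term(net: nn.Module, lam: float):
    reg = None
    for p in net.parameters():
        t = (p * p).sum()
        reg = t if reg is None else reg + t
    return reg * lam


def _train_epochs(net: nn.Module, loss_fn, epochs: int, lr0: float, decay: float,
                  l2_penalty: float = 0.0) -> list[float]:
    opt = nn.Adam(net.parameters(), lr=lr0)
    trace = []
    for epoch in range(epochs):
        opt.lr = nn.inverse_time_lr(lr0, decay, epoch)
        trace.append(opt.lr)
        net.zero_grad()
        loss = loss_fn()
        if l2_penalty > 0:
            loss = loss + _l2_term(net, l2_penalty)
        loss.backward()
        opt.step()
    return trace


def train_fold(spec: ModelSpec, spatial: np.ndarray, centers: np.ndarray,
               clinical: np.ndarray, labels: np.ndarray, seed: int) -> TrainedModel:
    """Train one fold model on the training split (full-batch Adam)."""
    std = Standardizer.fit(spatial)
    z = std.transform(spatial)
    labels = np.asarray(labels, dtype=int)
    w = spec.class_weights

    if spec.kind == "spb":
        net = _SpBClassifier(spec.d_spatial, seed)
        zt = Tensor(z)

        def loss_fn():
            return _weighted_ce_tensor(net.head(net.spb(zt)), labels, *w)

        trace = _train_epochs(net, loss_fn, spec.epochs, spec.lr0, spec.decay, spec.l2_penalty)
        return TrainedModel(spec, net, std, trace)

    if spec.kind == "mvnet":
        net = MVNet(spec.d_spatial, spec.d_m, seed=seed)
        zt, ct = Tensor(z), Tensor(centers)

        # branch pretraining with randomly initialized weights, then joint
        if spec.pretrain_epochs > 0:
            spb_head = nn.Linear(32, 2, np.random.default_rng(seed + 11))
            wrap_s = nn.Module()
            wrap_s.spb, wrap_s.head = net.spb, spb_head
            _train_epochs(
                wrap_s,
                lambda: _weighted_ce_tensor(spb_head(net.spb(zt)), labels, *w),
                spec.pretrain_epochs, spec.lr0, spec.decay, spec.l2_penalty)
            mpb_head = nn.Linear(64, 2, np.random.default_rng(seed + 12))
            wrap_m = nn.Module()
            wrap_m.mpb, wrap_m.head = net.mpb, mpb_head
            _train_epochs(
                wrap_m,
                lambda: _weighted_ce_tensor(mpb_head(net.mpb(ct)[1]), labels, *w),
                spec.pretrain_epochs, spec.lr0, spec.decay, spec.l2_penalty)

        def loss_fn():
            _, logits = net.forward(zt, ct)
            return _weighted_ce_tensor(logits, labels, *w)

        trace = _train_epochs(net, loss_fn, spec.epochs, spec.lr0, spec.decay, spec.l2_penalty)
        return TrainedModel(spec, net, std, trace)

    if spec.kind == "mmf":
        base = train_fold(
            ModelSpec("mvnet", spec.d_spatial, spec.d_m, spec.epochs, spec.lr0,
                      spec.decay, spec.pretrain_epochs, spec.class_weights),
            spatial, centers, clinical, labels, seed)
        stack = _MMFStack(base.net, seed + 31)
        pen = Tensor(base.net.penultimate(z, centers))
        clin = Tensor(np.asarray(clinical, dtype=np.float64))

        def loss_fn():
            stack.mmf.set_training(True)
            return _weighted_ce_tensor(stack.mmf.forward(clin, pen), labels, *w)

        trace = _train_epochs(stack, loss_fn, spec.epochs, spec.lr0, spec.decay, spec.l2_penalty)
        stack.mmf.set_training(False)
        return TrainedModel(spec, stack, std, trace)

    raise ValueError(f"unknown model kind {spec.kind!r}")


@dataclass
class CVResult:
    split: FoldSplit
    oof_probs: np.ndarray        # out-of-fold probability per case (cohort order)
    oof_fold: np.ndarray         # which fold predicted each case
    models: list[TrainedModel]


def run_cv(case_ids: list[str], labels: np.ndarray, spatial: np.ndarray,
           centers: np.ndarray, clinical: np.ndarray, spec: ModelSpec,
           seed: int, split: FoldSplit | None = None) -> CVResult:
    """Stratified 5-fold case-level CV with out-of-fold concatenation.

    Every case is predicted exactly once, by the model not trained on it.
    Passing an existing ``split`` reuses the same data division across model
    variants.
    """
    labels = np.asarray(labels, dtype=int)
    if len(case_ids) < 10:
        raise ValueError("need at least 10 cases")
    if split is None:
        split = FoldSplit.stratified(case_ids, labels, seed)
    index = {c: i for i, c in enumerate(case_ids)}
    oof = np.full(len(case_ids), np.nan)
    fold_of = np.full(len(case_ids), -1)
    models = []
    for k, test_ids in enumerate(split.folds):
        test_idx = np.array([index[c] for c in test_ids])
        train_mask = np.ones(len(case_ids), dtype=bool)
        train_mask[test_idx] = False
        tm = train_fold(spec, spatial[train_mask], centers[train_mask],
                        clinical[train_mask], labels[train_mask], seed + 1000 * k)
        oof[test_idx] = tm.predict_proba(spatial[test_idx], centers[test_idx],
                                         clinical[test_idx])
        fold_of[test_idx] = k
        models.append(tm)
    assert not np.isnan(oof).any()
    return CVResult(split, oof, fold_of, models)


def ensemble_predict(models: list[TrainedModel], spatial: np.ndarray,
                     centers: np.ndarray | None = None,
                     clinical: np.ndarray | None = None) -> np.ndarray:
    """Arithmetic mean of the five fold models' probabilities per case."""
    if len(models) != N_FOLDS:
        raise ValueError(f"expected {N_FOLDS} models, got {len(models)}")
    preds = [m.predict_proba(spatial, centers, clinical) for m in models]
    return np.mean(preds, axis=0)


# -- thresholding and metrics --------------------------------------------------

def eer_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Equal-Error-Rate threshold: minimizes |FPR - FNR| over candidates.

    Candidates are the unique probabilities plus +inf; classification rule is
    ``probability >= t  =>  high risk``.  Ties go to the smaller threshold.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    cands = np.unique(probs)
    if cands.size == 1:
        warnings.warn("all probabilities identical; degenerate EER threshold")
        return float(cands[0])
    cands = np.append(cands, np.inf)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_t, best_gap = None, np.inf
    for t in cands:
        pred = probs >= t
        fpr = (pred & (labels == 0)).sum() / n_neg
        fnr = (~pred & (labels == 1)).sum() / n_pos
        gap = abs(fpr - fnr)
        if gap < best_gap - 1e-15:
            best_gap, best_t = gap, t
    return float(best_t)


def stratify(case_ids: list[str], probs: np.ndarray, threshold: float,
             folds: np.ndarray | None = None) -> list[RiskPrediction]:
    out = []
    for i, (cid, p) in enumerate(zip(case_ids, probs)):
        out.append(RiskPrediction(cid, float(p), int(p >= threshold), threshold,
                                  int(folds[i]) if folds is not None else -1))
    return out


def auroc(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann-Whitney statistic with half-credit for ties."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    order = stats.rankdata(probs)
    r_pos = order[labels == 1].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def bootstrap_auroc_ci(probs: np.ndarray, labels: np.ndarray, n_boot: int = 2000,
                       seed: int = 0, alpha: float = 0.05) -> tuple[float, float, float]:
    """Point estimate and percentile bootstrap CI for the AUROC."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=np.float64)
    n = len(labels)
    vals = []
    while len(vals) < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(set(labels[idx].tolist())) < 2:
            continue
        vals.append(auroc(probs[idx], labels[idx]))
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return auroc(probs, labels), float(lo), float(hi)


def _delong_structural_components(probs: np.ndarray, labels: np.ndarray):
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    m, n = len(pos), len(neg)
    # V10[i] = P(pos_i > neg) + 0.5 P(=); V01[j] symmetric
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    return v10, v01


def delong_compare(probs_a: np.ndarray, probs_b: np.ndarray,
                   labels: np.ndarray) -> dict:
    """DeLong's paired test for the difference of two correlated AUROCs.

    Returns z, the two-sided p-value, each model's AUROC variance, and their
    covariance (structural-components estimator).
    """
    labels = np.asarray(labels, dtype=int)
    probs_a = np.asarray(probs_a, dtype=np.float64)
    probs_b = np.asarray(probs_b, dtype=np.float64)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    va10, va01 = _delong_structural_components(probs_a, labels)
    vb10, vb01 = _delong_structural_components(probs_b, labels)
    m, n = len(va10), len(va01)
    auc_a, auc_b = va10.mean(), vb10.mean()
    s10 = np.cov(np.stack([va10, vb10]))  # 2x2 over positives
    s01 = np.cov(np.stack([va01, vb01]))
    var = s10 / m + s01 / n  # covariance matrix of (auc_a, auc_b)
    var_diff = var[0, 0] + var[1, 1] - 2 * var[0, 1]
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return {"z": 0.0, "p": 1.0, "var_a": float(var[0, 0]),
                    "var_b": float(var[1, 1]), "cov": float(var[0, 1]),
                    "auc_a": float(auc_a), "auc_b": float(auc_b)}
        raise ValueError("degenerate DeLong variance; cannot form the z statistic")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p), "var_a": float(var[0, 0]),
            "var_b": float(var[1, 1]), "cov": float(var[0, 1]),
            "auc_a": float(auc_a), "auc_b": float(auc_b)}


def km_curve(times: np.ndarray, events: np.ndarray):
    """Product-limit (Kaplan-Meier) survival estimate with right censoring.

    Returns (event_times, survival_probabilities).
    """
    times = np.asarray(times, dtype=np.float64)
    if times.size == 0:
        raise ValueError("empty group")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()


def logrank(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    g0, g1 = group == 0, group == 1
    if not g0.any() or not g1.any():
        raise ValueError("both groups must be non-empty")
    res = logrank_test(times[g0], times[g1], events[g0], events[g1])
    return float(res.test_statistic), float(res.p_value)
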