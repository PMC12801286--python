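"""Attention- and attribution-based explanations.

Three layers of explanation mirror how the risk models are inspected:

* the top-k (default 50) highest-attention instances per case, as
  representative patches;
* k-means clustering (default 5 clusters) of those representative patches'
  features, summarized as cluster sizes;
* exact Shapley attribution of the spatial-branch prediction over a small
  partition of the 226 features into named groups (full 2^g coalition
  enumeration, so the efficiency axiom holds to machine precision).

The default grouping keeps per-distance-bin resolution for the mature FL-2
subtype (the maturity class whose peritumoral placement the models weight
most), pools the immature subtypes' distance features, and keeps area-bin,
joint-bin and tumor-global blocks whole: 11 groups in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

from tlsview.spatial_branch import N_BINS, N_FEATURES, registry_names

MAX_SHAPLEY_GROUPS = 12
TOP_K_TILES = 50
N_PATCH_CLUSTERS = 5


def top_attention_tiles(scores: np.ndarray, k: int = TOP_K_TILES) -> np.ndarray:
    """Indices of the k highest-attention instances, ties broken by index."""
    scores = np.asarray(scores, dtype=np.float64)
    k = min(k, scores.size)
    # stable sort on (-score, index): mergesort keeps index order within ties
    order = np.argsort(-scores, kind="mergesort")
    return order[:k]


def cluster_patches(features: np.ndarray, k: int = N_PATCH_CLUSTERS,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """k-means the selected tiles' features; returns (assignments, cluster sizes)."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n = features.shape[0]
    if n < k:
        warnings.warn(f"only {n} tiles; reducing clusters from {k} to {n}")
        k = n
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(features)
    sizes = np.bincount(labels, minlength=k)
    return labels, sizes


def default_feature_groups() -> dict[str, list[int]]:
    """The default 11-group partition of the 226 spatial features."""
    names = registry_names()
    idx = {n: i for i, n in enumerate(names)}
    groups: dict[str, list[int]] = {}
    for b in range(N_BINS):
        groups[f"FL2_dist_bin{b}"] = [
            idx[f"dist{b}_FL2_{stat}"] for stat in ("count", "area_total", "area_mean")
        ]
    groups["immature_dist"] = [
        idx[f"dist{b}_{s}_{stat}"]
        for s in ("Agg", "FL1") for b in range(N_BINS)
        for stat in ("count", "area_total", "area_mean")
    ]
    groups["area_bins"] = [i for i, n in enumerate(names) if n.startswith("area")]
    groups["joint_bins"] = [i for i, n in enumerate(names) if n.startswith("joint_")]
    groups["tumor_globals"] = [idx["tumor_area_total_mm2"],
                               idx["tumor_area_mean_per_slide_mm2"]]
    return groups


@dataclass
class AttributionReport:
    """Exact grouped Shapley attributions of one prediction."""

    group_names: list[str]
    values: np.ndarray           # Shapley value per group
    baseline_value: float        # model output at the baseline vector
    prediction_value: float      # model output at the explained vector
    groups: dict[str, list[int]]

    @property
    def directions(self) -> list[str]:
        """'unfavorable' pushes the prediction up (toward relapse), else 'favorable'."""
        return ["unfavorable" if v > 0 else "favorable" for v in self.values]

    def efficiency_gap(self) -> float:
        return float(abs(self.values.sum() - (self.prediction_value - self.baseline_value)))


def _validate_groups(groups: dict[str, list[int]], n_features: int) -> None:
    if len(groups) > MAX_SHAPLEY_GROUPS:
        raise ValueError(
            f"{len(groups)} groups exceed the exact-enumeration bound of "
            f"{MAX_SHAPLEY_GROUPS}")
    all_idx = sorted(i for g in groups.values() for i in g)
    if all_idx != list(range(n_features)):
        raise ValueError("groups must partition the feature indices exactly once")


def shapley_groups(model_fn, x: np.ndarray, baseline: np.ndarray,
                   groups: dict[str, list[int]] | None = None) -> AttributionReport:
    """Exact Shapley values over feature groups by full coalition enumeration.

    ``model_fn`` maps a (m, d) matrix of feature vectors to m scalars.  For
    each coalition S the features of groups in S are taken from ``x`` and all
    others from ``baseline``; with g groups the model is evaluated on all 2^g
    coalition vectors in one batch.
    """
    x = np.asarray(x, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if x.shape != baseline.shape:
        raise ValueError("x and baseline must share a shape")
    if groups is None:
        if x.shape[0] != N_FEATURES:
            raise ValueError("default grouping requires the 226-feature vector")
        groups = default_feature_groups()
    _validate_groups(groups, x.shape[0])

    gnames = list(groups.keys())
    g = len(gnames)
    n_coal = 1 << g

    vectors = np.tile(baseline, (n_coal, 1))
    for mask in range(n_coal):
        for gi in range(g):
            if mask >> gi & 1:
                cols = groups[gnames[gi]]
                vectors[mask, cols] = x[cols]
    values = np.asarray(model_fn(vectors), dtype=np.float64).reshape(n_coal)

    # precomputed coalition-size weights |S|!(g-|S|-1)!/g!
    wgt = np.array([factorial(s) * factorial(g - s - 1) / factorial(g)
                    for s in range(g)])
    sizes = np.array([bin(m).count("1") for m in range(n_coal)])
    shap = np.zeros(g)
    for i in range(g):
        bit = 1 << i
        without = np.array([m for m in range(n_coal) if not m & bit])
        shap[i] = np.sum(wgt[sizes[without]]
                         * (values[without | bit] - values[without]))

    return AttributionReport(
        group_names=gnames,
        values=shap,
        baseline_value=float(values[0]),
        prediction_value=float(values[-1]),
        groups=groups,
    )


def shapley_spb(trained_model, x: np.ndarray, baseline: np.ndarray,
                groups: dict[str, list[int]] | None = None) -> AttributionReport:
    """Grouped Shapley attribution of a spatial-branch model's relapse probability."""

    def model_fn(v: np.ndarray) -> np.ndarray:
        return trained_model.predict_proba(v)

    return shapley_groups(model_fn, x, baseline, groups)


def cohort_attributions(trained_model, spatial: np.ndarray,
                        groups: dict[str, list[int]] | None = None) -> dict:
    """Cohort-level grouped Shapley summary for a spatial-branch model.

    The baseline is the cohort mean feature vector.  Besides the mean |value|
    and mean signed value per group, each group gets a ``direction``: the sign
    of the correlation between a case's group exposure (mean of the group's
    z-scored features) and its attribution.  A negative correlation means more
    of the group's features pushes the predicted relapse risk down
    ("favorable"); positive means "unfavorable".
    """
    spatial = np.asarray(spatial, dtype=np.float64)
    baseline = spatial.mean(axis=0)
    reports = [shapley_spb(trained_model, row, baseline, groups) for row in spatial]
    vals = np.stack([r.values for r in reports])
    gps = reports[0].groups
    names = reports[0].group_names
    sd = spatial.std(axis=0)
    sd[sd < 1e-12] = 1.0
    z = (spatial - baseline) / sd
    corr = np.zeros(len(names))
    for gi, name in enumerate(names):
        exposure = z[:, gps[name]].mean(axis=1)
        if exposure.std() > 1e-12 and vals[:, gi].std() > 1e-12:
            corr[gi] = np.corrcoef(exposure, vals[:, gi])[0, 1]
    return {
        "group_names": names,
        "mean_abs": np.abs(vals).mean(axis=0),
        "mean_signed": vals.mean(axis=0),
        "exposure_corr": corr,
        "direction": ["unfavorable" if c > 0 else "favorable" for c in corr],
        "reports": reports,
    }


def maturity_outcome_table(top_subtypes: np.ndarray, outcomes: np.ndarray) -> dict:
    """Contingency of each case's top-attention TLS subtype vs outcome group.

    ``top_subtypes`` holds subtype codes (1 Agg, 2 FL-1, 3 FL-2) of the
    highest-attention TLS per case; ``outcomes`` the relapse labels.  Returns
    the 3 x 2 table and a chi-square test.
    """
    top_subtypes = np.asarray(top_subtypes, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    table = np.zeros((3, 2), dtype=int)
    for st, y in zip(top_subtypes, outcomes):
        table[st - 1, y] += 1
    keep = table.sum(axis=1) > 0
    chi2, p = np.nan, np.nan
    if keep.sum() >= 2 and (table.sum(axis=0) > 0).all():
        chi2, p, _, _ = chi2_contingency(table[keep])
    return {"table": table, "chi2": float(chi2), "p": float(p)}
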