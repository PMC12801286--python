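"""Seed-reproducible synthetic cohorts: heatmaps, patch bags, clinical
covariates and relapse outcomes with a planted TLS-dependent risk structure.

Each slide carries one smoothed tumor blob and a Poisson number of elliptical
TLS domains placed at controlled signed distances from the tumor margin, with
sampled maturity subtype and log-normal area.  Case outcomes are planted on
the biology the downstream models are meant to recover: peritumoral mature
(FL-2) TLS burden 1.0-4.5 mm from the margin is protective, total tumor area
is adverse, and one clinical covariate (insufficient lymph-node sampling)
adds risk.  The generator emits a per-component ground-truth table so
extraction can be audited against what was planted.

Defaults describe the study conditions the pipeline is exercised under:
three slides per case, ~6 TLS per slide spread uniformly over the seven
distance bins, subtype mix 40/35/25 (Agg/FL-1/FL-2), areas log-normal around
0.05 mm^2, and a relapse prevalence near 25%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tlsview.heatmap_core import (
    DEFAULT_PIXEL_PITCH_MM,
    SUBTYPE_AGG,
    SUBTYPE_FL1,
    SUBTYPE_FL2,
    TLS,
    TUMOR,
    TissueHeatmap,
)
from tlsview.fusion_nets import N_CLINICAL, PatchFeatureBag

CLINICAL_COLUMNS = [
    "age_z", "sex", "t4_stage", "poor_differentiation", "tumor_budding",
    "pni", "vi", "srcc", "mac", "lns_insufficient", "mmr_deficient",
    "cea_elevated", "obstruction", "perforation",
]
assert len(CLINICAL_COLUMNS) == N_CLINICAL

#: distance-bin sampling support (mm): (low, high] per bin; bin 0 is inside
#: tumor (kept clear of the margin so sign recovery is unambiguous)
_DIST_SAMPLING_RANGES = [
    (-1.2, -0.15), (0.0, 0.4), (0.4, 1.0), (1.0, 2.2),
    (2.2, 4.5), (4.5, 6.4), (6.4, 8.0),
]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 60
    slides_per_case: int = 3
    grid_shape: tuple[int, int] = (224, 224)
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    tumor_radius_px: float = 26.0       # ~1.7 mm tumor mass radius
    tumor_wobble: float = 0.12          # relative boundary roughness
    tls_mean_per_slide: float = 6.0
    subtype_probs: tuple[float, float, float] = (0.40, 0.35, 0.25)
    area_log_mean: float = float(np.log(0.05))   # mm^2, log-normal location
    area_log_sigma: float = 0.55
    area_min_mm2: float = 0.012
    area_max_mm2: float = 0.55
    effect_size: float = 2.0            # beta on standardized peritumoral FL-2 area
    beta_tumor: float = 1.0             # adverse weight on standardized tumor area
    beta_clinical: float = 0.5          # adverse weight on the LNS covariate
    link_gain: float = 1.6              # slope of the logistic outcome link
    relapse_prevalence: float = 0.25    # calibration point for the intercept
    censor_rate: float = 0.15           # early-censor fraction among non-relapse
    bag_dim: int = 64
    bag_mean_patches: int = 120
    bag_signal_delta: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_probs) - 1.0) > 1e-9:
            raise ValueError("subtype probabilities must sum to 1")
        if self.n_cases < 10:
            raise ValueError("n_cases must be at least 10")


def _tumor_radius_fn(cfg: SynthConfig, rng: np.random.Generator):
    """Smooth wobbly radius r(theta) for one slide's tumor blob."""
    coeffs = rng.normal(scale=cfg.tumor_wobble / 2, size=(3, 2))

    def r(theta):
        out = np.ones_like(theta)
        for k, (c, s) in enumerate(coeffs, start=2):
            out = out + c * np.cos(k * theta) + s * np.sin(k * theta)
        return cfg.tumor_radius_px * np.clip(out, 0.6, 1.4)

    return r


def _rasterize_tumor(cfg: SynthConfig, center: np.ndarray, radius_fn) -> np.ndarray:
    h, w = cfg.grid_shape
    rr, cc = np.mgrid[0:h, 0:w]
    dy, dx = rr - center[0], cc - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return dist <= radius_fn(theta)


def _rasterize_ellipse(cfg: SynthConfig, center: np.ndarray, area_mm2: float,
                       rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.grid_shape
    area_px = area_mm2 / cfg.pixel_pitch_mm**2
    ratio = rng.uniform(1.0, 2.2)
    b = np.sqrt(area_px / (np.pi * ratio))
    a = b * ratio
    phi = rng.uniform(0, np.pi)
    rr, cc = np.mgrid[0:h, 0:w]
    dy, dx = rr - center[0], cc - center[1]
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _dilate(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        out |= np.roll(mask, shift, axis=ax)
    return out


def _boundary_pixels(tumor: np.ndarray) -> np.ndarray:
    interior = (
        np.roll(tumor, 1, 0) & np.roll(tumor, -1, 0)
        & np.roll(tumor, 1, 1) & np.roll(tumor, -1, 1)
    )
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    return np.argwhere(tumor & ~interior)


def make_heatmap(cfg: SynthConfig, rng: np.random.Generator,
                 slide_id: str = "") -> tuple[TissueHeatmap, pd.DataFrame]:
    """One slide: a tumor blob plus TLS ellipses at controlled placements.

    Returns the heatmap and a ground-truth table with one row per planted TLS
    (sampled subtype/area/distance plus the achieved rasterized values).
    """
    h, w = cfg.grid_shape
    labels = np.zeros((h, w), dtype=np.int16)
    subtypes = np.zeros((h, w), dtype=np.int16)
    center = np.array([h / 2 + rng.uniform(-8, 8), w / 2 + rng.uniform(-8, 8)])
    radius_fn = _tumor_radius_fn(cfg, rng)
    tumor = _rasterize_tumor(cfg, center, radius_fn)
    if tumor.sum() < 200:
        tumor = _rasterize_tumor(cfg, center, lambda t: np.full_like(t, cfg.tumor_radius_px))
    labels[tumor] = TUMOR
    boundary = _boundary_pixels(tumor)

    n_tls = rng.poisson(cfg.tls_mean_per_slide)
    rows = []
    pitch = cfg.pixel_pitch_mm
    for j in range(n_tls):
        subtype = int(rng.choice([SUBTYPE_AGG, SUBTYPE_FL1, SUBTYPE_FL2],
                                 p=cfg.subtype_probs))
        area = float(np.clip(np.exp(rng.normal(cfg.area_log_mean, cfg.area_log_sigma)),
                             cfg.area_min_mm2, cfg.area_max_mm2))
        dist_bin = int(rng.integers(0, 7))
        lo, hi = _DIST_SAMPLING_RANGES[dist_bin]
        target_mm = float(rng.uniform(lo, hi))
        placed = False
        for _ in range(100):
            theta = rng.uniform(-np.pi, np.pi)
            rb = float(radius_fn(np.array([theta]))[0])
            unit = np.array([np.sin(theta), np.cos(theta)])
            mask = None
            # an ellipse whose center sits closer to the margin than its own
            # minor axis would overlap tumor: push outward a few px if needed
            for push in range(0, 13):
                radial = max(rb + target_mm / pitch + (push if target_mm > 0 else 0), 2.0)
                pos = center + radial * unit
                if not (4 <= pos[0] < h - 4 and 4 <= pos[1] < w - 4):
                    mask = None
                    break
                cand = _rasterize_ellipse(cfg, pos, area, rng)
                if cand.sum() < 2:
                    continue
                grown = _dilate(cand)
                if target_mm > 0:
                    if (labels[cand] != 0).any() or (labels[grown] == TLS).any():
                        continue
                elif (labels[grown] == TLS).any():
                    break  # intratumoral: pushing outward would not help
                mask = cand
                break
            if mask is not None:
                placed = True
                break
        if not placed:
            warnings.warn(f"TLS placement failed on slide {slide_id}; resampled away")
            continue
        labels[mask] = TLS
        subtypes[mask] = subtype
        rows.append({
            "slide_id": slide_id, "tls_index": j, "subtype": subtype,
            "sampled_area_mm2": area, "area_px": int(mask.sum()),
            "achieved_area_mm2": float(mask.sum()) * pitch**2,
            "sampled_distance_mm": target_mm,
            "_mask_coords": np.argwhere(mask),
            "dist_bin_target": dist_bin,
        })
    # achieved distances measured the way extraction measures them: against
    # the margin of the hole-filled final tumor region
    from scipy import ndimage

    region = ndimage.binary_fill_holes(labels == TUMOR)
    boundary = _boundary_pixels(region)
    for row in rows:
        centroid = row.pop("_mask_coords").mean(axis=0)
        d_px = float(np.min(np.hypot(*(boundary - centroid).T)))
        inside = region[int(round(centroid[0])), int(round(centroid[1]))]
        row["achieved_distance_mm"] = (-1.0 if inside else 1.0) * d_px * pitch
    hm = TissueHeatmap(labels, subtypes, pitch, slide_id)
    truth = pd.DataFrame(rows, columns=[
        "slide_id", "tls_index", "subtype", "sampled_area_mm2", "area_px",
        "achieved_area_mm2", "sampled_distance_mm", "achieved_distance_mm",
        "dist_bin_target"])
    return hm, truth


def add_speckle(hm: TissueHeatmap, rate: float, rng: np.random.Generator) -> TissueHeatmap:
    """Inject isolated single-pixel mispredictions into a heatmap copy.

    Emulates patch-classifier noise: a ``rate`` fraction of background pixels
    not adjacent to any existing tissue become isolated normal/tumor/TLS
    specks.  Because every speck is a single pixel away from real tissue,
    post-processing removes all of them exactly and extracted features are
    unchanged; only the raw-vs-cleaned SSIM drops below 1.
    """
    from tlsview.heatmap_core import NORMAL

    labels = hm.labels.copy()
    subtypes = hm.subtypes.copy()
    tissue = labels != 0
    eligible = ~_dilate(_dilate(tissue))
    coords = np.argwhere(eligible)
    n = int(rate * coords.shape[0])
    if n > 0:
        pick = coords[rng.choice(coords.shape[0], size=n, replace=False)]
        # thin the picks so no two specks touch (keeps them single-pixel)
        taken = np.zeros_like(labels, dtype=bool)
        for r, c in pick:
            nb = taken[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
            if nb.any():
                continue
            taken[r, c] = True
            cls = int(rng.choice([NORMAL, TUMOR, TLS]))
            labels[r, c] = cls
            subtypes[r, c] = int(rng.integers(1, 4)) if cls == TLS else 0
    return TissueHeatmap(labels, subtypes, hm.pixel_pitch_mm, hm.slide_id)


@dataclass
class SynthCase:
    case_id: str
    heatmaps: list[TissueHeatmap]
    truth: pd.DataFrame
    clinical: np.ndarray
    act_flag: int
    eta: float = np.nan
    relapse_label: int = 0
    rfs_time_months: float = np.nan
    event: int = 0


@dataclass
class SynthCohort:
    cfg: SynthConfig
    cases: list[SynthCase]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    def labels(self) -> np.ndarray:
        return np.array([c.relapse_label for c in self.cases])

    def clinical_matrix(self) -> np.ndarray:
        return np.stack([c.clinical for c in self.cases])

    def outcome_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "case_id": self.case_ids,
            "relapse_label": [c.relapse_label for c in self.cases],
            "rfs_time_months": [c.rfs_time_months for c in self.cases],
            "event": [c.event for c in self.cases],
            "act_flag": [c.act_flag for c in self.cases],
            "eta": [c.eta for c in self.cases],
        })


def _make_clinical(rng: np.random.Generator) -> np.ndarray:
    prev = {
        "sex": 0.55, "t4_stage": 0.2, "poor_differentiation": 0.25,
        "tumor_budding": 0.3, "pni": 0.15, "vi": 0.15, "srcc": 0.03,
        "mac": 0.1, "lns_insufficient": 0.3, "mmr_deficient": 0.15,
        "cea_elevated": 0.3, "obstruction": 0.08, "perforation": 0.03,
    }
    row = np.empty(N_CLINICAL)
    row[0] = rng.normal()  # standardized age
    for i, name in enumerate(CLINICAL_COLUMNS[1:], start=1):
        row[i] = float(rng.random() < prev[name])
    return row


def peritumoral_fl2_area(truth: pd.DataFrame) -> float:
    """Planted protective exposure: FL-2 area (mm^2) 1.0-4.5 mm outside the margin."""
    if truth.empty:
        return 0.0
    sel = (
        (truth["subtype"] == SUBTYPE_FL2)
        & (truth["achieved_distance_mm"] > 1.0)
        & (truth["achieved_distance_mm"] <= 4.5)
    )
    return float(truth.loc[sel, "achieved_area_mm2"].sum())


def make_outcome(eta: np.ndarray, cfg: SynthConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relapse labels and censored RFS times from the linear predictor eta.

    Relapse is a logistic draw on -eta (higher eta is protective), with the
    intercept set to the configured prevalence; relapse times follow an
    exponential model whose mean scales with exp(0.4 * eta); non-relapse cases
    are right-censored at their follow-up end (uniform 36-96 months, with a
    ``censor_rate`` fraction censored earlier).  The relapse label equals the
    observed event flag by construction.
    """
    eta = np.asarray(eta, dtype=np.float64)
    n = eta.size

    def mean_prob(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a - cfg.link_gain * eta)))))

    # intercept solved so the expected prevalence matches the configured one
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < cfg.relapse_prevalence:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    p_relapse = 1.0 / (1.0 + np.exp(-(alpha - cfg.link_gain * eta)))
    labels = (rng.random(n) < p_relapse).astype(int)
    times = np.empty(n)
    events = np.zeros(n, dtype=int)
    for i in range(n):
        if labels[i]:
            t = rng.exponential(30.0 * np.exp(0.4 * eta[i]))
            times[i] = float(np.clip(t, 2.0, 90.0))
            events[i] = 1
        else:
            if rng.random() < cfg.censor_rate:
                times[i] = rng.uniform(12.0, 36.0)
            else:
                times[i] = rng.uniform(36.0, 96.0)
    return labels, times, events


def make_patch_bag(eta: float, cfg: SynthConfig, rng: np.random.Generator,
                   case_id: str = "") -> PatchFeatureBag:
    """A MIL bag from a two-component Gaussian mixture keyed to case risk.

    The signal-component mixing weight increases monotonically with the risk
    latent (-eta), so attention has a recoverable target.
    """
    n = max(10, int(rng.poisson(cfg.bag_mean_patches)))
    risk = -eta
    w_signal = 0.1 + 0.6 / (1.0 + np.exp(-risk))
    direction = np.zeros(cfg.bag_dim)
    direction[0] = 1.0  # fixed signal axis
    is_signal = rng.random(n) < w_signal
    x = rng.normal(size=(n, cfg.bag_dim))
    x[is_signal] += cfg.bag_signal_delta * direction
    slide_index = rng.integers(0, cfg.slides_per_case, size=n)
    return PatchFeatureBag(case_id, x, slide_index)


def make_cohort(cfg: SynthConfig) -> SynthCohort:
    """Generate a full cohort: heatmaps, truth table, clinical rows, outcomes."""
    rng = np.random.default_rng(cfg.seed)
    cases: list[SynthCase] = []
    for i in range(cfg.n_cases):
        cid = f"case{i:04d}"
        hms, truths = [], []
        for s in range(cfg.slides_per_case):
            sid = f"{cid}_s{s}"
            hm, truth = make_heatmap(cfg, rng, slide_id=sid)
            hms.append(hm)
            truths.append(truth)
        nonempty = [t for t in truths if not t.empty]
        truth = (pd.concat(nonempty, ignore_index=True) if nonempty
                 else truths[0].iloc[:0].copy())
        truth.insert(0, "case_id", cid)
        cases.append(SynthCase(cid, hms, truth, _make_clinical(rng),
                               act_flag=int(rng.random() < 0.35)))

    fl2 = np.array([peritumoral_fl2_area(c.truth) for c in cases])
    tumor_area = np.array([
        sum(float((h.labels == TUMOR).sum()) * h.pixel_pitch_mm**2 for h in c.heatmaps)
        for c in cases
    ])

    def z(x):
        s = x.std()
        return (x - x.mean()) / (s if s > 1e-12 else 1.0)

    lns = np.array([c.clinical[CLINICAL_COLUMNS.index("lns_insufficient")]
                    for c in cases])
    eta = (cfg.effect_size * z(fl2) - cfg.beta_tumor * z(tumor_area)
           - cfg.beta_clinical * lns)
    labels, times, events = make_outcome(eta, cfg, rng)
    for c, e, y, t, ev in zip(cases, eta, labels, times, events):
        c.eta = float(e)
        c.relapse_label = int(y)
        c.rfs_time_months = float(t)
        c.event = int(ev)
    truth_all = pd.concat([c.truth for c in cases], ignore_index=True)
    return SynthCohort(cfg, cases, truth_all)
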