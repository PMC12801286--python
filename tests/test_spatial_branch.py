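"""Spatial feature construction: subtype vote, signed margin distance,
binning, and the 226-feature registry."""

import numpy as np
import pytest

from tlsview.heatmap_core import TLS, TUMOR, TissueHeatmap, find_components
from tlsview.spatial_branch import (
    AREA_BIN_EDGES_MM2,
    DISTANCE_BIN_EDGES_MM,
    N_FEATURES,
    TLSComponent,
    bin_area,
    bin_distance,
    build_spatial_features,
    case_features,
    extract_tls_components,
    registry_names,
    shipped_registry,
    signed_margin_distance,
    subtype_of,
)

from conftest import make_hm


def tls_comp(h, idx=0):
    return find_components(h, TLS)[idx]


class TestSubtypeVote:
    def test_unanimous(self):
        labels = np.zeros((5, 5), int)
        labels[1:3, 1:3] = TLS
        h = make_hm(labels, np.where(labels == TLS, 3, 0))
        assert subtype_of(tls_comp(h), h) == 3

    def test_majority_count_oracle(self):
        # 5 Agg + 4 FL-1 in one component -> Agg
        labels = np.zeros((3, 9), int)
        labels[1, :] = TLS
        sub = np.zeros((3, 9), int)
        sub[1, :5] = 1
        sub[1, 5:] = 2
        h = make_hm(labels, sub)
        counts = {s: (sub[labels == TLS] == s).sum() for s in (1, 2, 3)}
        assert max(counts, key=counts.get) == 1  # oracle: plain majority
        assert subtype_of(tls_comp(h), h) == 1

    def test_tie_goes_to_more_mature(self):
        labels = np.zeros((3, 6), int)
        labels[1, :] = TLS
        sub = np.zeros((3, 6), int)
        sub[1, :3] = 1   # Agg
        sub[1, 3:] = 3   # FL-2
        h = make_hm(labels, sub)
        assert subtype_of(tls_comp(h), h) == 3


def brute_force_signed_distance(h, centroid):
    """Oracle: scan every margin pixel of the filled tumor region."""
    from scipy.ndimage import binary_fill_holes

    region = binary_fill_holes(h.labels == TUMOR)
    best = np.inf
    H, W = region.shape
    for r in range(H):
        for c in range(W):
            if not region[r, c]:
                continue
            on_edge = r in (0, H - 1) or c in (0, W - 1)
            nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            if on_edge or any(not region[rr, cc] for rr, cc in nbrs
                              if 0 <= rr < H and 0 <= cc < W):
                best = min(best, np.hypot(r - centroid[0], c - centroid[1]))
    ir, ic = int(round(centroid[0])), int(round(centroid[1]))
    sign = -1.0 if region[ir, ic] else 1.0
    return sign * best * h.pixel_pitch_mm


class TestSignedMarginDistance:
    def _slab_heatmap(self, tls_row):
        labels = np.zeros((16, 16), int)
        labels[0:4, :] = TUMOR         # straight edge at row 3
        labels[tls_row, 7:9] = TLS
        labels[tls_row + 1, 7:9] = TLS
        return make_hm(labels)

    def test_three_pixels_outside_straight_edge(self):
        # TLS centroid 3 px above a straight tumor edge -> +3 * pitch
        labels = np.zeros((16, 16), int)
        labels[0:4, :] = TUMOR
        labels[6, 7] = TLS
        h = make_hm(labels)
        d = signed_margin_distance(tls_comp(h), h)
        assert d == pytest.approx(3 * 0.064)

    def test_centroid_on_boundary_is_zero(self):
        # TLS ring around a tumor spur: centroid coincides with a margin pixel
        labels = np.zeros((10, 10), int)
        labels[3, 4] = TUMOR
        labels[2, 4] = labels[4, 4] = labels[3, 3] = labels[3, 5] = TLS
        h = make_hm(labels)
        assert signed_margin_distance(tls_comp(h), h) == pytest.approx(0.0)
        assert bin_distance(0.0) == 0

    def test_two_pixels_inside_tumor(self):
        # TLS enclave 2 px below the margin of a filled tumor region
        labels = np.zeros((16, 16), int)
        labels[0:8, :] = TUMOR
        labels[5, 7] = TLS  # margin row is 7; depth 2 px
        h = make_hm(labels)
        d = signed_margin_distance(tls_comp(h), h)
        assert d == pytest.approx(-2 * 0.064)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        labels = np.zeros((20, 20), int)
        cr, cc = r.integers(5, 15, 2)
        labels[cr - 3:cr + 3, cc - 3:cc + 3] = TUMOR
        tr, tc = r.integers(1, 19, 2)
        if labels[tr, tc] == TUMOR:
            tr, tc = 0, 0
        labels[tr, tc] = TLS
        h = make_hm(labels)
        comp = tls_comp(h)
        expected = brute_force_signed_distance(h, comp.centroid)
        assert signed_margin_distance(comp, h) == pytest.approx(expected)

    def test_no_tumor_raises(self):
        labels = np.zeros((6, 6), int)
        labels[2, 2:4] = TLS
        h = make_hm(labels)
        with pytest.raises(ValueError):
            signed_margin_distance(tls_comp(h), h)


class TestBinning:
    @pytest.mark.parametrize("d,expected", [
        (-0.5, 0), (0.0, 0), (0.2, 1), (0.4, 1), (0.41, 2), (1.0, 2),
        (1.5, 3), (2.2, 3), (3.0, 4), (4.5, 4), (5.0, 5), (6.4, 5), (6.5, 6),
    ])
    def test_distance_bins_at_printed_edges(self, d, expected):
        assert bin_distance(d) == expected

    @pytest.mark.parametrize("a,expected", [
        (0.01, 0), (0.03, 0), (0.04, 1), (0.05, 1), (0.06, 2), (0.07, 2),
        (0.08, 3), (0.10, 3), (0.12, 4), (0.15, 4), (0.2, 5), (0.28, 5),
        (0.30, 6),
    ])
    def test_area_bins_at_printed_edges(self, a, expected):
        assert bin_area(a) == expected

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            bin_area(0.0)

    def test_bin_edges_cover_all_reals(self):
        for d in np.linspace(-3, 10, 400):
            assert 0 <= bin_distance(float(d)) <= 6
        assert len(DISTANCE_BIN_EDGES_MM) == 6
        assert len(AREA_BIN_EDGES_MM2) == 6


def two_slide_case(seed=0):
    r = np.random.default_rng(seed)
    hms = []
    for s in range(2):
        labels = np.zeros((40, 40), int)
        labels[14:26, 14:26] = TUMOR
        sub = np.zeros((40, 40), int)
        for _ in range(3):
            rr, cc = r.integers(2, 12, 2)
            labels[rr:rr + 2, cc:cc + 2] = TLS
            sub[rr:rr + 2, cc:cc + 2] = r.integers(1, 4)
        hms.append(TissueHeatmap(labels, np.where(labels == TLS, sub, 0),
                                 0.064, f"s{s}"))
    return hms


class TestBuildSpatialFeatures:
    def test_vector_length_is_226(self):
        hms = two_slide_case()
        fv = case_features(hms, "c0")
        assert fv.values.shape == (N_FEATURES,)
        assert len(registry_names()) == 226

    def test_empty_case_zero_tls_blocks_positive_tumor(self):
        labels = np.zeros((20, 20), int)
        labels[5:15, 5:15] = TUMOR
        h = make_hm(labels)
        fv = build_spatial_features([], [h], case_id="c")
        assert fv["tumor_area_total_mm2"] > 0
        tls_part = fv.values[:-2]
        assert (tls_part == 0).all()

    def test_single_fl2_component_hand_registry(self):
        # one FL-2 TLS, area 0.05 mm^2, distance 3.0 mm: exactly one count per
        # involved block, areas equal 0.05
        labels = np.zeros((10, 10), int)
        labels[0:3, :] = TUMOR
        h = make_hm(labels)
        comp = find_components(make_hm(
            np.pad(np.full((2, 2), TLS), ((6, 2), (6, 2)))), TLS)[0]
        tc = TLSComponent(component=comp, subtype=3,
                          signed_margin_distance_mm=3.0, slide_id="s")
        # override area via a fake component with known pixel count
        area = 0.05
        tc.component.pixel_coords = tc.component.pixel_coords[:1]
        tc.component.pixel_pitch_mm = np.sqrt(area)  # 1 px of area 0.05
        fv = build_spatial_features([tc], [h], case_id="c")
        d_bin, a_bin = 4, 1  # 3.0 mm -> (2.2,4.5]; 0.05 -> (0.03,0.05]
        assert fv[f"dist{d_bin}_FL2_count"] == 1
        assert fv[f"dist{d_bin}_FL2_area_total"] == pytest.approx(area)
        assert fv[f"dist{d_bin}_FL2_area_mean"] == pytest.approx(area)
        assert fv[f"area{a_bin}_FL2_count"] == 1
        assert fv[f"joint_d{d_bin}_a{a_bin}_count"] == 1
        assert fv[f"joint_d{d_bin}_a{a_bin}_area_total"] == pytest.approx(area)
        # all other counts zero
        counts = [n for n in fv.names if n.endswith("count")]
        assert sum(fv[n] for n in counts) == 3  # one per bin family

    @pytest.mark.parametrize("seed", range(3))
    def test_triple_bookkeeping_conservation(self, seed):
        hms = two_slide_case(seed)
        comps = [c for h in hms for c in extract_tls_components(h)]
        fv = build_spatial_features(comps, hms)
        n = len(comps)
        dist_counts = sum(fv[f"dist{b}_{s}_count"] for b in range(7)
                          for s in ("Agg", "FL1", "FL2"))
        area_counts = sum(fv[f"area{b}_{s}_count"] for b in range(7)
                          for s in ("Agg", "FL1", "FL2"))
        joint_counts = sum(fv[f"joint_d{d}_a{a}_count"] for d in range(7)
                           for a in range(7))
        assert dist_counts == area_counts == joint_counts == n
        total_area = sum(c.area_mm2 for c in comps)
        for fam in ("dist", "area"):
            got = sum(fv[f"{fam}{b}_{s}_area_total"] for b in range(7)
                      for s in ("Agg", "FL1", "FL2"))
            assert got == pytest.approx(total_area, abs=1e-9)

    def test_order_invariance(self):
        hms = two_slide_case(1)
        comps = [c for h in hms for c in extract_tls_components(h)]
        fv1 = build_spatial_features(comps, hms)
        fv2 = build_spatial_features(comps[::-1], hms[::-1])
        assert np.allclose(fv1.values, fv2.values)

    def test_translation_invariance(self):
        labels = np.zeros((30, 30), int)
        labels[2:10, 2:10] = TUMOR
        labels[16:18, 16:19] = TLS
        h1 = make_hm(labels)
        h2 = make_hm(np.roll(np.roll(labels, 3, 0), 4, 1))
        fv1 = case_features([h1])
        fv2 = case_features([h2])
        assert np.allclose(fv1.values, fv2.values)

    def test_shipped_registry_matches_code(self):
        reg = shipped_registry()
        assert reg["names"] == registry_names()
        assert reg["n_features"] == N_FEATURES
        assert tuple(reg["distance_bin_right_edges_mm"]) == DISTANCE_BIN_EDGES_MM
        assert tuple(reg["area_bin_right_edges_mm2"]) == AREA_BIN_EDGES_MM2
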