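"""ideaCTV, the six ratio families, the 110-feature schema, Dice/Hausdorff."""

import numpy as np
import pytest

from ctvrecur.features import (
    FEATURE_NAMES,
    N_FEATURES,
    OVERLAP_FLAG_STATIONS,
    dice,
    extract_features,
    feature_table,
    hausdorff_mm,
    idea_ctv,
    ratio_families,
    scalar_features,
)
from ctvrecur.mask_model import StructureSetError, VoxelGrid
from ctvrecur.phantoms import AtlasSpec, generate_cohort

from conftest import GRID48, blank_box, build_box_ss, station_box


# ---------------------------------------------------------------------------
# Independent oracle: per-voxel recount with plain python loops
# ---------------------------------------------------------------------------


def brute_force_ratios(ss, gross="union"):
    """Naive voxel recount of all six ratio families.

    Deliberately scans every voxel in python, classifying it into at most
    one station (stations are disjoint), and applies the ratio formulas to
    the tallied integers — no shared code with the vectorized path.
    """
    n = int(np.prod(ss.grid.shape))
    ln_flat = [None] + [ss.ln[i].ravel().tolist() for i in range(1, 17)]
    ctv = ss.ctv.ravel().tolist()
    g_arr = (ss.gtv | ss.gtvnd) if gross == "union" else ss.gtv
    g = g_arr.ravel().tolist()
    n_ln = [0] * 17
    n_ctv = [0] * 17
    n_g = [0] * 17
    n_cmg = [0] * 17
    for v in range(n):
        for i in range(1, 17):
            if ln_flat[i][v]:
                n_ln[i] += 1
                if ctv[v]:
                    n_ctv[i] += 1
                    if not g[v]:
                        n_cmg[i] += 1
                if g[v]:
                    n_g[i] += 1
                break
    n_idea = sum(n_ln[i] for i in range(1, 17) if n_ctv[i] > 0)
    out = {}
    for i in range(1, 17):
        out[f"RctvLN{i}"] = n_ctv[i] / n_ln[i]
        out[f"RIctvLN{i}"] = n_ctv[i] / n_idea if n_idea else 0.0
        out[f"RgtvLN{i}"] = n_g[i] / n_ln[i]
        out[f"RIgtvLN{i}"] = n_g[i] / n_idea if n_idea else 0.0
        out[f"RcmgLN{i}"] = n_cmg[i] / n_ln[i]
        out[f"RIcmgLN{i}"] = n_cmg[i] / n_idea if n_idea else 0.0
    return out


class TestIdeaCtv:
    def test_union_of_violated_stations(self):
        ctv = blank_box()
        ctv[station_box(11)] = True            # all of LN11 (station 7)
        x = station_box(13)[0].start
        ctv[x, 2 + 5 * 3, 2] = True            # one voxel of LN13 (10R)
        ss = build_box_ss(ctv=ctv)
        idea = idea_ctv(ss)
        expect = ss.ln[11] | ss.ln[13]
        assert np.array_equal(idea, expect)

    def test_single_voxel_contact_pulls_whole_station(self):
        ctv = blank_box()
        b = station_box(7)  # LN7 = station 4R
        ctv[b[0].start, b[1].start, b[2].start] = True
        ss = build_box_ss(ctv=ctv)
        assert np.array_equal(idea_ctv(ss), ss.ln[7])

    def test_no_contact_is_empty(self):
        ctv = blank_box()
        ctv[20:22, 20:22, 20:22] = True  # away from every station cube
        ss = build_box_ss(ctv=ctv)
        assert not idea_ctv(ss).any()

    def test_idempotent_under_union_with_ideactv(self):
        ctv = blank_box()
        b = station_box(5)
        ctv[b[0].start, b[1].start, b[2].start] = True
        ss = build_box_ss(ctv=ctv)
        idea1 = idea_ctv(ss)
        ss.ctv = ss.ctv | idea1
        assert np.array_equal(idea_ctv(ss), idea1)


class TestRatioFamilies:
    def test_half_coverage(self):
        ctv = blank_box()
        b = station_box(11)  # LN11 = station 7, 8 voxels
        ctv[b[0].start, b[1], b[2]] = True  # 4 of 8 voxels
        ss = build_box_ss(ctv=ctv)
        r = ratio_families(ss)
        assert r["RctvLN11"] == 0.5
        assert r["RgtvLN11"] == 0.0
        assert r["RcmgLN11"] == 0.5

    def test_ctv_equals_one_station(self):
        ctv = blank_box()
        ctv[station_box(13)] = True
        ss = build_box_ss(ctv=ctv)
        r = ratio_families(ss)
        assert r["RIctvLN13"] == 1.0
        assert all(r[f"RIctvLN{j}"] == 0.0 for j in range(1, 17) if j != 13)

    def test_empty_ideactv_defines_ri_as_zero(self):
        ctv = blank_box()
        ctv[20:22, 20:22, 20:22] = True
        ss = build_box_ss(ctv=ctv)
        r = ratio_families(ss)
        assert all(r[f"RIctvLN{j}"] == 0.0 for j in range(1, 17))

    def test_matches_brute_force_recount(self, atlas48):
        cohort = generate_cohort(3, atlas_spec=AtlasSpec.default(GRID48), seed=21)
        for ss, _rec in cohort:
            fast = ratio_families(ss)
            slow = brute_force_ratios(ss)
            for k, v in slow.items():
                assert fast[k] == v, k

    def test_family_inequalities(self, cohort64):
        for ss, _rec in list(cohort64)[:10]:
            r = ratio_families(ss)
            for i in range(1, 17):
                assert r[f"RgtvLN{i}"] <= r[f"RctvLN{i}"] + 1e-15
                # G ⊆ CTV in phantoms, so the elective ratio is the difference
                assert r[f"RcmgLN{i}"] == pytest.approx(
                    r[f"RctvLN{i}"] - r[f"RgtvLN{i}"], abs=1e-12
                )
            s = sum(r[f"RIctvLN{i}"] for i in range(1, 17))
            assert s <= 1.0 + 1e-12


class TestScalarFeatures:
    def test_counts_and_flags(self):
        ctv = blank_box()
        for i in (7, 11, 13):   # stations 4R, 7, 10R
            ctv[station_box(i)] = True
        ss = build_box_ss(ctv=ctv)
        s = scalar_features(ss, ss.patient)
        assert s["n_ln_ctv"] == 3
        assert s["overlap_4R"] == 1 and s["overlap_7"] == 1
        assert s["overlap_4L"] == 0
        assert s["gtvnd_volume"] == 0 and s["n_ln_gtvnd"] == 0

    def test_image_resolution_is_inplane_spacing(self):
        ss = build_box_ss()
        ss.grid = VoxelGrid(ss.grid.shape, (1.1543, 1.1543, 5.0))
        assert scalar_features(ss, ss.patient)["image_resolution"] == 1.1543


class TestExtractFeatures:
    def test_schema(self, cohort64):
        ss, rec = cohort64.patients[0]
        fv = extract_features(ss, rec)
        assert fv.names == FEATURE_NAMES and len(fv.values) == N_FEATURES
        assert fv.names[0] == "RctvLN1" and fv.names[96] == "ctv_volume"
        assert fv.names[109] == "gtv_size"

    def test_cohort_table(self, cohort64):
        tab = feature_table(list(cohort64)[:20])
        assert tab.shape == (20, N_FEATURES + 1)
        ratios = tab[list(FEATURE_NAMES[:96])]
        assert ((ratios >= 0) & (ratios <= 1)).all().all()
        flags = tab[[f"overlap_{s}" for s in OVERLAP_FLAG_STATIONS]]
        assert flags.isin([0.0, 1.0]).all().all()


class TestMaskMetrics:
    def test_dice_basic(self):
        a = blank_box(); a[2:6, 2:6, 2:6] = True
        assert dice(a, a) == 1.0
        b = blank_box(); b[10:14, 10:14, 10:14] = True
        assert dice(a, b) == 0.0
        assert dice(blank_box(), blank_box()) == 1.0

    def test_dice_half_overlap(self):
        a = np.zeros((10, 10, 10), bool); a.ravel()[:100] = True
        b = np.zeros((10, 10, 10), bool); b.ravel()[50:150] = True
        assert dice(a, b) == 0.5
        assert dice(b, a) == dice(a, b)

    def test_hausdorff_axis_separation(self):
        g = VoxelGrid((24, 24, 24), (1.5, 1.5, 1.5))
        a = np.zeros(g.shape, bool); a[5, 5, 5] = True
        b = np.zeros(g.shape, bool); b[15, 5, 5] = True
        assert hausdorff_mm(a, b, g) == pytest.approx(15.0)
        assert hausdorff_mm(a, a, g) == 0.0

    def test_hausdorff_empty_mask_raises(self):
        g = VoxelGrid((8, 8, 8))
        a = np.zeros(g.shape, bool); a[1, 1, 1] = True
        with pytest.raises(StructureSetError):
            hausdorff_mm(a, np.zeros(g.shape, bool), g)

    def test_hausdorff_matches_all_pairs_oracle(self):
        g = VoxelGrid((12, 12, 12), (1.0, 1.2, 0.8))
        rng = np.random.default_rng(4)
        a = np.zeros(g.shape, bool); a[2:6, 2:7, 3:6] = True
        b = np.zeros(g.shape, bool); b[5:10, 4:9, 2:8] = True

        def boundary(mask):
            pts = []
            for x in range(g.shape[0]):
                for y in range(g.shape[1]):
                    for z in range(g.shape[2]):
                        if not mask[x, y, z]:
                            continue
                        on_edge = False
                        for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                            nx, ny, nz = x+dx, y+dy, z+dz
                            if not (0 <= nx < g.shape[0] and 0 <= ny < g.shape[1]
                                    and 0 <= nz < g.shape[2]) or not mask[nx, ny, nz]:
                                on_edge = True
                                break
                        if on_edge:
                            pts.append((x * 1.0, y * 1.2, z * 0.8))
            return pts

        pa, pb = boundary(a), boundary(b)

        def directed(p, q):
            return max(
                min(sum((u - v) ** 2 for u, v in zip(x, yy)) ** 0.5 for yy in q)
                for x in p
            )

        expect = max(directed(pa, pb), directed(pb, pa))
        assert hausdorff_mm(a, b, g) == pytest.approx(expect, abs=1e-9)
        assert hausdorff_mm(b, a, g) == hausdorff_mm(a, b, g)
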