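"""Spot-pair quality cascade: isolation, contour, density, Gaussian fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from f2f import (OpticalConfig, contour_filter, density_filter,
                 gaussian_fit_filter, isolation_filter, segment_cells)
from f2f.errors import InputError
from f2f.select import _fit_gaussian_window
from f2f.simulate import render_spots


def make_pairs(anchors, preys, fov=0):
    anchors, preys = np.atleast_2d(anchors), np.atleast_2d(preys)
    n = len(anchors)
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "pair_id": np.arange(n), "fov": fov,
        "anchor_row_px": anchors[:, 0], "anchor_col_px": anchors[:, 1],
        "anchor_mass": 1000.0, "anchor_m2_px2": rng.normal(10, 1, n),
        "anchor_ecc": rng.normal(0.1, 0.02, n),
        "prey_row_px": preys[:, 0], "prey_col_px": preys[:, 1],
        "prey_mass": 800.0, "prey_m2_px2": rng.normal(10, 1, n),
        "prey_ecc": rng.normal(0.1, 0.02, n),
        "sep_px": np.linalg.norm(anchors - preys, axis=1),
        "distance_nm": np.linalg.norm(anchors - preys, axis=1) * 64.5,
    })


def spots_of_pairs(pairs, extra=None):
    rows = []
    for r in pairs.itertuples():
        rows.append((r.fov, 1, r.anchor_row_px, r.anchor_col_px, 1000.0))
        rows.append((r.fov, 2, r.prey_row_px, r.prey_col_px, 800.0))
    if extra is not None:
        for p in np.atleast_2d(extra):
            rows.append((pairs.fov.iat[0], 2, p[0], p[1], 500.0))
    return pd.DataFrame(rows, columns=["fov", "channel", "row_px", "col_px",
                                       "mass"])


class TestIsolationFilter:
    def test_well_separated_pairs_pass(self):
        pairs = make_pairs([[20, 20], [70, 70]], [[20, 21], [70, 71]])
        out = isolation_filter(pairs, spots_of_pairs(pairs), 10)
        assert out.pass_isolation.all()

    def test_stray_spot_near_anchor_fails_pair(self):
        pairs = make_pairs([[20, 20], [70, 70]], [[20, 21], [70, 71]])
        spots = spots_of_pairs(pairs, extra=[[25, 20]])   # 5 px from anchor 0
        out = isolation_filter(pairs, spots, 10)
        assert not out.pass_isolation[0]
        assert out.pass_isolation[1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_brute_force_oracle(self, seed):
        """Exact agreement with an all-vs-all distance check on random
        instances with planted near-neighbours."""
        rng = np.random.default_rng(seed)
        n = 40
        anchors = rng.uniform(0, 400, (n, 2))
        preys = anchors + rng.normal(0, 1, (n, 2))
        pairs = make_pairs(anchors, preys)
        extra = rng.uniform(0, 400, (60, 2))
        spots = spots_of_pairs(pairs, extra=extra)
        out = isolation_filter(pairs, spots, 10)

        allpts = spots[["row_px", "col_px"]].to_numpy()
        expected = []
        for i in range(n):
            own = np.array([anchors[i], preys[i]])
            ok = True
            for q in allpts:
                if np.linalg.norm(q - own, axis=1).min() < 1e-9:
                    continue
                if np.linalg.norm(q - own, axis=1).min() <= 10:
                    ok = False
                    break
            expected.append(ok)
        assert out.pass_isolation.tolist() == expected


class TestSegmentCells:
    def test_threshold_backend_recovers_disks(self, cell_scene):
        """Five-plus disk cells segmented with IoU >= 0.9 each against the
        generator's truth mask."""
        img, _, mask = cell_scene
        seg = segment_cells(img[1], "threshold")
        assert seg.max() == mask.max()
        for lbl in range(1, mask.max() + 1):
            t = mask == lbl
            best = 0.0
            for c in np.unique(seg[t]):
                if c:
                    s = seg == c
                    best = max(best, (t & s).sum() / (t | s).sum())
            assert best >= 0.9

    def test_external_mask_passthrough(self):
        m = np.zeros((64, 64), dtype=np.uint16)
        m[10:20, 10:20] = 3
        out = segment_cells(np.zeros((64, 64)), "external_mask",
                            external_mask=m)
        assert np.array_equal(out, m)

    def test_external_mask_shape_mismatch(self):
        with pytest.raises(InputError):
            segment_cells(np.zeros((64, 64)), "external_mask",
                          external_mask=np.zeros((32, 32)))

    def test_blank_image_all_zero(self):
        assert segment_cells(np.zeros((64, 64)), "threshold").max() == 0


class TestContourFilter:
    @staticmethod
    def disk_mask(shape=(128, 128), center=(64, 64), radius=40):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return ((np.hypot(yy - center[0], xx - center[1]) <= radius)
                .astype(np.uint16))

    def test_spots_on_boundary_pass_any_threshold(self):
        mask = self.disk_mask()
        # both members sit exactly on boundary pixels of the disk
        pairs = make_pairs([[64, 104]], [[63, 103]])
        out = contour_filter(pairs, mask, 0.0)
        assert out.pass_contour[0]

    def test_spot_at_disk_centre_fails(self):
        mask = self.disk_mask()
        pairs = make_pairs([[64, 64]], [[64, 65]])
        out = contour_filter(pairs, mask, 13)
        assert not out.pass_contour[0]

    def test_empty_mask_fails_all_with_warning(self):
        pairs = make_pairs([[10, 10]], [[10, 11]])
        with pytest.warns(UserWarning):
            out = contour_filter(pairs, np.zeros((64, 64), np.uint16), 13)
        assert not out.pass_contour.any()

    def test_rim_placed_truth_pairs_pass(self, cell_scene):
        _, truth, mask = cell_scene
        e = truth.emitters
        a = e.query("channel == 1").sort_values("pair_id")
        p = e.query("channel == 2").sort_values("pair_id")
        pairs = make_pairs(a[["row_px", "col_px"]].to_numpy(),
                           p[["row_px", "col_px"]].to_numpy())
        out = contour_filter(pairs, mask, 13)
        assert out.pass_contour.all()


class TestDensityFilter:
    @staticmethod
    def gaussian_pairs(n, seed=0):
        rng = np.random.default_rng(seed)
        anchors = rng.uniform(0, 4000, (n, 2))
        pairs = make_pairs(anchors, anchors + 1.0)
        for pre in ("anchor", "prey"):
            pairs[f"{pre}_m2_px2"] = rng.normal(10, 1.5, n)
            pairs[f"{pre}_ecc"] = np.abs(rng.normal(0.15, 0.05, n))
        return pairs

    def test_cutoff_half_retains_half(self):
        out = density_filter(self.gaussian_pairs(1000), 0.5)
        assert out.pass_density.sum() == 500

    def test_cutoff_limits(self):
        pairs = self.gaussian_pairs(200)
        assert density_filter(pairs, 0.995).pass_density.sum() <= 2
        assert density_filter(pairs, 0.005).pass_density.sum() >= 198

    def test_planted_outlier_cluster_rejected(self):
        """A 5% cluster far from the bulk in feature space has the lowest
        density ranks and is entirely rejected at cutoff 0.5."""
        pairs = self.gaussian_pairs(400, seed=1)
        idx = np.arange(380, 400)
        for pre in ("anchor", "prey"):
            pairs.loc[idx, f"{pre}_m2_px2"] = 40.0 + np.arange(20) * 0.1
            pairs.loc[idx, f"{pre}_ecc"] = 0.9
        out = density_filter(pairs, 0.5)
        assert not out.loc[idx, "pass_density"].any()

    def test_small_sample_skipped_with_warning(self):
        pairs = self.gaussian_pairs(10)
        with pytest.warns(UserWarning):
            out = density_filter(pairs, 0.5, min_pairs=20)
        assert out.pass_density.all()
        assert out.attrs.get("density_filter_skipped")


class TestGaussianFitFilter:
    def test_clean_spot_near_perfect_r2(self):
        win = render_spots((11, 11), [[5.2, 4.8]], 5000, 2.336)
        assert _fit_gaussian_window(win) > 0.999

    def test_pure_noise_window_fails(self):
        """R-squared of a Gaussian fit to pure noise is near zero and fails
        the 0.35 threshold in every seeded replicate."""
        rng = np.random.default_rng(0)
        r2 = [_fit_gaussian_window(rng.normal(0, 1, (11, 11)).clip(0))
              for _ in range(20)]
        assert max(r2) < 0.35
        assert np.median(r2) < 0.1

    def test_double_lobe_artifact_rejected(self):
        win = (render_spots((11, 11), [[2, 5]], 3000, 1.5)
               + render_spots((11, 11), [[8, 5]], 3000, 1.5))
        assert _fit_gaussian_window(win) < 0.35

    def test_pair_filter_updates_r2_and_status(self):
        img = np.zeros((2, 64, 64))
        img[0] = render_spots((64, 64), [[20.0, 20.0]], 5000, 2.336)
        img[1] = (render_spots((64, 64), [[20.0, 21.0]], 5000, 2.336)
                  + render_spots((64, 64), [[40.0, 37.0]], 3000, 1.5)
                  + render_spots((64, 64), [[40.0, 43.0]], 3000, 1.5))
        pairs = make_pairs([[20, 20], [40, 40]], [[20, 21], [40, 40]])
        out = gaussian_fit_filter(pairs, {0: img}, 0.35, 11)
        assert out.pass_gauss[0]
        assert not out.pass_gauss[1]         # prey is a double lobe
        assert out.anchor_r2[0] > 0.99


class TestCascadeMonotonicity:
    def test_each_stage_returns_subset(self, cell_scene, optical):
        """Every selection stage passes a subset of the previous one, in
        the fixed order isolation -> contour -> density -> gauss."""
        from f2f import (detect_spots, link_pairs, preprocess_image,
                         run_selection)
        from f2f.config import SelectionConfig

        img, _, mask = cell_scene
        pre = np.stack([preprocess_image(img[c]) for c in range(2)])
        ch = {c: detect_spots(pre[c - 1], 11, 1000, 99.0, channel=c,
                              psf_sigma_px=optical.sigma_px)
              for c in (1, 2)}
        spots = pd.concat([ch[1], ch[2]], ignore_index=True)
        pairs = link_pairs(ch[1], ch[2], 2.0, pixel_size_nm=64.5)
        pairs["pair_id"] = np.arange(len(pairs))
        out = run_selection(pairs, spots, {0: mask}, {0: pre},
                            SelectionConfig(density_min_pairs=5))
        stages = ["pass_isolation", "pass_contour", "pass_density",
                  "pass_gauss"]
        counts = [out[s].fillna(False).sum() for s in stages]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > 0
        # failing a stage forces False downstream
        for k, s in enumerate(stages[:-1]):
            failed = ~out[s].fillna(False).astype(bool)
            assert not out.loc[failed, stages[k + 1]].fillna(False).any()
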