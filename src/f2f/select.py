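"""Spot-pair quality cascade: isolation → cell contour → feature density →
2D-Gaussian goodness of fit.

The cascade order is fixed.  Each filter updates its own boolean status
column and only evaluates pairs that passed every earlier stage, so each
stage returns a subset of the previous one.  Pairs that failed an earlier
stage carry ``False`` in all later columns.

The feature-density filter keeps the pairs most probable to be found in
(second momentum, eccentricity) space: a kernel density estimate is built
per channel on standardized features, each pair is scored by the lower of
its two channels' density percentile ranks, and a pair passes when its
score-rank probability is at least the cutoff — retention ≈ 1 − cutoff, so
the default cutoff of 0.5 keeps exactly the denser half of the population,
a cutoff near 1 keeps only the very densest pairs, and a cutoff near 0
keeps everything.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import lmfit
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde
from skimage import filters, measure, morphology, segmentation

from .config import SelectionConfig
from .errors import InputError, ParameterError

__all__ = ["isolation_filter", "segment_cells", "contour_filter",
           "density_filter", "gaussian_fit_filter", "run_selection"]

log = logging.getLogger(__name__)

_STAGES = ["pass_isolation", "pass_contour", "pass_density", "pass_gauss"]


def _eligible(pairs: pd.DataFrame, stage: str) -> np.ndarray:
    """Pairs that passed every stage before ``stage``."""
    ok = np.ones(len(pairs), dtype=bool)
    for col in _STAGES[:_STAGES.index(stage)]:
        if col in pairs:
            ok &= pairs[col].fillna(False).to_numpy(dtype=bool)
    return ok


def _member_coords(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(anchor, prey) coordinates in the raw (pre-correction) frame."""
    a_cols = (["anchor_row_raw_px", "anchor_col_raw_px"]
              if "anchor_row_raw_px" in pairs
              else ["anchor_row_px", "anchor_col_px"])
    return (pairs[a_cols].to_numpy(dtype=float),
            pairs[["prey_row_px", "prey_col_px"]].to_numpy(dtype=float))


def isolation_filter(pairs: pd.DataFrame, all_spots: pd.DataFrame,
                     max_closest_neighbour_px: float = 10.0) -> pd.DataFrame:
    """Reject pairs with any third spot too close to either member.

    A pair fails if any other detected spot of its field — either channel,
    excluding the pair's own two members — lies within
    ``max_closest_neighbour_px`` of the anchor or the prey centroid.
    Distances are evaluated in the raw (pre-correction) coordinate frame in
    which the spots were detected.
    """
    pairs = pairs.copy()
    status = np.zeros(len(pairs), dtype=bool)
    eligible = _eligible(pairs, "pass_isolation")
    anchors, preys = _member_coords(pairs)
    for fov, spot_grp in all_spots.groupby("fov"):
        sel = (pairs["fov"] == fov).to_numpy() & eligible
        if not sel.any():
            continue
        pts = spot_grp[["row_px", "col_px"]].to_numpy(dtype=float)
        tree = cKDTree(pts)
        for i in np.flatnonzero(sel):
            own = np.vstack([anchors[i], preys[i]])
            bad = False
            for member in own:
                idx = tree.query_ball_point(member, max_closest_neighbour_px)
                for j in idx:
                    if np.min(np.linalg.norm(pts[j] - own, axis=1)) > 1e-6:
                        bad = True
                        break
                if bad:
                    break
            status[i] = not bad
    pairs["pass_isolation"] = status
    return pairs


def segment_cells(image: np.ndarray, backend: str = "threshold",
                  external_mask: np.ndarray | None = None,
                  min_cell_area_px: int = 200) -> np.ndarray:
    """Produce an integer cell label mask (0 = background).

    The segmentation backend is pluggable.  ``external_mask`` accepts any
    label image of matching shape (e.g. produced by a CNN segmentation
    tool); the bundled ``threshold`` backend smooths the raw image,
    thresholds it (Otsu refined to the half-height between the inside and
    outside medians, which places the boundary at the mid-point of the
    blurred cell edge), fills holes, shrinks the mask by one pixel to
    compensate the outward pull of the bright membrane rim, and labels
    connected components.  It is a fallback for well-separated round
    cells; crowded or irregular cells warrant an external mask.
    """
    image = np.asarray(image)
    if backend == "external_mask":
        if external_mask is None:
            raise InputError("external_mask backend requires a mask array")
        mask = np.asarray(external_mask)
        if mask.shape != image.shape:
            raise InputError(
                f"mask shape {mask.shape} != image shape {image.shape}")
        return mask.astype(np.uint16)
    if backend != "threshold":
        raise ParameterError("backend must be 'threshold' or 'external_mask'")
    smooth = filters.gaussian(image.astype(float), sigma=1.0,
                              preserve_range=True)
    if smooth.max() <= smooth.min():
        return np.zeros(image.shape, dtype=np.uint16)
    t0 = filters.threshold_otsu(smooth)
    inside = smooth > t0
    if inside.all() or not inside.any():
        return np.zeros(image.shape, dtype=np.uint16)
    thr = 0.5 * (np.median(smooth[inside]) + np.median(smooth[~inside]))
    binary = ndimage.binary_fill_holes(smooth > thr)
    binary = ndimage.binary_erosion(binary, morphology.disk(1))
    binary = morphology.remove_small_objects(binary,
                                             max_size=min_cell_area_px - 1)
    if not binary.any():
        return np.zeros(image.shape, dtype=np.uint16)
    return measure.label(binary).astype(np.uint16)


def contour_distance_map(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (px) of every pixel to the nearest cell-contour
    pixel; infinite when the mask is empty."""
    if mask.max() == 0:
        return np.full(mask.shape, np.inf)
    boundary = segmentation.find_boundaries(mask, mode="inner")
    return ndimage.distance_transform_edt(~boundary)


def contour_filter(pairs: pd.DataFrame,
                   masks: Mapping[object, np.ndarray] | np.ndarray,
                   max_contour_dist_px: float = 13.0) -> pd.DataFrame:
    """Keep pairs whose two members both sit near a cell contour.

    ``masks`` maps FOV id to label mask (a bare array is accepted for a
    single-FOV table).  A pair passes iff both centroids are within
    ``max_contour_dist_px`` of some contour pixel; spots slightly outside
    the cell still pass (the anchor sits on the membrane).  An all-zero
    mask fails every pair of that FOV with a warning.
    """
    pairs = pairs.copy()
    status = np.zeros(len(pairs), dtype=bool)
    eligible = _eligible(pairs, "pass_contour")
    anchors, preys = _member_coords(pairs)
    if not isinstance(masks, Mapping):
        masks = {fov: masks for fov in pairs["fov"].unique()}
    for fov, mask in masks.items():
        sel = (pairs["fov"] == fov).to_numpy() & eligible
        if not sel.any():
            continue
        if np.max(mask) == 0:
            warnings.warn(f"FOV {fov}: empty segmentation mask, "
                          "all pairs fail the contour filter")
            continue
        dist = contour_distance_map(mask)
        H, W = dist.shape
        for i in np.flatnonzero(sel):
            ok = True
            for member in (anchors[i], preys[i]):
                r = int(np.clip(round(member[0]), 0, H - 1))
                c = int(np.clip(round(member[1]), 0, W - 1))
                if dist[r, c] > max_contour_dist_px:
                    ok = False
                    break
            status[i] = ok
    pairs["pass_contour"] = status
    return pairs


def density_filter(pairs: pd.DataFrame, density_cutoff: float = 0.5,
                   min_pairs: int = 20) -> pd.DataFrame:
    """Retain pairs whose probability of being found is >= the cutoff.

    Features are (second momentum, eccentricity) per channel, standardized;
    densities come from a Gaussian KDE with Scott's-rule bandwidth, one per
    channel; a pair's score is the lower of its two channels' density
    percentile ranks, and pairs are kept from the top of the score ranking
    down, retaining the fraction ``1 - density_cutoff`` (cutoff 0.5: the
    denser half).  With fewer than ``min_pairs`` eligible pairs the filter
    is skipped (pass-by-default) and flagged in ``attrs``.
    """
    if not 0 < density_cutoff < 1:
        raise ParameterError("density_cutoff must be in (0, 1)")
    pairs = pairs.copy()
    eligible = _eligible(pairs, "pass_density")
    idx = np.flatnonzero(eligible)
    n = len(idx)
    status = np.zeros(len(pairs), dtype=bool)
    if n < min_pairs:
        warnings.warn(f"density filter skipped: {n} < {min_pairs} pairs")
        status[idx] = True
        pairs["pass_density"] = status
        pairs.attrs["density_filter_skipped"] = True
        return pairs

    ranks = []
    for prefix in ("anchor", "prey"):
        feats = pairs.loc[eligible, [f"{prefix}_m2_px2", f"{prefix}_ecc"]]
        X = feats.to_numpy(dtype=float).T
        std = X.std(axis=1, ddof=1)
        std[std == 0] = 1.0
        Z = (X - X.mean(axis=1, keepdims=True)) / std[:, None]
        try:
            dens = gaussian_kde(Z)(Z)
        except np.linalg.LinAlgError:   # degenerate feature cloud
            dens = np.ones(n)
        order = np.argsort(dens, kind="stable")
        rank = np.empty(n)
        rank[order] = (np.arange(n) + 1) / n
        ranks.append(rank)
    score = np.minimum(ranks[0], ranks[1])

    n_keep = n - int(round(density_cutoff * n))
    # highest score first; ties resolved by table order for determinism
    keep_local = np.argsort(-score, kind="stable")[:n_keep]
    status[idx[keep_local]] = True
    pairs["pass_density"] = status
    pairs["density_score"] = np.nan
    pairs.loc[pairs.index[idx], "density_score"] = score
    return pairs


def _fit_gaussian_window(window: np.ndarray) -> float:
    """R² of an isotropic 2D Gaussian + offset fit over one spot window."""
    win = np.asarray(window, dtype=float)
    h, w = win.shape
    rr, cc = np.mgrid[0:h, 0:w]

    def model(x, amp, r0, c0, sigma, offset):
        r, c = x
        return amp * np.exp(-((r - r0) ** 2 + (c - c0) ** 2)
                            / (2 * sigma ** 2)) + offset

    gmod = lmfit.Model(model, independent_vars=["x"])
    params = gmod.make_params(
        amp=dict(value=max(win.max() - win.min(), 1e-6), min=0),
        r0=dict(value=(h - 1) / 2, min=-1, max=h),
        c0=dict(value=(w - 1) / 2, min=-1, max=w),
        sigma=dict(value=max(min(h, w) / 5.0, 1.0), min=0.5, max=max(h, w)),
        offset=dict(value=float(np.percentile(win, 10))),
    )
    data = win.ravel()
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot <= 0:
        return -np.inf
    try:
        res = gmod.fit(data, params, x=(rr.ravel(), cc.ravel()))
    except Exception:
        return -np.inf
    if not res.success:
        return -np.inf
    return 1.0 - float(np.sum(res.residual ** 2)) / ss_tot


def gaussian_fit_filter(pairs: pd.DataFrame,
                        images: Mapping[object, np.ndarray],
                        r2_threshold: float = 0.35,
                        diameter_px: int = 11) -> pd.DataFrame:
    """Reject pairs whose members do not fit a 2D Gaussian profile.

    For each member spot an isotropic 2D Gaussian with constant offset is
    fitted by nonlinear least squares over the detection window of the
    preprocessed image, and R² = 1 − SS_res/SS_tot is recorded
    (``anchor_r2`` / ``prey_r2``).  A pair passes iff both R² values reach
    ``r2_threshold``; a non-converged fit scores −inf and fails.
    ``images`` maps FOV id to the (2, H, W) preprocessed frame.
    """
    pairs = pairs.copy()
    radius = diameter_px // 2
    status = np.zeros(len(pairs), dtype=bool)
    r2a = np.full(len(pairs), np.nan)
    r2p = np.full(len(pairs), np.nan)
    eligible = _eligible(pairs, "pass_gauss")
    anchors, preys = _member_coords(pairs)
    for i in np.flatnonzero(eligible):
        stack = images[pairs["fov"].iat[i]]
        r2 = []
        for chan, member in ((0, anchors[i]), (1, preys[i])):
            img = stack[chan]
            H, W = img.shape
            r0 = int(np.clip(round(member[0]), radius, H - radius - 1))
            c0 = int(np.clip(round(member[1]), radius, W - radius - 1))
            win = img[r0 - radius:r0 + radius + 1, c0 - radius:c0 + radius + 1]
            r2.append(_fit_gaussian_window(win))
        r2a[i], r2p[i] = r2
        status[i] = min(r2) >= r2_threshold
        if not np.isfinite(min(r2)):
            log.warning("pair %s: non-converged Gaussian fit",
                        pairs["pair_id"].iat[i])
    pairs["anchor_r2"] = r2a
    pairs["prey_r2"] = r2p
    pairs["pass_gauss"] = status
    return pairs


def run_selection(pairs: pd.DataFrame, all_spots: pd.DataFrame,
                  masks: Mapping[object, np.ndarray],
                  pre_images: Mapping[object, np.ndarray],
                  cfg: SelectionConfig | None = None,
                  diameter_px: int = 11) -> pd.DataFrame:
    """Apply the full cascade in its fixed order and return the pair table."""
    cfg = cfg or SelectionConfig()
    pairs = isolation_filter(pairs, all_spots, cfg.max_closest_neighbour_px)
    pairs = contour_filter(pairs, masks, cfg.max_contour_dist_px)
    pairs = density_filter(pairs, cfg.density_cutoff, cfg.density_min_pairs)
    pairs = gaussian_fit_filter(pairs, pre_images, cfg.r2_threshold,
                                diameter_px=diameter_px)
    return pairs
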