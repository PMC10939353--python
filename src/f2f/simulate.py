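"""Synthetic bead-calibration and two-colour cell scenes with ground truth.

Every downstream stage of the pipeline is testable against scenes generated
here: bead fields carrying a known inter-channel affine distortion, and
yeast-like cell fields with membrane-anchored anchor/prey spot pairs at a
known true separation.

Conventions
-----------
Coordinates are (row, col), 0-based, with pixel centres at integer
coordinates; all physical distances convert to pixels via
``OpticalConfig.pixel_size_nm``.  Spots are rendered as 2D Gaussians of the
configured PSF sigma whose *amplitude* is set by a total photon budget; the
camera adds Poisson shot noise, Gaussian read noise and a constant baseline
offset.  Photon budgets emulate bright multicolour calibration beads
(~2×10⁵ photons) and much dimmer single-complex fluorescent-protein spots
(several thousand photons); neither number is a measured property of any
instrument — they are free parameters of the generator.

The prey truth position is the anchor truth position plus a vector of length
``true_sep_nm`` in a uniformly random direction; each channel's *observed*
(rendered) position additionally carries independent per-axis Gaussian
localization jitter of s.d. ``loc_noise_nm``.  Observed pair distances are
therefore Rice(true_sep_nm, sqrt(2)·loc_noise_nm) distributed — the sigma the
downstream estimator is expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import OpticalConfig
from .errors import GenerationError, ParameterError
from .registration import AffineMap

__all__ = ["SceneTruth", "sample_rician", "make_bead_dataset",
           "make_pict_fov", "make_pict_dataset", "render_spots",
           "add_camera_noise"]

# camera model defaults (counts / photons)
READ_NOISE = 2.0
BASELINE = 100.0

# photon budgets
BEAD_PHOTONS = 5.0e5
ANCHOR_PHOTONS = 8000.0
PREY_PHOTONS = 5000.0
BEAD_BG = 20.0          # photons/px, flat
EXTRACELL_BG = 10.0     # photons/px outside cells
CYTOPLASM_BG = 40.0     # extra photons/px inside cells
RIM_BG = 20.0           # extra photons/px on the membrane rim


@dataclass
class SceneTruth:
    """Ground truth emitted alongside a rendered scene.

    ``emitters`` holds one row per rendered spot: fov, channel, row_px,
    col_px, and (for cell scenes) pair_id / cell_id.  ``pairs`` holds one row
    per anchor/prey pair with the nominal and realized separations in nm.
    ``cells`` lists cell centres/radii; ``distortion`` is the inter-channel
    affine applied to channel-1 positions (bead and cell scenes alike).
    """

    emitters: pd.DataFrame
    pairs: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    distortion: AffineMap | None = None

    def to_csv(self, path) -> None:
        self.emitters.to_csv(path, index=False)


def sample_rician(mu: float, sigma: float, n: int,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` distances from the Rice(mu, sigma) law.

    Generated as the modulus of a 2D Gaussian displacement with mean length
    ``mu`` and per-axis s.d. ``sigma`` — exactly the physical situation of a
    fixed separation observed with isotropic localization noise.
    """
    if mu < 0 or sigma <= 0:
        raise ParameterError("require mu >= 0 and sigma > 0")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dx = rng.normal(mu, sigma, n)
    dy = rng.normal(0.0, sigma, n)
    return np.hypot(dx, dy)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def render_spots(shape: tuple[int, int], positions: np.ndarray,
                 photons: np.ndarray | float, sigma_px: float) -> np.ndarray:
    """Render 2D Gaussian spots (photon-rate image, no noise).

    ``photons`` is the total photon budget per spot; the peak amplitude is
    ``photons / (2π σ²)``.  Each spot is evaluated on a local window of
    ±5 sigma for speed.
    """
    img = np.zeros(shape, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return img
    photons = np.broadcast_to(np.asarray(photons, dtype=float), (len(positions),))
    half = int(math.ceil(5 * sigma_px))
    H, W = shape
    for (r0, c0), ph in zip(positions, photons):
        amp = ph / (2 * math.pi * sigma_px ** 2)
        r_lo, r_hi = max(int(r0) - half, 0), min(int(r0) + half + 1, H)
        c_lo, c_hi = max(int(c0) - half, 0), min(int(c0) + half + 1, W)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi, dtype=float)[:, None] - r0
        cc = np.arange(c_lo, c_hi, dtype=float)[None, :] - c0
        img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
            -(rr * rr + cc * cc) / (2 * sigma_px ** 2))
    return img


def add_camera_noise(photon_rate: np.ndarray, rng: np.random.Generator,
                     read_noise: float = READ_NOISE,
                     baseline: float = BASELINE) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise + constant baseline."""
    img = rng.poisson(np.clip(photon_rate, 0, None)).astype(float)
    img += rng.normal(0.0, read_noise, img.shape) + baseline
    return np.clip(img, 0, None).astype(np.float32)


def _sample_spaced(rng: np.random.Generator, n: int, lo: np.ndarray,
                   hi: np.ndarray, min_spacing: float,
                   max_tries: int = 200) -> np.ndarray:
    """Rejection-sample n points in a box with a minimum pairwise spacing."""
    pts: list[np.ndarray] = []
    for _ in range(n * max_tries):
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - p) >= min_spacing for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise GenerationError(
        f"could not place {n} points with spacing {min_spacing:.1f} px "
        f"in box {lo}..{hi} after {n * max_tries} tries")


# ---------------------------------------------------------------------------
# bead calibration fields
# ---------------------------------------------------------------------------

def make_bead_dataset(cfg: OpticalConfig | None = None, n_fov: int = 100,
                      beads_per_fov: tuple[int, int] = (25, 75),
                      distortion: AffineMap | None = None,
                      loc_noise_nm: float = 0.2,
                      seed: int = 0, *,
                      bead_photons: float = BEAD_PHOTONS,
                      bg_photons: float = BEAD_BG,
                      noise: bool = True,
                      margin_px: float = 12.0,
                      ) -> tuple[list[np.ndarray], SceneTruth]:
    """Generate a grid of two-channel multicolour-bead calibration fields.

    Channel-2 bead positions are drawn uniformly per FOV (with a minimum
    spacing of 4 PSF sigmas, emulating a negligible number of aggregates);
    channel-1 positions are the channel-2 positions passed through
    ``distortion`` plus isotropic Gaussian localization noise of s.d.
    ``loc_noise_nm``.  Returns a list of (2, H, W) float32 images and the
    scene truth.
    """
    cfg = cfg or OpticalConfig()
    if distortion is None:
        distortion = AffineMap.identity()
    lo_n, hi_n = beads_per_fov
    if not (1 <= lo_n <= hi_n):
        raise ParameterError("beads_per_fov must be an increasing pair >= 1")
    rng = np.random.default_rng(seed)
    H, W = cfg.image_shape
    sigma = cfg.sigma_px
    spacing = 4.0 * sigma
    loc_noise_px = loc_noise_nm / cfg.pixel_size_nm

    images, truth_rows = [], []
    lo = np.array([margin_px, margin_px])
    hi = np.array([H - margin_px, W - margin_px])
    for fov in range(n_fov):
        n_b = int(rng.integers(lo_n, hi_n + 1))
        p2 = _sample_spaced(rng, n_b, lo, hi, spacing)
        p1 = distortion.apply(p2) + rng.normal(0.0, loc_noise_px, p2.shape)
        # multicolour beads share a brightness factor across channels
        bright = rng.uniform(0.9, 1.1, n_b) * bead_photons
        ch1 = render_spots((H, W), p1, bright, sigma) + bg_photons
        ch2 = render_spots((H, W), p2, bright, sigma) + bg_photons
        if noise:
            ch1 = add_camera_noise(ch1, rng)
            ch2 = add_camera_noise(ch2, rng)
        else:
            ch1 = (ch1 + BASELINE).astype(np.float32)
            ch2 = (ch2 + BASELINE).astype(np.float32)
        images.append(np.stack([ch1, ch2]))
        for b in range(n_b):
            truth_rows.append((fov, 1, p1[b, 0], p1[b, 1], b))
            truth_rows.append((fov, 2, p2[b, 0], p2[b, 1], b))
    emitters = pd.DataFrame(
        truth_rows, columns=["fov", "channel", "row_px", "col_px", "bead_id"])
    return images, SceneTruth(emitters=emitters, distortion=distortion)


# ---------------------------------------------------------------------------
# PICT-like cell fields
# ---------------------------------------------------------------------------

def make_pict_fov(cfg: OpticalConfig | None = None, n_cells: int = 10,
                  pairs_per_cell: int = 2, true_sep_nm: float = 20.0,
                  loc_noise_nm: float = 7.0, seed: int = 0, *,
                  cell_radius_px: tuple[float, float] = (22.0, 28.0),
                  distortion: AffineMap | None = None,
                  anchor_photons: float = ANCHOR_PHOTONS,
                  prey_photons: float = PREY_PHOTONS,
                  noise: bool = True, fov: int = 0,
                  ) -> tuple[np.ndarray, SceneTruth, np.ndarray]:
    """Render one two-channel field of yeast-like cells with spot pairs.

    Cells are disks with elevated cytoplasmic background and a brighter
    membrane rim; anchor spots sit on the rim (the equatorial section of a
    membrane platform) and prey spots are displaced by ``true_sep_nm`` in a
    random direction.  If ``distortion`` is given, channel-1 emitters are
    rendered at distortion-applied coordinates so the pipeline's chromatic
    correction is exercised end to end.  Returns the (2, H, W) image, the
    truth, and the cell label mask.
    """
    cfg = cfg or OpticalConfig()
    rng = np.random.default_rng(seed)
    H, W = cfg.image_shape
    sigma = cfg.sigma_px
    sep_px = true_sep_nm / cfg.pixel_size_nm
    noise_px = loc_noise_nm / cfg.pixel_size_nm
    r_lo, r_hi = cell_radius_px
    if true_sep_nm < 0 or loc_noise_nm < 0:
        raise ParameterError("true_sep_nm and loc_noise_nm must be >= 0")

    # --- geometry: non-overlapping cells, pairs spread along each rim -----
    pad = 14.0
    if n_cells > 0 and 2 * (r_hi + pad) > min(H, W):
        raise GenerationError("cells do not fit inside the frame")
    radii = rng.uniform(r_lo, r_hi, n_cells)
    centers = np.empty((0, 2))
    if n_cells > 0:
        centers = _sample_spaced(
            rng, n_cells,
            np.array([r_hi + pad, r_hi + pad]),
            np.array([H - r_hi - pad, W - r_hi - pad]),
            2 * r_hi + 26.0)

    min_arc_px = 26.0
    emitter_rows, pair_rows, cell_rows = [], [], []
    anchors_obs, preys_obs = [], []
    pid = 0
    for ci in range(n_cells):
        R, ctr = radii[ci], centers[ci]
        cell_rows.append((ci, ctr[0], ctr[1], R))
        dtheta = min_arc_px / R
        if pairs_per_cell * dtheta > 2 * math.pi:
            raise GenerationError("too many pairs per cell for rim spacing")
        base = rng.uniform(0, 2 * math.pi)
        thetas = base + np.arange(pairs_per_cell) * (2 * math.pi / pairs_per_cell)
        thetas += rng.uniform(-0.2, 0.2, pairs_per_cell)
        for th in thetas:
            anchor_true = ctr + R * np.array([math.sin(th), math.cos(th)])
            phi = rng.uniform(0, 2 * math.pi)
            prey_true = anchor_true + sep_px * np.array([math.sin(phi),
                                                         math.cos(phi)])
            a_obs = anchor_true + rng.normal(0, noise_px, 2)
            p_obs = prey_true + rng.normal(0, noise_px, 2)
            anchors_obs.append(a_obs)
            preys_obs.append(p_obs)
            obs_sep_nm = float(np.linalg.norm(a_obs - p_obs) * cfg.pixel_size_nm)
            emitter_rows.append((fov, 1, a_obs[0], a_obs[1], pid, ci))
            emitter_rows.append((fov, 2, p_obs[0], p_obs[1], pid, ci))
            pair_rows.append((fov, pid, ci, true_sep_nm, obs_sep_nm))
            pid += 1

    # --- label mask and background structure ------------------------------
    mask = np.zeros((H, W), dtype=np.uint16)
    rim = np.zeros((H, W), dtype=float)
    yy, xx = np.mgrid[0:H, 0:W]
    for ci in range(n_cells):
        R, ctr = radii[ci], centers[ci]
        d = np.hypot(yy - ctr[0], xx - ctr[1])
        mask[d <= R] = ci + 1
        rim += np.exp(-((d - R) ** 2) / (2 * 1.2 ** 2))
    inside = (mask > 0).astype(float)
    structure = EXTRACELL_BG + CYTOPLASM_BG * inside + RIM_BG * rim

    anchors_obs = np.array(anchors_obs) if anchors_obs else np.empty((0, 2))
    preys_obs = np.array(preys_obs) if preys_obs else np.empty((0, 2))
    anchors_render = (distortion.apply(anchors_obs)
                      if distortion is not None and len(anchors_obs)
                      else anchors_obs)
    ch1 = structure + render_spots((H, W), anchors_render,
                                   rng.uniform(0.8, 1.2, len(anchors_obs))
                                   * anchor_photons if len(anchors_obs) else 0.0,
                                   sigma)
    ch2 = structure + render_spots((H, W), preys_obs,
                                   rng.uniform(0.8, 1.2, len(preys_obs))
                                   * prey_photons if len(preys_obs) else 0.0,
                                   sigma)
    if noise:
        ch1 = add_camera_noise(ch1, rng)
        ch2 = add_camera_noise(ch2, rng)
    else:
        ch1 = (ch1 + BASELINE).astype(np.float32)
        ch2 = (ch2 + BASELINE).astype(np.float32)

    truth = SceneTruth(
        emitters=pd.DataFrame(
            emitter_rows,
            columns=["fov", "channel", "row_px", "col_px", "pair_id", "cell_id"]),
        pairs=pd.DataFrame(
            pair_rows,
            columns=["fov", "pair_id", "cell_id", "true_sep_nm", "obs_sep_nm"]),
        cells=pd.DataFrame(
            cell_rows, columns=["cell_id", "row_px", "col_px", "radius_px"]),
        distortion=distortion,
    )
    return np.stack([ch1, ch2]), truth, mask


def make_pict_dataset(cfg: OpticalConfig | None = None, n_fov: int = 4,
                      seed: int = 0, **fov_kw):
    """Generate ``n_fov`` cell fields with independent child seeds.

    Returns (list of images, list of SceneTruth, list of masks).
    """
    seeds = np.random.SeedSequence(seed).spawn(n_fov)
    images, truths, masks = [], [], []
    for i, ss in enumerate(seeds):
        img, truth, mask = make_pict_fov(
            cfg, seed=int(ss.generate_state(1)[0] % (2 ** 31)), fov=i, **fov_kw)
        truth.emitters["fov"] = i
        if truth.pairs is not None:
            truth.pairs["fov"] = i
        images.append(img)
        truths.append(truth)
        masks.append(mask)
    return images, truths, masks
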