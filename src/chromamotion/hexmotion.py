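"""Hexagonal-lattice chromatic motion model.

An RGB image is resampled onto a compound-eye-like lattice of flat-topped
hexagons (default 120 px point-to-point width × 104 px flat-to-flat
height, so each interior hexagon owns exactly 9360 pixels) by replacing
every hexagon's pixels with their mean RGB.  At each lattice site and for
each of the four cardinal directions, a directional Weber contrast
C = (I_h − I_b)/I_b compares the mean intensity of the *home* group (the
site plus its six neighbors) with the mean of the three *background*
facets adjacent to the home group's leading edge along that direction.

Motion toward or away from a focus of expansion is then estimated per
site: positive contrasts feed the ON channel and negative contrasts
(magnitudes) the OFF channel, each as a 2-D vector sum of direction unit
vectors weighted by contrast, evaluated under channel-specific spectral
weights (e.g. ON from the red channel, OFF from the blue channel to mimic
spectrally asymmetric ON/OFF pathways).  Each channel's vector is
projected onto the site's radial unit vector — pointing away from the
focus for approach, toward it for recession — and the combined estimate
is the sum of the two projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TestResult, test as run_test

__all__ = [
    "HexLattice",
    "MotionEstimate",
    "ModeComparison",
    "hex_sample",
    "weber_contrast",
    "directional_contrast",
    "radial_motion",
    "compare_modes",
    "CHANNEL_WEIGHTS",
    "DIRECTIONS",
    "DIRECTION_VECTORS",
    "HOME_RING",
    "BACKGROUND_OFFSETS",
]

#: Named channel weight vectors (w_R, w_G, w_B).
CHANNEL_WEIGHTS = {
    "RGB": (1 / 3, 1 / 3, 1 / 3),
    "R": (1.0, 0.0, 0.0),
    "G": (0.0, 1.0, 0.0),
    "B": (0.0, 0.0, 1.0),
}

DIRECTIONS = ("left", "up", "right", "down")
#: Cardinal unit vectors in the pixel frame (x rightward, y downward).
DIRECTION_VECTORS = {
    "left": (-1.0, 0.0),
    "up": (0.0, -1.0),
    "right": (1.0, 0.0),
    "down": (0.0, 1.0),
}

#: Axial (q, r) offsets of the six neighbors of a flat-topped hexagon.
HOME_RING = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))

#: Axial offsets of the three background facets adjacent to the home
#: group's leading edge in each direction (read from the model's
#: neighborhood template; configurable).
BACKGROUND_OFFSETS = {
    "right": ((2, -2), (2, -1), (2, 0)),
    "left": ((-2, 0), (-2, 1), (-2, 2)),
    "up": ((0, -2), (-1, -1), (1, -2)),
    "down": ((0, 2), (-1, 2), (1, 1)),
}


@dataclass
class HexLattice:
    """Hexagonal sampling of an image.

    Sites are indexed by axial coordinates (q = column, r); ``centers``
    are pixel-frame (x, y) site centers, ``counts`` the member-pixel
    count of each site (9360 for interior sites at the default geometry),
    and ``mean_rgb`` the per-site mean channel values.
    """

    q: np.ndarray
    r: np.ndarray
    centers: np.ndarray       # (n, 2) as (x, y)
    counts: np.ndarray
    mean_rgb: np.ndarray      # (n, 3)
    hex_width: float
    hex_height: float
    image_shape: tuple[int, int]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {(int(q), int(r)): i for i, (q, r) in enumerate(zip(self.q, self.r))}

    @property
    def n_sites(self) -> int:
        return len(self.q)

    def site_index(self, q, r) -> int:
        """Index of site (q, r), or −1 if absent."""
        return self._index.get((int(q), int(r)), -1)

    def interior(self) -> np.ndarray:
        """Sites whose hexagon lies fully inside the image."""
        h, w = self.image_shape
        x, y = self.centers[:, 0], self.centers[:, 1]
        return ((x >= self.hex_width / 2) & (x <= w - 1 - self.hex_width / 2)
                & (y >= self.hex_height / 2) & (y <= h - 1 - self.hex_height / 2))

    def full(self) -> np.ndarray:
        """Sites owning a full (unclipped) complement of pixels.

        Border-clipped hexagons average far fewer pixels, so their means
        are noisier; contrast computations only admit full cells as group
        members to avoid an outward bias at the image border.
        """
        expected = 0.75 * self.hex_width * self.hex_height
        return self.counts >= 0.98 * expected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "q": self.q, "r": self.r,
            "x": self.centers[:, 0], "y": self.centers[:, 1],
            "n_pixels": self.counts,
            "mean_r": self.mean_rgb[:, 0],
            "mean_g": self.mean_rgb[:, 1],
            "mean_b": self.mean_rgb[:, 2],
        })


def _assign_pixels(h, w, hex_width, hex_height):
    """Nearest hexagon center for every pixel, with exact tie-breaking.

    Distances are measured after rescaling the vertical axis so the tiling
    is regular, using the integer-valued quantity
    ``h² Δx² + 3 (w/2)² Δy²`` (∝ the rescaled squared distance).  Boundary
    ties are broken lexicographically on (distance, Δy, Δx), which depends
    only on the pixel's offset from the candidate center, so every
    interior cell is an exact integer translate of every other and owns
    the same number of pixels.
    """
    a = hex_width / 2.0
    xs = np.arange(w, dtype=float)[None, :]
    ys = np.arange(h, dtype=float)[:, None]
    q0 = np.floor(xs / (1.5 * a)).astype(int) + np.zeros((h, w), dtype=int)

    best_key = np.full((h, w), np.inf)
    best_q = np.zeros((h, w), dtype=int)
    best_r = np.zeros((h, w), dtype=int)
    wx = hex_height * hex_height
    wy = 3.0 * a * a
    for dq in (-1, 0, 1):
        q = q0 + dq
        cx = 1.5 * a * q
        r0 = np.floor(ys / hex_height - q / 2.0).astype(int)
        for dr in (-1, 0, 1):
            r = r0 + dr
            cy = hex_height * (r + q / 2.0)
            ddx = xs - cx
            ddy = ys - cy
            dist = wx * ddx * ddx + wy * ddy * ddy
            # Composite key: exact for integer geometries (values < 2^53).
            key = dist * 2**20 + (ddy + 512.0) * 2**10 + (ddx + 512.0)
            better = key < best_key
            best_key = np.where(better, key, best_key)
            best_q = np.where(better, q, best_q)
            best_r = np.where(better, r, best_r)
    return best_q, best_r


def hex_sample(image, hex_width=120.0, hex_height=104.0) -> HexLattice:
    """Partition an image into flat-topped hexagons and average each.

    The tiling has horizontal pitch ¾·``hex_width`` and vertical pitch
    ``hex_height`` with alternate columns offset by half a height.  Every
    pixel is assigned to exactly one site (the nearest hexagon center in a
    vertically rescaled frame, with deterministic tie-breaking); site means
    are taken over the member pixels.  At the default 120 × 104 geometry
    every interior hexagon owns exactly 9360 pixels.  Grayscale input is
    treated as three identical channels.
    """
    if hex_width <= 0 or hex_height <= 0:
        raise ValueError("hexagon dimensions must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be (H, W) or (H, W, 3)")
    h, w = img.shape[:2]
    if w < hex_width or h < hex_height:
        raise ValueError("image smaller than one hexagon")

    a = hex_width / 2.0
    q, r = _assign_pixels(h, w, hex_width, hex_height)

    keys = np.stack([q.ravel(), r.ravel()], axis=1)
    uniq, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((uniq.shape[0], 3))
    flat = img.reshape(-1, 3)
    for c in range(3):
        sums[:, c] = np.bincount(inverse, weights=flat[:, c], minlength=uniq.shape[0])
    means = sums / counts[:, None]

    qs, rs = uniq[:, 0], uniq[:, 1]
    centers = np.stack([1.5 * a * qs, hex_height * (rs + qs / 2.0)], axis=1)
    return HexLattice(qs, rs, centers, counts, means, float(hex_width),
                      float(hex_height), (h, w))


def weber_contrast(i_h, i_b) -> float:
    """Weber contrast (I_h − I_b) / I_b of a home intensity against background."""
    i_b = float(i_b)
    if i_b <= 0:
        raise ValueError("background intensity must be positive for Weber contrast")
    return (float(i_h) - i_b) / i_b


def _group_intensity(lattice, intensities, q0, r0, offsets, usable):
    idx = [lattice.site_index(q0 + dq, r0 + dr) for dq, dr in offsets]
    if any(i < 0 or not usable[i] for i in idx):
        return None
    return float(np.mean([intensities[i] for i in idx]))


def directional_contrast(lattice: HexLattice, site_index, direction,
                         channel_weights=(1 / 3, 1 / 3, 1 / 3),
                         background_offsets=None, require_full=True) -> float:
    """Directional Weber contrast at one site.

    Returns NaN (after a warning for a non-positive background) when a
    required neighbor is missing at the lattice edge — with
    ``require_full`` (default) a border-clipped hexagon also counts as
    missing — or when the background intensity is non-positive; such
    sites are excluded from statistics.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if background_offsets is None:
        background_offsets = BACKGROUND_OFFSETS
    wts = np.asarray(channel_weights, dtype=float)
    intensities = lattice.mean_rgb @ wts
    usable = lattice.full() if require_full else np.ones(lattice.n_sites, bool)
    q0, r0 = int(lattice.q[site_index]), int(lattice.r[site_index])

    home = _group_intensity(lattice, intensities, q0, r0, ((0, 0),) + tuple(HOME_RING), usable)
    back = _group_intensity(lattice, intensities, q0, r0, background_offsets[direction], usable)
    if home is None or back is None:
        return float("nan")
    if back <= 0:
        warnings.warn(f"non-positive background intensity at site {site_index}; excluded",
                      stacklevel=2)
        return float("nan")
    return (home - back) / back


@dataclass
class MotionEstimate:
    """Per-site radial motion estimates for one mode and channel config."""

    q: np.ndarray
    r: np.ndarray
    centers: np.ndarray
    contrasts_on: np.ndarray   # (n, 4) directional contrasts under on_weights
    contrasts_off: np.ndarray  # (n, 4) under off_weights
    on_component: np.ndarray
    off_component: np.ndarray
    combined: np.ndarray
    valid: np.ndarray
    mode: str
    focus: tuple[float, float]
    on_weights: tuple
    off_weights: tuple

    def to_frame(self) -> pd.DataFrame:
        cols = {"q": self.q, "r": self.r,
                "x": self.centers[:, 0], "y": self.centers[:, 1]}
        for j, d in enumerate(DIRECTIONS):
            cols[f"c_{d[0]}_on"] = self.contrasts_on[:, j]
            cols[f"c_{d[0]}_off"] = self.contrasts_off[:, j]
        cols.update(on=self.on_component, off=self.off_component,
                    combined=self.combined, valid=self.valid)
        return pd.DataFrame(cols)


def _neighbor_index_array(lattice, offsets):
    out = np.empty((lattice.n_sites, len(offsets)), dtype=int)
    for i, (q0, r0) in enumerate(zip(lattice.q, lattice.r)):
        for j, (dq, dr) in enumerate(offsets):
            out[i, j] = lattice.site_index(q0 + dq, r0 + dr)
    return out


def _all_contrasts(lattice, weights, background_offsets, require_full=True):
    """(n_sites, 4) directional contrasts; NaN where neighbors are missing."""
    intensities = lattice.mean_rgb @ np.asarray(weights, dtype=float)
    usable = lattice.full() if require_full else np.ones(lattice.n_sites, bool)
    home_idx = _neighbor_index_array(lattice, ((0, 0),) + tuple(HOME_RING))
    home_ok = (home_idx >= 0).all(axis=1) & usable[np.clip(home_idx, 0, None)].all(axis=1)
    i_h = np.where(home_ok, intensities[np.clip(home_idx, 0, None)].mean(axis=1), np.nan)

    out = np.full((lattice.n_sites, len(DIRECTIONS)), np.nan)
    for j, d in enumerate(DIRECTIONS):
        b_idx = _neighbor_index_array(lattice, background_offsets[d])
        b_ok = (b_idx >= 0).all(axis=1) & usable[np.clip(b_idx, 0, None)].all(axis=1)
        i_b = np.where(b_ok, intensities[np.clip(b_idx, 0, None)].mean(axis=1), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (i_h - i_b) / i_b
        c = np.where(home_ok & b_ok & (i_b > 0), c, np.nan)
        out[:, j] = c
    return out


def radial_motion(lattice: HexLattice, focus, mode="approach",
                  on_weights=(1 / 3, 1 / 3, 1 / 3),
                  off_weights=(1 / 3, 1 / 3, 1 / 3),
                  background_offsets=None, require_full=True) -> MotionEstimate:
    """Per-site ON/OFF radial motion estimates relative to a focus.

    ``focus`` is an (x, y) pixel position inside the image; string channel
    names from :data:`CHANNEL_WEIGHTS` ('R', 'B', 'RGB', …) may be passed
    for the weight vectors.  ``mode`` selects approach (radial unit vector
    away from the focus) or recede (toward it).
    """
    if mode not in ("approach", "recede"):
        raise ValueError("mode must be 'approach' or 'recede'")
    fx, fy = float(focus[0]), float(focus[1])
    h, w = lattice.image_shape
    if not (0 <= fx < w and 0 <= fy < h):
        raise ValueError("focus must lie inside the image")
    if isinstance(on_weights, str):
        on_weights = CHANNEL_WEIGHTS[on_weights]
    if isinstance(off_weights, str):
        off_weights = CHANNEL_WEIGHTS[off_weights]
    if background_offsets is None:
        background_offsets = BACKGROUND_OFFSETS

    c_on = _all_contrasts(lattice, on_weights, background_offsets, require_full)
    c_off = _all_contrasts(lattice, off_weights, background_offsets, require_full)
    valid = np.isfinite(c_on).all(axis=1) & np.isfinite(c_off).all(axis=1)

    unit = np.array([DIRECTION_VECTORS[d] for d in DIRECTIONS])  # (4, 2)
    v_on = np.nan_to_num(np.clip(c_on, 0.0, None)) @ unit        # (n, 2)
    v_off = np.nan_to_num(np.clip(-c_off, 0.0, None)) @ unit

    radial = lattice.centers - np.array([fx, fy])
    norm = np.linalg.norm(radial, axis=1)
    with np.errstate(invalid="ignore"):
        radial = np.where(norm[:, None] > 0, radial / np.where(norm == 0, 1, norm)[:, None], 0.0)
    if mode == "recede":
        radial = -radial

    on_comp = np.where(valid, (v_on * radial).sum(axis=1), np.nan)
    off_comp = np.where(valid, (v_off * radial).sum(axis=1), np.nan)
    return MotionEstimate(lattice.q, lattice.r, lattice.centers, c_on, c_off,
                          on_comp, off_comp, on_comp + off_comp, valid, mode,
                          (fx, fy), tuple(on_weights), tuple(off_weights))


@dataclass
class ModeComparison:
    """Approach-vs-recede comparison across lattice sites."""

    ranked_a: np.ndarray      # combined values of estimate a, sorted
    ranked_b: np.ndarray
    differences: np.ndarray   # per-site a − b
    result: TestResult
    n_sites: int


def compare_modes(est_a: MotionEstimate, est_b: MotionEstimate) -> ModeComparison:
    """Two-sided rank-sum comparison of combined motion across sites.

    Both estimates must cover the same lattice sites; only sites valid in
    both enter the statistics.
    """
    if not (np.array_equal(est_a.q, est_b.q) and np.array_equal(est_a.r, est_b.r)):
        raise ValueError("motion estimates cover different site sets")
    valid = est_a.valid & est_b.valid
    a = est_a.combined[valid]
    b = est_b.combined[valid]
    if a.size < 2:
        raise ValueError("fewer than 2 jointly valid sites")
    res = run_test("rank_sum", a, b, sidedness="two-sided")
    return ModeComparison(np.sort(a), np.sort(b), a - b, res, int(a.size))
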