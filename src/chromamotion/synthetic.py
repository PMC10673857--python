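"""Synthetic data with known ground truth for every analysis stage.

Three generators emulate the experimental measurements:

* :func:`simulate_behavior` — tethered-flight ΔWBA trials whose
  condition-mean response crosses zero at a configurable UV isoluminance,
  separately for ON- and OFF-motion protocols.  The response-vs-UV
  nonlinearity is a tanh of configurable slope (the data themselves
  constrain only the zero crossing, not the transfer function); mirrored
  stimuli (CCW rotation, left-side discs) carry sign-inverted responses.

* :func:`simulate_movie` — trial-structured 256 × 256 fluorescence movies
  with planted Gaussian "column" blobs whose noiseless ΔF/F₀ disc-response
  metric is linear in UV level with a zero at each blob's true
  isoluminance (increasing for ON polarity, decreasing for OFF), slowed by
  an exponential indicator kernel, plus integer rigid frame jitter
  (recorded for alignment-recovery tests) and additive Gaussian noise.

* :func:`make_test_image` — a colored disc on a colored background, the
  stand-in input for the hexagonal-lattice motion model.

:func:`predict_visibility` encodes the chromatic-contrast prediction the
disc responses follow: a UV disc on a calibrated green background always
presents motion contrast to at least one pathway, while a green disc on a
UV background is invisible exactly when the background intensity falls
between the ON and OFF isoluminance levels (neither pathway sees an edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging import Movie

__all__ = [
    "GroundTruth",
    "Trial",
    "WbaRecording",
    "SyntheticMovie",
    "predict_visibility",
    "simulate_behavior",
    "simulate_movie",
    "make_test_image",
    "FULL_RANGE_LEVELS",
    "COMPACT_LEVELS",
    "BEHAVIOR_PROTOCOLS",
]

#: UV intensities shown in the full-range protocols.
FULL_RANGE_LEVELS = (0, 2, 4, 5, 6, 7, 8, 9, 10, 12, 15)
#: Restricted range of the compact combined ON/OFF protocol.
COMPACT_LEVELS = tuple(range(3, 10))

BEHAVIOR_PROTOCOLS = ("disc_uv", "disc_green", "edges_on", "edges_off", "edges_compact")


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of one simulated fly.

    ``i_on``/``i_off`` are the true ON- and OFF-pathway isoluminance levels
    in UV units (0–15); ``amplitude`` sets the asymptotic response,
    ``noise_sd`` the per-trial Gaussian noise on the trial-mean response,
    and ``n_trials`` the presentations per rotation (so folded trial counts
    are doubled).
    """

    i_on: float = 4.5
    i_off: float = 9.2
    amplitude: float = 1.0
    noise_sd: float = 0.05
    n_trials: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.i_on <= 15 and 0 <= self.i_off <= 15):
            raise ValueError("isoluminance levels must lie in 0..15")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")


@dataclass
class Trial:
    """One ΔWBA trial: a 500 Hz trace plus its stimulus metadata."""

    trace: np.ndarray
    protocol: str
    uv_level: int
    rotation: str           # 'cw'/'ccw' for edges, 'right'/'left' for discs
    fly_id: int = 0


@dataclass
class WbaRecording:
    """All trials of one simulated (or converted) fly."""

    trials: list[Trial]
    sample_rate: float = 500.0
    fly_id: int = 0
    compact: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (fly, trial, protocol, uv_level, rotation, t, dwba)."""
        rows = []
        for k, tr in enumerate(self.trials):
            t = np.arange(tr.trace.size) / self.sample_rate
            rows.append(pd.DataFrame({
                "fly": tr.fly_id, "trial": k, "protocol": tr.protocol,
                "uv_level": tr.uv_level, "rotation": tr.rotation,
                "t": t, "dwba": tr.trace,
            }))
        return pd.concat(rows, ignore_index=True)


def predict_visibility(disc_channel, uv_level, i_on, i_off) -> str:
    """Predict whether an expanding disc presents motion contrast.

    A UV disc on a calibrated green background is visible at every UV
    level: below ``i_off`` it drives the OFF pathway, above ``i_on`` the ON
    pathway, and the two bands overlap whenever ``i_on ≤ i_off``.  A green
    disc on a UV background is invisible exactly when the background level
    lies strictly inside ``(i_on, i_off)``.  The regime ``i_on > i_off`` is
    unsupported.
    """
    if not (0 <= uv_level <= 15):
        raise ValueError("uv_level must lie in 0..15")
    if not (0 <= i_on <= 15 and 0 <= i_off <= 15):
        raise ValueError("isoluminance levels must lie in 0..15")
    if i_on > i_off:
        raise ValueError("unsupported regime: i_on > i_off")
    if disc_channel == "UV_on_green":
        return "visible"
    if disc_channel == "green_on_UV":
        return "invisible" if i_on < uv_level < i_off else "visible"
    raise ValueError(f"unknown disc_channel {disc_channel!r}")


def _disc_drive(protocol, uv, i_on, i_off) -> float:
    """Normalized response magnitude of a disc trial (0 when invisible)."""
    if protocol == "disc_green":
        if predict_visibility("green_on_UV", uv, i_on, i_off) == "invisible":
            return 0.0
        # Distance to the nearer edge of the invisibility band.
        return (i_on - uv if uv <= i_on else uv - i_off) / 15.0
    # UV disc: contrast from whichever pathway sees the larger luminance gap.
    return max(i_off - uv, uv - i_on) / 15.0


def simulate_behavior(gt: GroundTruth, protocol, uv_levels=None, sample_rate=500.0,
                      slope=0.5, fly_id=0, trial_duration=2.0,
                      expansion_end=1.0) -> WbaRecording:
    """Simulate the ΔWBA trials of one fly for one protocol.

    Edge trials carry a constant trial-mean response
    ``amplitude · tanh(slope · (uv − I))`` with I = ``i_on`` for ON motion
    and ``i_off`` for OFF motion; disc trials respond only after full
    expansion, scaled by the visibility drive.  Each presentation comes as
    a CW/CCW (or right/left) pair with the mirrored member sign-inverted,
    plus an independent per-trial Gaussian offset of SD ``noise_sd``.
    Deterministic under ``gt.seed``.

    ``edges_compact`` produces both ON and OFF trials (tagged ``edges_on``
    and ``edges_off``) restricted to UV 3–9, and marks the recording
    compact so downstream estimates are capped at the range ends.
    """
    if protocol not in BEHAVIOR_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    compact = protocol == "edges_compact"
    if uv_levels is None:
        uv_levels = COMPACT_LEVELS if compact else FULL_RANGE_LEVELS
    uv_levels = [int(u) for u in uv_levels]
    if not uv_levels:
        raise ValueError("uv_levels must be non-empty")
    if any(not 0 <= u <= 15 for u in uv_levels):
        raise ValueError("uv_levels must lie in 0..15")
    if compact and any(not 3 <= u <= 9 for u in uv_levels):
        raise ValueError("compact protocol is restricted to UV 3..9")

    rng = np.random.default_rng(gt.seed)
    n = int(round(trial_duration * sample_rate))
    t = np.arange(n) / sample_rate

    sub_protocols = ["edges_on", "edges_off"] if compact else [protocol]
    trials: list[Trial] = []
    for proto in sub_protocols:
        is_disc = proto.startswith("disc")
        rotations = ("right", "left") if is_disc else ("cw", "ccw")
        for uv in uv_levels:
            if is_disc:
                base = gt.amplitude * _disc_drive(proto, uv, gt.i_on, gt.i_off)
                shape = (t >= expansion_end).astype(float)
            else:
                target = gt.i_on if proto == "edges_on" else gt.i_off
                base = gt.amplitude * np.tanh(slope * (uv - target))
                shape = np.ones_like(t)
            for _ in range(gt.n_trials):
                for rot in rotations:
                    sign = -1.0 if rot in ("ccw", "left") else 1.0
                    eps = rng.normal(0.0, gt.noise_sd) if gt.noise_sd > 0 else 0.0
                    trials.append(Trial(sign * base * shape + eps, proto, uv, rot, fly_id))
    return WbaRecording(trials, sample_rate, fly_id, compact)


@dataclass
class SyntheticMovie:
    """A simulated calcium movie bundled with its ground truth."""

    movie: Movie
    rois: list[dict]          # {'center': (y, x), 'polarity', 'isoluminance'}
    jitter: np.ndarray        # (T, 2) integer (dy, dx) applied per frame
    seed: int
    params: dict = field(default_factory=dict)


def _gaussian_blob(shape, center, fwhm) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = np.arange(shape[0])[:, None]
    x = np.arange(shape[1])[None, :]
    return np.exp(-(((y - center[0]) ** 2 + (x - center[1]) ** 2) / (2 * sigma ** 2)))


def simulate_movie(rois, uv_levels=None, *, kinetics_tau=0.3, jitter_sd=0.0,
                   noise_sd=0.0, seed=0, frame_rate=6.83, image_size=256,
                   n_trials_per_level=3, blob_fwhm=60.0, baseline=100.0,
                   blob_amplitude=150.0, response_gain=0.6, pre_stim=3.0,
                   expansion=1.0, hold=1.0, recorded=7.6) -> SyntheticMovie:
    """Simulate one fly's trial-structured calcium movie.

    ``rois`` is a list of ``(center (y, x), polarity, true_isoluminance)``;
    blob centers must be at least one column spacing (``blob_fwhm``) apart.
    Each trial presents one UV level of an expanding disc; a blob's
    fluorescence is ``baseline + blob_amplitude · (1 + r · h(t))`` where
    ``r = ±response_gain · (uv − iso)/15`` (positive slope for ON polarity)
    and ``h`` is the disc drive (ramp during expansion, sustained during
    the hold) convolved with an exponential kernel of time constant
    ``kinetics_tau``.  Per-frame rigid jitter is an integer-rounded
    N(0, jitter_sd²) circular shift, recorded in the output.  Only the
    recorded portion of each trial (``recorded`` seconds) is generated;
    the unrecorded tail of the nominal 8 s trial exists only as timing
    metadata.  Bit-reproducible under ``seed``.
    """
    rois = [(tuple(c), str(pol), float(iso)) for c, pol, iso in rois]
    if not rois:
        raise ValueError("need at least one planted ROI")
    centers = np.array([c for c, _, _ in rois], dtype=float)
    if len(centers) > 1:
        d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() < blob_fwhm:
            raise ValueError("overlapping blobs: centers closer than one column spacing")
    for (cy, cx), pol, iso in rois:
        if pol not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")
        if not (0 <= iso <= 15):
            raise ValueError("true isoluminance must lie in 0..15")
    if min(kinetics_tau, jitter_sd, noise_sd) < 0:
        raise ValueError("kinetics_tau, jitter_sd and noise_sd must be non-negative")

    if uv_levels is None:
        uv_levels = FULL_RANGE_LEVELS
    uv_levels = [int(u) for u in uv_levels]

    rng = np.random.default_rng(seed)
    n_frames = int(np.floor(recorded * frame_rate))
    t = np.arange(n_frames) / frame_rate
    dt = 1.0 / frame_rate

    drive = np.clip((t - pre_stim) / expansion, 0.0, 1.0)
    drive[t >= pre_stim + expansion + hold] = 0.0
    if kinetics_tau > 0:
        ks = np.arange(0, 5 * kinetics_tau + dt, dt)
        kernel = np.exp(-ks / kinetics_tau)
        kernel /= kernel.sum()
        h = np.convolve(drive, kernel)[:n_frames]
    else:
        h = drive

    shape = (image_size, image_size)
    blobs = [_gaussian_blob(shape, c, blob_fwhm) for c, _, _ in rois]
    static = baseline + blob_amplitude * np.sum(blobs, axis=0)

    level_list = np.repeat(uv_levels, n_trials_per_level)
    order = rng.permutation(level_list.size)
    level_list = level_list[order]

    frames = np.empty((level_list.size * n_frames, image_size, image_size), dtype=np.float32)
    jitter = np.zeros((frames.shape[0], 2), dtype=int)
    trial_rows = []
    for ti, uv in enumerate(level_list):
        dyn = np.zeros(shape)
        for blob, (_, pol, iso) in zip(blobs, rois):
            r = response_gain * (uv - iso) / 15.0
            if pol == "OFF":
                r = -r
            dyn += blob * blob_amplitude * r
        trial = static[None, :, :] + h[:, None, None] * dyn[None, :, :]
        if jitter_sd > 0:
            dydx = np.rint(rng.normal(0.0, jitter_sd, size=(n_frames, 2))).astype(int)
        else:
            dydx = np.zeros((n_frames, 2), dtype=int)
        if noise_sd > 0:
            trial = trial + rng.normal(0.0, noise_sd, size=trial.shape)
        start = ti * n_frames
        for k in range(n_frames):
            frames[start + k] = np.roll(trial[k], tuple(dydx[k]), axis=(0, 1))
        jitter[start:start + n_frames] = dydx
        trial_rows.append({"trial": ti, "uv_level": int(uv), "start": start, "length": n_frames})

    np.clip(frames, 0.0, None, out=frames)
    movie = Movie(frames, frame_rate, pd.DataFrame(trial_rows),
                  stim_onset=pre_stim, expansion_end=pre_stim + expansion,
                  hold_end=pre_stim + expansion + hold)
    params = dict(kinetics_tau=kinetics_tau, jitter_sd=jitter_sd, noise_sd=noise_sd,
                  frame_rate=frame_rate, image_size=image_size,
                  n_trials_per_level=n_trials_per_level, blob_fwhm=blob_fwhm,
                  baseline=baseline, blob_amplitude=blob_amplitude,
                  response_gain=response_gain, pre_stim=pre_stim,
                  expansion=expansion, hold=hold, recorded=recorded,
                  uv_levels=list(uv_levels))
    roi_meta = [{"center": list(c), "polarity": pol, "isoluminance": iso}
                for c, pol, iso in rois]
    return SyntheticMovie(movie, roi_meta, jitter, int(seed), params)


def make_test_image(image_size, disc_center, disc_radius, disc_rgb,
                    background_rgb, noise_sd=0.0, seed=0,
                    texture_amp=0.0, texture_scale=40.0) -> np.ndarray:
    """RGB float image of a colored disc on a colored background.

    ``image_size`` may be an int (square) or (H, W); intensities are
    clipped to [0, 1].  ``texture_amp`` adds a smooth achromatic luminance
    texture (Gaussian-filtered noise of spatial scale ``texture_scale`` px,
    shared by all channels across disc and background) mimicking the
    luminance structure of natural scenes; ``noise_sd`` adds independent
    per-pixel noise.  Deterministic under ``seed``.
    """
    if np.isscalar(image_size):
        image_size = (int(image_size), int(image_size))
    h, w = image_size
    cy, cx = disc_center
    if disc_radius <= 0:
        raise ValueError("disc_radius must be positive")
    if not (disc_radius <= cy <= h - disc_radius and disc_radius <= cx <= w - disc_radius):
        raise ValueError("disc does not fit inside the image")
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    inside = (y - cy) ** 2 + (x - cx) ** 2 <= disc_radius ** 2
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(background_rgb, dtype=float)
    img[inside] = np.asarray(disc_rgb, dtype=float)
    rng = np.random.default_rng(seed)
    if texture_amp > 0:
        from scipy import ndimage as ndi

        t = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), texture_scale)
        img = img + (texture_amp / t.std()) * t[..., None]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)
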