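"""Calcium-imaging analysis pipeline.

Stages, in the order a recording flows through them:

1. **Rigid alignment** — a binary template is the thresholded mean image
   over one reference stimulus (UV = 0 trials for OFF-polarity cells,
   UV = 15 for ON cells).  Every frame is binarized and the integer shift
   maximizing its spatial cross-correlation with the template is removed.
   A recording in which any shift component exceeds 25 px is rejected.
2. **ROI detection** — the reference-stimulus mean image is smoothed with
   a Gaussian of 11 px full width at half maximum; local maxima above a
   floor seed a flood fill (watershed on the inverted smoothed image) that
   grows each seed downhill to disjoint, connected masks.  The minimum
   peak separation corresponds to one neuronal column (~5 µm in medulla
   fields of view, ~4 µm in lobula).
3. **ΔF/F₀** — per trial, F₀ is the mean mask fluorescence in the 1.5 s
   before stimulus onset; the trace is (F − F₀)/F₀.
4. **Response metric** — the mean ΔF/F₀ over the two frames immediately
   after the disc reaches full expansion (for most cell classes; the Dm9
   class instead uses the frames after the screen returns to green).
5. **Responsiveness threshold** — an ROI is kept iff its mean metric over
   the polarity's reference levels (UV 12–15 for ON, 0–3 for OFF, 0–1 for
   Dm9) reaches the threshold; a threshold sweep reports how the cohort
   isoluminance and fly count change with the cutoff.
6. **Isoluminance** — per-ROI zero crossing of the metric-vs-UV curve,
   scanned downward from UV = 15 for ON cells and upward from UV = 0 for
   OFF cells with linear interpolation; with no crossing, the level of the
   curve's minimum is used.  ROI estimates average within fly, fly means
   average to the grand mean (each fly weighted equally), and a population
   isoluminance is the crossing of the across-fly mean curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .behavior import IsoluminanceEstimate, TuningCurve

__all__ = [
    "Movie",
    "Roi",
    "align",
    "detect_rois",
    "dff",
    "roi_metric",
    "build_tuning",
    "threshold_responsive",
    "threshold_sweep",
    "roi_isoluminance",
    "aggregate",
    "AggregateResult",
    "run_pipeline",
    "PipelineResult",
    "REFERENCE_LEVELS",
]

#: UV ranges over which the responsiveness threshold is evaluated.
REFERENCE_LEVELS = {"ON": (12, 15), "OFF": (0, 3), "Dm9": (0, 1)}


@dataclass
class Movie:
    """Trial-structured fluorescence movie.

    ``trials`` has one row per trial with columns ``trial``, ``uv_level``,
    ``start`` (first frame index) and ``length`` (frames).  Stimulus timing
    is trial-relative, in seconds: onset of the disc, end of expansion, and
    end of the hold period (return to green).
    """

    frames: np.ndarray            # (T, H, W) fluorescence
    frame_rate: float
    trials: pd.DataFrame
    stim_onset: float = 3.0
    expansion_end: float = 4.0
    hold_end: float = 5.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, H, W)")
        need = {"trial", "uv_level", "start", "length"}
        if not need.issubset(self.trials.columns):
            raise ValueError(f"trial table must have columns {sorted(need)}")
        if self.trials["length"].nunique() != 1:
            raise ValueError("all trials must be of equal length")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def trial_length(self) -> int:
        return int(self.trials["length"].iloc[0])

    @property
    def trial_times(self) -> np.ndarray:
        """Within-trial frame times, seconds from trial start."""
        return np.arange(self.trial_length) / self.frame_rate

    def trial_frames(self, i) -> np.ndarray:
        row = self.trials.iloc[i]
        start = int(row["start"])
        return self.frames[start:start + int(row["length"])]

    def frames_for_level(self, uv_level) -> np.ndarray:
        sel = self.trials[self.trials["uv_level"] == uv_level]
        if sel.empty:
            raise ValueError(f"no trials at UV level {uv_level}")
        return np.concatenate([
            self.frames[int(r["start"]):int(r["start"]) + int(r["length"])]
            for _, r in sel.iterrows()
        ])


@dataclass
class Roi:
    """A connected pixel mask with its traces and tuning."""

    mask: np.ndarray              # (H, W) bool
    peak: tuple[int, int]         # (row, col) of the seed maximum
    dff_traces: np.ndarray | None = None   # (n_trials, n_frames)
    tuning: TuningCurve | None = None
    polarity: str | None = None
    valid: bool = True

    @property
    def size(self) -> int:
        return int(self.mask.sum())


def _binarize(img) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=float)
    return (img > threshold_otsu(img)).astype(float)


def _wrapped_lags(n) -> np.ndarray:
    """FFT lag values mapped to signed shifts in (−n/2, n/2]."""
    lags = np.arange(n)
    return np.where(lags > n // 2, lags - n, lags)


def align(movie: Movie, template_uv, max_shift=32, reject_threshold=25):
    """Rigid, integer-pixel alignment against a binary stimulus template.

    The template is the Otsu-binarized mean image over all frames of the
    ``template_uv`` trials.  For every frame, the signed circular shift
    (|Δ| ≤ ``max_shift`` per axis) maximizing the cross-correlation of the
    binarized frame with the template is found and undone.

    Returns ``(aligned_movie, shifts, rejected)`` where ``shifts`` is the
    (T, 2) array of detected (dy, dx) and ``rejected`` is True when any
    shift component exceeds ``reject_threshold`` (the movie is still
    returned; the caller decides whether to discard it).
    """
    if movie.frames.shape[0] == 0:
        raise ValueError("empty movie")
    template = _binarize(movie.frames_for_level(template_uv).mean(axis=0))
    t_fft = np.conj(np.fft.rfft2(template))
    h, w = template.shape
    ly = _wrapped_lags(h)[:, None]
    lx = _wrapped_lags(w)[None, :]
    allowed = (np.abs(ly) <= max_shift) & (np.abs(lx) <= max_shift)

    frames = movie.frames
    aligned = np.empty_like(frames)
    shifts = np.zeros((frames.shape[0], 2), dtype=int)
    for i, frame in enumerate(frames):
        corr = np.fft.irfft2(np.fft.rfft2(_binarize(frame)) * t_fft, s=(h, w))
        corr = np.where(allowed, corr, -np.inf)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        dy, dx = int(ly[iy, 0]), int(lx[0, ix])
        shifts[i] = (dy, dx)
        aligned[i] = np.roll(frame, (-dy, -dx), axis=(0, 1))

    rejected = bool(np.any(np.abs(shifts) > reject_threshold))
    out = Movie(aligned, movie.frame_rate, movie.trials.copy(),
                movie.stim_onset, movie.expansion_end, movie.hold_end)
    return out, shifts, rejected


def detect_rois(mean_image, fwhm=11.0, min_separation=60, peak_floor=None,
                floor_frac=0.2) -> list[Roi]:
    """Segment column-scale ROIs around smoothed fluorescence peaks.

    The image is Gaussian-smoothed (σ = fwhm / 2√(2 ln 2)); local maxima at
    least ``min_separation`` px apart and above ``peak_floor`` (default:
    mean + 1 SD of the smoothed image) seed a watershed flood fill of the
    inverted smoothed image.  Each ROI is then restricted to pixels whose
    smoothed intensity exceeds the image background (smoothed minimum) by
    at least ``floor_frac`` of its own seed's rise above background, and
    to the connected component containing the seed, so masks are disjoint,
    connected, and not inflated by baseline fluorescence.

    An image with no qualifying peaks yields an empty list.
    """
    img = np.asarray(mean_image, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    smoothed = ndi.gaussian_filter(img, sigma)
    if smoothed.max() == smoothed.min():
        return []
    if peak_floor is None:
        peak_floor = smoothed.mean() + smoothed.std()
    peaks = peak_local_max(smoothed, min_distance=int(round(min_separation)),
                           threshold_abs=peak_floor, exclude_border=False)
    if peaks.shape[0] == 0:
        return []

    markers = np.zeros(img.shape, dtype=int)
    for j, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = j
    territories = watershed(-smoothed, markers)

    rois = []
    background = smoothed.min()
    for j, (py, px) in enumerate(peaks, start=1):
        stop = background + floor_frac * (smoothed[py, px] - background)
        mask = (territories == j) & (smoothed >= stop)
        comps = cc_label(mask)
        mask = comps == comps[py, px]
        rois.append(Roi(mask=mask, peak=(int(py), int(px))))
    return rois


def dff(movie: Movie, roi: Roi, baseline_window=1.5) -> np.ndarray:
    """Per-trial ΔF/F₀ traces for one ROI.

    F₀ is the mean mask fluorescence over the ``baseline_window`` seconds
    preceding stimulus onset.  A non-positive F₀ marks the ROI invalid and
    yields NaN traces for the affected trials.
    """
    t = movie.trial_times
    b_idx = (t >= movie.stim_onset - baseline_window) & (t < movie.stim_onset)
    if not b_idx.any():
        raise ValueError("trial does not cover the pre-stimulus baseline window")
    traces = np.empty((movie.n_trials, movie.trial_length))
    for i in range(movie.n_trials):
        f = movie.trial_frames(i)[:, roi.mask].mean(axis=1)
        f0 = f[b_idx].mean()
        if f0 <= 0:
            roi.valid = False
            traces[i] = np.nan
        else:
            traces[i] = (f - f0) / f0
    roi.dff_traces = traces
    return traces


def _event_window(movie: Movie, cell_class, n_frames=2):
    event = movie.hold_end if cell_class == "Dm9" else movie.expansion_end
    i0 = int(np.searchsorted(movie.trial_times, event, side="left"))
    if i0 + n_frames > movie.trial_length:
        raise ValueError("response window falls outside the recorded trial")
    return i0, i0 + n_frames


def roi_metric(trace, movie: Movie, cell_class="T4", blank_response=0.0) -> float:
    """Scalar response of one trial: mean ΔF/F₀ over the two frames after
    the designated event (full disc expansion; return-to-green for Dm9).

    ``blank_response`` is subtracted from the result — used for ON-edge
    control stimuli, where the response to the screen blanking before the
    edges appear is removed.
    """
    i0, i1 = _event_window(movie, cell_class)
    trace = np.asarray(trace, dtype=float)
    if trace.size != movie.trial_length:
        raise ValueError("trace length does not match the trial length")
    return float(trace[i0:i1].mean() - blank_response)


def build_tuning(movie: Movie, traces, label="", cell_class="T4",
                 blank_response=0.0) -> TuningCurve:
    """Reduce per-trial ΔF/F₀ traces to a metric-vs-UV tuning curve."""
    traces = np.asarray(traces, dtype=float)
    per_level: dict[float, list[float]] = {}
    for i, row in movie.trials.reset_index(drop=True).iterrows():
        m = roi_metric(traces[i], movie, cell_class, blank_response)
        per_level.setdefault(float(row["uv_level"]), []).append(m)
    levels = sorted(per_level)
    return TuningCurve(np.array(levels), [np.array(per_level[u]) for u in levels],
                       label=label)


def _reference_mean(curve: TuningCurve, reference_levels) -> float:
    lo, hi = reference_levels
    sel = (curve.uv_levels >= lo) & (curve.uv_levels <= hi)
    if not sel.any():
        raise ValueError(f"tuning curve has no levels in the reference range {reference_levels}")
    return float(curve.mean_response[sel].mean())


def threshold_responsive(rois, polarity, threshold, reference_levels=None) -> list[Roi]:
    """Keep ROIs whose mean metric over the polarity's reference UV levels
    reaches ``threshold``."""
    if reference_levels is None:
        reference_levels = REFERENCE_LEVELS[polarity]
    kept = []
    for roi in rois:
        if roi.tuning is None:
            raise ValueError("ROI has no tuning curve; run build_tuning first")
        if _reference_mean(roi.tuning, reference_levels) >= threshold:
            kept.append(roi)
    return kept


def roi_isoluminance(curve: TuningCurve, polarity) -> IsoluminanceEstimate:
    """Zero crossing of an ROI tuning curve, with polarity-specific scan.

    OFF cells respond to the disc when UV is dim, so the curve is scanned
    upward from UV = 0 for the first transition to a negative response; ON
    cells are scanned downward from UV = 15.  The crossing is linearly
    interpolated.  With no sign change anywhere, the level of the curve's
    minimum response is returned (``crossing_found = False``); a curve
    already negative at the scan start returns that end level, capped.
    """
    levels = curve.uv_levels
    if levels.size < 2:
        raise ValueError("need at least 2 UV levels to estimate isoluminance")
    m = curve.mean_response
    if polarity == "OFF":
        order = range(levels.size)
        method = "roi_off"
    elif polarity == "ON":
        order = range(levels.size - 1, -1, -1)
        method = "roi_on"
    else:
        raise ValueError("polarity must be 'ON' or 'OFF'")

    idx = list(order)
    if m[idx[0]] < 0:
        return IsoluminanceEstimate(float(levels[idx[0]]), True, False, method)
    for a, b in zip(idx[:-1], idx[1:]):
        if m[a] >= 0 > m[b]:
            ua, ub = levels[a], levels[b]
            value = float(ua + (ub - ua) * (0.0 - m[a]) / (m[b] - m[a]))
            return IsoluminanceEstimate(value, False, True, method)
    return IsoluminanceEstimate(float(levels[int(np.argmin(m))]), False, False, method)


def threshold_sweep(rois, fly_ids, polarity, thresholds, reference_levels=None) -> pd.DataFrame:
    """Cohort isoluminance as a function of the responsiveness threshold.

    For each threshold, unresponsive ROIs are dropped, per-ROI estimates are
    averaged within fly, and the across-fly mean ± SEM and fly count are
    reported — the stability diagnostic for choosing the cutoff.
    """
    rois = list(rois)
    fly_ids = list(fly_ids)
    if len(rois) != len(fly_ids):
        raise ValueError("need one fly id per ROI")
    rows = []
    for thr in np.atleast_1d(thresholds):
        per_fly: dict[object, list[float]] = {}
        for roi, fly in zip(rois, fly_ids):
            if roi.tuning is None:
                raise ValueError("ROI has no tuning curve")
            if _reference_mean(roi.tuning, reference_levels or REFERENCE_LEVELS[polarity]) >= thr:
                per_fly.setdefault(fly, []).append(roi_isoluminance(roi.tuning, polarity).value)
        fly_means = np.array([np.mean(v) for v in per_fly.values()])
        rows.append({
            "threshold": float(thr),
            "mean_isoluminance": float(fly_means.mean()) if fly_means.size else np.nan,
            "sem": float(fly_means.std(ddof=1) / np.sqrt(fly_means.size)) if fly_means.size > 1 else np.nan,
            "n_flies": int(fly_means.size),
            "n_rois": int(sum(len(v) for v in per_fly.values())),
        })
    return pd.DataFrame(rows)


@dataclass
class AggregateResult:
    """Two-level average of per-ROI isoluminance estimates."""

    per_fly: dict
    grand_mean: float
    population: IsoluminanceEstimate | None = None


def aggregate(estimates, per_fly_curves=None, polarity=None,
              expected_flies=None) -> AggregateResult:
    """ROIs → fly means → grand mean, with every fly weighted equally.

    ``estimates`` is a sequence of ``(fly_id, value)``.  If per-fly mean
    tuning curves are supplied (all on the same UV levels) the population
    isoluminance — the crossing of the across-fly mean curve — is computed
    too.  Flies listed in ``expected_flies`` but contributing no surviving
    ROI are excluded with a warning.
    """
    per_fly: dict[object, list[float]] = {}
    for fly, value in estimates:
        per_fly.setdefault(fly, []).append(float(value))
    if not per_fly:
        raise ValueError("no estimates to aggregate")
    if expected_flies is not None:
        missing = sorted(set(expected_flies) - set(per_fly), key=str)
        if missing:
            warnings.warn(f"flies with no surviving ROIs excluded: {missing}", stacklevel=2)
    fly_means = {fly: float(np.mean(v)) for fly, v in per_fly.items()}
    grand = float(np.mean(list(fly_means.values())))

    population = None
    if per_fly_curves is not None:
        if polarity is None:
            raise ValueError("polarity is required to compute the population isoluminance")
        curves = list(per_fly_curves)
        levels = curves[0].uv_levels
        for c in curves[1:]:
            if not np.array_equal(c.uv_levels, levels):
                raise ValueError("per-fly curves must share UV levels")
        mean_curve = TuningCurve(
            levels,
            [np.array([c.mean_response[i] for c in curves]) for i in range(levels.size)],
            label="population",
        )
        population = roi_isoluminance(mean_curve, polarity)
    return AggregateResult(fly_means, grand, population)


@dataclass
class PipelineResult:
    """Everything one fly's movie produces on its way to an isoluminance."""

    rois: list
    estimates: list           # (roi_index, IsoluminanceEstimate) for kept ROIs
    fly_curve: TuningCurve | None
    shifts: np.ndarray
    rejected: bool


def run_pipeline(movie: Movie, polarity, template_uv=None, threshold=0.05,
                 fwhm=11.0, min_separation=60, cell_class="T4",
                 max_shift=32, reject_threshold=25) -> PipelineResult:
    """Full single-fly analysis: align → detect → ΔF/F₀ → metric →
    threshold → per-ROI isoluminance.

    ``fly_curve`` is the mean tuning curve over this fly's kept ROIs (the
    per-fly input to the population isoluminance).  A movie rejected for
    excessive movement returns no ROIs or estimates.
    """
    if template_uv is None:
        template_uv = 15 if polarity == "ON" else 0
    aligned, shifts, rejected = align(movie, template_uv, max_shift, reject_threshold)
    if rejected:
        return PipelineResult([], [], None, shifts, True)

    mean_img = aligned.frames_for_level(template_uv).mean(axis=0)
    rois = detect_rois(mean_img, fwhm=fwhm, min_separation=min_separation)
    for roi in rois:
        traces = dff(aligned, roi)
        roi.polarity = polarity
        roi.tuning = build_tuning(aligned, traces, cell_class=cell_class)
    rois = [r for r in rois if r.valid]
    kept = threshold_responsive(rois, polarity, threshold)
    kept_ids = {id(r) for r in kept}
    estimates = [(i, roi_isoluminance(r.tuning, polarity))
                 for i, r in enumerate(rois) if id(r) in kept_ids]

    fly_curve = None
    if kept:
        levels = kept[0].tuning.uv_levels
        fly_curve = TuningCurve(
            levels,
            [np.array([r.tuning.mean_response[i] for r in kept]) for i in range(levels.size)],
            label="fly_mean",
        )
    return PipelineResult(rois, estimates, fly_curve, shifts, False)
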