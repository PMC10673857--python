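"""Behavioral ΔWBA analysis: trial folding, response metrics, and
isoluminance estimation from tuning curves.

A tethered fly's turning response (ΔWBA, the left-minus-right wing-beat
amplitude difference) is recorded at 500 Hz while UV/green stimuli of
varying UV intensity (integer levels 0–15 at fixed, calibrated green) are
displayed.  Responses to mirror-image stimulus pairs (clockwise vs
counterclockwise edge rotation, or discs on the right vs left) are folded
together with the mirrored trials sign-inverted.  A scalar response metric
per trial — the mean ΔWBA in the 100 ms after a looming disc has fully
expanded, or over the full 2 s of a competing-edge stimulus — produces a
tuning curve of response versus UV level.  The behavioral isoluminance is
the zero crossing of that curve: the first UV level, scanning upward from
0, at which the mean response becomes positive, located by linear
interpolation between adjacent tested levels.

For the compact competing-motion protocol, only UV levels 3–9 are shown
and estimates are capped at the range ends.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TuningCurve",
    "IsoluminanceEstimate",
    "fold_trials",
    "disc_metric",
    "edge_metric",
    "estimate_isoluminance",
    "population_curve",
    "tuning_from_recording",
    "INVERTED_ROTATIONS",
]

#: Trial rotation/side labels whose traces are sign-inverted before pooling.
INVERTED_ROTATIONS = frozenset({"ccw", "left"})
_UPRIGHT_ROTATIONS = frozenset({"cw", "right"})


@dataclass
class TuningCurve:
    """Per-UV-level response values for one fly (or one ROI, or a population).

    ``per_trial[i]`` holds the individual trial (or per-fly) values at
    ``uv_levels[i]``; ``mean_response`` is their mean.  ``level_range_cap``
    marks curves from a restricted-range protocol whose estimates must be
    capped at the range ends.
    """

    uv_levels: np.ndarray
    per_trial: list[np.ndarray]
    label: str = ""
    level_range_cap: tuple[float, float] | None = None

    def __post_init__(self):
        self.uv_levels = np.asarray(self.uv_levels, dtype=float)
        if self.uv_levels.ndim != 1 or len(self.uv_levels) == 0:
            raise ValueError("uv_levels must be a non-empty 1-D sequence")
        if np.any(np.diff(self.uv_levels) <= 0):
            raise ValueError("uv_levels must be strictly increasing")
        if len(self.per_trial) != len(self.uv_levels):
            raise ValueError("per_trial must have one entry per UV level")
        self.per_trial = [np.atleast_1d(np.asarray(v, dtype=float)) for v in self.per_trial]
        if any(v.size == 0 for v in self.per_trial):
            raise ValueError("per_trial entries must be non-empty")

    @property
    def mean_response(self) -> np.ndarray:
        return np.array([v.mean() for v in self.per_trial])

    @classmethod
    def from_means(cls, uv_levels, means, label="", level_range_cap=None) -> "TuningCurve":
        """Build a curve directly from per-level mean responses."""
        means = np.asarray(means, dtype=float)
        return cls(np.asarray(uv_levels), [np.array([m]) for m in means], label, level_range_cap)


@dataclass(frozen=True)
class IsoluminanceEstimate:
    """Zero-crossing estimate of a tuning curve, in UV-level units.

    ``capped`` marks estimates pinned to a range end (no usable crossing
    inside the tested range, or a compact-protocol cap); ``crossing_found``
    is False when no interpolated sign change existed.
    """

    value: float
    capped: bool
    crossing_found: bool
    method: str


def fold_trials(recording) -> dict[tuple[str, int], np.ndarray]:
    """Pool mirror-image trial pairs, sign-inverting the mirrored ones.

    Counterclockwise (or left-side) traces are multiplied by −1 and pooled
    with the clockwise (right-side) traces, so each stimulus condition's
    trial count doubles.  Returns ``{(protocol, uv_level): (n_trials, T)}``.

    Raises ``ValueError`` listing the orphan trials if the two rotation
    groups of any condition are of unequal size.
    """
    groups: dict[tuple[str, int], dict[str, list[np.ndarray]]] = {}
    for trial in recording.trials:
        key = (trial.protocol, trial.uv_level)
        bucket = groups.setdefault(key, {"keep": [], "invert": []})
        if trial.rotation in INVERTED_ROTATIONS:
            bucket["invert"].append(np.asarray(trial.trace, dtype=float))
        elif trial.rotation in _UPRIGHT_ROTATIONS:
            bucket["keep"].append(np.asarray(trial.trace, dtype=float))
        else:
            raise ValueError(f"unknown rotation label {trial.rotation!r}")

    orphans = [
        f"{key}: {len(b['keep'])} cw/right vs {len(b['invert'])} ccw/left"
        for key, b in groups.items()
        if len(b["keep"]) != len(b["invert"])
    ]
    if orphans:
        raise ValueError("unmatched rotation pairs: " + "; ".join(sorted(orphans)))

    return {
        key: np.vstack(b["keep"] + [-tr for tr in b["invert"]])
        for key, b in groups.items()
    }


def _window_mean(trace, start_time, duration, sample_rate) -> float:
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(start_time * sample_rate))
    i1 = i0 + int(round(duration * sample_rate))
    if i0 < 0 or i1 > trace.size or i1 <= i0:
        raise ValueError(
            f"response window [{start_time}, {start_time + duration}) s "
            f"falls outside the {trace.size / sample_rate:.3f} s trace"
        )
    return float(trace[i0:i1].mean())


def disc_metric(trace, expansion_end_time, sample_rate=500.0) -> float:
    """Mean ΔWBA in the 100 ms after the disc has fully expanded.

    The window is half-open, ``[expansion_end, expansion_end + 0.1)``
    (50 samples at 500 Hz).
    """
    return _window_mean(trace, expansion_end_time, 0.1, sample_rate)


def edge_metric(trace, stim_start, stim_duration=2.0, sample_rate=500.0) -> float:
    """Mean ΔWBA over the competing-edge stimulus (2 s by default)."""
    return _window_mean(trace, stim_start, stim_duration, sample_rate)


def estimate_isoluminance(curve: TuningCurve, method="behavior_increasing") -> IsoluminanceEstimate:
    """Behavioral isoluminance: first upward zero crossing of the curve.

    Scanning UV levels in increasing order, the estimate is the linearly
    interpolated level at which the mean response first becomes greater
    than zero (lower side of the crossing may equal zero exactly).  A curve
    that is already positive at its first level returns that level, capped;
    a curve with no crossing returns the last level, capped.  Curves from a
    restricted-range protocol additionally clamp to ``level_range_cap``.
    """
    levels = curve.uv_levels
    if levels.size < 2:
        raise ValueError("need at least 2 UV levels to estimate isoluminance")
    m = curve.mean_response

    if m[0] > 0:
        value, capped, found = float(levels[0]), True, False
    else:
        for i in range(levels.size - 1):
            if m[i] <= 0 < m[i + 1]:
                u1, u2 = levels[i], levels[i + 1]
                value = float(u1 + (u2 - u1) * (0.0 - m[i]) / (m[i + 1] - m[i]))
                capped, found = False, True
                break
        else:
            value, capped, found = float(levels[-1]), True, False

    if curve.level_range_cap is not None:
        lo, hi = curve.level_range_cap
        clipped = float(np.clip(value, lo, hi))
        if clipped != value:
            value, capped = clipped, True
    return IsoluminanceEstimate(value, capped, found, method)


def population_curve(per_fly_curves) -> TuningCurve:
    """Across-fly mean tuning curve, each fly weighted equally.

    ``per_trial`` of the result holds the per-fly mean responses at each
    level, so the population isoluminance is simply
    :func:`estimate_isoluminance` of the returned curve.
    """
    curves = list(per_fly_curves)
    if not curves:
        raise ValueError("no curves supplied")
    levels = curves[0].uv_levels
    for c in curves[1:]:
        if not np.array_equal(c.uv_levels, levels):
            raise ValueError("all curves must share the same UV levels")
    fly_means = np.vstack([c.mean_response for c in curves])  # (n_flies, n_levels)
    caps = {c.level_range_cap for c in curves}
    cap = caps.pop() if len(caps) == 1 else None
    return TuningCurve(
        levels,
        [fly_means[:, i] for i in range(levels.size)],
        label="population",
        level_range_cap=cap,
    )


def tuning_from_recording(recording, protocol, sample_rate=None,
                          expansion_end_time=1.0, edge_duration=2.0) -> TuningCurve:
    """Fold a ΔWBA recording and reduce it to a tuning curve for one protocol.

    Disc protocols use the 100 ms post-expansion window (expansion ends at
    ``expansion_end_time`` seconds after stimulus onset); edge protocols use
    the mean over the whole stimulus.  Compact recordings carry a (3, 9)
    estimate cap.
    """
    sr = float(sample_rate if sample_rate is not None else recording.sample_rate)
    folded = fold_trials(recording)
    items = sorted((uv, traces) for (proto, uv), traces in folded.items() if proto == protocol)
    if not items:
        raise ValueError(f"recording has no trials for protocol {protocol!r}")
    levels = [uv for uv, _ in items]
    if protocol.startswith("disc"):
        per_trial = [
            np.array([disc_metric(tr, expansion_end_time, sr) for tr in traces])
            for _, traces in items
        ]
    else:
        per_trial = [
            np.array([edge_metric(tr, 0.0, edge_duration, sr) for tr in traces])
            for _, traces in items
        ]
    cap = (3.0, 9.0) if getattr(recording, "compact", False) else None
    return TuningCurve(np.asarray(levels, dtype=float), per_trial, label=protocol,
                       level_range_cap=cap)
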