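"""Simulated cohorts: many flies run end-to-end through the analyses.

These are the parameter-recovery workhorses: a behavioral cohort whose
per-fly ON/OFF isoluminances are known, and an imaging validation cohort
in which every planted ROI's zero crossing is fixed at a single UV level
(mirroring the experiment of expanding discs over a UV background, which
pins the true isoluminance at the background intensity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior, imaging, synthetic

__all__ = [
    "behavior_cohort",
    "imaging_validation_cohort",
    "DEFAULT_ROI_CENTERS",
]

#: Planted blob centers (row, col) in a 256 × 256 field, pairwise ≥ 60 px apart.
DEFAULT_ROI_CENTERS = ((64, 64), (64, 192), (192, 128), (192, 32), (32, 150))


def _child_seeds(seed, n):
    """Deterministic per-fly integer seeds below 2**31."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def behavior_cohort(n_flies=10, i_on=4.5, i_off=9.2, amplitude=1.0,
                    noise_sd=0.1, n_trials=5, seed=0, protocol_pair=("edges_on", "edges_off"),
                    slope=0.5) -> pd.DataFrame:
    """Simulate and analyze a behavioral cohort.

    Each fly contributes one ON and one OFF competing-edge recording (or
    the compact combined protocol when ``protocol_pair == ('edges_compact',)``);
    returns one row per fly with the estimated ``i_on``/``i_off`` and cap
    flags.  ``noise_sd`` is in units of ``amplitude`` × 1 (per-trial SD).
    """
    seeds = _child_seeds(seed, n_flies * len(protocol_pair))
    rows = []
    for fly in range(n_flies):
        row = {"fly": fly}
        for j, protocol in enumerate(protocol_pair):
            gt = synthetic.GroundTruth(i_on=i_on, i_off=i_off, amplitude=amplitude,
                                       noise_sd=noise_sd, n_trials=n_trials,
                                       seed=int(seeds[fly * len(protocol_pair) + j]))
            rec = synthetic.simulate_behavior(gt, protocol, slope=slope, fly_id=fly)
            sub = ("edges_on", "edges_off") if protocol == "edges_compact" else (protocol,)
            for proto in sub:
                curve = behavior.tuning_from_recording(rec, proto)
                est = behavior.estimate_isoluminance(curve)
                tag = "i_on" if proto == "edges_on" else "i_off"
                row[tag] = est.value
                row[f"{tag}_capped"] = est.capped
        rows.append(row)
    return pd.DataFrame(rows)


def imaging_validation_cohort(polarity, true_iso, n_flies=8, n_rois=3, seed=0, *,
                              kinetics_tau=0.3, jitter_sd=2.0, noise_sd=4.0,
                              n_trials_per_level=3, uv_levels=None, threshold=0.05,
                              min_separation=60, cell_class="T4"):
    """Simulate an imaging cohort with one unambiguous planted isoluminance
    and recover it with the full pipeline.

    Every planted ROI of every fly has the same polarity and true zero
    crossing ``true_iso``.  Each fly's movie is aligned, segmented,
    converted to ΔF/F₀ tuning curves, thresholded, and reduced to per-ROI
    isoluminance estimates; flies rejected for excessive movement are
    dropped.  Returns the :class:`~chromamotion.imaging.AggregateResult`
    (grand mean across flies, per-fly means, population isoluminance) and
    the per-fly pipeline results.
    """
    if n_rois > len(DEFAULT_ROI_CENTERS):
        raise ValueError(f"at most {len(DEFAULT_ROI_CENTERS)} planted ROIs supported")
    centers = DEFAULT_ROI_CENTERS[:n_rois]
    seeds = _child_seeds(seed, n_flies)
    estimates = []
    per_fly_curves = []
    results = {}
    for fly in range(n_flies):
        syn = synthetic.simulate_movie(
            [(c, polarity, true_iso) for c in centers],
            uv_levels=uv_levels, kinetics_tau=kinetics_tau, jitter_sd=jitter_sd,
            noise_sd=noise_sd, seed=int(seeds[fly]),
            n_trials_per_level=n_trials_per_level,
        )
        res = imaging.run_pipeline(syn.movie, polarity, threshold=threshold,
                                   min_separation=min_separation, cell_class=cell_class)
        results[fly] = res
        if res.rejected:
            continue
        estimates.extend((fly, est.value) for _, est in res.estimates)
        if res.fly_curve is not None:
            per_fly_curves.append(res.fly_curve)
    agg = imaging.aggregate(estimates, per_fly_curves=per_fly_curves,
                            polarity=polarity, expected_flies=range(n_flies))
    return agg, results
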