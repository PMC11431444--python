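"""In silico local field potentials and evoked responses.

Precision-weighted prediction errors play the role of superficial-
pyramidal-cell activity: the weighted percept (outcome) error is the LFP
of the first (sensory) region and the weighted lobe-cause error that of
the second (higher) region.  Epochs are extracted on a peristimulus
window of -5..+25 samples around each lobe switch, upsampled 10x by cubic
interpolation, split by transition direction -- "expected" for switches
into the prior-favoured +1 lobe (-1 -> +1), "unexpected" for switches out
of it (+1 -> -1) -- and averaged over repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .filtering import PosteriorTrajectory
from .speaker import LobeSchedule

__all__ = ["ERPResult", "extract_lfps", "peristimulus_erp", "baseline_return_time"]


class EmptyConditionError(ValueError):
    """No usable switch epochs for one of the transition directions."""


@dataclass(frozen=True)
class ERPResult:
    """Peristimulus-averaged error waveforms per region and direction.

    Waveforms are sampled on ``peristimulus_times`` (10x upsampled by
    default, so 301 points for the -5..+25 window).  ``n_expected`` /
    ``n_unexpected`` count the averaged epochs; ``n_dropped`` the switches
    rejected for clipped or overlapping windows.
    """

    peristimulus_times: np.ndarray
    region1_expected: np.ndarray
    region1_unexpected: np.ndarray
    region2_expected: np.ndarray
    region2_unexpected: np.ndarray
    n_expected: int
    n_unexpected: int
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, r1, r2 in (
            ("expected", self.region1_expected, self.region2_expected),
            ("unexpected", self.region1_unexpected, self.region2_unexpected),
        ):
            for region, wave in (("region1", r1), ("region2", r2)):
                rows.append(
                    pd.DataFrame(
                        {
                            "condition": cond,
                            "region": region,
                            "peristimulus_time": self.peristimulus_times,
                            "amplitude": wave,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_lfps(posterior: PosteriorTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """The two simulated LFP series of a posterior trajectory.

    Region 1 is the precision-weighted percept (outcome) error; region 2
    the precision-weighted lobe-cause error.  The zeroth generalized
    order of each weighted error stream is used.
    """
    region1 = posterior.weighted_outcome_error[:, 0]
    if posterior.weighted_cause_error.shape[1] == 0:
        raise ValueError("posterior has no cause level; no region-2 LFP")
    region2 = posterior.weighted_cause_error[:, 0]
    return region1, region2


def peristimulus_erp(
    lfps: tuple[np.ndarray, np.ndarray],
    schedule: LobeSchedule,
    window: tuple[int, int] = (-5, 25),
    upsample: int = 10,
) -> ERPResult:
    """Average peristimulus epochs of the two LFPs around lobe switches.

    Per switch the (window[1]-window[0]+1)-sample epoch is extracted,
    upsampled ``upsample``x by cubic interpolation, grouped by transition
    direction and averaged within groups.  Epochs whose window crosses the
    series boundary or contains another switch are dropped and counted.
    A direction with no clean epochs (e.g. a single-switch schedule)
    yields NaN waveforms and a zero epoch count for that condition; only
    a schedule with no usable epochs at all is an error.
    """
    region1, region2 = (np.asarray(s, dtype=float) for s in lfps)
    if region1.shape != region2.shape or region1.ndim != 1:
        raise ValueError("LFPs must be two equal-length 1-D series")
    n = len(region1)
    if len(schedule) != n:
        raise ValueError("schedule length must match LFP length")
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    switches = schedule.switch_indices
    if len(switches) == 0:
        raise EmptyConditionError("schedule contains no lobe switches")

    coarse = np.arange(lo, hi + 1, dtype=float)
    fine = np.linspace(lo, hi, upsample * (hi - lo) + 1)
    epochs = {("expected"): ([], []), ("unexpected"): ([], [])}
    dropped = 0
    switch_set = set(int(s) for s in switches)
    for s in switches:
        a, b = s + lo, s + hi
        if a < 0 or b >= n:
            dropped += 1
            continue
        # reject epochs contaminated by a second switch inside the window
        others = [t for t in switch_set if t != s and a <= t <= b]
        if others:
            dropped += 1
            continue
        direction = "expected" if schedule.values[s] > 0 else "unexpected"
        for series, bucket in zip((region1, region2), epochs[direction]):
            seg = series[a : b + 1]
            bucket.append(CubicSpline(coarse, seg)(fine))

    if not (epochs["expected"][0] or epochs["unexpected"][0]):
        raise EmptyConditionError("no clean epochs in either direction")

    def _avg(bucket):
        return (
            np.mean(bucket, axis=0) if bucket else np.full(len(fine), np.nan)
        )

    r1_exp, r2_exp = (_avg(b) for b in epochs["expected"])
    r1_une, r2_une = (_avg(b) for b in epochs["unexpected"])
    return ERPResult(
        peristimulus_times=fine,
        region1_expected=r1_exp,
        region1_unexpected=r1_une,
        region2_expected=r2_exp,
        region2_unexpected=r2_une,
        n_expected=len(epochs["expected"][0]),
        n_unexpected=len(epochs["unexpected"][0]),
        n_dropped=dropped,
    )


def baseline_return_time(
    times: np.ndarray,
    wave: np.ndarray,
    threshold: float = 0.10,
) -> float:
    """Post-switch time at which the response first falls back to baseline.

    The baseline is the mean over the pre-switch part of the window; the
    deviation is |wave - baseline|.  Returns the earliest time at or after
    the post-switch peak deviation at which the deviation drops below
    ``threshold`` times that peak (inf if it never does within the
    window).  Smaller values mean faster adaptation.
    """
    times = np.asarray(times, dtype=float)
    wave = np.asarray(wave, dtype=float)
    pre = times < 0
    post = ~pre
    dev = np.abs(wave - wave[pre].mean())
    t_post = times[post]
    dev_post = dev[post]
    peak = dev_post.max()
    if peak == 0:
        return 0.0
    k_peak = int(np.argmax(dev_post))
    idx = np.flatnonzero(dev_post[k_peak:] <= threshold * peak)
    return float(t_post[k_peak + idx[0]]) if len(idx) else float("inf")
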