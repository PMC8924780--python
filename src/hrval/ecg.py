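"""Criterion-side ECG processing: R-peak detection and 1 Hz reduction.

The criterion chain is: voltage trace -> R peaks -> RR intervals ->
instantaneous HR (60/RR, one value per interval, timestamped at the
interval's end beat) -> 1 Hz series by within-second averaging.

The detector is a Pan-Tompkins-style chain: band-pass 5-15 Hz,
differentiate, square, moving-window integrate (150 ms), adaptive
signal/noise threshold with a 200 ms refractory period, then peak-time
refinement on the raw trace. Pipelines that already have trusted beat
times (simulated ground truth, or manually corrected annotations) can
skip the detector and enter at :func:`rr_to_hr`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .series import RR_MAX_S, RR_MIN_S, BeatSequence, HRSeries

__all__ = ["detect_r_peaks", "rr_to_hr", "beats_to_1hz", "criterion_to_1hz", "InstantHR"]

log = logging.getLogger(__name__)

MIN_RATE_HZ = 128.0
REFRACTORY_S = 0.2
EDGE_GUARD_S = 0.25
_BANDPASS_HZ = (5.0, 15.0)
_MWI_WINDOW_S = 0.150


def detect_r_peaks(trace: np.ndarray, rate_hz: float) -> BeatSequence:
    """Detect R peaks in a single-lead ECG voltage trace.

    Returns peak times in seconds. A 200 ms refractory period is
    enforced and no peak is reported within the first or last 250 ms of
    the trace. An all-constant trace yields an empty sequence.

    Raises
    ------
    ValueError
        If ``rate_hz`` < 128 (QRS undersampled) or the trace is shorter
        than 2 s.
    """
    if rate_hz < MIN_RATE_HZ:
        raise ValueError(f"sampling rate must be >= {MIN_RATE_HZ} Hz")
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 2 * rate_hz:
        raise ValueError("trace must be at least 2 s long")
    if np.ptp(trace) == 0.0:
        return BeatSequence(peak_times=np.array([]))

    sos = signal.butter(2, _BANDPASS_HZ, btype="bandpass", fs=rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trace)
    deriv = np.gradient(filtered) * rate_hz
    squared = deriv**2
    win = max(int(round(_MWI_WINDOW_S * rate_hz)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    min_dist = max(int(round(REFRACTORY_S * rate_hz)), 1)
    cand, _ = signal.find_peaks(integrated, distance=min_dist)
    if len(cand) == 0:
        return BeatSequence(peak_times=np.array([]))
    amps = integrated[cand]

    # adaptive running signal/noise peak estimates (offline init from the
    # candidate amplitude distribution)
    spki = float(np.percentile(amps, 90))
    npki = 0.1 * spki
    accepted: list[int] = []
    for idx, a in zip(cand, amps):
        thr = npki + 0.25 * (spki - npki)
        if a > thr:
            accepted.append(idx)
            spki = 0.125 * a + 0.875 * spki
        else:
            npki = 0.125 * a + 0.875 * npki
    if not accepted:
        return BeatSequence(peak_times=np.array([]))

    # refine to the raw R apex near each integrated-envelope peak
    half = int(round(0.10 * rate_hz))
    refined: list[int] = []
    for idx in accepted:
        lo = max(idx - half, 0)
        hi = min(idx + half + 1, len(trace))
        refined.append(lo + int(np.argmax(trace[lo:hi])))
    refined = sorted(set(refined))

    # refractory dedup on refined times, keeping the larger apex
    kept: list[int] = []
    for idx in refined:
        if kept and (idx - kept[-1]) < min_dist:
            if trace[idx] > trace[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)

    times = np.asarray(kept, dtype=float) / rate_hz
    t_end = len(trace) / rate_hz
    times = times[(times >= EDGE_GUARD_S) & (times <= t_end - EDGE_GUARD_S)]
    return BeatSequence(peak_times=times)


@dataclass(frozen=True)
class InstantHR:
    """Instantaneous HR samples, one per retained RR interval.

    Each sample is timestamped at the interval's end beat; ``start_s`` /
    ``end_s`` keep the spanning interval available for the empty-second
    fill rule in :func:`beats_to_1hz`. ``n_dropped`` counts RR intervals
    rejected by the plausibility window.
    """

    start_s: np.ndarray
    end_s: np.ndarray
    hr_bpm: np.ndarray
    n_dropped: int = 0

    @property
    def t_s(self) -> np.ndarray:
        return self.end_s

    def __len__(self) -> int:
        return len(self.hr_bpm)


def rr_to_hr(
    beats: BeatSequence, rr_window_s: tuple[float, float] = (RR_MIN_S, RR_MAX_S)
) -> InstantHR:
    """Convert beat times to instantaneous HR: ``hr_k = 60 / RR_k`` bpm.

    RR intervals outside the open plausibility window (default
    0.25-3.0 s, i.e. 20-240 bpm) are dropped and counted — the automatic
    stand-in for manual rejection of evidently wrong beats.
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 peaks to form an RR interval")
    rr = beats.rr_intervals
    lo, hi = rr_window_s
    keep = (rr > lo) & (rr < hi)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("rr_to_hr: dropped %d implausible RR interval(s)", n_dropped)
    return InstantHR(
        start_s=beats.peak_times[:-1][keep],
        end_s=beats.peak_times[1:][keep],
        hr_bpm=60.0 / rr[keep],
        n_dropped=n_dropped,
    )


def beats_to_1hz(inst: InstantHR, source_id: str = "criterion") -> HRSeries:
    """Reduce instantaneous HR samples to a 1 Hz series.

    Second bucket ``[s, s+1)``: if one or more HR samples fall in it
    (interval end beats), take their arithmetic mean — the usual case at
    HR > 60 bpm. If none do (HR < 60 bpm, the interval outlasts the
    second), use the instantaneous HR of the RR interval spanning the
    second. Seconds covered by neither rule — before the first interval,
    after the last, or inside a plausibility-rejection gap — are masked
    invalid.
    """
    if len(inst) == 0:
        raise ValueError("no instantaneous HR samples")
    grid_start = float(np.floor(inst.start_s[0]))
    grid_end = float(np.ceil(inst.end_s[-1]))
    n = int(grid_end - grid_start)
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    bucket = np.floor(inst.end_s - grid_start).astype(int)
    in_range = (bucket >= 0) & (bucket < n)
    sums = np.bincount(bucket[in_range], weights=inst.hr_bpm[in_range], minlength=n)
    counts = np.bincount(bucket[in_range], minlength=n)
    has = counts > 0
    values[has] = sums[has] / counts[has]
    mask[has] = True
    # fill empty seconds from the interval containing the second's midpoint
    empty = np.flatnonzero(~has)
    if len(empty):
        mids = grid_start + empty + 0.5
        k = np.searchsorted(inst.start_s, mids, side="right") - 1
        ok = (k >= 0) & (mids < inst.end_s[np.clip(k, 0, None)])
        values[empty[ok]] = inst.hr_bpm[k[ok]]
        mask[empty[ok]] = True
    return HRSeries(start_s=grid_start, values=values, mask=mask, source_id=source_id)


def criterion_to_1hz(beats: BeatSequence, source_id: str = "criterion") -> HRSeries:
    """Full criterion reduction: beats -> instantaneous HR -> 1 Hz series."""
    return beats_to_1hz(rr_to_hr(beats), source_id=source_id)
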