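"""Device-side resampling to the common 1 Hz grid.

Two device families, two rules:

* sparse streams (one HR value every few seconds, as training-mode
  fitness trackers emit): each grid second takes the value observed in
  that second if any; otherwise the **next** available observation's
  value (backward fill). This next-value imputation is unusual — most
  pipelines carry the previous value forward — but it is the convention
  this pipeline standardizes on for sparse wearable exports. Trailing
  seconds with no later observation carry the last value forward, the
  only non-extrapolating completion.
* oversampled streams (several samples per second, as smart-watch
  sensor APIs emit): within-second arithmetic averaging; empty seconds
  are masked invalid.
"""

from __future__ import annotations

import numpy as np

from .series import HRSeries, SampleStream

__all__ = ["upsample_next_value", "downsample_average", "to_1hz"]


def _check_span(span: tuple[float, float]) -> tuple[int, int]:
    start, end = int(np.floor(span[0])), int(np.ceil(span[1]))
    if end - start < 2:
        raise ValueError("span must cover at least 2 s")
    return start, end


def upsample_next_value(stream: SampleStream, span: tuple[float, float]) -> HRSeries:
    """Impute a sparse stream onto the 1 Hz grid over ``[start, end)``.

    Per grid second: the value observed in that second (the last one if
    several), else the next available observation's value, else — for
    trailing seconds — the last observed value carried forward. Only
    observations inside the span participate; a span containing no
    observation at all yields a fully masked series.
    """
    if len(stream) == 0:
        raise ValueError("empty sample stream")
    start, end = _check_span(span)
    n = end - start
    t, hr = stream.t_s, stream.hr_bpm
    in_span = (t >= start) & (t < end)
    t, hr = t[in_span], hr[in_span]
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    if len(t) == 0:
        return HRSeries(start_s=float(start), values=values, mask=mask,
                        source_id=stream.device_id)
    sec = np.floor(t - start).astype(int)
    # last observation per second wins (timestamps are non-decreasing)
    values[sec] = hr
    observed = np.zeros(n, dtype=bool)
    observed[sec] = True
    # backward fill from the next observed second, then carry the last forward
    obs_idx = np.flatnonzero(observed)
    nxt = np.searchsorted(obs_idx, np.arange(n), side="left")
    fill_from = obs_idx[np.minimum(nxt, len(obs_idx) - 1)]
    values = values[fill_from]
    mask[:] = True
    return HRSeries(start_s=float(start), values=values, mask=mask,
                    source_id=stream.device_id)


def downsample_average(stream: SampleStream, span: tuple[float, float]) -> HRSeries:
    """Average an oversampled stream within each 1 Hz bucket ``[s, s+1)``.

    Seconds containing no sample are masked invalid and skipped by all
    downstream metrics.
    """
    if len(stream) == 0:
        raise ValueError("empty sample stream")
    start, end = _check_span(span)
    n = end - start
    t, hr = stream.t_s, stream.hr_bpm
    in_span = (t >= start) & (t < end)
    t, hr = t[in_span], hr[in_span]
    sec = np.floor(t - start).astype(int)
    sums = np.bincount(sec, weights=hr, minlength=n) if len(t) else np.zeros(n)
    counts = np.bincount(sec, minlength=n) if len(t) else np.zeros(n)
    mask = counts > 0
    values = np.zeros(n)
    values[mask] = sums[mask] / counts[mask]
    return HRSeries(start_s=float(start), values=values, mask=mask,
                    source_id=stream.device_id)


def to_1hz(stream: SampleStream, span: tuple[float, float]) -> HRSeries:
    """Resample by the rule matching the stream's nominal mode."""
    if stream.nominal_mode == "sparse":
        return upsample_next_value(stream, span)
    return downsample_average(stream, span)
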