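"""Signal-driven time alignment of device streams to the criterion.

Consumer wearables run closed-source firmware and cloud pipelines whose
clocks and processing delays are unknown, so absolute timestamps are not
trusted. Instead, each device's 1 Hz series is aligned to the criterion
series by searching integer-second lags and maximizing the Pearson
correlation over the pairwise-valid overlap (a raw cross-correlation
objective is also available; on typical data the two pick the same lag).

Sign convention: a positive ``lag_s`` means the device stream trails the
criterion and must be shifted *earlier* by ``lag_s`` seconds to align.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import HRSeries

__all__ = ["SyncResult", "estimate_lag", "apply_lag"]

DEFAULT_MAX_LAG_S = 60
DEFAULT_MIN_OVERLAP = 30


@dataclass(frozen=True)
class SyncResult:
    lag_s: int
    pcc_at_lag: float
    n_overlap: int
    search_range_s: int
    objective: str = "pcc"


def _paired(ref: HRSeries, dev: HRSeries, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (ref[t], dev[t + lag]) over seconds valid in both."""
    start = max(ref.start_s, dev.start_s - lag)
    end = min(ref.end_s, dev.end_s - lag)
    if end <= start:
        return np.empty(0), np.empty(0)
    ir = int(round(start - ref.start_s))
    idv = int(round(start + lag - dev.start_s))
    n = int(round(end - start))
    m = ref.mask[ir : ir + n] & dev.mask[idv : idv + n]
    return ref.values[ir : ir + n][m], dev.values[idv : idv + n][m]


def estimate_lag(
    ref: HRSeries,
    dev: HRSeries,
    max_lag_s: int = DEFAULT_MAX_LAG_S,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    objective: str = "pcc",
) -> SyncResult:
    """Estimate the device lag by scanning integer-second shifts.

    For every lag in ``[-max_lag_s, +max_lag_s]`` the objective is
    computed over the pairwise-valid overlap; lags with overlap below
    ``min_overlap``, or zero variance in either window under the PCC
    objective, are skipped. Ties are broken by smaller ``|lag|``, then by
    the more negative lag, making the search fully deterministic.

    Raises
    ------
    ValueError
        If every candidate lag is skipped (insufficient overlap or
        constant windows everywhere).
    """
    if objective not in ("pcc", "xcorr"):
        raise ValueError(f"unknown objective {objective!r}")
    best: tuple[float, int, int] | None = None  # (score, |lag|, lag) ordering
    best_stats: tuple[int, float, int] | None = None
    for lag in range(-max_lag_s, max_lag_s + 1):
        x, y = _paired(ref, dev, lag)
        if len(x) < max(min_overlap, 2):
            continue
        if objective == "pcc":
            sx, sy = x.std(), y.std()
            if sx == 0.0 or sy == 0.0:
                continue
            score = float(np.corrcoef(x, y)[0, 1])
            pcc = score
        else:
            # raw cross-correlation, normalized by overlap length so that
            # lags with different overlaps are comparable
            score = float(np.mean(x * y))
            sx, sy = x.std(), y.std()
            pcc = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else np.nan
        key = (score, -abs(lag), -lag)
        if best is None or key > best:
            best = key
            best_stats = (lag, pcc, len(x))
    if best_stats is None:
        raise ValueError(
            "no admissible lag: every candidate shift had insufficient "
            "overlap or an undefined correlation"
        )
    lag, pcc, n = best_stats
    return SyncResult(
        lag_s=lag, pcc_at_lag=pcc, n_overlap=n,
        search_range_s=max_lag_s, objective=objective,
    )


def apply_lag(
    dev: HRSeries, lag_s: int, ref_span: tuple[float, float] | None = None
) -> HRSeries:
    """Shift a device series earlier by the estimated lag.

    Timestamps move by ``-lag_s``; if ``ref_span`` is given, seconds
    falling outside the criterion span after the shift are dropped.
    """
    if abs(lag_s) >= len(dev):
        raise ValueError("lag magnitude must be smaller than the series length")
    shifted = dev.shifted(-float(lag_s))
    if ref_span is not None:
        start = max(shifted.start_s, ref_span[0])
        end = min(shifted.end_s, ref_span[1])
        if end <= start:
            raise ValueError("shift leaves no overlap with the criterion span")
        shifted = shifted.crop(start, end)
    return shifted
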