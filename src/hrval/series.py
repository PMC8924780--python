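"""Core time-series containers shared across the pipeline.

Everything downstream of raw device exports works on a common currency:
a uniformly sampled 1 Hz heart-rate sequence (:class:`HRSeries`) with a
per-second validity mask. Criterion-side beat data live in
:class:`BeatSequence`; raw device exports in :class:`SampleStream`;
aligned, mask-intersected data ready for agreement statistics in
:class:`PairedSeries`.

All timestamps are seconds from recording start (t = 0). Absolute device
clocks are deliberately not trusted; alignment is estimated from the
signals themselves (see :mod:`hrval.sync`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["HRSeries", "BeatSequence", "SampleStream", "PairedSeries"]

RR_MIN_S = 0.25
RR_MAX_S = 3.0


@dataclass(frozen=True)
class HRSeries:
    """Uniformly sampled heart-rate sequence at exactly 1 Hz.

    Parameters
    ----------
    start_s : float
        Time of the first sample, seconds from recording start. Sample k
        covers the half-open second ``[start_s + k, start_s + k + 1)``.
    values : ndarray of float
        Heart rate in bpm, one value per second. Entries where ``mask``
        is False are undefined and ignored by every consumer.
    mask : ndarray of bool
        Per-second validity flags; True = valid.
    source_id : str
        Identifier of the producing device or processing path.
    """

    start_s: float
    values: np.ndarray
    mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.ndim != 1 or values.shape != mask.shape:
            raise ValueError("values and mask must be 1-D arrays of equal length")
        if len(values) < 1:
            raise ValueError("HRSeries must contain at least one second")
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("HR values must be finite wherever mask is valid")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Start time of each one-second bucket."""
        return self.start_s + np.arange(len(self.values), dtype=float)

    @property
    def end_s(self) -> float:
        return self.start_s + len(self.values)

    def shifted(self, dt_s: float) -> "HRSeries":
        """Return a copy with all timestamps shifted by ``dt_s`` seconds."""
        return replace(self, start_s=self.start_s + dt_s)

    def crop(self, start_s: float, end_s: float) -> "HRSeries":
        """Restrict to seconds whose bucket start lies in ``[start_s, end_s)``."""
        t = self.times
        keep = (t >= start_s) & (t < end_s)
        if not keep.any():
            raise ValueError("crop leaves an empty series")
        idx = np.flatnonzero(keep)
        return HRSeries(
            start_s=float(t[idx[0]]),
            values=self.values[idx[0] : idx[-1] + 1],
            mask=self.mask[idx[0] : idx[-1] + 1],
            source_id=self.source_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "hr_bpm": self.values, "valid": self.mask.astype(int)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source_id: str = "") -> "HRSeries":
        t = df["t_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValueError("empty frame")
        if len(t) > 1 and not np.allclose(np.diff(t), 1.0):
            raise ValueError("HRSeries frames must be sampled at exactly 1 Hz")
        mask = (
            df["valid"].to_numpy(dtype=bool)
            if "valid" in df
            else np.isfinite(df["hr_bpm"].to_numpy(dtype=float))
        )
        values = df["hr_bpm"].to_numpy(dtype=float)
        values = np.where(mask, values, 0.0)
        return cls(start_s=float(t[0]), values=values, mask=mask, source_id=source_id)


@dataclass(frozen=True)
class BeatSequence:
    """Ordered R-peak times (seconds) with derived RR intervals."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("peak_times must be 1-D")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times", t)

    def __len__(self) -> int:
        return len(self.peak_times)

    @property
    def rr_intervals(self) -> np.ndarray:
        """Consecutive RR intervals in seconds (length ``n_peaks - 1``)."""
        return np.diff(self.peak_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.peak_times})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeatSequence":
        return cls(peak_times=df["t_s"].to_numpy(dtype=float))


@dataclass(frozen=True)
class SampleStream:
    """Raw device HR export: timestamped bpm samples, possibly irregular.

    ``nominal_mode`` records whether the device emits sparsely (one sample
    every few seconds, needing next-value imputation) or oversampled
    (several samples per second, needing within-second averaging).
    """

    samples: pd.DataFrame  # columns t_s, hr_bpm
    device_id: str = ""
    nominal_mode: str = "sparse"  # {"sparse", "oversampled"}

    def __post_init__(self) -> None:
        df = self.samples
        if not {"t_s", "hr_bpm"}.issubset(df.columns):
            raise ValueError("samples must have columns t_s and hr_bpm")
        t = df["t_s"].to_numpy(dtype=float)
        hr = df["hr_bpm"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError("sample timestamps must be non-decreasing")
        if len(hr) and (not np.all(np.isfinite(hr)) or np.any(hr <= 0)):
            raise ValueError("HR samples must be finite and positive")
        if self.nominal_mode not in ("sparse", "oversampled"):
            raise ValueError(f"unknown nominal_mode {self.nominal_mode!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def t_s(self) -> np.ndarray:
        return self.samples["t_s"].to_numpy(dtype=float)

    @property
    def hr_bpm(self) -> np.ndarray:
        return self.samples["hr_bpm"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls, t_s, hr_bpm, device_id: str = "", nominal_mode: str = "sparse"
    ) -> "SampleStream":
        return cls(
            samples=pd.DataFrame({"t_s": np.asarray(t_s, float), "hr_bpm": np.asarray(hr_bpm, float)}),
            device_id=device_id,
            nominal_mode=nominal_mode,
        )


@dataclass(frozen=True)
class PairedSeries:
    """Criterion/device value pairs retained for agreement statistics.

    Built by intersecting validity masks of two aligned 1 Hz series;
    every retained second contributes one (ref, dev) pair.
    """

    ref_values: np.ndarray
    dev_values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ref = np.asarray(self.ref_values, dtype=float)
        dev = np.asarray(self.dev_values, dtype=float)
        if ref.shape != dev.shape or ref.ndim != 1:
            raise ValueError("ref and dev must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(dev))):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "ref_values", ref)
        object.__setattr__(self, "dev_values", dev)

    @property
    def n(self) -> int:
        return len(self.ref_values)

    def __len__(self) -> int:
        return self.n

    @staticmethod
    def from_aligned(ref: HRSeries, dev: HRSeries, label: str = "") -> "PairedSeries":
        """Pair two aligned series over their temporal overlap.

        Seconds are paired by bucket start time; only seconds valid in
        both series are retained.
        """
        start = max(ref.start_s, dev.start_s)
        end = min(ref.end_s, dev.end_s)
        if end <= start:
            raise ValueError("series do not overlap")
        ir = int(round(start - ref.start_s))
        id_ = int(round(start - dev.start_s))
        n = int(round(end - start))
        m = ref.mask[ir : ir + n] & dev.mask[id_ : id_ + n]
        return PairedSeries(
            ref_values=ref.values[ir : ir + n][m],
            dev_values=dev.values[id_ : id_ + n][m],
            label=label,
        )

    def concat(self, other: "PairedSeries") -> "PairedSeries":
        return PairedSeries(
            ref_values=np.concatenate([self.ref_values, other.ref_values]),
            dev_values=np.concatenate([self.dev_values, other.dev_values]),
            label=self.label,
        )
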