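"""Seeded synthetic cohorts with known ground truth.

Real paired recordings from wearable-validation studies are rarely
deposited, so every stage of this pipeline is exercised against synthetic
data whose generating parameters are known exactly. The generator
produces, per subject:

* a continuous criterion heart-rate trajectory following a structured
  activity protocol (first-order exponential approach to each activity's
  target HR with a subject-specific time constant),
* the beat (R-peak) times realizing that trajectory, with optional
  Gaussian RR jitter as a simple heart-rate-variability stand-in,
* optionally a 256 Hz ECG voltage trace realizing the beats, and
* one timestamped HR sample stream per simulated wrist device, produced
  by a parametric observation model (lag, bias, smoothing, noise, sparse
  or uniform sampling, dropout, and gross-malfunction windows).

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BeatSequence, HRSeries, SampleStream

__all__ = [
    "ProtocolSegment",
    "Protocol",
    "SubjectParams",
    "Malfunction",
    "DeviceErrorModel",
    "TruthTrajectory",
    "RealizedHR",
    "SyntheticRecording",
    "default_protocol",
    "default_exclusion_scenario",
    "generate_truth",
    "synthesize_ecg",
    "apply_device_model",
    "generate_cohort",
    "write_cohort",
]

HR_FLOOR_BPM = 30.0
HR_CEIL_BPM = 220.0


@dataclass(frozen=True)
class ProtocolSegment:
    label: str
    duration_s: float
    target_hr: float  # bpm the subject's HR approaches during this activity
    hr_slope: float = 0.0  # bpm/min drift of the target within the segment


@dataclass(frozen=True)
class Protocol:
    """Ordered activity list defining the criterion HR trajectory."""

    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise ValueError("segment labels must be unique within a protocol")
        for s in self.segments:
            if s.duration_s <= 0:
                raise ValueError(f"segment {s.label!r}: duration must be > 0")
            if not (HR_FLOOR_BPM <= s.target_hr <= HR_CEIL_BPM):
                raise ValueError(
                    f"segment {s.label!r}: target_hr must lie in "
                    f"[{HR_FLOOR_BPM}, {HR_CEIL_BPM}] bpm"
                )
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def boundaries(self) -> np.ndarray:
        """Segment start times plus the final end time (length n+1)."""
        d = np.array([s.duration_s for s in self.segments], dtype=float)
        return np.concatenate([[0.0], np.cumsum(d)])

    def with_slack(self, slack_s: float) -> "Protocol":
        """Insert transition segments of ``slack_s`` seconds between activities.

        During a transition the HR target is already the next activity's,
        emulating subjects moving into position before the activity window
        formally starts.
        """
        if slack_s <= 0:
            return self
        segs: list[ProtocolSegment] = []
        for i, s in enumerate(self.segments):
            segs.append(s)
            if i + 1 < len(self.segments):
                nxt = self.segments[i + 1]
                segs.append(
                    ProtocolSegment(
                        label=f"transition-{i + 1}",
                        duration_s=slack_s,
                        target_hr=nxt.target_hr,
                    )
                )
        return Protocol(segments=tuple(segs))


def default_protocol() -> Protocol:
    """The package's reference 10-activity protocol.

    Five resting/sedentary phases, two low-intensity and three
    high-intensity exercise phases, closing with a recovery rest —
    intensity escalates over the session, then relaxes. Durations are
    2, 1.5, 1.5, 1.5, 1, 1, 2, 1.5, 1.5 and 1.5 minutes; targets are
    typical group-mean heart rates for these activities in young healthy
    adults.
    """
    rows = [
        ("seated_rest", 120, 76.0),
        ("typing", 90, 79.0),
        ("laying_left", 90, 74.0),
        ("laying_back", 90, 68.0),
        ("standing_up", 60, 89.0),
        ("walking_slow", 60, 86.0),
        ("walking_brisk", 120, 100.0),
        ("stairs", 90, 120.0),
        ("squats", 90, 129.0),
        ("resting", 90, 106.0),
    ]
    return Protocol(
        segments=tuple(ProtocolSegment(l, d, t) for l, d, t in rows)
    )


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiological parameters of the truth model."""

    baseline_hr: float = 70.0  # bpm at recording start
    hr_response_tau: float = 15.0  # s, first-order response time constant
    hrv_sd_ms: float = 20.0  # Gaussian RR jitter, milliseconds
    seed: int = 0

    def __post_init__(self) -> None:
        if not (40.0 <= self.baseline_hr <= 120.0):
            raise ValueError("baseline_hr must lie in [40, 120] bpm")
        if self.hr_response_tau <= 0:
            raise ValueError("hr_response_tau must be positive")
        if self.hrv_sd_ms < 0:
            raise ValueError("hrv_sd_ms must be non-negative")


@dataclass(frozen=True)
class Malfunction:
    """Gross device failure over a time window.

    ``flatline`` pins every sample in the window to ``level_bpm``;
    ``excess`` emits ``level_bpm`` plus a bounded random walk (step sd
    2 bpm, reflected at ±40 bpm of the level), mimicking the erratic,
    grossly elevated traces occasionally produced by wrist devices with
    poor skin contact.
    """

    mode: str  # {"flatline", "excess"}
    start_s: float
    end_s: float
    level_bpm: float

    def __post_init__(self) -> None:
        if self.mode not in ("flatline", "excess"):
            raise ValueError(f"unknown malfunction mode {self.mode!r}")
        if self.end_s <= self.start_s:
            raise ValueError("malfunction window must have positive length")


EXCESS_STEP_SD_BPM = 2.0
EXCESS_BOUND_BPM = 40.0


@dataclass(frozen=True)
class DeviceErrorModel:
    """Parametric observation model from criterion HR to a device stream.

    The device sample emitted at time ``t`` reports the (optionally
    moving-average smoothed) criterion HR at ``t - lag_s``, plus ``bias_bpm``
    and zero-mean Gaussian noise. ``sampling_mode='sparse'`` draws
    inter-sample gaps uniformly in ``[min_interval_s, max_interval_s]``
    (emulating trackers that report one value every few seconds);
    ``'uniform'`` samples at ``rate_hz``. Samples are then thinned by
    ``dropout_prob`` and overridden inside any malfunction window.
    """

    device_id: str = "device"
    lag_s: float = 0.0
    bias_bpm: float = 0.0
    noise_sd_bpm: float = 0.0
    smoothing_window_s: float = 0.0
    sampling_mode: str = "uniform"  # {"uniform", "sparse"}
    rate_hz: float = 1.0
    min_interval_s: float = 1.0
    max_interval_s: float = 5.0
    dropout_prob: float = 0.0
    malfunction: Malfunction | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_bpm < 0:
            raise ValueError("noise_sd_bpm must be non-negative")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must lie in [0, 1)")
        if self.sampling_mode not in ("uniform", "sparse"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")
        if self.sampling_mode == "sparse" and not (
            1.0 <= self.min_interval_s <= self.max_interval_s
        ):
            raise ValueError("sparse intervals must satisfy 1 <= min <= max")
        if self.sampling_mode == "uniform" and self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.isfinite(self.lag_s):
            raise ValueError("lag_s must be finite")

    @property
    def nominal_mode(self) -> str:
        if self.sampling_mode == "sparse" or self.rate_hz < 1.0:
            return "sparse"
        return "oversampled"


class TruthTrajectory:
    """Continuous-time criterion HR: piecewise first-order response.

    Within each protocol segment the HR approaches the segment's target
    exponentially with time constant ``tau``; with a within-segment target
    slope ``m`` (bpm/s) the exact solution of ``dH/dt = (T(t) - H)/tau`` is

        H(t) = T(t) - m*tau + (H(a) - T(a) + m*tau) * exp(-(t - a)/tau)

    with ``a`` the segment start. Segment boundary values are chained so
    the trajectory is continuous.
    """

    def __init__(self, protocol: Protocol, subject: SubjectParams):
        self.protocol = protocol
        self.subject = subject
        bounds = protocol.boundaries()
        self._starts = bounds[:-1]
        self.duration_s = float(bounds[-1])
        self._targets = np.array([s.target_hr for s in protocol.segments])
        self._slopes = np.array([s.hr_slope / 60.0 for s in protocol.segments])  # bpm/s
        tau = subject.hr_response_tau
        # chain the initial condition through segment boundaries
        h0 = np.empty(len(self._starts))
        h = subject.baseline_hr
        for i, seg in enumerate(protocol.segments):
            h0[i] = h
            m = self._slopes[i]
            t_end = seg.duration_s
            target_end = self._targets[i] + m * t_end
            h = target_end - m * tau + (h - self._targets[i] + m * tau) * np.exp(
                -t_end / tau
            )
        self._h0 = h0
        self._validate_range()

    def hr_at(self, t) -> np.ndarray:
        """Vectorized HR (bpm) at time ``t`` seconds; clamped to the span."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, self.duration_s)
        idx = np.clip(
            np.searchsorted(self._starts, t, side="right") - 1, 0, len(self._starts) - 1
        )
        tau = self.subject.hr_response_tau
        dt = t - self._starts[idx]
        target = self._targets[idx] + self._slopes[idx] * dt
        m = self._slopes[idx]
        return target - m * tau + (
            self._h0[idx] - self._targets[idx] + m * tau
        ) * np.exp(-dt / tau)

    def _validate_range(self) -> None:
        probe = np.arange(0.0, self.duration_s + 0.25, 0.25)
        h = self.hr_at(probe)
        if h.min() < HR_FLOOR_BPM or h.max() > HR_CEIL_BPM:
            raise ValueError(
                "protocol/subject combination drives HR outside "
                f"[{HR_FLOOR_BPM}, {HR_CEIL_BPM}] bpm "
                f"(range {h.min():.1f}-{h.max():.1f})"
            )


class RealizedHR:
    """Beat-level realization of a criterion HR trajectory.

    Instantaneous HR as a pulse-sensing device observes it: at time ``t``
    the value is ``60 / RR`` of the most recently *completed* beat
    interval (before the first complete interval, and past the beat span,
    the smooth trajectory is used). This carries the beat-to-beat (HRV)
    fluctuations the idealized trajectory lacks, and it coincides with
    the trajectory when the RR jitter is zero.

    Reporting the last completed interval, rather than the interval
    containing ``t``, avoids length-biased sampling: an interval's
    holding time is its successor's duration, independent of its own, so
    time-sampled device values and the criterion's beat-weighted
    within-second averages share the same expectation.
    """

    def __init__(self, trajectory: TruthTrajectory, beats: BeatSequence):
        self.trajectory = trajectory
        self.beats = beats
        self.duration_s = trajectory.duration_s
        self._rr = beats.rr_intervals

    def hr_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        base = self.trajectory.hr_at(t)
        if len(self._rr) == 0:
            return base
        # index of the last completed interval: peak_times[j + 1] <= t
        j = np.searchsorted(self.beats.peak_times, t, side="right") - 2
        inside = j >= 0
        out = np.atleast_1d(base).copy()
        jj = np.clip(j, 0, len(self._rr) - 1)
        out = np.where(inside, 60.0 / self._rr[jj], out)
        return out


def generate_truth(
    protocol: Protocol, subject: SubjectParams
) -> tuple[HRSeries, BeatSequence]:
    """Realize a subject's criterion HR: 1 Hz ground truth plus beat times.

    Beats are laid down sequentially from t = 0 with
    ``RR_k = 60 / HR(t_k) + jitter`` where the jitter is Gaussian with sd
    ``hrv_sd_ms`` (truncated so RR > 0.25 s). Deterministic given
    ``subject.seed``.
    """
    traj = TruthTrajectory(protocol, subject)
    rng = np.random.default_rng(subject.seed)
    sd_s = subject.hrv_sd_ms / 1000.0
    times = [0.0]
    t = 0.0
    while True:
        rr = 60.0 / float(traj.hr_at(t))
        if sd_s > 0:
            rr = rr + rng.normal(0.0, sd_s)
            rr = max(rr, 0.2501)
        t = t + rr
        if t > traj.duration_s:
            break
        times.append(t)
    beats = BeatSequence(peak_times=np.array(times))
    n_sec = int(np.floor(traj.duration_s))
    grid = np.arange(n_sec, dtype=float)
    truth = HRSeries(
        start_s=0.0,
        values=traj.hr_at(grid),
        mask=np.ones(n_sec, dtype=bool),
        source_id="truth",
    )
    return truth, beats


# --- ECG synthesis -------------------------------------------------------

# (amplitude mV, offset s from R, width s) for the P, Q, R, S, T deflections
_ECG_WAVES = (
    (0.12, -0.200, 0.025),
    (-0.10, -0.030, 0.010),
    (1.00, 0.000, 0.012),
    (-0.12, 0.030, 0.010),
    (0.30, 0.220, 0.055),
)

MIN_ECG_RATE_HZ = 128.0


def synthesize_ecg(
    beats: BeatSequence,
    rate_hz: float = 256.0,
    snr_db: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render beats as a stereotyped single-lead ECG voltage trace.

    Each beat becomes a sum-of-Gaussians P-QRS-T complex centred on the
    beat time; ``snr_db=None`` means noise-free, otherwise white Gaussian
    noise is added at the requested signal-to-noise ratio. Returns
    ``(t_s, mv)`` arrays; the trace covers ``[0, last beat + 1 s]``.
    """
    if rate_hz < MIN_ECG_RATE_HZ:
        raise ValueError(f"sampling rate must be >= {MIN_ECG_RATE_HZ} Hz")
    if len(beats) == 0:
        raise ValueError("cannot synthesize an ECG from an empty beat list")
    t = np.arange(0.0, beats.peak_times[-1] + 1.0, 1.0 / rate_hz)
    mv = np.zeros_like(t)
    for amp, off, width in _ECG_WAVES:
        centers = beats.peak_times + off
        # accumulate each wave of each beat; loop over beats is fine at
        # the trace lengths this generator targets (minutes)
        for c in centers:
            lo = np.searchsorted(t, c - 5 * width)
            hi = np.searchsorted(t, c + 5 * width)
            mv[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    if snr_db is not None and np.isfinite(snr_db):
        p_signal = float(np.mean(mv**2))
        noise_sd = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
        mv = mv + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(mv))
    return t, mv


# --- Device observation model -------------------------------------------


def _reflect(x: np.ndarray, bound: float) -> np.ndarray:
    """Fold values into [-bound, +bound] by reflection at the boundaries."""
    period = 4.0 * bound
    y = np.mod(x + bound, period)
    return np.where(y <= 2.0 * bound, y - bound, 3.0 * bound - y)


def _smoothed_eval(truth, t: np.ndarray, window_s: float) -> np.ndarray:
    """Trailing moving average of a continuous HR process over [t - w, t]."""
    if window_s <= 0:
        return truth.hr_at(t)
    grid_rate = 8.0  # Hz; resolves beat-interval steps well enough
    grid = np.arange(0.0, truth.duration_s + 1.0 / grid_rate, 1.0 / grid_rate)
    vals = truth.hr_at(grid)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    lo = np.clip(t - window_s, 0.0, truth.duration_s)
    hi = np.clip(t, 0.0, truth.duration_s)
    ilo = np.searchsorted(grid, lo, side="left")
    ihi = np.maximum(np.searchsorted(grid, hi, side="right"), ilo + 1)
    return (csum[ihi] - csum[ilo]) / (ihi - ilo)


def apply_device_model(
    truth: TruthTrajectory | RealizedHR, model: DeviceErrorModel, seed: int
) -> SampleStream:
    """Observe a criterion HR process through a device error model.

    A sample emitted at time ``t`` reports
    ``smooth(truth)(t - lag) + bias + noise``; emission times follow the
    model's sampling mode, malfunction windows override values, and
    samples are finally thinned by ``dropout_prob``. Deterministic given
    ``seed``. ``truth`` is any continuous HR process exposing ``hr_at``
    and ``duration_s`` — the idealized trajectory or, more faithfully,
    its beat-level realization.
    """
    span = truth.duration_s
    if abs(model.lag_s) >= span:
        raise ValueError("device lag exceeds the recording span")
    rng = np.random.default_rng(seed)
    if model.sampling_mode == "uniform":
        t = np.arange(0.0, span, 1.0 / model.rate_hz)
    else:
        # enough gap draws to cover the span even at min_interval
        n_max = int(np.ceil(span / model.min_interval_s)) + 2
        gaps = rng.uniform(model.min_interval_s, model.max_interval_s, size=n_max)
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        t = t[t < span]
    shifted = t - model.lag_s
    keep = (shifted >= 0.0) & (shifted <= span)
    t, shifted = t[keep], shifted[keep]
    values = _smoothed_eval(truth, shifted, model.smoothing_window_s) + model.bias_bpm
    if model.noise_sd_bpm > 0:
        values = values + rng.normal(0.0, model.noise_sd_bpm, size=len(values))
    mf = model.malfunction
    if mf is not None:
        in_win = (t >= mf.start_s) & (t <= mf.end_s)
        if mf.mode == "flatline":
            values[in_win] = mf.level_bpm
        else:  # excess
            walk = np.cumsum(rng.normal(0.0, EXCESS_STEP_SD_BPM, size=int(in_win.sum())))
            values[in_win] = mf.level_bpm + _reflect(walk, EXCESS_BOUND_BPM)
    if model.dropout_prob > 0:
        kept = rng.random(len(t)) >= model.dropout_prob
        t, values = t[kept], values[kept]
    return SampleStream.from_arrays(
        t_s=t,
        hr_bpm=np.maximum(values, 1.0),
        device_id=model.device_id,
        nominal_mode=model.nominal_mode,
    )


# --- Cohort generation ---------------------------------------------------


@dataclass
class SyntheticRecording:
    """One subject's complete synthetic session with full provenance."""

    participant_id: str
    truth_hr: HRSeries
    beats: BeatSequence
    trajectory: TruthTrajectory
    device_streams: dict[str, SampleStream]
    annotations: pd.DataFrame  # participant_id, activity, start_s, end_s, status
    provenance: dict
    ecg: tuple[np.ndarray, np.ndarray] | None = None  # (t_s, mv)

    def synthesize_ecg(
        self, rate_hz: float = 256.0, snr_db: float | None = 20.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Render (and cache) the subject's ECG trace from its beats."""
        seed = int(self.provenance.get("ecg_seed", 0))
        self.ecg = synthesize_ecg(self.beats, rate_hz=rate_hz, snr_db=snr_db, seed=seed)
        return self.ecg


# Reference exclusion scenario: a 23-subject cohort in which criterion
# recordings of three subjects are unusable throughout, two lose the
# high-intensity activities, one loses the final rest, and scattered
# activities needed manual beat annotation. Status codes:
# o = original, a = annotated (included), x = excluded.
_REFERENCE_STATUS_GRID: dict[int, str] = {
    1: "ooaoaooooo",
    2: "ooooooooox",
    3: "ooaaaoaaoo",
    4: "oaaaoaaaao",
    5: "ooaooaaxxo",
    6: "xxxxxxxxxx",
    7: "oooooaaxxx",
    8: "xxxxxxxxxx",
    9: "oooooooooo",
    10: "ooooaooaoo",
    11: "oooaooooao",
    12: "oooooooooo",
    13: "oooooooooo",
    14: "ooooooooao",
    15: "ooooooooao",
    16: "ooooaooooo",
    17: "oooooooooo",
    18: "aoooaooooo",
    19: "ooooooooao",
    20: "ooooaoooao",
    21: "oooooooooo",
    22: "oooooooooo",
    23: "xxxxxxxxxx",
}
_STATUS_NAMES = {"o": "original", "a": "annotated", "x": "excluded"}


def default_exclusion_scenario(n_subjects: int = 23) -> dict[str, list[str]]:
    """Per-participant activity statuses for the reference 23-subject cohort.

    Returns ``{participant_id: [status per activity]}`` with statuses in
    {original, annotated, excluded}. Three participants are fully
    excluded, so 20 of 23 survive whole-cohort exclusion. For cohorts
    smaller/larger than 23 the grid is truncated/cycled.
    """
    out: dict[str, list[str]] = {}
    for i in range(1, n_subjects + 1):
        code = _REFERENCE_STATUS_GRID[(i - 1) % 23 + 1]
        out[f"p{i:02d}"] = [_STATUS_NAMES[c] for c in code]
    return out


def _draw_subject_params(rng: np.random.Generator, seed: int) -> SubjectParams:
    baseline = float(np.clip(rng.normal(70.0, 8.0), 50.0, 95.0))
    tau = float(rng.uniform(8.0, 25.0))
    hrv = float(rng.uniform(5.0, 40.0))
    return SubjectParams(
        baseline_hr=baseline, hr_response_tau=tau, hrv_sd_ms=hrv, seed=seed
    )


def generate_cohort(
    n_subjects: int,
    device_models: dict[str, DeviceErrorModel],
    protocol: Protocol | None = None,
    master_seed: int = 0,
    subjects: list[SubjectParams] | None = None,
    statuses: dict[str, list[str]] | None = None,
    device_overrides: dict[tuple[str, str], DeviceErrorModel] | None = None,
    slack_s: float = 0.0,
) -> list[SyntheticRecording]:
    """Generate a seeded cohort of paired criterion/device recordings.

    Per-subject seeds are derived deterministically from ``master_seed``.
    ``subjects`` fixes subject parameters explicitly (length must match);
    otherwise they are drawn from the documented distributions
    (baseline ~ N(70, 8) truncated to [50, 95] bpm, tau ~ U(8, 25) s,
    hrv ~ U(5, 40) ms). ``statuses`` attaches per-activity inclusion
    statuses to the annotation table; ``device_overrides`` swaps in a
    different error model for a specific (participant, device) pair, e.g.
    to give one subject a malfunctioning device. ``slack_s`` inserts
    transition gaps between activities: annotations still cover only the
    activity windows.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if subjects is not None and len(subjects) != n_subjects:
        raise ValueError("subjects list length must equal n_subjects")
    protocol = protocol or default_protocol()
    sim_protocol = protocol.with_slack(slack_s)
    # activity windows within the (possibly slack-expanded) timeline
    bounds = sim_protocol.boundaries()
    activity_windows = [
        (seg.label, float(bounds[i]), float(bounds[i + 1]))
        for i, seg in enumerate(sim_protocol.segments)
        if not seg.label.startswith("transition-")
    ]
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(n_subjects)
    recordings: list[SyntheticRecording] = []
    for i in range(n_subjects):
        pid = f"p{i + 1:02d}"
        sub_ss, beat_ss, ecg_ss, *dev_ss = children[i].spawn(3 + len(device_models))
        subj_seed = int(beat_ss.generate_state(1)[0] % 2**31)
        if subjects is not None:
            subject = subjects[i]
        else:
            subject = _draw_subject_params(
                np.random.default_rng(sub_ss), subj_seed
            )
        truth, beats = generate_truth(sim_protocol, subject)
        traj = TruthTrajectory(sim_protocol, subject)
        realized = RealizedHR(traj, beats)
        streams: dict[str, SampleStream] = {}
        for (dev_id, model), ss in zip(device_models.items(), dev_ss):
            model = dataclasses.replace(model, device_id=dev_id)
            if device_overrides and (pid, dev_id) in device_overrides:
                model = dataclasses.replace(
                    device_overrides[(pid, dev_id)], device_id=dev_id
                )
            dev_seed = int(ss.generate_state(1)[0] % 2**31)
            streams[dev_id] = apply_device_model(realized, model, seed=dev_seed)
        stat = (
            statuses.get(pid, ["original"] * len(activity_windows))
            if statuses
            else ["original"] * len(activity_windows)
        )
        if len(stat) != len(activity_windows):
            raise ValueError(f"{pid}: need one status per activity")
        ann = pd.DataFrame(
            {
                "participant_id": pid,
                "activity": [w[0] for w in activity_windows],
                "start_s": [w[1] for w in activity_windows],
                "end_s": [w[2] for w in activity_windows],
                "status": stat,
            }
        )
        prov = {
            "participant_id": pid,
            "master_seed": master_seed,
            "subject": dataclasses.asdict(subject),
            "ecg_seed": int(ecg_ss.generate_state(1)[0] % 2**31),
            "devices": {
                d: dataclasses.asdict(
                    device_overrides[(pid, d)]
                    if device_overrides and (pid, d) in device_overrides
                    else m
                )
                for d, m in device_models.items()
            },
            "slack_s": slack_s,
        }
        recordings.append(
            SyntheticRecording(
                participant_id=pid,
                truth_hr=truth,
                beats=beats,
                trajectory=traj,
                device_streams=streams,
                annotations=ann,
                provenance=prov,
            )
        )
    return recordings


def write_cohort(
    recordings: list[SyntheticRecording], out_dir: str | Path, ecg: bool = False
) -> Path:
    """Write a cohort to disk in the pipeline's CSV/JSON exchange formats.

    Layout: one subdirectory per participant with ``truth_hr.csv``,
    ``beats.csv``, ``device_<id>.csv`` (and ``ecg.csv`` if requested),
    plus cohort-level ``annotations.csv`` and ``provenance.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_ann = []
    prov = {}
    for rec in recordings:
        pdir = out / rec.participant_id
        pdir.mkdir(exist_ok=True)
        rec.truth_hr.to_frame().to_csv(pdir / "truth_hr.csv", index=False)
        rec.beats.to_frame().to_csv(pdir / "beats.csv", index=False)
        for dev_id, stream in rec.device_streams.items():
            stream.samples.to_csv(pdir / f"device_{dev_id}.csv", index=False)
        if ecg:
            t, mv = rec.ecg if rec.ecg is not None else rec.synthesize_ecg()
            pd.DataFrame({"t_s": t, "mv": mv}).to_csv(pdir / "ecg.csv", index=False)
        all_ann.append(rec.annotations)
        prov[rec.participant_id] = rec.provenance
    pd.concat(all_ann, ignore_index=True).to_csv(out / "annotations.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=float))
    return out
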