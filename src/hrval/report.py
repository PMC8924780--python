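"""Pipeline orchestration and report assembly.

Flow per participant: criterion beats -> 1 Hz criterion series; each raw
device stream -> 1 Hz (sparse or oversampled rule) -> lag estimation and
alignment against the criterion. Activity windows then slice the aligned
pair into per-activity pools, exclusion statuses drop spans whose
criterion data are unusable, and pools are aggregated across
participants into per-activity and overall metric blocks.

Exclusion semantics: a span is excluded only when the *criterion*
recording is inadequate there; evidently wrong device data stay in (that
situation occurs in real deployments too, and dropping it would flatter
the device). ``annotated`` means the criterion beats were manually
corrected upstream — the span is included. Participants with every
activity excluded vanish from the cohort; partially excluded
participants keep their remaining activities in both the per-activity
and the overall pools.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ecg import criterion_to_1hz, detect_r_peaks
from .metrics import MetricBlock, bland_altman, metric_block
from .resample import downsample_average, to_1hz
from .series import BeatSequence, HRSeries, PairedSeries, SampleStream
from .sync import DEFAULT_MAX_LAG_S, DEFAULT_MIN_OVERLAP, SyncResult, apply_lag, estimate_lag

log = logging.getLogger(__name__)

__all__ = [
    "ActivitySegment",
    "PipelineConfig",
    "ParticipantData",
    "AgreementReport",
    "segment",
    "apply_exclusions",
    "process_participant",
    "run_pipeline",
    "aggregate",
    "sensitivity_excluding",
]

OVERALL_LABEL = "overall"


@dataclass(frozen=True)
class ActivitySegment:
    """One labeled activity window of one participant, half-open [start, end)."""

    participant_id: str
    activity: str
    start_s: float
    end_s: float
    status: str = "original"  # {original, annotated, excluded}

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")
        if self.status not in ("original", "annotated", "excluded"):
            raise ValueError(f"unknown status {self.status!r}")


def segments_from_frame(df: pd.DataFrame) -> list[ActivitySegment]:
    return [
        ActivitySegment(
            participant_id=str(r.participant_id),
            activity=str(r.activity),
            start_s=float(r.start_s),
            end_s=float(r.end_s),
            status=str(getattr(r, "status", "original")),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class PipelineConfig:
    max_lag_s: int = DEFAULT_MAX_LAG_S
    min_overlap: int = DEFAULT_MIN_OVERLAP
    sync_objective: str = "pcc"  # {"pcc", "xcorr"}
    trim_s: float = 0.0  # shaved off both ends of each activity window
    loa_method: str = "sd"  # {"sd", "percentile"}
    validity_limit_pct: float = 10.0
    overall_includes_transitions: bool = True
    pooling: str = "seconds"  # {"seconds", "participants"}
    use_ecg_detector: bool = False  # detect beats from ecg trace when present


def _check_no_overlap(segs: list[ActivitySegment]) -> None:
    by_pid: dict[str, list[ActivitySegment]] = {}
    for s in segs:
        by_pid.setdefault(s.participant_id, []).append(s)
    for pid, group in by_pid.items():
        ordered = sorted(group, key=lambda s: s.start_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"{pid}: activities {a.activity!r} and {b.activity!r} overlap"
                )


def segment(
    ref: HRSeries,
    dev: HRSeries,
    segs: list[ActivitySegment],
    trim_s: float = 0.0,
) -> dict[str, PairedSeries]:
    """Slice an aligned criterion/device pair into per-activity pools.

    Retains, per activity, the seconds in ``[start + trim_s, end - trim_s)``
    where both series are valid. Segments must lie within the criterion
    recording span and must not overlap within a participant.
    """
    _check_no_overlap(segs)
    out: dict[str, PairedSeries] = {}
    for s in segs:
        if s.start_s < ref.start_s or s.end_s > ref.end_s:
            raise ValueError(
                f"segment {s.activity!r} [{s.start_s}, {s.end_s}) lies outside "
                f"the recording span [{ref.start_s}, {ref.end_s})"
            )
        lo, hi = s.start_s + trim_s, s.end_s - trim_s
        # clip to the device overlap: an aligned device series can end a
        # few seconds early after the lag shift
        lo, hi = max(lo, dev.start_s), min(hi, dev.end_s)
        if hi - lo < 1.0:
            out[s.activity] = PairedSeries(np.empty(0), np.empty(0), label=s.activity)
            continue
        out[s.activity] = PairedSeries.from_aligned(
            ref.crop(lo, hi), dev.crop(lo, hi), label=s.activity
        )
    return out


def apply_exclusions(
    segs: list[ActivitySegment],
) -> tuple[list[ActivitySegment], list[dict]]:
    """Drop excluded spans; report what was dropped.

    Returns the included segments (``original`` and ``annotated``) and a
    log with one entry per dropped (participant, activity) span.
    Participants whose every activity is excluded disappear entirely.
    """
    included = [s for s in segs if s.status != "excluded"]
    dropped = [s for s in segs if s.status == "excluded"]
    logbook = [
        {
            "participant_id": s.participant_id,
            "activity": s.activity,
            "start_s": s.start_s,
            "end_s": s.end_s,
            "reason": "criterion recording inadequate",
        }
        for s in dropped
    ]
    return included, logbook


@dataclass
class ParticipantData:
    """One participant's aligned series plus segmentation metadata."""

    participant_id: str
    ref: HRSeries
    devices: dict[str, HRSeries]  # aligned (lag-corrected) 1 Hz series
    sync: dict[str, SyncResult]
    segments: list[ActivitySegment]

    @property
    def included_segments(self) -> list[ActivitySegment]:
        return [s for s in self.segments if s.status != "excluded"]


def process_participant(
    participant_id: str,
    beats: BeatSequence | None,
    device_streams: dict[str, SampleStream],
    segments_: list[ActivitySegment],
    config: PipelineConfig = PipelineConfig(),
    ecg_trace: tuple[np.ndarray, np.ndarray] | None = None,
    ecg_rate_hz: float = 256.0,
) -> ParticipantData:
    """Criterion reduction, device resampling and alignment for one subject."""
    if config.use_ecg_detector:
        if ecg_trace is None:
            raise ValueError("use_ecg_detector=True but no ECG trace supplied")
        beats = detect_r_peaks(np.asarray(ecg_trace[1]), ecg_rate_hz)
    if beats is None or len(beats) < 2:
        raise ValueError(f"{participant_id}: no usable criterion beats")
    ref = criterion_to_1hz(beats, source_id=f"{participant_id}/criterion")
    if segments_:
        # pad with masked seconds so every annotated window lies within
        # the criterion span (the last beat can fall short of it)
        ref = _pad_series(
            ref,
            min(s.start_s for s in segments_),
            max(s.end_s for s in segments_),
        )
    span = (ref.start_s, ref.end_s)
    devices: dict[str, HRSeries] = {}
    sync: dict[str, SyncResult] = {}
    for dev_id, stream in device_streams.items():
        series = to_1hz(stream, span)
        # the lag is estimated on observed seconds only: backward-filled
        # seconds are copies of a *later* observation and would drag the
        # correlation peak earlier by about half a sampling gap
        observed = downsample_average(stream, span)
        res = estimate_lag(
            ref,
            observed,
            max_lag_s=config.max_lag_s,
            min_overlap=config.min_overlap,
            objective=config.sync_objective,
        )
        sync[dev_id] = res
        devices[dev_id] = apply_lag(series, res.lag_s, ref_span=span)
    return ParticipantData(
        participant_id=participant_id,
        ref=ref,
        devices=devices,
        sync=sync,
        segments=segments_,
    )


@dataclass
class AgreementReport:
    """Per-activity and overall agreement blocks for each device."""

    blocks: dict[str, dict[str, MetricBlock]]  # device -> activity -> block
    activity_order: list[str]
    exclusion_log: list[dict]
    sync: dict[str, dict[str, SyncResult]]  # participant -> device -> result
    config: PipelineConfig
    sensitivity_excluded: tuple[str, ...] = ()
    ba_points: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per device x activity x metric value."""
        rows = []
        for dev, acts in self.blocks.items():
            for act in [OVERALL_LABEL] + self.activity_order:
                if act not in acts:
                    continue
                d = acts[act].to_dict()
                d = {
                    k: (round(v, 2) if k in ("ref_mean", "ref_sd", "dev_mean",
                                             "dev_sd", "bias", "loa_lower",
                                             "loa_upper")
                        else round(v, 3) if isinstance(v, float) else v)
                    for k, v in d.items()
                }
                rows.append({"device": dev, "activity": act, **d})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "config": self.config.__dict__,
            "sensitivity_excluded": list(self.sensitivity_excluded),
            "blocks": {
                dev: {act: blk.to_dict() for act, blk in acts.items()}
                for dev, acts in self.blocks.items()
            },
            "exclusions": self.exclusion_log,
            "sync": {
                pid: {d: r.__dict__ for d, r in devs.items()}
                for pid, devs in self.sync.items()
            },
        }
        return json.dumps(payload, indent=2, default=float)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "report.csv", index=False)
        (out / "report.json").write_text(self.to_json())
        (out / "sync.json").write_text(
            json.dumps(
                {
                    pid: {d: r.__dict__ for d, r in devs.items()}
                    for pid, devs in self.sync.items()
                },
                indent=2,
                default=float,
            )
        )
        with open(out / "exclusions.log", "w") as fh:
            for entry in self.exclusion_log:
                fh.write(
                    f"{entry['participant_id']}\t{entry['activity']}\t"
                    f"[{entry['start_s']}, {entry['end_s']})\t{entry['reason']}\n"
                )
        for dev, pts in self.ba_points.items():
            pts.to_csv(out / f"ba_points_{dev}.csv", index=False)


def _overall_pair(
    part: ParticipantData, dev_id: str, config: PipelineConfig
) -> PairedSeries:
    """One participant's overall pool for one device.

    With ``overall_includes_transitions`` the pool is the entire aligned
    overlap minus excluded spans; otherwise it is the union of the
    included (trimmed) activity windows.
    """
    ref, dev = part.ref, part.devices[dev_id]
    if config.overall_includes_transitions:
        excluded = [s for s in part.segments if s.status == "excluded"]
        ref_m = ref.mask.copy()
        t = ref.times
        for s in excluded:
            ref_m &= ~((t >= s.start_s) & (t < s.end_s))
        ref_cut = HRSeries(ref.start_s, ref.values, ref_m, ref.source_id)
        return PairedSeries.from_aligned(ref_cut, dev, label=OVERALL_LABEL)
    pools = segment(ref, dev, part.included_segments, trim_s=config.trim_s)
    out = PairedSeries(np.empty(0), np.empty(0), label=OVERALL_LABEL)
    for act in [s.activity for s in part.included_segments]:
        out = out.concat(pools[act])
    return out


def aggregate(
    participants: list[ParticipantData],
    config: PipelineConfig = PipelineConfig(),
    sensitivity_excluded: tuple[str, ...] = (),
) -> AgreementReport:
    """Pool seconds across participants and assemble the report.

    Default pooling is second-level: all retained seconds of all
    participants enter one pool per (device, activity) cell and one
    overall pool per device. ``pooling='participants'`` instead computes
    per-participant blocks and averages them with equal participant
    weight (reported means of metrics; n is the participant count).
    Blocks with fewer than 2 paired seconds are omitted with a warning.
    """
    participants = [
        p for p in participants if p.participant_id not in sensitivity_excluded
    ]
    if not participants:
        raise ValueError("no participants left to aggregate")
    all_segs = [s for p in participants for s in p.segments]
    included, logbook = apply_exclusions(all_segs)
    device_ids = sorted({d for p in participants for d in p.devices})
    activity_order: list[str] = []
    for s in included:
        if s.activity not in activity_order:
            activity_order.append(s.activity)

    blocks: dict[str, dict[str, MetricBlock]] = {}
    ba_points: dict[str, pd.DataFrame] = {}
    for dev_id in device_ids:
        pools: dict[str, list[PairedSeries]] = {a: [] for a in activity_order}
        overall: list[PairedSeries] = []
        for part in participants:
            if dev_id not in part.devices:
                continue
            frag = segment(
                part.ref, part.devices[dev_id], part.included_segments,
                trim_s=config.trim_s,
            )
            for act, p in frag.items():
                pools[act].append(p)
            overall.append(_overall_pair(part, dev_id, config))
        dev_blocks: dict[str, MetricBlock] = {}
        for act in [OVERALL_LABEL] + activity_order:
            parts_pools = overall if act == OVERALL_LABEL else pools[act]
            dev_blocks_entry = _pool_block(parts_pools, act, config)
            if dev_blocks_entry is None:
                warnings.warn(
                    f"device {dev_id!r}, block {act!r}: fewer than 2 paired "
                    "seconds; block omitted"
                )
                continue
            dev_blocks[act] = dev_blocks_entry
        blocks[dev_id] = dev_blocks
        pooled_overall = _concat_pools(overall)
        if pooled_overall.n >= 2:
            ba_points[dev_id] = bland_altman(
                pooled_overall, loa_method=config.loa_method
            ).points
    return AgreementReport(
        blocks=blocks,
        activity_order=activity_order,
        exclusion_log=logbook,
        sync={p.participant_id: p.sync for p in participants},
        config=config,
        sensitivity_excluded=sensitivity_excluded,
        ba_points=ba_points,
    )


def _concat_pools(pools: list[PairedSeries]) -> PairedSeries:
    out = PairedSeries(np.empty(0), np.empty(0))
    for p in pools:
        out = out.concat(p)
    return out


def _pool_block(
    pools: list[PairedSeries], label: str, config: PipelineConfig
) -> MetricBlock | None:
    if config.pooling == "participants":
        per = []
        for p in pools:
            if p.n >= 2:
                per.append(
                    metric_block(p, loa_method=config.loa_method,
                                 validity_limit_pct=config.validity_limit_pct)
                )
        if not per:
            return None
        mean_of = lambda attr: float(np.mean([getattr(b, attr) for b in per]))
        m = mean_of("mape")
        return MetricBlock(
            n=len(per),
            ref_mean=mean_of("ref_mean"), ref_sd=mean_of("ref_sd"),
            dev_mean=mean_of("dev_mean"), dev_sd=mean_of("dev_sd"),
            mae=mean_of("mae"), mape=m,
            ccc=mean_of("ccc"), pcc=mean_of("pcc"),
            bias=mean_of("bias"),
            loa_lower=mean_of("loa_lower"), loa_upper=mean_of("loa_upper"),
            valid_mape=bool(m < config.validity_limit_pct),
        )
    pooled = _concat_pools(pools)
    if pooled.n < 2:
        return None
    pooled = replace(pooled, label=label)
    return metric_block(
        pooled, loa_method=config.loa_method,
        validity_limit_pct=config.validity_limit_pct,
    )


def run_pipeline(
    cohort,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[ParticipantData], AgreementReport]:
    """Run the full pipeline on a synthetic cohort (or compatible records).

    ``cohort`` is a list of objects exposing ``participant_id``,
    ``beats``, ``device_streams`` and ``annotations`` (as produced by
    :func:`hrval.synthetic.generate_cohort`). Returns the per-participant
    processed data and the aggregated report.
    """
    participants = []
    for rec in cohort:
        segs = segments_from_frame(rec.annotations)
        if all(s.status == "excluded" for s in segs):
            log.info("%s: all activities excluded; participant dropped",
                     rec.participant_id)
            participants.append(
                _excluded_placeholder(rec.participant_id, segs)
            )
            continue
        participants.append(
            process_participant(
                rec.participant_id,
                rec.beats,
                rec.device_streams,
                segs,
                config=config,
                ecg_trace=getattr(rec, "ecg", None),
            )
        )
    report = aggregate(participants, config=config)
    return participants, report


def _pad_series(s: HRSeries, start_s: float, end_s: float) -> HRSeries:
    start = min(float(np.floor(start_s)), s.start_s)
    end = max(float(np.ceil(end_s)), s.end_s)
    before = int(round(s.start_s - start))
    after = int(round(end - s.end_s))
    if before == 0 and after == 0:
        return s
    values = np.concatenate([np.zeros(before), s.values, np.zeros(after)])
    mask = np.concatenate(
        [np.zeros(before, bool), s.mask, np.zeros(after, bool)]
    )
    return HRSeries(start_s=start, values=values, mask=mask, source_id=s.source_id)


def _excluded_placeholder(pid: str, segs: list[ActivitySegment]) -> ParticipantData:
    dummy = HRSeries(0.0, np.zeros(2), np.zeros(2, bool), source_id=pid)
    return ParticipantData(pid, dummy, {}, {}, segs)


def sensitivity_excluding(
    participants: list[ParticipantData],
    subject_ids: tuple[str, ...] | list[str],
    config: PipelineConfig = PipelineConfig(),
) -> AgreementReport:
    """Re-aggregate with the listed subjects dropped (sensitivity run)."""
    known = {p.participant_id for p in participants}
    missing = set(subject_ids) - known
    if missing:
        raise ValueError(f"unknown participant id(s): {sorted(missing)}")
    if set(subject_ids) >= known:
        raise ValueError("cannot drop every participant")
    return aggregate(
        participants, config=config, sensitivity_excluded=tuple(subject_ids)
    )
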