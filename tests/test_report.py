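"""Segmentation, exclusion semantics, aggregation, sensitivity runs."""

import numpy as np
import pytest

from hrval.report import (
    ActivitySegment,
    PipelineConfig,
    aggregate,
    apply_exclusions,
    run_pipeline,
    segment,
    segments_from_frame,
    sensitivity_excluding,
)
from hrval.synthetic import (
    DeviceErrorModel,
    Malfunction,
    default_exclusion_scenario,
    default_protocol,
    generate_cohort,
)

from conftest import series


def seg(pid, act, a, b, status="original"):
    return ActivitySegment(pid, act, float(a), float(b), status)


class TestSegment:
    def test_length_bookkeeping(self):
        ref = series(np.linspace(60, 120, 30))
        dev = series(np.linspace(61, 121, 30))
        out = segment(ref, dev, [seg("p", "walk", 10, 20)])
        assert out["walk"].n == 10

    def test_mask_intersection(self):
        mask = np.ones(30, bool)
        mask[12:15] = False
        ref = series(np.linspace(60, 120, 30))
        dev = series(np.linspace(61, 121, 30), mask=mask)
        out = segment(ref, dev, [seg("p", "walk", 10, 20)])
        assert out["walk"].n == 7

    def test_trim_shaves_both_ends(self):
        ref = series(np.linspace(60, 120, 30))
        out = segment(ref, ref, [seg("p", "walk", 10, 20)], trim_s=2.0)
        assert out["walk"].n == 6

    def test_overlapping_segments_rejected(self):
        ref = series(np.linspace(60, 120, 30))
        with pytest.raises(ValueError, match="overlap"):
            segment(ref, ref, [seg("p", "a", 0, 10), seg("p", "b", 5, 15)])

    def test_segment_outside_span_rejected(self):
        ref = series(np.linspace(60, 120, 30))
        with pytest.raises(ValueError, match="outside"):
            segment(ref, ref, [seg("p", "a", 20, 40)])


class TestExclusions:
    def test_reference_scenario_keeps_20_of_23(self):
        scen = default_exclusion_scenario()
        segs = [
            seg(pid, f"act{i}", i * 10, (i + 1) * 10, status)
            for pid, statuses in scen.items()
            for i, status in enumerate(statuses)
        ]
        included, logbook = apply_exclusions(segs)
        survivors = {s.participant_id for s in included}
        assert len(survivors) == 20
        assert len(logbook) == sum(1 for s in segs if s.status == "excluded")

    def test_no_exclusions_is_identity(self):
        segs = [seg("p1", "a", 0, 10), seg("p1", "b", 10, 20)]
        included, logbook = apply_exclusions(segs)
        assert included == segs
        assert logbook == []

    def test_annotated_counts_as_included(self):
        segs = [seg("p1", "a", 0, 10, "annotated"), seg("p1", "b", 10, 20, "excluded")]
        included, _ = apply_exclusions(segs)
        assert [s.activity for s in included] == ["a"]

    def test_partial_participant_keeps_remaining_activities(self):
        statuses = ["original"] * 8 + ["excluded"] * 2
        segs = [
            seg("p1", f"act{i}", i * 10, (i + 1) * 10, st)
            for i, st in enumerate(statuses)
        ]
        included, _ = apply_exclusions(segs)
        assert len(included) == 8


class TestPipeline:
    def test_end_to_end_recovers_device_parameters(self, small_cohort):
        parts, report = run_pipeline(small_cohort)
        for p in parts:
            assert p.sync["tracker"].lag_s == 3
            assert p.sync["watch"].lag_s == 7
        for dev, bias in (("tracker", -2.0), ("watch", 4.0)):
            blk = report.blocks[dev]["overall"]
            # tolerance scales with the number of independent device
            # observations (imputed grid seconds are copies, not samples)
            n_eff = min(
                blk.n, sum(len(r.device_streams[dev]) for r in small_cohort)
            )
            assert abs(blk.bias - bias) < 3 * 3.0 / np.sqrt(n_eff)
            assert blk.mae >= abs(blk.bias)

    def test_activity_blocks_cover_protocol(self, small_cohort):
        _, report = run_pipeline(small_cohort)
        acts = set(report.activity_order)
        assert acts == {s.label for s in default_protocol().segments}
        for dev in ("tracker", "watch"):
            assert set(report.blocks[dev]) == acts | {"overall"}

    def test_accounting_without_transitions(self, small_cohort):
        cfg = PipelineConfig(overall_includes_transitions=False)
        _, report = run_pipeline(small_cohort, config=cfg)
        for dev in ("tracker", "watch"):
            n_overall = report.blocks[dev]["overall"].n
            n_acts = sum(
                report.blocks[dev][a].n for a in report.activity_order
            )
            assert n_overall == n_acts

    def test_pooling_identical_participants_is_invariant(self):
        ref = series(np.linspace(70, 130, 60))
        dev = series(np.linspace(72, 132, 60))
        from hrval.report import ParticipantData
        from hrval.sync import SyncResult

        def part(pid):
            return ParticipantData(
                pid, ref, {"d": dev},
                {"d": SyncResult(0, 1.0, 60, 60)},
                [seg(pid, "a", 0, 60)],
            )

        one = aggregate([part("p1")]).blocks["d"]["a"]
        two = aggregate([part("p1"), part("p2")]).blocks["d"]["a"]
        assert one.mae == pytest.approx(two.mae)
        assert one.ccc == pytest.approx(two.ccc)
        assert two.n == 2 * one.n

    def test_single_activity_overall_equals_activity_block(self):
        ref = series(np.linspace(70, 130, 60))
        dev = series(np.linspace(72, 132, 60))
        from hrval.report import ParticipantData
        from hrval.sync import SyncResult

        p = ParticipantData(
            "p1", ref, {"d": dev}, {"d": SyncResult(0, 1.0, 60, 60)},
            [seg("p1", "a", 0, 60)],
        )
        rep = aggregate([p])
        assert rep.blocks["d"]["overall"].mae == pytest.approx(
            rep.blocks["d"]["a"].mae
        )

    def test_fully_excluded_participants_vanish(self, two_device_models):
        statuses = default_exclusion_scenario(23)
        cohort = generate_cohort(
            23, two_device_models, master_seed=3, statuses=statuses
        )
        parts, report = run_pipeline(cohort)
        contributing = {
            pid for pid, devs in report.sync.items() if devs
        }
        assert len(contributing) == 20

    def test_exclusion_only_affects_own_blocks(self, small_cohort):
        parts, base = run_pipeline(small_cohort)
        # exclude p01's first activity and re-aggregate
        modified = []
        for p in parts:
            if p.participant_id == "p01":
                segs = [
                    ActivitySegment(s.participant_id, s.activity, s.start_s,
                                    s.end_s, "excluded")
                    if s.activity == "seated_rest" else s
                    for s in p.segments
                ]
                from dataclasses import replace as _r
                p = type(p)(p.participant_id, p.ref, p.devices, p.sync, segs)
            modified.append(p)
        rep = aggregate(modified)
        assert rep.blocks["tracker"]["seated_rest"].n < base.blocks["tracker"]["seated_rest"].n
        for act in base.activity_order:
            if act == "seated_rest":
                continue
            assert rep.blocks["tracker"][act].n == base.blocks["tracker"][act].n
            assert rep.blocks["tracker"][act].mae == pytest.approx(
                base.blocks["tracker"][act].mae
            )


@pytest.fixture(scope="module")
def malfunction_cohort(two_device_models):
    mf = Malfunction(mode="excess", start_s=0.0, end_s=450.0, level_bpm=150.0)
    bad = DeviceErrorModel(
        sampling_mode="uniform", rate_hz=1.0, lag_s=7.0, bias_bpm=4.0,
        noise_sd_bpm=3.0, malfunction=mf,
    )
    cohort = generate_cohort(
        5, two_device_models, master_seed=17,
        device_overrides={("p03", "watch"): bad},
    )
    return run_pipeline(cohort)


class TestSensitivity:
    def test_drop_none_matches_main_report(self, malfunction_cohort):
        parts, base = malfunction_cohort
        rep = sensitivity_excluding(parts, [])
        assert rep.blocks["watch"]["overall"].mae == pytest.approx(
            base.blocks["watch"]["overall"].mae
        )

    def test_dropping_malfunction_subject_reduces_error(self, malfunction_cohort):
        parts, base = malfunction_cohort
        rep = sensitivity_excluding(parts, ["p03"])
        assert rep.blocks["watch"]["overall"].mae < base.blocks["watch"]["overall"].mae
        assert rep.sensitivity_excluded == ("p03",)

    def test_unknown_subject_rejected(self, malfunction_cohort):
        parts, _ = malfunction_cohort
        with pytest.raises(ValueError, match="unknown"):
            sensitivity_excluding(parts, ["ghost"])

    def test_dropping_everyone_rejected(self, malfunction_cohort):
        parts, _ = malfunction_cohort
        with pytest.raises(ValueError, match="every"):
            sensitivity_excluding(parts, [p.participant_id for p in parts])


def test_segments_from_frame_round_trip():
    import pandas as pd

    df = pd.DataFrame(
        {
            "participant_id": ["p1", "p1"],
            "activity": ["a", "b"],
            "start_s": [0.0, 10.0],
            "end_s": [10.0, 20.0],
            "status": ["original", "excluded"],
        }
    )
    segs = segments_from_frame(df)
    assert segs[1].status == "excluded"
    assert segs[0].end_s == 10.0
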