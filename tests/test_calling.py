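import numpy as np
import pandas as pd
import pytest

from exome2cnv import (CnaEvent, PipelineConfig, SimConfig, build_reference,
                       call_candidates, deviation_filter, run_pipeline,
                       simulate_cohort)
from exome2cnv.calling import CnaCall
from exome2cnv.segmentation import RatioTrack, Segment
from conftest import profile_from_rpkm
from test_segmentation import track_from_values


def seg(track, first, last):
    vals = track.entries["log2_ratio"].values[first:last + 1]
    return Segment(track.entries["chrom"].iloc[first], first, last,
                   last - first + 1, float(np.mean(vals)))


class TestCallCandidates:
    def test_five_exon_segment_not_called(self):
        track = track_from_values([-1.0] * 5 + [0.0] * 10)
        calls = call_candidates([seg(track, 0, 4), seg(track, 5, 14)], track)
        assert calls == []

    def test_six_exon_loss_called(self):
        track = track_from_values([-0.35] * 6 + [0.0] * 10)
        calls = call_candidates([seg(track, 0, 5), seg(track, 6, 15)], track)
        assert len(calls) == 1
        c = calls[0]
        assert c.direction == "loss" and c.n_exons == 6
        assert c.start == 0 and c.end == 5 * 1000 + 200

    def test_below_threshold_not_called_even_when_long(self):
        track = track_from_values([0.1] * 200)
        assert call_candidates([seg(track, 0, 199)], track) == []

    def test_threshold_strict_by_default_inclusive_on_request(self):
        track = track_from_values([0.3] * 6)
        s = [seg(track, 0, 5)]
        assert call_candidates(s, track) == []
        assert len(call_candidates(s, track, inclusive=True)) == 1

    def test_monotone_in_min_exons_and_threshold(self):
        rng = np.random.default_rng(3)
        vals = np.r_[rng.normal(-0.8, 0.05, 7), rng.normal(0, 0.05, 10),
                     rng.normal(0.5, 0.05, 12)]
        track = track_from_values(vals)
        segs = [seg(track, 0, 6), seg(track, 7, 16), seg(track, 17, 28)]
        n_by_exons = [len(call_candidates(segs, track, min_exons=m)) for m in (6, 8, 13)]
        assert n_by_exons == sorted(n_by_exons, reverse=True)
        n_by_thresh = [len(call_candidates(segs, track, log2_threshold=t))
                       for t in (0.3, 0.6, 1.0)]
        assert n_by_thresh == sorted(n_by_thresh, reverse=True)


class TestDeviationFilter:
    def _ref(self, targets, sd=2.0):
        rng = np.random.default_rng(0)
        base = rng.uniform(10, 30, len(targets))
        panel = [profile_from_rpkm(f"n{i}", targets,
                                   base + (i - 1.5) * sd / 1.118)  # sd ~ prescribed
                 for i in range(4)]
        return build_reference(panel, targets), base

    def test_tumor_at_panel_mean_fails(self, small_targets):
        ref, _ = self._ref(small_targets)
        tumor = profile_from_rpkm("t", small_targets, ref.mean.values)
        call = CnaCall("chr1", 0, 1, tuple(small_targets.probe_ids[:6]), 6, -0.5, "loss")
        out = deviation_filter(call, tumor, ref)
        assert out.deviation_score == pytest.approx(0.0)
        assert out.filter_status == "fail_deviation"

    def test_boundary_inclusive_at_exactly_1_5(self, small_targets):
        ref, _ = self._ref(small_targets)
        tumor = profile_from_rpkm(
            "t", small_targets, (ref.mean - 1.5 * ref.sd).values)
        call = CnaCall("chr1", 0, 1, tuple(small_targets.probe_ids[:6]), 6, -0.5, "loss")
        out = deviation_filter(call, tumor, ref)
        assert out.deviation_score == pytest.approx(1.5)
        assert out.filter_status == "pass"

    def test_score_matches_direct_formula(self, small_targets):
        ref, _ = self._ref(small_targets)
        rng = np.random.default_rng(5)
        vals = ref.mean.values * rng.uniform(0.3, 1.8, 9)
        tumor = profile_from_rpkm("t", small_targets, vals)
        ids = tuple(small_targets.probe_ids)
        call = CnaCall("chr1", 0, 1, ids, 9, -0.5, "loss")
        out = deviation_filter(call, tumor, ref)
        expect = np.mean([abs(tumor.rpkm[p] - ref.mean[p]) / ref.sd[p] for p in ids])
        assert out.deviation_score == pytest.approx(expect)

    def test_no_usable_probes_fails(self, small_targets):
        panel = [profile_from_rpkm(f"n{i}", small_targets, [10.0] * 9) for i in range(3)]
        ref = build_reference(panel, small_targets)  # sd 0 everywhere
        tumor = profile_from_rpkm("t", small_targets, [25.0] * 9)
        call = CnaCall("chr1", 0, 1, tuple(small_targets.probe_ids[:6]), 6, 1.0, "gain")
        assert deviation_filter(call, tumor, ref).filter_status == "fail_deviation"

    def test_monotone_in_min_avg_dev(self, small_targets):
        ref, _ = self._ref(small_targets)
        rng = np.random.default_rng(6)
        tumor = profile_from_rpkm("t", small_targets,
                                  ref.mean.values + 1.6 * ref.sd.values
                                  * rng.uniform(0.5, 1.5, 9))
        calls = [CnaCall("chr1", 0, 1, tuple(small_targets.probe_ids[i:i + 6]),
                         6, 0.5, "gain") for i in range(3)]
        n_pass = [sum(deviation_filter(c, tumor, ref, d).filter_status == "pass"
                      for c in calls) for d in (1.0, 1.5, 2.0)]
        assert n_pass == sorted(n_pass, reverse=True)


class TestRunPipeline:
    def test_injected_event_recovered_at_full_purity(self):
        cfg = SimConfig(n_probes=800, n_chroms=4, panel_size=8, depth_mean=115_000,
                        purity=1.0, events=(CnaEvent("chr2", 60, 50, 1),), seed=17)
        cohort = simulate_cohort(cfg)
        res = run_pipeline(cohort.tumor, cohort.matched_normal, cohort.panel,
                           cohort.targets, PipelineConfig(n_perm=500, seed=2))
        passing = res.passing
        assert len(passing) == 1
        call = passing[0]
        truth = cohort.truth.iloc[0]
        assert call.direction == "loss"
        assert call.chrom == "chr2"
        assert abs(call.start - truth["start"]) < 20_000
        assert abs(call.end - truth["end"]) < 20_000
        assert call.mean_log2 == pytest.approx(-1.0, abs=0.35)

    def test_self_pair_yields_no_passing_calls(self):
        cfg = SimConfig(n_probes=800, n_chroms=4, panel_size=8, depth_mean=115_000,
                        seed=18)
        cohort = simulate_cohort(cfg)
        res = run_pipeline(cohort.panel[1], cohort.panel[1], cohort.panel,
                           cohort.targets, PipelineConfig(n_perm=500, seed=2))
        assert res.passing == []

    def test_high_panel_variance_region_fails_deviation(self):
        # an 8-probe noisy run big enough to segment out, but with panel SD so
        # inflated the tumor deviation cannot average 1.5
        cfg = SimConfig(n_probes=800, n_chroms=4, panel_size=12, depth_mean=115_000,
                        noisy_probe_fraction=0.01, noisy_run_length=8,
                        noisy_probe_sigma=1.2, seed=19)
        cohort = simulate_cohort(cfg)
        res = run_pipeline(cohort.tumor, cohort.matched_normal, cohort.panel,
                           cohort.targets, PipelineConfig(n_perm=500, seed=2))
        # whether or not noise produced a candidate, none may pass
        assert res.passing == []

    def test_no_call_spans_chromosome_boundary(self, tiny_cohort):
        res = run_pipeline(tiny_cohort.tumor, tiny_cohort.matched_normal,
                           tiny_cohort.panel, tiny_cohort.targets,
                           PipelineConfig(n_perm=300, seed=1))
        cs = tiny_cohort.targets.chrom_slices()
        for call in res.calls:
            sub = tiny_cohort.targets.df.iloc[cs[call.chrom]]
            assert set(call.probe_ids) <= set(sub["probe_id"])

    def test_run_log_counts_consistent(self, tiny_cohort):
        res = run_pipeline(tiny_cohort.tumor, tiny_cohort.matched_normal,
                           tiny_cohort.panel, tiny_cohort.targets,
                           PipelineConfig(n_perm=300, seed=1))
        lg = res.run_log
        assert lg["n_track_probes"] + lg["n_excluded_low_normal"] == lg["n_probes"]
        assert lg["n_pass"] + lg["n_fail_deviation"] == lg["n_candidates"]
        assert lg["n_segments"] >= len(tiny_cohort.targets.chrom_slices())
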