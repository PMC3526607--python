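"""Turn segments into CNA calls and apply the reference-panel deviation filter.

A segment becomes a candidate call when it spans at least `min_exons` probes
and its mean log2 ratio lies strictly below -log2_threshold (loss) or strictly
above +log2_threshold (gain). Candidates then face the deviation filter: the
average, over the call's probes, of |RPKM_tumor - panel mean| / panel SD must
reach min_avg_dev; runs of exons whose capture efficiency merely varies a lot
across samples fail this and are flagged rather than reported as CNAs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import CoverageProfile, rpkm_normalize
from .io_formats import TargetSet
from .reference import ReferenceExome, build_reference
from .segmentation import (DEFAULT_ALPHA, DEFAULT_MIN_NORMAL_RPKM, DEFAULT_MIN_WIDTH,
                           DEFAULT_N_PERM, RatioTrack, Segment, cbs_segment,
                           make_ratio_track, smooth_outliers)

log = logging.getLogger(__name__)

DEFAULT_MIN_EXONS = 6
DEFAULT_LOG2_THRESHOLD = 0.3
DEFAULT_MIN_AVG_DEV = 1.5


@dataclass(frozen=True)
class CnaCall:
    """A called copy-number alteration."""

    chrom: str
    start: int  # 0-based half-open genomic span, first to last member probe
    end: int
    probe_ids: tuple[str, ...]
    n_exons: int
    mean_log2: float
    direction: str  # "loss" | "gain"
    deviation_score: float = float("nan")
    filter_status: str = "unset"  # "pass" | "fail_deviation"


@dataclass
class PipelineConfig:
    """All tunables of the calling pipeline, with the method's defaults."""

    min_normal_rpkm: float = DEFAULT_MIN_NORMAL_RPKM
    min_exons: int = DEFAULT_MIN_EXONS
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD
    min_avg_dev: float = DEFAULT_MIN_AVG_DEV
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    min_width: int = DEFAULT_MIN_WIDTH
    smooth: bool = True
    inclusive_log2_threshold: bool = False
    seed: int = 0


def call_candidates(segments: list[Segment], track: RatioTrack,
                    min_exons: int = DEFAULT_MIN_EXONS,
                    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
                    inclusive: bool = False) -> list[CnaCall]:
    """Candidate calls from segments: >= min_exons probes and |mean log2| past
    the threshold (strict by default, matching "below -0.3 or above 0.3").
    """
    calls = []
    ids = track.entries["probe_id"].values
    for seg in segments:
        if seg.n_probes < min_exons:
            continue
        m = seg.seg_mean
        if inclusive:
            is_loss, is_gain = m <= -log2_threshold, m >= log2_threshold
        else:
            is_loss, is_gain = m < -log2_threshold, m > log2_threshold
        if not (is_loss or is_gain):
            continue
        start, end = track.segment_span(seg)
        calls.append(CnaCall(
            chrom=seg.chrom, start=start, end=end,
            probe_ids=tuple(ids[seg.first_index:seg.last_index + 1]),
            n_exons=seg.n_probes, mean_log2=m,
            direction="loss" if is_loss else "gain",
        ))
    return calls


def deviation_filter(call: CnaCall, tumor: CoverageProfile, ref: ReferenceExome,
                     min_avg_dev: float = DEFAULT_MIN_AVG_DEV) -> CnaCall:
    """Score a call as mean over usable member probes of |rpkm_T - mean_N|/sd_N.

    Pass when the score is at least min_avg_dev (inclusive boundary). Probes
    whose panel SD sits below the floor are excluded from both numerator and
    denominator; a call with no usable probe fails outright.
    """
    if tumor.rpkm is None:
        raise ValueError("tumor profile must be RPKM-normalized")
    ids = [p for p in call.probe_ids if ref.usable.get(p, False)]
    if not ids:
        log.info("call %s:%d-%d: no usable probes for the deviation filter; failing",
                 call.chrom, call.start, call.end)
        return replace(call, deviation_score=0.0, filter_status="fail_deviation")
    dev = (tumor.rpkm[ids].values - ref.mean[ids].values) / ref.sd[ids].values
    score = float(np.mean(np.abs(dev)))
    status = "pass" if score >= min_avg_dev else "fail_deviation"
    return replace(call, deviation_score=score, filter_status=status)


def mask_calls(calls: list[CnaCall], mask: list[tuple[str, int, int]]) -> list[CnaCall]:
    """Drop calls overlapping any masked interval (e.g. immunoglobulin loci)."""
    def hit(c: CnaCall) -> bool:
        return any(c.chrom == m[0] and c.start < m[2] and c.end > m[1] for m in mask)
    return [c for c in calls if not hit(c)]


@dataclass
class PipelineResult:
    """Output of run_pipeline: calls (pass and fail) plus stage-count run log."""

    calls: list[CnaCall]
    track: RatioTrack
    segments: list[Segment]
    reference: ReferenceExome
    run_log: dict

    @property
    def passing(self) -> list[CnaCall]:
        return [c for c in self.calls if c.filter_status == "pass"]


def run_pipeline(tumor: CoverageProfile, normal: CoverageProfile,
                 panel: list[CoverageProfile], targets: TargetSet,
                 config: PipelineConfig | None = None,
                 reference: ReferenceExome | None = None,
                 exclude: list[tuple[str, int, int]] | None = None) -> PipelineResult:
    """Full chain: normalize -> reference -> ratio track -> smooth -> CBS ->
    candidates -> deviation filter. Deterministic given config.seed.
    """
    cfg = config or PipelineConfig()
    if tumor.rpkm is None:
        tumor = rpkm_normalize(tumor, targets)
    if normal.rpkm is None:
        normal = rpkm_normalize(normal, targets)
    panel = [p if p.rpkm is not None else rpkm_normalize(p, targets) for p in panel]
    ref = reference or build_reference(panel, targets)
    track = make_ratio_track(tumor, normal, targets, cfg.min_normal_rpkm)
    if cfg.smooth:
        track = smooth_outliers(track)
    segments = cbs_segment(track, cfg.alpha, cfg.n_perm, cfg.min_width, cfg.seed)
    candidates = call_candidates(segments, track, cfg.min_exons, cfg.log2_threshold,
                                 cfg.inclusive_log2_threshold)
    if exclude:
        candidates = mask_calls(candidates, exclude)
    calls = [deviation_filter(c, tumor, ref, cfg.min_avg_dev) for c in candidates]
    run_log = {
        "n_probes": len(targets),
        "n_track_probes": len(track),
        "n_excluded_low_normal": len(track.excluded),
        "n_segments": len(segments),
        "n_candidates": len(candidates),
        "n_pass": sum(c.filter_status == "pass" for c in calls),
        "n_fail_deviation": sum(c.filter_status == "fail_deviation" for c in calls),
        "config": vars(cfg).copy(),
    }
    log.info("pipeline %s: %s", track.sample_pair_id,
             {k: v for k, v in run_log.items() if k != "config"})
    return PipelineResult(calls, track, segments, ref, run_log)
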