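"""Evaluate exome-based CNA calls against aCGH segments.

A call is *supported* when at least min_shared_exons of its probes lie fully
inside one aCGH segment of identical direction; an aCGH segment is *detected*
when some same-direction call shares at least that many probes with it.
Sensitivity is reported both over all aCGH segments and over "eligible" ones
(those spanning at least min_exons captured probes, the only ones the
exon-count rule could ever call).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CnaCall
from .io_formats import AcghSegment, TargetSet

DEFAULT_MIN_SHARED_EXONS = 2
DEFAULT_MIN_EXONS_ELIGIBLE = 6


@dataclass(frozen=True)
class AcghMatch:
    segment_index: int  # index into the aCGH list
    shared_exons: int
    acgh_exons: int     # target probes fully inside the aCGH segment


@dataclass
class ConcordanceReport:
    n_calls: int
    n_supported: int
    n_acgh: int
    n_acgh_detected: int
    n_acgh_eligible: int
    n_acgh_eligible_detected: int
    sensitivity_all: float
    sensitivity_eligible: float
    support_fraction: float
    per_event: pd.DataFrame  # one row per call: match status and exon counts

    def summary(self) -> dict:
        return {
            "n_calls": self.n_calls, "n_supported": self.n_supported,
            "support_fraction": self.support_fraction,
            "n_acgh": self.n_acgh, "n_acgh_detected": self.n_acgh_detected,
            "n_acgh_eligible": self.n_acgh_eligible,
            "sensitivity_all": self.sensitivity_all,
            "sensitivity_eligible": self.sensitivity_eligible,
        }


def _probes_inside(targets: TargetSet, chrom: str, start: int, end: int) -> pd.DataFrame:
    df = targets.df
    m = (df["chrom"] == chrom) & (df["start"] >= start) & (df["end"] <= end)
    return df.loc[m]


def match_call_to_acgh(call: CnaCall, acgh: list[AcghSegment], targets: TargetSet,
                       min_shared_exons: int = DEFAULT_MIN_SHARED_EXONS
                       ) -> AcghMatch | None:
    """Best same-direction aCGH segment fully containing >= min_shared_exons of
    the call's probes, or None. Ties go to the segment sharing most exons,
    then to the earliest segment by genomic position (order-independent).
    """
    call_ids = set(call.probe_ids)
    best: AcghMatch | None = None
    best_key = None
    for idx, seg in enumerate(acgh):
        if seg.chrom != call.chrom or seg.direction != call.direction:
            continue
        inside = _probes_inside(targets, seg.chrom, seg.start, seg.end)
        shared = int(inside["probe_id"].isin(call_ids).sum())
        if shared < min_shared_exons:
            continue
        key = (-shared, seg.start, seg.end)
        if best is None or key < best_key:
            best = AcghMatch(idx, shared, len(inside))
            best_key = key
    return best


def evaluate_concordance(calls: list[CnaCall], acgh: list[AcghSegment],
                         targets: TargetSet,
                         min_shared_exons: int = DEFAULT_MIN_SHARED_EXONS,
                         min_exons_eligible: int = DEFAULT_MIN_EXONS_ELIGIBLE,
                         annotate: list[tuple[str, int, int, str]] | None = None
                         ) -> ConcordanceReport:
    """Support and sensitivity accounting in both directions.

    One call supports only its best-matching segment, but every segment
    sharing >= min_shared_exons same-direction probes with some call counts as
    detected. `annotate` optionally re-labels unsupported calls overlapping
    the given (chrom, start, end, label) intervals (e.g. immunoglobulin loci
    or manually confirmed subclonal events).
    """
    rows = []
    detected = np.zeros(len(acgh), dtype=bool)
    for call in calls:
        m = match_call_to_acgh(call, acgh, targets, min_shared_exons)
        # every segment this call detects, not just the best match
        for idx, seg in enumerate(acgh):
            if seg.chrom != call.chrom or seg.direction != call.direction:
                continue
            inside = _probes_inside(targets, seg.chrom, seg.start, seg.end)
            if int(inside["probe_id"].isin(set(call.probe_ids)).sum()) >= min_shared_exons:
                detected[idx] = True
        label = ""
        if m is None and annotate:
            for achrom, astart, aend, alabel in annotate:
                if call.chrom == achrom and call.start < aend and call.end > astart:
                    label = alabel
                    break
        rows.append({
            "chrom": call.chrom, "start": call.start, "end": call.end,
            "direction": call.direction, "n_exons": call.n_exons,
            "supported": m is not None,
            "acgh_index": m.segment_index if m else -1,
            "shared_exons": m.shared_exons if m else 0,
            "acgh_exons": m.acgh_exons if m else 0,
            "annotation": label,
        })
    eligible = np.array([
        len(_probes_inside(targets, s.chrom, s.start, s.end)) >= min_exons_eligible
        for s in acgh], dtype=bool) if acgh else np.zeros(0, dtype=bool)
    per_event = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                            "n_exons", "supported", "acgh_index",
                                            "shared_exons", "acgh_exons", "annotation"])
    n_calls = len(calls)
    n_supported = int(per_event["supported"].sum()) if n_calls else 0
    n_acgh = len(acgh)
    n_det = int(detected.sum())
    n_elig = int(eligible.sum())
    n_elig_det = int((detected & eligible).sum())
    return ConcordanceReport(
        n_calls=n_calls, n_supported=n_supported, n_acgh=n_acgh,
        n_acgh_detected=n_det, n_acgh_eligible=n_elig,
        n_acgh_eligible_detected=n_elig_det,
        sensitivity_all=n_det / n_acgh if n_acgh else float("nan"),
        sensitivity_eligible=n_elig_det / n_elig if n_elig else float("nan"),
        support_fraction=n_supported / n_calls if n_calls else float("nan"),
        per_event=per_event,
    )


def exon_count_correlation(report: ConcordanceReport) -> float | None:
    """Pearson r^2 between exome-call exon counts and the probe counts of
    their matched aCGH segments; None with fewer than 3 matched pairs or a
    degenerate (constant) vector.
    """
    pairs = report.per_event[report.per_event["supported"]]
    if len(pairs) < 3:
        return None
    x = pairs["n_exons"].values.astype(float)
    y = pairs["acgh_exons"].values.astype(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r, _ = stats.pearsonr(x, y)
    return float(r ** 2)
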