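"""X-chromosome dosage validation: male (one X) versus female (two X) coverage.

Hemizygous samples should show per-probe RPKM near half the female reference
outside the pseudoautosomal regions; scoring windows of k consecutive exons
against the -1.5 SD boundary traces the sensitivity/FDR trade-off that
motivates requiring several consecutive exons per call.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .io_formats import GRCH37_PAR, TargetSet
from .reference import ReferenceExome, per_probe_z

Z_ONE_COPY = -1.5  # window mean z strictly below this is called one-copy
DEFAULT_MIN_RPKM = 2.0


@dataclass(frozen=True)
class WindowClassification:
    sample_id: str
    window_index: int
    k: int
    mean_z: float
    called_one_copy: bool


@dataclass(frozen=True)
class SensitivityFdrPoint:
    k: int
    sensitivity: float  # fraction of true one-copy (male) windows called
    fdr: float          # fraction of two-copy (female) windows called


def select_x_exons(ref_female: ReferenceExome, targets: TargetSet,
                   par_regions=GRCH37_PAR, min_rpkm: float = DEFAULT_MIN_RPKM,
                   chrom: str = "chrX") -> list[str]:
    """X probes outside the PARs whose female reference mean is >= min_rpkm.

    PAR membership is judged by the probe midpoint. Raises when nothing
    survives (wrong chromosome name or hopeless coverage).
    """
    df = targets.df[targets.df["chrom"] == chrom]
    mid = (df["start"].values + df["end"].values) // 2
    in_par = np.zeros(len(df), dtype=bool)
    for pchrom, a, b in par_regions:
        if pchrom == chrom:
            in_par |= (mid >= a) & (mid < b)
    ids = df.loc[~in_par, "probe_id"]
    means = ref_female.mean.reindex(ids)
    usable = ref_female.usable.reindex(ids).fillna(False)
    keep = ids[(means.values >= min_rpkm) & usable.values]
    if keep.empty:
        raise ValueError("no non-PAR X probes pass the female-coverage filter")
    return list(keep)


def mean_dosage_ratio(profiles: list[CoverageProfile], ref_female: ReferenceExome,
                      probe_ids: list[str]) -> float:
    """Mean over samples and probes of rpkm / female-reference-mean.

    ~0.5 for hemizygous samples, ~1.0 for diploid ones.
    """
    ref = ref_female.mean[probe_ids].values
    ratios = [p.rpkm[probe_ids].values / ref for p in profiles]
    return float(np.mean(ratios))


def classify_windows(profile: CoverageProfile, ref_female: ReferenceExome,
                     probe_ids: list[str], k: int) -> list[WindowClassification]:
    """Split the selected probes (genome order) into disjoint blocks of k and
    call one-copy when the block's mean z is strictly below -1.5.

    The trailing remainder (< k probes) is dropped; with fewer than k probes
    the result is empty.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    z = per_probe_z(profile, ref_female).reindex(probe_ids).values
    n_blocks = len(z) // k
    out = []
    for w in range(n_blocks):
        mz = float(np.nanmean(z[w * k:(w + 1) * k]))
        out.append(WindowClassification(profile.sample_id, w, k, mz, mz < Z_ONE_COPY))
    return out


def sensitivity_fdr_curve(males: list[CoverageProfile], females: list[CoverageProfile],
                          ref_female: ReferenceExome, probe_ids: list[str],
                          ks: list[int]) -> list[SensitivityFdrPoint]:
    """One (sensitivity, FDR) point per window size k.

    Sensitivity: fraction of male windows called one-copy (true hemizygous
    regions detected). FDR: fraction of female windows called one-copy
    (diploid regions miscalled).
    """
    points = []
    for k in ks:
        m = [w.called_one_copy for p in males for w in classify_windows(p, ref_female, probe_ids, k)]
        f = [w.called_one_copy for p in females for w in classify_windows(p, ref_female, probe_ids, k)]
        points.append(SensitivityFdrPoint(
            k,
            float(np.mean(m)) if m else float("nan"),
            float(np.mean(f)) if f else float("nan"),
        ))
    return points


def curve_to_frame(points: list[SensitivityFdrPoint]) -> pd.DataFrame:
    return pd.DataFrame([(p.k, p.sensitivity, p.fdr) for p in points],
                        columns=["k", "sensitivity", "fdr"])
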