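"""The reference exome: per-probe RPKM mean and SD across a panel of normals.

The reference serves two roles: the diploid coverage baseline (for the X
dosage analysis) and the cross-sample variance model behind the deviation
filter that removes capture-efficiency artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageProfile
from .io_formats import TargetSet

#: Probes whose cross-panel SD falls below this floor (RPKM units) are flagged
#: unusable: a zero-variance probe would yield an infinite z-score.
SD_FLOOR = 1e-6


@dataclass
class ReferenceExome:
    """Per-probe RPKM mean/SD over a panel of normal samples."""

    n_samples: int
    mean: pd.Series   # probe_id -> mean RPKM across the panel
    sd: pd.Series     # probe_id -> sample SD (n-1 denominator)
    usable: pd.Series  # probe_id -> sd >= SD_FLOOR

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"mean": self.mean, "sd": self.sd,
                           "n": self.n_samples, "usable": self.usable.astype(int)})
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceExome":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(int(df["n"].iloc[0]), df["mean"], df["sd"], df["usable"].astype(bool))


def build_reference(panel: list[CoverageProfile], targets: TargetSet,
                    sd_floor: float = SD_FLOOR) -> ReferenceExome:
    """Average the panel's RPKM per probe; SD uses the n-1 denominator.

    Requires at least two normalized profiles covering the full target set.
    Panel order does not matter.
    """
    if len(panel) < 2:
        raise ValueError(f"reference panel needs >=2 samples, got {len(panel)}")
    want = targets.probe_ids
    cols = {}
    for p in panel:
        if p.rpkm is None:
            raise ValueError(f"sample {p.sample_id}: rpkm not computed")
        rp = p.rpkm.reindex(want)
        if rp.isna().any():
            missing = rp.index[rp.isna()][:3].tolist()
            raise ValueError(f"sample {p.sample_id}: probes missing from profile, e.g. {missing}")
        cols[p.sample_id] = rp
    mat = pd.DataFrame(cols)
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    return ReferenceExome(len(panel), mean, sd, sd >= sd_floor)


def per_probe_z(profile: CoverageProfile, ref: ReferenceExome) -> pd.Series:
    """Signed per-probe z-score (rpkm_i - mean_i) / sd_i, usable probes only.

    The deviation filter takes absolute values downstream; the X-chromosome
    analysis uses the signed value against the -1.5 SD boundary.
    """
    if profile.rpkm is None:
        raise ValueError(f"sample {profile.sample_id}: rpkm not computed")
    usable = ref.usable[ref.usable].index
    rp = profile.rpkm.reindex(usable)
    return (rp - ref.mean[usable]) / ref.sd[usable]
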