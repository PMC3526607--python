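import numpy as np
import pandas as pd
import pytest

from exome2cnv import (CnaEvent, CoverageProfile, SimConfig, TargetProbe, TargetSet,
                       build_reference, rpkm_normalize, simulate_cohort)


@pytest.fixture
def small_targets() -> TargetSet:
    """Nine handmade probes on two chromosomes, 200 bp each, flank 50."""
    probes = []
    for c, chrom in enumerate(["chr1", "chr2"]):
        for k in range(5 if chrom == "chr1" else 4):
            s = 1000 + 2000 * k
            probes.append(TargetProbe(f"{chrom}_p{k}", chrom, s, s + 200,
                                      s - 50, s + 250))
    return TargetSet(probes)


def profile_from_rpkm(sample_id: str, targets: TargetSet, rpkm_values) -> CoverageProfile:
    """Profile with prescribed RPKM values (counts back-derived, total 1e6)."""
    total = 1_000_000
    rpkm = pd.Series(np.asarray(rpkm_values, dtype=float), index=targets.probe_ids)
    counts = (rpkm * targets.lengths.values * total / 1e9).round().astype(int)
    return CoverageProfile(sample_id, counts, total, rpkm)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but full simulated cohort: one 30-probe het loss on chr1."""
    cfg = SimConfig(n_probes=600, n_chroms=4, panel_size=6, depth_mean=85_000,
                    events=(CnaEvent("chr1", 40, 30, 1),), seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_reference(tiny_cohort):
    return build_reference(tiny_cohort.panel, tiny_cohort.targets)
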