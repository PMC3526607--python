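"""Synthetic exome-capture coverage cohorts with known copy-number truth.

The generative model: each probe i has a cohort-wide capture efficiency
e_i ~ LogNormal(0, efficiency_sigma) (capture + sequencing efficiency, shared
by every sample prepared with the same protocol), and each sample s adds
per-probe multiplicative wobble w_si ~ LogNormal(mean 1, sigma) — the
inter-sample capture variability that creates false positives. A configurable
fraction of probes ("noisy probes", optionally in consecutive runs) get a
much larger wobble sigma; within a run the wobble draw is shared per sample
(regional capture variability is correlated, so a bad run shifts coherently
and mimics a CNA). Read counts are Poisson:

    counts_si ~ Poisson(e_i * w_si * f_si * L_i * depth_scale)

where f_si = fraction-weighted copy factor (c/2 mixed by tumor purity and
subclonality) and depth_scale calibrates the expected diploid on-target total
to depth_mean. Log-normal-mixed Poisson gives the overdispersion real capture
data shows without a separate dispersion parameter.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import CoverageProfile, rpkm_normalize
from .io_formats import GRCH37_PAR, TargetProbe, TargetSet


@dataclass(frozen=True)
class CnaEvent:
    """One injected alteration, addressed by probe index within a chromosome."""

    chrom: str
    start_probe: int
    n_probes: int
    copy_number: int  # 0 (homozygous loss), 1 (het loss), 3 (gain), ...
    clonal: bool = True


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults emulate the real study scaled to desk size: ~141 on-target reads
    per probe (a 3e7-read exome over 213k targets) on 2e4 probes across 22
    autosomes, probe lengths log-normal around a 235 bp median, a panel of 20
    normals, and 95% tumor purity.
    """

    n_probes: int = 20000
    n_chroms: int = 22
    #: Optional per-chromosome share of probes (length n_chroms, any positive
    #: scale). None distributes probes evenly. Real exomes are uneven — chr21
    #: carries ~1% of coding targets — which matters because RPKM divides by
    #: the sample's own on-target total, so an event's effect on the genome-wide
    #: baseline scales with its share of that total.
    chrom_probe_weights: tuple[float, ...] | None = None
    probe_length_median: float = 235.0
    probe_length_sigma: float = 0.45
    gap_mean_bp: float = 10000.0
    flank_bp: int = 50
    panel_size: int = 20
    depth_mean: float = 2.82e6
    efficiency_sigma: float = 0.5
    sample_wobble_sigma: float = 0.10
    noisy_probe_fraction: float = 0.01
    noisy_probe_sigma: float = 0.8
    noisy_run_length: int = 1
    purity: float = 0.95
    subclone_fraction: float = 0.4
    events: tuple[CnaEvent, ...] = ()
    seed: int = 0


@dataclass
class SimulatedCohort:
    """A simulated target set, normal panel, tumor/normal pair, and truth."""

    config: SimConfig
    targets: TargetSet
    efficiencies: np.ndarray
    wobble_sigma: np.ndarray   # per-probe wobble SD (inflated at noisy probes)
    noisy_mask: np.ndarray
    panel: list[CoverageProfile]
    tumor: CoverageProfile
    truth: pd.DataFrame

    @property
    def matched_normal(self) -> CoverageProfile:
        """The tumor's matched normal; also a member of the panel."""
        return self.panel[0]


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


def simulate_targets(config: SimConfig) -> TargetSet:
    """Draw a sorted synthetic target set; deterministic per seed."""
    rng = _rng(config.seed, 1)
    if config.chrom_probe_weights is None:
        per = np.full(config.n_chroms, config.n_probes // config.n_chroms)
        per[: config.n_probes % config.n_chroms] += 1
    else:
        w = np.asarray(config.chrom_probe_weights, dtype=float)
        if len(w) != config.n_chroms or (w <= 0).any():
            raise ValueError("chrom_probe_weights must hold one positive weight "
                             "per chromosome")
        frac = w / w.sum() * config.n_probes
        per = np.maximum(1, np.floor(frac).astype(int))
        # hand the remaining probes to the largest fractional parts
        short = config.n_probes - int(per.sum())
        if short > 0:
            for c in np.argsort(-(frac - np.floor(frac)))[:short]:
                per[c] += 1
        elif short < 0:
            for c in np.argsort(frac - np.floor(frac)):
                if short == 0:
                    break
                if per[c] > 1:
                    per[c] -= 1
                    short += 1
    probes = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n = int(per[c])
        lengths = np.maximum(
            50, rng.lognormal(np.log(config.probe_length_median),
                              config.probe_length_sigma, n)).astype(int)
        gaps = rng.exponential(config.gap_mean_bp, n).astype(int) + 200
        starts = np.cumsum(gaps) + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for k in range(n):
            s, e = int(starts[k]), int(starts[k] + lengths[k])
            probes.append(TargetProbe(f"{chrom}:{s}-{e}", chrom, s, e,
                                      max(0, s - config.flank_bp), e + config.flank_bp))
    return TargetSet(probes)


def draw_efficiencies(config: SimConfig, targets: TargetSet
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort-wide per-probe efficiencies, wobble sigmas, and the noisy mask.

    Noisy probes are drawn either scattered (noisy_run_length == 1) or as runs
    of consecutive probes within a chromosome, the capture-variability failure
    mode the deviation filter exists to reject.
    """
    rng = _rng(config.seed, 2)
    n = len(targets)
    eff = rng.lognormal(0.0, config.efficiency_sigma, n)
    noisy = np.zeros(n, dtype=bool)
    n_noisy = int(round(config.noisy_probe_fraction * n))
    run = max(1, config.noisy_run_length)
    if n_noisy:
        slices = list(targets.chrom_slices().values())
        n_runs = max(1, n_noisy // run)
        for _ in range(n_runs):
            sl = slices[rng.integers(len(slices))]
            width = sl.stop - sl.start
            if width <= run:
                continue
            a = sl.start + int(rng.integers(width - run))
            noisy[a:a + run] = True
    sigma = np.where(noisy, config.noisy_probe_sigma, config.sample_wobble_sigma)
    return eff, sigma, noisy


def simulate_profile(targets: TargetSet, efficiencies: np.ndarray,
                     copy_factor: np.ndarray | float, depth_mean: float,
                     wobble_sigma: np.ndarray | float,
                     rng: np.random.Generator, sample_id: str,
                     normalize: bool = True,
                     shared_noise_ids: np.ndarray | None = None) -> CoverageProfile:
    """One sample's Poisson counts under the log-normal efficiency model.

    copy_factor is the per-probe expected dosage relative to diploid (1.0 for
    two copies); depth_scale is calibrated so a diploid sample's expected
    on-target total equals depth_mean. shared_noise_ids (int per probe, -1 for
    independent) makes probes with the same id share one wobble draw within
    this sample: regional capture variability is correlated across neighboring
    probes, which is what turns a noisy run into a coherent CNA-mimicking
    shift rather than scattered spikes.
    """
    lengths = targets.df["length"].values.astype(float)
    copy_factor = np.broadcast_to(np.asarray(copy_factor, dtype=float), lengths.shape)
    sig = np.broadcast_to(np.asarray(wobble_sigma, dtype=float), lengths.shape)
    depth_scale = depth_mean / float(np.sum(efficiencies * lengths))
    z = rng.normal(0.0, 1.0, lengths.shape)
    if shared_noise_ids is not None:
        for rid in np.unique(shared_noise_ids[shared_noise_ids >= 0]):
            members = np.flatnonzero(shared_noise_ids == rid)
            z[members] = z[members[0]]
    wobble = np.exp(z * sig - sig ** 2 / 2.0)
    lam = efficiencies * wobble * copy_factor * lengths * depth_scale
    counts = rng.poisson(lam)
    prof = CoverageProfile(sample_id, pd.Series(counts, index=targets.probe_ids),
                           int(counts.sum()))
    return rpkm_normalize(prof, targets) if normalize and prof.total_on_target else prof


def noisy_run_ids(noisy_mask: np.ndarray) -> np.ndarray:
    """Label maximal consecutive stretches of noisy probes 0, 1, ...; -1
    elsewhere. Singleton stretches behave exactly like independent probes.
    """
    ids = np.full(len(noisy_mask), -1)
    rid = -1
    prev = False
    for i, flag in enumerate(noisy_mask):
        if flag and not prev:
            rid += 1
        if flag:
            ids[i] = rid
        prev = flag
    return ids


def event_copy_factor(config: SimConfig, targets: TargetSet) -> np.ndarray:
    """Per-probe tumor dosage factor f*c/2 + (1-f), f = cell fraction carrying
    each event (purity for clonal, purity*subclone_fraction for subclonal).
    Raises when events overlap.
    """
    factor = np.ones(len(targets))
    touched = np.zeros(len(targets), dtype=bool)
    slices = targets.chrom_slices()
    for ev in config.events:
        if ev.chrom not in slices:
            raise ValueError(f"event chromosome {ev.chrom} not in target set")
        sl = slices[ev.chrom]
        a = sl.start + ev.start_probe
        b = a + ev.n_probes
        if ev.start_probe < 0 or b > sl.stop:
            raise ValueError(f"event {ev} outside chromosome {ev.chrom}")
        if touched[a:b].any():
            raise ValueError(f"overlapping events at {ev.chrom}")
        touched[a:b] = True
        f = config.purity * (1.0 if ev.clonal else config.subclone_fraction)
        factor[a:b] = f * ev.copy_number / 2.0 + (1.0 - f)
    return factor


def truth_table(config: SimConfig, targets: TargetSet) -> pd.DataFrame:
    """BED-like truth records with expected tumor/normal log2 ratio."""
    rows = []
    slices = targets.chrom_slices()
    for ev in config.events:
        sl = slices[ev.chrom]
        sub = targets.df.iloc[sl.start + ev.start_probe: sl.start + ev.start_probe + ev.n_probes]
        f = config.purity * (1.0 if ev.clonal else config.subclone_fraction)
        factor = f * ev.copy_number / 2.0 + (1.0 - f)
        rows.append({
            "chrom": ev.chrom, "start": int(sub["start"].iloc[0]),
            "end": int(sub["end"].iloc[-1]), "first_probe": ev.start_probe,
            "n_probes": ev.n_probes, "copy_number": ev.copy_number,
            "clonal": ev.clonal,
            "expected_log2": float(np.log2(max(factor, 1e-6))),
            "direction": "loss" if ev.copy_number < 2 else "gain",
        })
    cols = ["chrom", "start", "end", "first_probe", "n_probes",
            "copy_number", "clonal", "expected_log2", "direction"]
    return pd.DataFrame(rows, columns=cols)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Panel of diploid normals plus one tumor with the configured events.

    panel[0] doubles as the tumor's matched normal (the panel may legitimately
    contain the matched normal). Byte-identical for a fixed seed.
    """
    targets = simulate_targets(config)
    eff, sigma, noisy = draw_efficiencies(config, targets)
    run_ids = noisy_run_ids(noisy)
    panel = [
        simulate_profile(targets, eff, 1.0, config.depth_mean, sigma,
                         _rng(config.seed, 10 + s), f"normal{s:02d}",
                         shared_noise_ids=run_ids)
        for s in range(config.panel_size)
    ]
    factor = event_copy_factor(config, targets)
    tumor = simulate_profile(targets, eff, factor, config.depth_mean, sigma,
                             _rng(config.seed, 9), "tumor",
                             shared_noise_ids=run_ids)
    return SimulatedCohort(config, targets, eff, sigma, noisy, panel, tumor,
                           truth_table(config, targets))


# ---------------------------------------------------------------------------
# X-chromosome male/female cohorts


@dataclass
class XCohort:
    """Hemizygous- and diploid-X samples on a simulated chrX target set."""

    targets: TargetSet
    males: list[CoverageProfile]
    females: list[CoverageProfile]
    par: tuple = GRCH37_PAR


def simulate_x_cohort(n_males: int = 55, n_females: int = 31,
                      n_x_probes: int = 800, n_autosome_probes: int = 19200,
                      depth_per_probe: float = 141.0,
                      efficiency_sigma: float = 0.5, wobble_sigma: float = 0.10,
                      probe_length_median: float = 235.0, seed: int = 0) -> XCohort:
    """Males carry one copy of chrX outside the GRCh37 PARs, two inside;
    females two everywhere; both sexes are diploid on the autosomal bulk.

    The autosomal probes matter: RPKM divides by the sample's total on-target
    reads, and a hemizygous X only leaves the male/female ratio near 1:2
    because chrX is a small fraction (~4% by default, as in a real exome) of
    that total. An X-only design would renormalize the deficit away.
    """
    rng = np.random.default_rng([seed, 101])
    probes: list[TargetProbe] = []

    def draw_chrom(chrom: str, n: int, span: int) -> None:
        lengths = np.maximum(50, rng.lognormal(np.log(probe_length_median), 0.45,
                                               n)).astype(int)
        starts = np.sort(rng.integers(0, span - 3000, n))
        for k in range(1, n):  # nudge overlapping neighbors apart
            if starts[k] < starts[k - 1] + lengths[k - 1] + 10:
                starts[k] = starts[k - 1] + lengths[k - 1] + 10
        probes.extend(
            TargetProbe(f"{chrom}:{int(s)}-{int(s + l)}", chrom, int(s), int(s + l),
                        max(0, int(s) - 50), int(s + l) + 50)
            for s, l in zip(starts, lengths))

    n_auto_chroms = 8
    per = np.full(n_auto_chroms, n_autosome_probes // n_auto_chroms)
    per[: n_autosome_probes % n_auto_chroms] += 1
    for c in range(n_auto_chroms):
        draw_chrom(f"chr{c + 1}", int(per[c]), 240_000_000)
    draw_chrom("chrX", n_x_probes, 155_260_000)
    targets = TargetSet(probes)
    n = len(targets)
    eff = np.random.default_rng([seed, 102]).lognormal(0.0, efficiency_sigma, n)
    mid = (targets.df["start"].values + targets.df["end"].values) // 2
    on_x = (targets.df["chrom"] == "chrX").values
    in_par = np.zeros(n, dtype=bool)
    for _, a, b in GRCH37_PAR:
        in_par |= on_x & (mid >= a) & (mid < b)
    male_factor = np.where(on_x & ~in_par, 0.5, 1.0)
    depth_mean = depth_per_probe * n
    males = [simulate_profile(targets, eff, male_factor, depth_mean, wobble_sigma,
                              np.random.default_rng([seed, 200 + s]), f"male{s:02d}")
             for s in range(n_males)]
    females = [simulate_profile(targets, eff, 1.0, depth_mean, wobble_sigma,
                                np.random.default_rng([seed, 300 + s]), f"female{s:02d}")
               for s in range(n_females)]
    return XCohort(targets, males, females)
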