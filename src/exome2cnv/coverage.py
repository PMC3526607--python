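"""Per-probe read counting and RPKM normalization.

RPKM here is reads mapped per kilobase of capture probe per million on-target
mapped reads: rpkm_i = counts_i * 1e9 / (length_bp_i * total_on_target).
A read is assigned to every probe whose flanked interval (+/- flank bp) its
aligned span overlaps by at least one base, but contributes only once to the
on-target total, so overlapping probes do not inflate the library-size term.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .io_formats import TargetSet

log = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 30


@dataclass
class CoverageProfile:
    """Per-probe read counts and RPKM values for one sample.

    counts and rpkm are pandas Series indexed by probe_id in target order.
    """

    sample_id: str
    counts: pd.Series
    total_on_target: int
    rpkm: pd.Series | None = None

    def copy(self) -> "CoverageProfile":
        return CoverageProfile(self.sample_id, self.counts.copy(), self.total_on_target,
                               None if self.rpkm is None else self.rpkm.copy())


def count_reads(alignment_path: str | Path, targets: TargetSet,
                mapq_min: int = DEFAULT_MAPQ_MIN, sample_id: str | None = None) -> CoverageProfile:
    """Count qualifying reads per flanked target interval from a BAM/SAM file.

    A read qualifies when it is mapped, not a duplicate, not secondary or
    supplementary, and has MAPQ >= mapq_min. It increments the count of every
    probe whose flanked interval its aligned span overlaps (>=1 bp); it adds 1
    to total_on_target if it overlaps at least one probe. Paired-end mates are
    counted as independent reads.

    The flank width is the one baked into the TargetSet at read_targets time.
    """
    alignment_path = str(alignment_path)
    trees: dict[str, IntervalTree] = {}
    for chrom, sl in targets.chrom_slices().items():
        sub = targets.df.iloc[sl]
        trees[chrom] = IntervalTree.from_tuples(
            (int(fs), int(fe), i) for i, fs, fe in zip(sub.index, sub["flank_start"], sub["flank_end"])
        )
    counts = np.zeros(len(targets), dtype=np.int64)
    total = 0
    mode = "r" if alignment_path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(alignment_path, mode) as af:
        is_bam = af.is_bam
        if is_bam and not af.has_index():
            raise FileNotFoundError(f"{alignment_path}: BAM index required (.bai missing)")
        bam_contigs = set(af.references or ())
        missing = [c for c in trees if c not in bam_contigs]
        if missing and len(missing) == len(trees):
            raise ValueError(
                f"{alignment_path}: no target contig found in alignment header; "
                f"examples of missing contigs: {missing[:3]} vs header {sorted(bam_contigs)[:3]}"
            )
        if missing:
            log.warning("%d target contig(s) absent from %s (e.g. %s)",
                        len(missing), alignment_path, missing[:3])

        def handle(read):
            nonlocal total
            if (read.is_unmapped or read.is_duplicate or read.is_secondary
                    or read.is_supplementary or read.mapping_quality < mapq_min):
                return
            tree = trees.get(read.reference_name)
            if tree is None:
                return
            hits = tree.overlap(read.reference_start, read.reference_end)
            if hits:
                total += 1
                for h in hits:
                    counts[h.data] += 1

        if is_bam:
            for chrom in trees:
                if chrom in bam_contigs:
                    for read in af.fetch(chrom):
                        handle(read)
        else:
            for read in af.fetch(until_eof=True):
                handle(read)
    sid = sample_id or Path(alignment_path).stem
    return CoverageProfile(sid, pd.Series(counts, index=targets.probe_ids), int(total))


def rpkm_normalize(profile: CoverageProfile, targets: TargetSet) -> CoverageProfile:
    """Fill in rpkm_i = counts_i * 1e9 / (length_bp_i * total_on_target).

    Uses the unflanked probe length. Raises on an empty sample.
    """
    if profile.total_on_target <= 0:
        raise ValueError(f"sample {profile.sample_id}: empty sample (total_on_target = 0)")
    lengths = targets.lengths.reindex(profile.counts.index)
    if lengths.isna().any():
        raise ValueError(f"sample {profile.sample_id}: counts index does not match target set")
    rpkm = profile.counts.astype(float) * 1e9 / (lengths * profile.total_on_target)
    return CoverageProfile(profile.sample_id, profile.counts, profile.total_on_target, rpkm)


def load_count_table(path: str | Path, targets: TargetSet,
                     normalize: bool = True) -> list[CoverageProfile]:
    """Load a TSV count matrix (rows = probes, columns = samples, first column
    probe_id) into one CoverageProfile per column.

    total_on_target is taken from a "#total_on_target" comment header when
    present (written by write_count_table); otherwise it falls back to the
    column sum, which is exact whenever every read hit exactly one probe.
    """
    totals: dict[str, int] | None = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#total_on_target\t"):
        header_vals = first.rstrip("\n").split("\t")[1:]
        with open(path) as fh:
            fh.readline()
            cols = fh.readline().rstrip("\n").split("\t")[1:]
        totals = {c: int(v) for c, v in zip(cols, header_vals)}
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    want = targets.probe_ids
    missing = want.difference(df.index)
    extra = df.index.difference(want)
    if len(missing) or len(extra):
        raise ValueError(
            f"{path}: probe set mismatch with targets "
            f"({len(missing)} missing, e.g. {list(missing[:3])}; "
            f"{len(extra)} extra, e.g. {list(extra[:3])})"
        )
    df = df.reindex(want)
    profiles = []
    for col in df.columns:
        counts = df[col].astype(np.int64)
        total = totals[str(col)] if totals and str(col) in totals else int(counts.sum())
        prof = CoverageProfile(str(col), counts, total)
        if normalize:
            prof = rpkm_normalize(prof, targets)
        profiles.append(prof)
    return profiles


def write_count_table(profiles: list[CoverageProfile], path: str | Path) -> None:
    """Write profiles as a probe x sample TSV count matrix.

    The on-target totals go in a "#total_on_target" comment header so that a
    round-trip through load_count_table reproduces the same RPKM values.
    """
    df = pd.DataFrame({p.sample_id: p.counts for p in profiles})
    df.index.name = "probe_id"
    with open(path, "w") as fh:
        fh.write("#total_on_target\t" + "\t".join(str(p.total_on_target) for p in profiles) + "\n")
        df.to_csv(fh, sep="\t")
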