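"""Readers and writers for capture targets, aCGH segments, and call/segment output.

All internal coordinates are 0-based half-open (BED convention). Any 1-based
input dialect is converted at the boundary, never inside the pipeline.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: GRCh37 pseudoautosomal regions, converted from the published 1-based
#: inclusive spans (PAR1 chrX:60001-2699520, PAR2 chrX:154931044-155260560)
#: to 0-based half-open.
GRCH37_PAR = (("chrX", 60000, 2699520), ("chrX", 154931043, 155260560))

_CHROM_RE = re.compile(r"^(?:chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: chr1..chr22, chrX, chrY, then others lexically."""
    m = _CHROM_RE.match(chrom)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (int(tok), "")
        rank = {"X": 23, "Y": 24, "M": 25, "MT": 25}[tok]
        return (rank, "")
    return (100, chrom)


@dataclass(frozen=True)
class TargetProbe:
    """One capture target region ("probe"/"exon" unit)."""

    probe_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    flank_start: int = -1
    flank_end: int = -1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"probe {self.probe_id}: end ({self.end}) must exceed start ({self.start})")

    @property
    def length_bp(self) -> int:
        """Unflanked target length; the RPKM denominator length."""
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class TargetSet:
    """An ordered, genome-sorted collection of target probes.

    Backed by a pandas DataFrame with columns probe_id, chrom, start, end,
    flank_start, flank_end, length. Probe order is (chromosome natural order,
    start, end); per-chromosome probe indices are contiguous.
    """

    def __init__(self, probes: Iterable[TargetProbe]):
        rows = [
            (p.probe_id, p.chrom, p.start, p.end, p.flank_start, p.flank_end, p.length_bp)
            for p in probes
        ]
        if not rows:
            raise ValueError("empty target set")
        df = pd.DataFrame(
            rows, columns=["probe_id", "chrom", "start", "end", "flank_start", "flank_end", "length"]
        )
        df["_ckey"] = df["chrom"].map(chrom_sort_key)
        if not df[["_ckey", "start", "end"]].apply(tuple, axis=1).is_monotonic_increasing:
            log.info("targets were not genome-sorted; sorting internally")
        df = df.sort_values(["_ckey", "start", "end"], kind="mergesort").drop(columns="_ckey")
        df = df.reset_index(drop=True)
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].head(3).tolist()
            raise ValueError(f"duplicate probe_id(s): {dups}")
        self.df = df
        self.chrom_order: list[str] = list(dict.fromkeys(df["chrom"]))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield TargetProbe(row.probe_id, row.chrom, row.start, row.end,
                              row.flank_start, row.flank_end)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.df["probe_id"])

    @property
    def lengths(self) -> pd.Series:
        return pd.Series(self.df["length"].values, index=self.df["probe_id"].values)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous positional slice of self.df per chromosome, in order."""
        out: dict[str, slice] = {}
        chroms = self.df["chrom"].values
        bounds = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1], True])
        for a, b in zip(bounds[:-1], bounds[1:]):
            out[chroms[a]] = slice(int(a), int(b))
        return out


@dataclass(frozen=True)
class AcghSegment:
    """An aCGH-derived segment, consumed as evaluation input only."""

    chrom: str
    start: int
    end: int
    direction: str  # "loss" | "gain"
    mean_log2: float | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"aCGH segment {self.chrom}:{self.start}-{self.end}: end must exceed start")
        if self.direction not in ("loss", "gain"):
            raise ValueError(f"direction must be loss/gain, got {self.direction!r}")
        if self.mean_log2 is not None:
            if (self.direction == "loss") != (self.mean_log2 < 0):
                raise ValueError(
                    f"direction {self.direction} inconsistent with mean_log2 {self.mean_log2}"
                )


def read_targets(path: str | Path, flank_bp: int = 50) -> TargetSet:
    """Read a BED3+ file of capture targets.

    Each probe carries a flanked interval [start - flank_bp, end + flank_bp)
    clipped at 0, used only for read assignment; length_bp stays unflanked.
    Derived probe ids are "chrom:start-end" when the name column is absent.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    probes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed coordinates: {e}") from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: zero- or negative-length interval")
            name = parts[3] if len(parts) >= 4 and parts[3] not in (".", "") else f"{chrom}:{start}-{end}"
            probes.append(TargetProbe(name, chrom, start, end,
                                      max(0, start - flank_bp), end + flank_bp))
    return TargetSet(probes)


def read_acgh_segments(path: str | Path) -> list[AcghSegment]:
    """Read aCGH segments from a minimal TSV: chrom, start, end, then either a
    loss/gain label or a numeric log2 column (direction from its sign).

    A header line is auto-skipped when its start column is non-numeric.
    Records with log2 == 0 and no label are rejected with a warning.
    """
    segs: list[AcghSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                if lineno == 1 or not segs:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
            label = parts[3].strip().lower()
            if label in ("loss", "gain"):
                # label is authoritative; a 5th column is kept as mean_log2
                # only when it is a sign-consistent number
                mean_log2 = None
                if len(parts) >= 5:
                    try:
                        v = float(parts[4])
                        if (label == "loss") == (v < 0) and v != 0:
                            mean_log2 = v
                    except ValueError:
                        pass
                segs.append(AcghSegment(parts[0], start, end, label, mean_log2))
            else:
                try:
                    val = float(label)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: fourth column is neither loss/gain nor numeric") from None
                if val == 0:
                    log.warning("%s:%d: zero log2 with no loss/gain label; record skipped", path, lineno)
                    continue
                segs.append(AcghSegment(parts[0], start, end, "loss" if val < 0 else "gain", val))
    return segs


_CALL_COLUMNS = ("chrom", "start", "end", "direction", "n_exons",
                 "mean_log2", "deviation_score", "filter_status")


def write_calls(calls: Sequence, path: str | Path, header_comment: str | None = None) -> None:
    """Write CNA calls as a BED-like TSV with a header row."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.direction}\t{c.n_exons}\t"
                f"{c.mean_log2:.6g}\t{c.deviation_score:.6g}\t{c.filter_status}\n"
            )


def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a calls TSV written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing call columns {sorted(missing)}")
    return df


def write_seg(sample_id: str, segments: Sequence, track, path: str | Path) -> None:
    """Write segments in SEG format (sample, chrom, start, end, num probes, seg mean)."""
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for s in segments:
            start, end = track.segment_span(s)
            fh.write(f"{sample_id}\t{s.chrom}\t{start}\t{end}\t{s.n_probes}\t{s.seg_mean:.6g}\n")


def write_targets_bed(targets: TargetSet, path: str | Path) -> None:
    """Write a target set back out as BED4 (unflanked coordinates)."""
    with open(path, "w") as fh:
        for row in targets.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.probe_id}\n")


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a plain BED3 of intervals (e.g. PAR regions or exclusion masks)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 fields")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
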