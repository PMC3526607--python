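"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in the most literal way possible (explicit loops,
direct formulas) and shares no code with the package internals it checks.
"""
from __future__ import annotations

import math

import numpy as np


def brute_force_counts(reads, probes, mapq_min=30):
    """Per-probe read counts and on-target total by exhaustive interval scan.

    reads: list of (chrom, start, end, mapq, is_dup, is_secondary) tuples;
    probes: list of (probe_id, chrom, flank_start, flank_end).
    """
    counts = {p[0]: 0 for p in probes}
    total = 0
    for chrom, start, end, mapq, is_dup, is_secondary in reads:
        if is_dup or is_secondary or mapq < mapq_min:
            continue
        hit = False
        for pid, pchrom, fs, fe in probes:
            if pchrom == chrom and start < fe and end > fs:
                counts[pid] += 1
                hit = True
        if hit:
            total += 1
    return counts, total


def two_pass_mean_sd(values_by_sample):
    """Mean and n-1 SD per position via the textbook two-pass formulas."""
    arr = np.asarray(values_by_sample, dtype=float)  # samples x probes
    n = arr.shape[0]
    means, sds = [], []
    for j in range(arr.shape[1]):
        m = sum(arr[i, j] for i in range(n)) / n
        ss = sum((arr[i, j] - m) ** 2 for i in range(n))
        means.append(m)
        sds.append(math.sqrt(ss / (n - 1)))
    return np.array(means), np.array(sds)


def cbs_exhaustive_best_arc(x, min_width=2):
    """Argmax over every contiguous window [i, j) of the two-sample t-type
    statistic, by direct double loop. Ties: smallest window, then smallest i.
    Returns (stat_scaled_by_sd, i, j) or None for degenerate input.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_width:
        return None
    sd = np.std(x, ddof=1)
    if sd == 0:
        return None
    total = float(np.sum(x))
    best = None
    for k in range(min_width, n - min_width + 1):
        for i in range(0, n - k + 1):
            w = float(np.sum(x[i:i + k]))
            diff = w / k - (total - w) / (n - k)
            stat = abs(diff) / (sd * math.sqrt(1.0 / k + 1.0 / (n - k)))
            if best is None or stat > best[0]:
                best = (stat, i, i + k)
    return best


def cbs_perm_decision(x, n_perm, alpha, seed_key, min_width=2):
    """Full (no early stop) permutation accept/reject for the best arc,
    drawing rng.permutation(x) once per permutation from default_rng(seed_key).
    """
    obs = cbs_exhaustive_best_arc(x, min_width)
    if obs is None:
        return False
    rng = np.random.default_rng(seed_key)
    # ties (a permutation reproducing the observed window content) count as
    # exceedances regardless of rounding, mirroring the implementation's rule
    tol = 1e-9 * max(1.0, abs(obs[0]))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        stat = cbs_exhaustive_best_arc(perm, min_width)
        if stat is not None and stat[0] >= obs[0] - tol:
            exceed += 1
    return exceed / n_perm < alpha


def max_arc_stat_fast(x, min_width=2):
    """Max two-sample arc statistic (scaled by the overall n-1 SD), cumsum
    based but written directly from the formula; used where the O(n^3) double
    loop is too slow. Cross-checked against cbs_exhaustive_best_arc.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = np.std(x, ddof=1)
    if n < 2 * min_width or sd == 0:
        return None
    csum = np.concatenate(([0.0], np.cumsum(x)))
    total = csum[-1]
    best = -1.0
    for k in range(min_width, n - min_width + 1):
        win = csum[k:] - csum[:-k]
        mean_in = win / k
        mean_out = (total - win) / (n - k)
        stat = np.abs(mean_in - mean_out) / (sd * math.sqrt(1.0 / k + 1.0 / (n - k)))
        best = max(best, float(stat.max()))
    return best


def cbs_perm_decision_fast(x, n_perm, alpha, seed_key, min_width=2):
    """Full (no early stop) permutation accept/reject using max_arc_stat_fast,
    drawing rng.permutation(x) once per permutation from default_rng(seed_key).
    """
    obs = max_arc_stat_fast(x, min_width)
    if obs is None:
        return False
    rng = np.random.default_rng(seed_key)
    tol = 1e-9 * max(1.0, abs(obs))
    exceed = 0
    for _ in range(n_perm):
        stat = max_arc_stat_fast(rng.permutation(x), min_width)
        if stat is not None and stat >= obs - tol:
            exceed += 1
    return exceed / n_perm < alpha


def pearson_r2(x, y):
    """Closed-form Pearson r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.sum(xm * ym) / math.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))
    return r ** 2
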