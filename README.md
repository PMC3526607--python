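# exome2cnv

Somatic copy-number alteration (CNA) calling from paired tumor/normal exome
depth of coverage, using a reference panel of normal exomes to separate real
dosage changes from capture artifacts.

## The problem

Exome capture measures each targeted exon's read depth, which is roughly
proportional to its copy number — but the proportionality constant varies by
orders of magnitude across exons (capture efficiency, GC content, mappability)
and also varies between samples. A tumor/normal pair shares the same capture
chemistry, so the per-exon depth *ratio* cancels most of that variation; a
panel of unrelated normals then provides a per-exon variability model to
reject exons whose depth is intrinsically unstable.

## Method overview

For tumor $T$ and matched normal $N$ over target probes $i = 1 \dots m$:

1. **Coverage → RPKM.** Reads with MAPQ ≥ 30 (excluding duplicates and
   secondary/supplementary alignments) are counted against probes extended by
   ±50 bp flanks; a read overlapping several probes increments each of them
   but counts once in the on-target total $C$. Then
   $\mathrm{rpkm}_i = c_i \cdot 10^9 / (L_i \cdot C)$
   with $L_i$ the unflanked probe length.
2. **Ratio track.** $r_i = \log_2\!\big((\mathrm{rpkm}^T_i + 0.01) /
   \mathrm{rpkm}^N_i\big)$, excluding probes with normal RPKM < 2.
3. **Outlier smoothing.** A probe whose distance to the nearest of its ±10
   neighbors exceeds 4 robust SDs is shrunk to that neighbor ± 3 robust SDs
   (robust SD = $1.4826 \cdot \mathrm{median}|\Delta r| / \sqrt{2}$).
4. **Circular binary segmentation (CBS).** Per chromosome, the maximal
   two-sample arc statistic
   $|\bar r_{\text{in}} - \bar r_{\text{out}}| \big/
   \big(s \sqrt{1/k + 1/(n-k)}\big)$
   over all contiguous windows is tested by permutation ($\alpha = 0.01$);
   accepted splits recurse.
5. **Candidate calls.** Segments with ≥ 6 exons and $|\text{seg mean}| > 0.3$
   become gain/loss candidates.
6. **Deviation filter.** Against a reference panel (per-probe mean $\mu_i$ and
   SD $\sigma_i$ over the normals), a candidate passes only if its mean
   standardized deviation $\frac{1}{k}\sum_i |\mathrm{rpkm}^T_i - \mu_i| /
   \sigma_i \ge 1.5$ — a segment that looks aberrant in the ratio but sits
   within the panel's normal variation is a capture artifact, not a CNA.

A separate chromosome-X module validates dosage calling where truth is known
by karyotype: male/female RPKM ratio on non-PAR X probes (expected 0.5), and
one-copy classification of $k$-probe windows at $\bar z < -1.5$, whose female
false-positive rate follows the Gaussian tail $\Phi(-1.5\sqrt{k})$.

See [docs/methods.md](docs/methods.md) for the full model, parameter
rationale, and known detection limits.

## Worked example

```python
from exome2cnv import (CnaEvent, PipelineConfig, SimConfig, run_pipeline,
                       simulate_cohort)

cfg = SimConfig(n_probes=6000, n_chroms=6, panel_size=20, depth_mean=850_000,
                events=(CnaEvent("chr2", 150, 25, 1),   # het deletion, 25 probes
                        CnaEvent("chr5", 400, 40, 4)),  # amplification, 40 probes
                seed=7)
cohort = simulate_cohort(cfg)

result = run_pipeline(cohort.tumor, cohort.matched_normal, cohort.panel,
                      cohort.targets, PipelineConfig(n_perm=1000, seed=7))

for call in result.passing:
    print(f"{call.chrom}:{call.start}-{call.end}  {call.direction:4s} "
          f"n_exons={call.n_exons:3d}  mean_log2={call.mean_log2:+.3f}  "
          f"deviation={call.deviation_score:.2f}")
```

Output:

```
chr2:1687803-1881658  loss n_exons= 25  mean_log2=-0.958  deviation=3.48
chr5:4158571-4491427  gain n_exons= 39  mean_log2=+0.967  deviation=6.79
```

Both injected events are recovered with their expected log-ratios
($\log_2 0.525 \approx -0.93$ for a heterozygous deletion at purity 0.95;
$\log_2 1.95 \approx +0.96$ for copy number 4) and nothing else passes.

A command-line interface covers the same pipeline on files:

```sh
exome2cnv count    --targets targets.tsv --bam tumor.bam --out tumor.counts.tsv
exome2cnv call     --targets targets.tsv --tumor tumor.counts.tsv \
                   --normal normal.counts.tsv --panel panel.counts.tsv \
                   --out calls.tsv --seg-out calls.seg
exome2cnv simulate --out simdir --seed 7
exome2cnv xcheck   --targets targets.tsv --males males.counts.tsv \
                   --females females.counts.tsv --out x_curve.tsv
exome2cnv compare  --targets targets.tsv --calls calls.tsv --acgh acgh.seg \
                   --out concordance.tsv
```

Count tables are multi-sample TSVs (`exome2cnv count` accepts `--bam`
repeatedly; `--panel`, `--males`, `--females` each take one such table).

## Tests

```sh
python -m pytest            # full suite (~6 min, single core)
python -m pytest tests/test_acceptance.py   # acceptance criteria only
```

Unit tests check every module against independent brute-force oracles
(exhaustive window search, literal two-pass statistics, naive interval
overlap) in `tests/oracles.py`.

## Layout

```
src/exome2cnv/
  io_formats.py     target/calls/SEG/BED readers and writers, PAR coordinates
  coverage.py       BAM counting, count tables, RPKM normalization
  reference.py      reference panel of normals (per-probe mean/SD, z-scores)
  segmentation.py   ratio track, outlier smoothing, CBS
  calling.py        candidate calling, deviation filter, pipeline driver
  chrx.py           chromosome-X validation (dosage ratio, window FDR)
  concordance.py    comparison of exome calls against aCGH segments
  simulate.py       synthetic cohorts with known copy-number truth
  cli.py            `exome2cnv` command-line interface
```
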