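# Methods

This document records the statistical model behind each pipeline stage, the
default parameters with their rationale, the simulator's generative model,
and the measured limits of the method. Notation: tumor $T$, matched normal
$N$, reference panel of normals $P$, probes $i = 1 \dots m$ in genome order.

## 1. Coverage and RPKM

Reads are filtered to MAPQ ≥ 30, excluding duplicates and
secondary/supplementary alignments. Each probe is extended by ±50 bp flanks
for overlap testing; a read overlapping $k$ flanked probes increments all
$k$ counts but contributes exactly once to the sample's on-target total $C$.
RPKM uses the *unflanked* probe length $L_i$:

$$\mathrm{rpkm}_i = \frac{c_i \cdot 10^9}{L_i \cdot C}.$$

Conservation identity (tested to machine precision):
$c_i = \mathrm{rpkm}_i \cdot L_i \cdot C / 10^9$ for every probe.

**Renormalization physics.** Because $C$ is the sample's own on-target
total, RPKM is invariant to any genome-wide multiplicative factor: a whole-
genome duplication produces a tumor/normal RPKM ratio of exactly 1, not 2.
More generally, an event of copy factor $f$ covering a fraction $p$ of the
on-target probe mass inflates $C$ by $1 + (f-1)p$, so every probe's log-ratio
is shifted by $-\log_2(1 + (f-1)p)$ and the event's own segment mean is
$\log_2 f - \log_2(1 + (f-1)p)$. For focal events ($p \lesssim 2\%$) the
shift is under 0.01 and negligible; for chromosome-arm or larger events it is
a real, intrinsic property of self-normalized depth data that any user of
segment means for copy-number quantification must account for. Example: a
gained chromosome holding 25% of the probe mass yields a segment mean of
$\log_2 1.5 - \log_2 1.125 \approx 0.41$, not $0.585$.

**Small-count log bias.** $E[\log_2(\mathrm{rpkm}^T/\mathrm{rpkm}^N)]$ over
Poisson counts exceeds $\log_2(E[T]/E[N])$ slightly for gains (measured
+0.013 at 141 reads/probe with sample-wobble 0.10, decaying to +0.001 at 10×
that depth): Jensen's inequality on the concave $\log$ penalizes the smaller
normal mean more than the larger tumor mean. At default simulated depth this
partially offsets the renormalization shift for gains.

## 2. Ratio track

$$r_i = \log_2\frac{\mathrm{rpkm}^T_i + 0.01}{\mathrm{rpkm}^N_i},
\qquad \text{keeping only probes with } \mathrm{rpkm}^N_i \ge 2.$$

The 0.01 pseudocount keeps homozygous deletions finite; the normal-RPKM
floor removes probes whose denominator is too unstable to carry ratio
information.

## 3. Outlier smoothing

Singleton spikes are shrunk before segmentation. With robust SD
$\hat\sigma = 1.4826 \cdot \mathrm{median}_i |r_{i+1} - r_i| / \sqrt{2}$
(per chromosome), a probe whose distance to the *nearest* of its ±10
neighbors exceeds $4\hat\sigma$ is moved to that nearest neighbor
$\pm 3\hat\sigma$ (sign toward the original value). Two outliers within 10
positions of each other protect one another and survive — intentional, since
a genuine two-probe event should reach segmentation intact.

## 4. Circular binary segmentation

Per chromosome, over all contiguous windows $[i, j)$ with
$\min(j-i,\, n-(j-i)) \ge$ `min_width` (default 2), the statistic

$$S = \max_{i<j} \frac{|\bar r_{[i,j)} - \bar r_{\text{complement}}|}
{s\sqrt{\tfrac1k + \tfrac1{n-k}}}, \qquad s = \text{SD}(r, \text{ddof}=1)$$

is compared against its permutation null: the probes are randomly permuted
(`n_perm` draws, default 10 000) and the split is accepted when the fraction
of permuted maxima $\ge S$ falls below $\alpha = 0.01$. The overall SD $s$ is
permutation-invariant and cancels from the comparison. Accepted windows
contribute both cut points and the segments recurse. Early stopping: the
permutation loop aborts as soon as $\lceil \alpha\,n_{\text{perm}}\rceil$
exceedances are seen, which cannot change the decision.

Two determinism details that matter for reproducibility:

- **Tie rule.** A permutation can reproduce the observed window content
  exactly, giving a mathematical tie with the observed statistic; floating-
  point evaluation order can round such ties either way. Ties (within a
  $10^{-9}$ relative tolerance) are counted as exceedances — slightly
  conservative, and it makes accept/reject decisions identical across
  independent re-implementations of the same statistic.
- **Complementary arcs.** The edge windows $[0,k)$ and $[k,n)$ describe the
  same split with exactly equal statistics; which one an argmax reports
  depends on scan order. The induced cut set, not the $(i,j)$ pair, is the
  canonical answer.

**Measured detection boundaries** (default simulation, 1% noisy probes): the
permutation null maximum is driven by the heavy-tailed noisy probes and sits
near raw statistic 2.0–2.5 per chromosome. A heterozygous 8-probe loss
(signal $\approx -0.93$) reaches raw $\approx 2.3$, i.e. $p \approx 0.013$ —
just outside $\alpha = 0.01$ regardless of `n_perm`. 8-probe losses are
therefore borderline, 12-probe losses are solid, while *gains* carry weaker
signal (one extra copy gives $\log_2 1.48 \approx 0.56$ at purity 0.95) and
need roughly 2.5× the probes of an equal-copy-change loss: 12-probe gains
sit at the boundary, 30-probe gains are solid.

## 5. Candidate calling and deviation filter

Segments become candidates when `n_exons ≥ 6` and
$|\text{seg mean}| > 0.3$ (strict), directioned by sign. A candidate passes
the deviation filter iff its mean standardized deviation against the panel,

$$\frac{1}{k}\sum_{i \in \text{seg}}
\frac{|\mathrm{rpkm}^T_i - \mu_i|}{\sigma_i} \ge 1.5
\quad (\mu_i, \sigma_i: \text{panel mean and ddof-1 SD, } \sigma_i
\text{ floored at } 10^{-6}),$$

computed over probes with usable panel statistics. The premise: a segment
that is aberrant in the tumor/normal ratio but sits within the panel's
normal variation is capture noise, not copy number.

**Operating regime (measured).** The filter's power depends on the
variability of the artifact-prone probes. When artifact probes are only
mildly variable, the rare ones that *do* form a candidate are conditioned on
extreme draws (3–30× normal depth in the tumor) — indistinguishable from
genuine focal amplifications, and rightly passed. The filter's designed
failure mode is *highly* variable capture regions (log-scale SD ≳ 1), where
candidates form routinely without tail conditioning while the 1.5-SD
threshold corresponds to ≈ 2.3σ of the skewed lognormal: there it rejects
≈ 90% of artifact candidates while passing 100% of true events (measured
with an 86-normal panel, which estimates $\sigma_i$ to a few percent;
a 20-normal panel carries ~30% relative error on a lognormal SD and lowers
the effective threshold).

Calls overlapping an exclusion BED (e.g. immunoglobulin loci, which
rearrange somatically in lymphocyte-derived samples) are masked before
output.

## 6. Chromosome-X validation

Probes on non-PAR chrX (midpoint outside the GRCh37 pseudoautosomal regions,
0-based [60000, 2699520) and [154931043, 155260560)) with female reference
mean ≥ 2 RPKM and usable SD are selected. Two checks:

- **Dosage ratio.** Mean over male samples and selected probes of
  $\mathrm{rpkm} / \mu^{\text{female}}_i$; one X versus two gives 0.5. Note
  this works because chrX is a small fraction (~4%) of the total target —
  by the renormalization argument above, the male's slightly smaller
  on-target total inflates the ratio by only $\approx 2\%$.
- **Window FDR.** Disjoint $k$-probe windows are called one-copy when mean
  $z < -1.5$ (strict), $z_i = (\mathrm{rpkm}_i - \mu_i)/\sigma_i$. On female
  (two-copy) samples with approximately Gaussian per-probe noise the
  false-call rate follows the closed form $\Phi(-1.5\sqrt{k})$: 6.7% at
  $k=1$, 0.11% at $k=4$, $10^{-5}$ at $k=8$. Sensitivity on males and FDR on
  females as functions of $k$ form the validation curve.

## 7. Simulator

`simulate_cohort` draws a target set (uniform 40–250 bp probes; optional
per-chromosome probe-mass weights for uneven layouts like a small
trisomy-candidate chromosome), per-probe capture efficiencies
$e_i \sim \mathrm{LogNormal}(\cdot, 0.5)$, and per-sample counts

$$c_{si} \sim \mathrm{Poisson}(e_i \cdot w_{si} \cdot f_i \cdot L_i \cdot
d_s), \qquad d_s = \frac{\text{depth}}{\sum_i e_i L_i},$$

where $f_i$ is the truth copy factor
($f = \text{purity} \cdot \text{CN}/2 + 1 - \text{purity}$, diploid
elsewhere; note $f$ deliberately does not enter $d_s$ — sequencers deliver a
fixed read budget regardless of the genome's copy state, which is exactly
what makes the renormalization effect real) and $w_{si}$ is per-sample
lognormal capture wobble (σ = 0.10, mean-corrected). A configurable fraction
of probes (default 1%) is "noisy": their wobble uses a much larger σ
(default 0.8), and when noisy probes are laid down in consecutive runs, all
probes of a run share a single wobble draw per sample — regional capture
variability is correlated, and this is what lets artifact runs form coherent
candidate segments. All randomness flows through
`numpy.random.default_rng([seed, tag])` streams, making every cohort
byte-identical for a fixed seed.

Default scale (20 000 probes, 22 chromosomes, 2.82M on-target reads ⇒ ~141
reads/probe, panel of 20) keeps a full pipeline run at ~10 s with
`n_perm=500`. The acceptance studies use `n_perm` 300–1000; this trades
permutation resolution ($p$-value granularity 1/`n_perm`) for runtime and is
a package-level choice — production use at `n_perm=10000` changes only
borderline decisions near $\alpha$.

## 8. Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| MAPQ minimum | 30 | excludes multi-mapping reads whose depth is locus-ambiguous |
| flank | 50 bp | captures reads overhanging probe edges |
| pseudocount | 0.01 RPKM | keeps homozygous-deletion ratios finite |
| min normal RPKM | 2.0 | unstable-denominator floor |
| smoothing window / trim | ±10, 4σ → 3σ | shrinks singleton spikes, preserves ≥2-probe events |
| CBS α | 0.01 | per-split false-positive rate |
| CBS n_perm | 10 000 | p-value resolution 10⁻⁴ at default α |
| min_width | 2 | smallest arc CBS will cut |
| min exons | 6 | calls below this are not robustly distinguishable from noise runs |
| log2 threshold | 0.3 | ≈ one-copy change at purity ~0.35; excludes drift segments |
| min avg deviation | 1.5 | panel-SD units; see §5 |
| X one-copy z | −1.5 | gives the closed-form FDR ladder in §6 |

## 9. Known limitations

- Segment means of large (arm-scale+) events are shifted by self-
  normalization (§1); the package reports the measured mean, it does not
  attempt to re-anchor the baseline.
- No GC-content or mappability covariate correction: the matched normal and
  the deviation filter absorb most of it, but unpaired designs would need
  explicit correction.
- No allele-fraction (BAF) input, so copy-neutral LOH is invisible.
- Purity/ploidy are not estimated; log-ratios are reported as measured.
- CBS detection limits as measured in §4: gains need substantially more
  probes than losses at equal copy change; sub-8-probe events at default
  noise are below the reliable detection boundary.
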