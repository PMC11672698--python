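# Methods

## The differentiation scan

The analytical core is a per-SNP two-group fixation index in Nei's
G_ST form. With group allele-b frequencies p₁, p₂ estimated from the
non-missing calls of each group,

    p̄   = (p₁ + p₂) / 2
    H_T  = 2 p̄ (1 − p̄)
    H_S  = [2 p₁(1−p₁) + 2 p₂(1−p₂)] / 2
    F_ST = (H_T − H_S) / H_T = (p₁ − p₂)² / (2 H_T)

The pooled frequency is unweighted (Nei's canonical definition with equal
subpopulation weights); a sample-size-weighted variant is available via
`ScanParams(weighting="size")`. No small-sample (Nei–Chesser) bias
correction is applied: with hundreds of animals per group the upward bias
is on the order of 1/(2n) ≈ 10⁻³ and uniform across markers, so it cannot
create spatial structure. F_ST is undefined when H_T = 0 (pooled
monomorphic) or a group has no calls at the marker; such SNPs are excluded
*before* smoothing so fit neighborhoods span informative markers only.
The statistic is invariant to allele-coding swaps, so the arbitrary
first-seen coding of PED input does not affect results.

### Smoothing

Raw F_ST is smoothed per chromosome by locally weighted regression:
at each marker the q = ⌈span·n⌉ nearest markers by base-pair distance are
fit with a degree-1 weighted least-squares line using tricube weights
(1 − (d/d_max)³)³, and the fit is evaluated at the marker's own position.
The span is 20/n (capped at 1), so every window holds 20 SNPs regardless
of chromosome marker density; n counts the chromosome's *informative*
markers, consistent with the pre-smoothing exclusion rule. No robustness
iterations are run. Base-pair position, not marker index, is the
predictor, since the smoothing is of positional data. Numerical details:
neighborhoods are selected by stable sort on distance with marker index as
tie-break; the design is centered at the evaluation position before
solving; a degenerate neighborhood (d_max = 0, or zero weighted
x-variance) falls back to the weighted neighborhood mean. On data with a
matching span fraction this smoother agrees with
`statsmodels.nonparametric.lowess(it=0, delta=0)` to machine precision,
but the q-nearest/tie-break semantics here are defined exactly so results
are reproducible bit-for-bit.

### Outlier calling and signatures

Per chromosome, markers whose smoothed F_ST strictly exceeds
mean + 3·SD of that chromosome's smoothed values are flagged (upper
one-sided Shewhart rule). The default sigma is the sample (n−1) standard
deviation; `sd_estimator="moving_range"` switches to the individuals-chart
estimate mean(|xᵢ−xᵢ₋₁|)/1.128, which is tighter on positively
autocorrelated series and therefore flags more aggressively. Consecutive
flagged SNPs on a chromosome are merged into a selection signature while
each inter-outlier gap is ≤ 1 Mb (configurable `signature_max_gap_bp`; the
merge rule is this package's own convention — the field has no standard —
and is recorded in the run manifest). The signature peak is the member
with the highest smoothed value, ties resolved to the lowest position.

Two structural facts about the rule worth knowing:

- A chromosome whose smoothed values are constant has SD 0 and can flag
  nothing; more generally a single spike among n values can never exceed
  3 sample SDs unless n ≥ 11, because the maximum standardized deviation
  is (n−1)/√n.
- Smoothed background F_ST is a weighted average of ~20 right-skewed
  (χ²₁-like) raw values and remains noticeably right-skewed, so the upper
  3-SD tail holds roughly 0.5% of background markers rather than the 0.13%
  a normal distribution would give. The scan is therefore a ranking and
  localization tool: flagged markers concentrate in and around genuinely
  divergent regions, but a genome-wide flag list at 3 SD always contains a
  background contingent, and no multiple-testing guarantee is implied.

## Quality control

Samples with call rate < 0.95 are removed first; marker statistics are
then computed on the surviving samples, pooled across groups, and markers
are removed by the first failing filter in the order call rate ≤ 0.975,
MAF ≤ 0.02, exact Hardy–Weinberg p < 10⁻⁵. All thresholds are retention
conditions read with their strict inequality, so boundary cases (e.g. MAF
exactly 0.02) fail closed. The HWE test is the standard two-sided exact
test: conditional on the allele counts, heterozygote counts are weighted
by n!/(n_AA! n_Aa! n_aa!)·2^h and the p-value sums all configurations no
more likely than the observed one (mid-p variant behind a flag, default
off). The X chromosome (label 27) is treated as autosomal because the
intended panels are all-female.

Pooling groups before the HWE test is deliberate but consequential: truly
divergent markers show a Wahlund heterozygote deficit, so the HWE filter
preferentially removes the *strongest* differentiation signals (on the
benchmark simulation the handful of HWE removals are all planted SNPs,
and the MAF filter removes a few more whose frequencies drifted to the
margins in both groups). This mirrors the standard practice the pipeline
reproduces and slightly attenuates, never inflates, the scan signal.

The MDS structure check uses classical (Torgerson) scaling of the
pairwise distance 1 − IBS/2, where IBS is the allele-sharing score over
jointly non-missing markers. Eigenvalues within 10⁻¹⁰ of zero (relative
to the largest) are treated as zero, and each axis's sign is fixed by
making its first nonzero loading positive, so coordinates are
deterministic.

## Thermal-environment grouping

Each flock is matched to its nearest weather station by the haversine
great-circle distance on a 6,371 km sphere; ties break by lexicographic
station id. Flocks farther than 50 km from every station are UNASSIGNED,
and their samples are logged and excluded from the scan rather than
raising an error, because synthetic fixtures deliberately include such
flocks. A matched flock is HE when the station's 20-year mean maximum
temperature is strictly above 21 °C and CE otherwise — the boundary side
at exactly 21 °C is a convention (cold), surfaced in configuration.
Nearest-station matching (rather than averaging all stations within
50 km) is the minimal reading of a neighborhood criterion; both the
breaking temperature and the radius are configurable.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: two groups
of several hundred ewes (defaults 395 + 430 in 23 + 23 flocks), 27
chromosomes × 2,000 SNPs (≈54k typed markers), ~1% missing calls, and an
ancestral minor-allele floor of 0.05 (post-QC chip panels rarely carry
rarer ancestral variants). Group allele frequencies follow the
Balding–Nichols model — Beta(p(1−F)/F, (1−p)(1−F)/F) around a uniform
ancestral frequency p — with F the background level genome-wide and the
planted level inside declared regions; genotypes are binomial(2, p_group),
i.e. within-group Hardy–Weinberg, so the HWE filter has calibrated
behavior. Positions are uniform, sorted, and de-duplicated by +1 bp
nudging so marker maps are strictly increasing. `simulate_study` adds a
coherent geography (cool stations clustered away from warm ones, flocks
placed within a few km of a station of their group's kind, one
sample-less flock > 50 km from everything) and a GTF with at least one
gene inside each planted region and one > 250 kb from any region.

A modeling fact that matters when interpreting results: with only two
sampled demes, the realized Nei G_ST is ≈ F/2, not F, because H_T is
computed from the two demes rather than the (unobserved) ancestral pool —
e.g. background F = 0.01 yields mean realized G_ST ≈ 0.005, and planted
F = 0.15 yields ≈ 0.07. Planted regions are declared in base pairs, so
their SNP content is binomial around the expectation (a 15% chromosome
window over 200 uniform SNPs holds ~30).

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure (each SNP draws independently), pedigree/relatedness,
genuine selective sweeps (planted regions are blocks of elevated drift,
not sweeps), chromosome-specific lengths or marker densities, hemizygous
X calls, and spatially structured missingness. Passing tests therefore
demonstrate the statistical machinery — frequency estimation, smoothing,
chart limits, window arithmetic — under a clean neutral-drift null, not
performance on real LD-structured chip data.

## Annotation and over-representation

A gene is reported for a significant marker when its 1-based inclusive
span intersects [position − 250 kb, position + 250 kb]; both window edges
are inclusive and strand is ignored. The signed distance is 0 when the
gene covers the marker, negative when the gene lies before it. Anchors
default to all outlier SNPs; `anchors="peaks"` restricts to signature
peaks. Over-representation of the deduplicated gene list against a
user-supplied GMT term map uses the upper-tail hypergeometric probability
with Benjamini–Hochberg adjustment across tested terms; terms with zero
query hits are excluded from the BH family, and term members outside the
declared universe are ignored. This local test replaces online enrichment
services so runs are deterministic and self-contained.

## Problem sizes and reproducibility

The benchmark configuration used throughout the test suite and in
`scripts/acceptance.py` is 2×400 samples, 27 chromosomes × 200 SNPs,
background F = 0.01, three planted 15 Mb regions at F = 0.15 — large
enough that group frequencies are estimated to ±0.018 and each chromosome
supports a 20-SNP smoothing window, small enough that a 20-replicate
stability study runs in well under a minute. All randomness flows from a
single integer seed through `numpy.random.default_rng`; pipeline reruns
with identical configuration produce byte-identical TSVs (timings are
confined to the JSON manifest).

## Known limitations

- The 3-SD chart on smoothed values has no false-discovery control; the
  ~0.5% skew-driven background flag rate discussed above is intrinsic.
- The exact HWE test is computed per marker in a Python loop; at chip
  scale (50k markers × 800 samples) QC takes a few seconds, which is
  acceptable but not optimized.
- PED/MAP files cannot carry allele-coding metadata, so a write/read
  round trip restores genotype content up to per-marker allele
  orientation (first-seen coding); every downstream statistic is
  invariant to this.
- The VCF reader handles biallelic SNPs only and skips multiallelic
  records with a warning.
- Signature merging at a fixed 1 Mb gap is a convention; on sparse maps
  it can bridge unrelated peaks and on dense maps split one sweep.
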