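# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `goosemethyl`.

## Methylcytosine identification

WGBS reads methylation as C/T ratios per cytosine: unmethylated cytosines
are bisulfite-converted and sequenced as T, methylated cytosines are
protected. Two error sources inflate apparent methylation — incomplete
conversion and T→C sequencing error. Since vertebrate methylation is
overwhelmingly restricted to CG dinucleotides, the pooled methylation rate
over all covered CHG and CHH cytosines is used as the empirical
false-positive rate:

    rate = (n_mCHH + n_mCHG) / n_depth

where the numerator sums methylated-read counts over non-CG sites and the
denominator sums their total depth. Each cytosine with depth *n* and
methylated count *k* is then tested one-sided against this background:
p = P(X ≥ k | Binomial(n, rate)), and the site is a methylcytosine when
p < α with α = 0.01 (99% confidence) **and** n ≥ 4. The one-sided form is
deliberate: only an excess of methylated reads evidences 5mC. Sites below
the depth floor are excluded from every downstream CG statistic, not merely
from mC calls.

Per-base quality is summarised by Q = 10·log10(p/(1−p)) with p the
correct-call probability; inverting at the conventional Q ≥ 20 cut gives
p = 100/101 ≈ 99.01%, the ">99% correct" guarantee. When the input table
carries a per-site `q` column the filter is applied; tables without
qualities are assumed pre-filtered by the upstream base-caller.
SNP-induced false mC (a read where a non-CG mC is actually a G variant)
must be removed upstream at alignment time; per-cytosine tables no longer
carry the read-level evidence needed to detect it.

The binomial tail is computed by `scipy.stats.binom.sf`; tests verify exact
agreement (≤ 1e−12 absolute) with point-mass enumeration for all depths
≤ 30 over a grid of error rates, and monotonicity in the methylated count.

## CpG islands, shores, shelves

An island satisfies three thresholds jointly: GC fraction > 0.5, length
> 200 bp, observed/expected CpG > 0.6, with
obs/exp = (#CpG × L)/(#C × #G). The thresholds define *what* an island is
but not *how* to find one, so detection follows the Takai–Jones scheme:
every 201-bp window (step 1) passing all thresholds seeds an island;
overlapping or adjacent seeds merge; each merged interval is trimmed to its
outermost CpG and revalidated, shrinking greedily from whichever end
improves composition if the merged interval dilutes below a threshold.
Consequences tested explicitly: every emitted island passes the thresholds,
and no passing 201-bp window lies wholly outside the detected islands.
Windows containing N never seed (undefined composition); N bases are
excluded from both counts and effective length.

Shores are the ±2 kb flanks of islands minus the islands; shelves the next
±2 kb minus islands and shores; all clipped at chromosome ends. Where
features of neighbouring islands collide, precedence island > shore > shelf
guarantees the three kinds partition their covered bases.

## Regional methylation and profiles

The methylation level of any region is the depth-weighted quotient
Σ meth / Σ depth over qualifying strand-specific sites of one context
(depth ≥ 4); a region with no qualifying site is *missing*, never zero.
Strands are kept separate throughout — dyad pooling happens only in the
promoter per-site comparison, where it is explicit.

Metagene profiles bin each gene in transcription orientation: 100-bp bins
over a 2-kb flank on each side and 60 percent-of-length bins over the body
(the body bin count is a package convention chosen so flank and body bins
plot on one axis). Bin levels pool read counts over all genes, and the
plotted series is a centred 5-bin moving average whose window shrinks
symmetrically at the series ends rather than padding with fabricated
values.

Group comparisons of per-replicate region levels use Welch's two-sided
t-test — the unequal-variance default is the safest choice at n = 3.
Genome-wide sample structure uses fixed 10-kb tiles (CG level per tile per
sample; tiles with < 5 qualifying sites in any sample are dropped so
distances stay comparable), Ward hierarchical clustering on Euclidean
distances, and PCA on per-window-centred levels via SVD.

## DMR and DMG detection

Replicate counts are pooled within each group at shared CG positions
(pooled depth ≥ 4 in both groups). Windows of 5 consecutive CpG sites
slide one site at a time; a window is discarded if any neighbouring pair of
its sites is > 1 kb apart. Each window's pooled counts form a 2×2 table
tested with a two-sided Fisher's exact test; p-values are
Benjamini–Hochberg adjusted across all tested windows. Windows passing
|Δ| ≥ 0.25 and q ≤ 0.05 merge when overlapping or within 1 kb with the
same direction; merged regions are re-scored on their full CpG content
(counts, Fisher p, BH across merged candidates) and must still satisfy
every threshold. A post-hoc validator recomputes each reported DMR from
the raw calls on every pipeline run.

Fisher's exact test on pooled counts was chosen as the window test because
it is exact at WGBS depths and brute-force verifiable (tests compare it to
rational-arithmetic hypergeometric enumeration). Pooling replicates before
testing matches the count-based window criteria; replicate-aware
(beta-binomial) modelling is out of scope. Of the two printed DMR
criterion sets in circulation (three-consecutive-CpG at p/FDR < 0.01
versus ≥ 5 CpGs, |Δ| ≥ 0.25, q ≤ 0.05 with ≤ 1 kb gaps), the stricter,
fully quantified set is primary and the 1-kb rule is retained as the
merge/gap constraint.

A gene is DMR-related for a region type (upstream 2 kb, body,
downstream 2 kb) when ≥ 1 DMR overlaps that region by ≥ 1 bp; its net
methylation direction is the depth-weighted sign of overlapping DMR deltas,
and exact ties exclude the gene from quadrant classification (the quadrant
scheme admits no mixed class). A DMG requires
|log2((level_a + 0.01)/(level_b + 0.01))| ≥ 1 at BH FDR ≤ 0.001, adjusted
across genes within each region type; the 0.01 pseudocount keeps fully
demethylated regions finite.

## Expression and integration

Expression classes from mean FPKM: high ≥ 100; 10 ≤ middle < 100;
0 < low < 10; none = 0 exactly (the printed class boundaries overlap at
zero; exactly-zero is read as "none"). Differential expression uses a
Welch t-test on log2(FPKM + 1) with BH adjustment and requires
|log2 FC| ≥ 1 and FDR ≤ 0.05. This is a deliberately simple, dependency-
free DE test defined by this package — it is not a reimplementation of a
negative-binomial count model, and with n = 3 its power profile differs
from one; planted fold changes of 4 are comfortably inside its range.

DEG × DMR-related intersections are classified into E±&M± quadrants from
the two directions; counts are reported per region type and quadrant, and
mismatched comparison orientations (different group labels on the two
inputs) are an error rather than a silent mislabel.

The promoter per-site comparison emulates a pyrosequencing readout: within
a TSS-relative window (default −723 to −480, inclusive, in transcription
orientation), each CpG dyad pools its plus- and minus-strand reads per
replicate; sites covered (pooled depth ≥ 4) in every replicate of both
groups get per-replicate levels and an unadjusted per-site Welch t-test —
per-site significance marks, no multiple-testing correction, matching how
such panels are conventionally presented. The window is configurable
because assay coordinates are sometimes quoted relative to the start codon
rather than the TSS.

## The synthetic-data generator

The generator produces the study the analysis assumes, at desk scale:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 500 kb | CpG-depleted background (GC ≈ 0.40, obs/exp ≈ 0.25) |
| islands | 10 per chromosome | embedded CpG-rich blocks (400–800 bp, GC ≈ 0.60, obs/exp ≈ 0.85), each verified against the island thresholds |
| genes | 200 | 1.5–3 kb, 1–5 exons, random strand |
| design | 2 breeds × 3 stages × 3 replicates | WZE-like and STE-like; E15/E23/P1 |
| depth | Poisson, mean 30 | per cytosine, both strands |
| conversion error | 0.8% | symmetric leakage; sets non-CG methylation inside the realistic 0.69–0.88% band |
| CG surface | intergenic 0.70, body 0.76, islands 0.15 | plus a Gaussian TSS dip (sd 900 bp, per-gene depth 0.05–0.95) and a TTS-proximal ramp (≤ 0.18 over the last 20% of the body) |
| breed/stage offsets | STE +0.015; WZE −0.02 (E23), −0.05 (P1) | STE-like stays high, WZE-like demethylates fastest late |
| planted DMRs | 40 × 8 CpGs, Δ = 0.5 | levels 0.2 vs 0.7, region types cycling upstream/body/downstream |
| expression | log2 FPKM = base + coupling × promoter methylation + noise | coupling −12 log2 units per unit methylation; replicate sd 0.1; 8% silent genes; 30 planted DE genes at FC 4 |
| promoter target | 13 CpGs at TSS−723…−480 | one plus-strand gene rewritten to hold exactly 13 dyads; breed levels 0.75 vs 0.35 |

Methylated counts are binomial given depth, with success probability the
true level plus symmetric conversion-error leakage (an unmethylated read
appears methylated with probability 0.008); non-CG sites have true level
zero, which is what makes them a clean error proxy. The TTS ramp scales
with each gene's latent expression rank except for the top quintile,
reproducing the observed pattern that the body/TTS methylation–expression
correlation is positive only outside the high-expression class.

Planted DE genes are drawn from expressed genes whose upstream 2 kb is
clear of every planted DMR: at this gene density a DMR in one gene's flank
can lie inside a neighbour's promoter, and the coupling would otherwise
fold that methylation difference into the neighbour's expression and
confound the planted fold change.

Everything regenerates bit-identically from (config, seed): each stage
draws from its own numbered `SeedSequence([seed, stream])` substream, and
group iteration orders are fixed (never over hash-ordered sets).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level artefacts (PCR duplicates,
M-bias, SNP-induced false mC), mappability gaps and coverage
autocorrelation, beta-binomial overdispersion between replicates,
chromatin-domain-scale methylation structure, and realistic gene density.
On that last point: with 200 genes plus flanks covering most of a 1-Mb toy
genome, TSS dips depress the pooled CG level to ≈ 56%, below the ≈ 65%
typical of a vertebrate muscle methylome whose genome is mostly
intergenic. The planted effect sizes (Δ = 0.5 DMRs, fold change 4) are
conventions chosen to be clearly detectable at depth 30 with n = 3, not
estimates of real breed differences.

## Numerical and policy choices

- Coordinates are 0-based half-open internally; GFF3 is converted on read;
  BED is written natively. For minus-strand genes the TSS is the *last*
  genomic base of the span.
- Degenerate Welch inputs (zero variance in both groups) yield p = 1 for
  equal means and p = 0 otherwise rather than NaN.
- BH adjustment is delegated to `statsmodels.stats.multitest.multipletests`
  and cross-checked in tests against a hand-written step-up oracle.
- The moving-average and metagene edge policies never extrapolate: windows
  shrink, uncovered bins stay NaN.
- Windows with insufficient sites propagate as missing and are dropped
  row-wise before clustering, keeping all pairwise distances on the same
  support.
- The pipeline's stages communicate only through declared files, recorded
  in a manifest with SHA-256 checksums; re-running with unchanged inputs
  and parameters skips a stage, and a repeated run is byte-identical.
- Default problem sizes (1-Mb genome, 18 samples, depth 30) keep a full
  pipeline run in the low minutes on a single CPU while leaving every
  planted signal strongly detectable.

## Known limitations

- The DE test is FPKM-based, not count-based; genes with FPKM near the
  +1 pseudocount are hard to call regardless of true fold change.
- DMR q-values are BH over Fisher windows; no smoothing or
  autocorrelation-aware correction is attempted.
- CHG/CHH methylation is carried through calling and level computation but
  not profiled or tested differentially (CG is the analysis focus).
- Whether upstream per-cytosine tables merged dyads is dialect-dependent;
  this package's dialect is strand-separated by definition, and dyad
  merging is always explicit.
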