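# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices and the known limitations of `mbcomics`.

## Count model and differential expression

Counts are modelled as negative binomial with mean `μ` and dispersion `φ`
so that `var = μ + φμ²`; `φ` is the squared biological coefficient of
variation (BCV²).

**Normalization.** Between-library scaling uses classic TMM: the reference
library is the one whose upper quartile of count fractions is closest to
the mean upper quartile; per-library log2 ratios (M) are trimmed 30% from
each tail and 5% from each tail of average abundance (A), and the factor is
the plain (unweighted) mean of the surviving M values, normalized to
geometric mean 1. We deliberately omit the precision weighting some
implementations add; the doubly-trimmed unweighted mean is simpler to
verify against a direct computation and differs negligibly on these data.

**Exact test.** For a two-group contrast, counts are rescaled to a common
effective library size (library size × TMM factor, geometric-mean target)
and summed per group. Sums of `n` i.i.d. NB(μ, φ) variables are NB with
size `n/φ`; conditioning the group-B sum on the total gives a
Beta-negative-binomial null that does not involve μ. The p-value is the
double tail: the total probability of all splits no more likely than the
observed one. When `n/φ` exceeds 1e8 the conditional law is numerically
binomial and we use the exact binomial two-sided test, which is also the
analytic φ→0 limit. Swapping the group labels negates log2fc and preserves
p by construction.

**Dispersion estimation.** Per-feature method-of-moments estimates are
pooled over the within-group variances of *every* labelled subset in the
matrix (not only the two groups under contrast) — one dispersion per
feature for the whole design, as is standard practice, which roughly
doubles the degrees of freedom available at n = 3 per subset. The default
mode is **trended**: features receive the abundance-binned average of the
moment estimates, interpolated over log mean abundance. Two details
matter:

- the prior averages the *unclamped* moment estimates; clamping the
  frequent negative small-sample values to ~0 first would bias the prior
  low and make the exact test anticonservative;
- the bin summary is a tail-winsorized mean, not a median — the moment
  estimator is strongly right-skewed and its median sits well below the
  true value.

A `tagwise` mode (50% shrinkage of the per-feature estimate toward the
trend, weight configurable) and a `common` mode are available. Tagwise
estimates at n = 3 per group couple estimation noise into the test and
push the observed type-I error slightly above the nominal band, so the
moderated trend is the default; measured type-I error at p < 0.05 on
2,000 null NB features (μ = 100, φ = 0.1, 3 vs 3) is 0.05–0.06 with a
Kolmogorov–Smirnov statistic below 0.05 against uniformity, and ≥ 95% of
planted 4-fold effects are recovered at p_adj < 0.05.

**Reporting.** Each feature gets log2fc (normalized group means with a
0.5 pseudocount), raw p, BH-adjusted p, normalized group means, and
`delta_abundance` — the absolute difference of TMM-normalized mean counts,
the quantity the miRNA (>1000) and lncRNA (>100) annotation rules screen.
Display-scale log2 RPKM/RPM uses a pseudocount of 1.

## Core transcriptional signature

A gene joins the signature iff it is DE in the same direction in both
swMBC-vs-NBC contrasts at `p_adj < 1e-29` (the stringent threshold printed
as 10 × 10⁻³⁰, exposed as config) **and** is not significant in the
IgG-vs-IgA contrast at `p_adj ≥ 0.05` (the "cancellation" rule, which we
implement as a formal filter with a configurable threshold). Ig
heavy-chain constant-region features (class `IGHC`) that would otherwise
qualify — IgCμ/IgCδ analogues are strongly down in both switched subsets —
are reported in a separate `excluded` list rather than as members. The
relaxed variant (default `p_adj < 1e-14`) serves the unswMBC-vs-NBC
screen. Heatmap rows are standardized with the population (ddof = 0)
standard deviation so constant rows map to zeros and output is
bit-reproducible; PCA embeds unit-variance-scaled features and reports the
silhouette of the subset labelling plus 95% bivariate-normal prediction
ellipses (χ²₂ quantile).

## Repertoire

The assigner is a deliberately simple germline aligner, not a full
VDJ annotation suite. V is chosen by edit-distance prefix alignment of
each germline V against the read (score = length − 2·distance, equal to
the +1/−1 match/mismatch score for substitution-only alignments); reads
whose best score falls below 30% of the V length (~35% edit distance) are
unassignable and excluded from profiles (counted in QC). J aligns to the
read suffix; D is the best ungapped junction match, called at score ≥ 5.
Because the read model is substitution-only (indels are a non-goal), the
V span used for mismatch enumeration is the full germline prefix rather
than the alignment-located end — the located end drops co-optimal terminal
mismatches and biases the mutation frequency low by ~half a terminal
base's worth.

Mismatches carry FR/CDR labels from the germline V architecture
(IMGT-like FR1/CDR1/FR2/CDR2/FR3 boundaries) and silent/replacement labels
from codon translation in the germline reading frame, using the read codon
with all its substitutions. CDR3 is the peptide strictly between the
conserved V-terminal Cys codon and the J-opening Trp codon; anchors are
excluded from the length.

The mutation frequency is `raw = Σ mismatches / Σ aligned V bases` and
`corrected = max(raw − error_rate, 0)` with `error_rate = 0.008` — a
subtractive correction with a floor, the simplest estimator consistent
with a naive-subset corrected rate of ~0.002 when the raw rate is ~0.010.
The denominator is aligned V-region bases (the V segment is where SHM is
measured); this choice is configurable only by supplying different
annotations.

## Synthetic-data design

The generator's defaults are the study conditions; they are not tuned per
run.

**Layout.** 4 subsets (NBC, unswMBC, IgG, IgA) × 3 subjects = 12 RNA
libraries; 4 NBC + 4 MBC ATAC libraries. mRNA library sizes are drawn
log-uniform from 120k–210k reads (the study's 12–21 M scaled ~100×; a
1000× scale-down leaves ~1.5 counts per gene and nothing can clear a
stringent screen). Small-RNA libraries use 120k–250k and lncRNA slices
12k–21k so that the Δ-abundance annotation rules (>1000 and >100
transcripts) keep their printed meaning.

**Dispersion.** `GeneratorConfig.dispersion` (default 0.1) is the BCV² at
the typical (median) abundance; per-feature dispersions follow the
canonical abundance trend `φ(λ) = floor + (φ₀ − floor)·(λ_ref/λ)`, clipped
to [floor, 2], with floor 0.01 (BCV 0.1 for abundant features — the usual
range for sorted human cell subsets). Setting the floor to `None` gives a
flat dispersion, used by the calibration simulations. The trend is not a
convenience: with a flat φ = 0.1 at n = 3 vs 3 the conditional exact test
is information-bounded near p ≈ 1e-13 for an 8-fold effect *at any
abundance and with any estimator* (the conditional null is
Beta-negative-binomial with size n/φ), so a stringent 1e-29 screen would
be unreachable by construction rather than by implementation. Abundant,
strongly-switched genes with low BCV are exactly the regime in which such
p-values arise in real data.

**Planted mRNA landscape.** 17 up / 7 down core genes at |log2 effect| = 3,
abundant (baseline ≈ 600 for up genes; down genes at 600·2³ so that their
*expressed-state* abundance in NBC matches the expressed state of the up
genes — downregulated signature genes like the TCL1A analogue are among
the most abundant naive-cell transcripts). Switched subsets carry the full
effect; unswMBC carries 0.4 of it (the transitional transcriptome), except
four members (TRPV3/TACI/COL4A4/SAMSN1 analogues) at 0.7, which the
relaxed unsw screen recovers alongside the unswMBC-specific TFEC/ZBTB32
analogues. A moderate background of 445 up / 605 down genes at
|log2 effect| = 1.1 (totals 462/612 with the core) sits at baseline ~60 —
abundances where a p_adj < 0.05 screen can see them; the 1.1 effect keeps
the stringent screen unreachable for background genes even when a
dispersion estimate collapses, preserving an exact 24-gene recovery.
Isotype-specific features (RPS17/RUNX2 analogues higher in IgA) and five
`IGHC`-class features with reciprocal isotype expression complete the
plan. Baselines of all features are lognormal (σ = 1.2) around the
configured medians; expected column totals equal the drawn library sizes.

**miRNA/lncRNA plans.** 6 up / 13 down miRNAs at |log2 effect| = 3 with
baselines placed so every planted miRNA clears Δ > 1000 and the MIR181a/b
analogues drop by >60,000 and >3,000 normalized transcripts; 23 up / 17
down lncRNAs of which exactly 21 clear Δ > 100. The MIAT analogue is
upregulated with the standard transitional attenuation, making its profile
the graded inverse of MIR181's so the planted sponge anticorrelation is
monotone across all 12 libraries.

**Repertoire.** A synthetic germline: 49 V genes in 7 families (97 random
sense codons plus a terminal Cys codon; ~12% of codons substituted within
a family), 27 D genes, 6 J genes opening with Trp. Family usage weights
follow the printed human proportions (V3 55%, V4 18%, V1 17%, …) with a
0.85 geometric decay across members within a family (within-family usage
is uneven in real repertoires, and equal weights would make gene-level
rank correlations meaningless). CDR3 lengths are per-subset normal
(means 16.05/14.86/15.53/15.08 aa, sd 3.3), junctions are
N–D-fragment–N with geometric(0.25) N lengths (keeping D calls noisy, as
observed). Substitutions land i.i.d. at rate `mutation + error` over the
whole read and are attributed to SHM vs error in the truth table at odds
`mutation : error`; rates default to 0.0020 (NBC), 0.0417 (unswMBC),
0.0314 (IgG), 0.0566 (IgA) over an 0.008 error floor.

**ATAC.** Peak categories are multinomial over the Venn plan
(43.6% MBC-only / 11.9% NBC-only / 44.5% shared). 4,198 DARs (51.7% up)
receive ±4-fold effects on the MBC side of shared peaks; 35.4% of planted
DE genes get a same-direction DAR placed 3 kb upstream of the gene body,
and all other peaks live on a gene-free scaffold chromosome so synthetic
concordance traces exactly to planted links. Peaks absent from a
condition's presence flags have counts reduced only mildly (×0.9) in that
condition — presence emulates per-condition peak calling, which is more
sensitive than a count-level differential test, and stronger reductions
would flood the DAR screen with presence-driven calls and distort the
planted up/down split.

**What the generator does not emulate.** Subject-level random effects,
hotspot-biased SHM (WRC/GYW), indels, isoform structure, read-level
qualities, peak calling from reads, and genuine genomic sequence. Passing
tests demonstrate that the pipeline recovers known structure planted under
the stated NB/substitution models — not performance on real libraries,
where dispersion trends, mapping artifacts and biological covariance are
richer.

## ncRNA screens

Seed sites are scanned as reverse-complement matches of miRNA nt 2–7
(6mer core), upgraded by a paired nt 8 (7mer-m8), an A opposite nt 1
(7mer-A1) or both (8mer); one maximal site is reported per core locus, and
if the maximal type is not allowed the best allowed contained type is
reported, so 8mer loci never vanish from 7mer-restricted scans. Duplex
ΔG is a dynamic program over Watson–Crick and G:U wobble pairs with
nearest-neighbor stack energies (Turner-style 37 °C values), a 4.09
kcal/mol initiation penalty, 3.2 per single-side bulge and 2.6 per 1×1
internal loop; it is a hybridization score, not a full secondary-structure
fold — printed fold energies from structure-aware tools are not
comparable, and the score is used only to rank candidate sites.

The target-release rule is: gene upregulated, miRNA downregulated, at
least one site of ≥ 7mer-m8 (configurable down to 6mer), and Spearman
r_s ≤ −0.5 with p < 0.05 between miRNA RPM and gene RPKM across the 12
sorted libraries. The sponge rule is: lncRNA up, miRNA down,
r_s(lncRNA, miRNA) < 0 at p < 0.05, and median r_s(lncRNA, released
targets) > 0; candidates whose miRNA has no released targets are evaluated
on the first three conditions and flagged partial. cis pairs are same
chromosome within 1 Mb (configurable); the thresholds −0.5, 0.05 and the
1 Mb window are explicit configuration because the study reports the
screens without numeric rules.

## Numerical and interface conventions

Coordinates are 0-based half-open everywhere; strand is carried but
ignored by overlap logic. BED loads sorted (stable for ties); FASTA wraps
at 60 columns. All randomness flows through explicit seeds into
counter-based Philox streams (one stream per generator product), so
identical config + seed reproduces byte-identical outputs, which the
pipeline verifies by hashing every output into a manifest. Degenerate
inputs are defined errors: empty groups, zero-total libraries, zero
aligned bases, malformed intervals, p-values outside [0, 1], windows
outside [8, 40] nt, and Venn fractions not summing to 1 are all rejected
rather than coerced.

## Problem sizes used in the checked runs

The default study (10,000 genes, 500 miRNAs, 1,000 lncRNAs, 10,000 peaks,
12 libraries, 10,000 repertoire reads per profiled subset) runs end to end
in well under a minute on one CPU; the test suite simulates at these sizes
where a claim depends on them (signature recovery, Venn fractions, SHM
recovery grid) and at reduced sizes elsewhere.
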