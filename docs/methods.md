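# Methods

## Model and procedure

The package analyzes per-CpG bisulfite counts from two groups of samples
whose genomes may differ by millions of SNVs and indels. The analysis chain
is: (1) build each genotype's personal genome and the coordinate map its
indels induce; (2) lift every sample's CpG counts into one target
coordinate system, discarding CpGs whose C or G position falls inside an
indel; (3) optionally filter sites (shared-only mode, per-sample
heterozygous CpGs, externally known variant CpGs); (4) smooth each sample's
methylation proportions along the genome; (5) score group differences with
per-site t statistics, segment candidate regions, and control family-wise
error with genotype-balanced label permutations.

The central modelling idea is that a CpG absent from a sample's genome is
*missing data*, not 0% methylation. Representing it as zero coverage lets
the smoother ignore it for that sample while the other genotype's data at
the same position — and each genotype's private CpGs nearby — still shape
the local methylation estimate. This is what gives the *unique-included*
mode its power: differences carried entirely by genotype-unique CpGs
propagate, through imputation, into the shared sites where the two groups
can be compared.

## Coordinate maps

A map is a list of colinear blocks `(ref_start, personal_start, length)`
per chromosome, derived purely from the applied variant set (SNVs never
move coordinates; each applied indel ends a block). Both directions are
served by the same blocks; positions between blocks return an explicit
`UNMAPPABLE` sentinel, while out-of-bounds positions raise an error —
the two conditions are never conflated. Round-trip identity
(`map(map(p)) = p` for mutually mappable `p`) is a tested invariant.
Heterozygous variants are applied per `het_policy` (default `reference`:
keep the reference allele, so the map depends only on homozygous indels);
heterozygous site positions are recorded under every policy because the
downstream per-sample filter needs them regardless of which allele went
into the sequence.

## Smoothing

BSmooth-style local regression: at site `x` the window half-width is
`max(h, distance to the ns-th nearest covered site)` (`ns = 70`,
`h = 1000 bp` by default; `ns = 500`, `h = 20 000` for block analysis),
truncated at cluster boundaries (`max_gap = 1e8` bp by default, i.e.
per-chromosome clusters). Observed proportions `M/Cov` are fit by weighted
least squares on a quadratic in position with weights
`Cov × tricube(|d|/w)`; the fitted intercept, clamped to [0, 1], is the
smoothed value. This is a deliberate design choice over full
binomial-likelihood IRLS: it is closed-form per window, exactly
reproducible by an independent normal-equations oracle (agreement ≤ 1e-8 is
a tested property), and exact on constants (≤ 1e-10). Differences from IRLS
are second order at the coverages involved.

Numerical edge cases: windows with fewer than 3 distinct covered positions
drop the polynomial degree 2 → 1 → 0 (weighted mean) rather than failing;
if every in-window site sits exactly at the kernel boundary (`u = 1`, weight
zero), the fit falls back to a coverage-weighted mean including the
boundary; a sample with no covered site in a whole cluster gets missing
values there, recorded, not fatal.

## t statistics, regions and gFWER

Per masked site: `meanDiff = mean(group2) − mean(group1)` of smoothed
values; pooled within-group sd, floored at its 75th percentile over masked
sites and then smoothed with a centered running mean over 101 masked sites
per chromosome; `t = meanDiff / (sd·√(1/n1+1/n2))`. If the floor quantile
is exactly zero (a degenerate all-constant track), the smallest positive raw
sd (or 1e-8) is used so t stays finite. The variance floor/smoothing
conventions are exposed as parameters.

Candidate regions are maximal runs of masked sites with `|t| ≥ cutoff`,
constant sign, and inter-site gaps ≤ `max_gap` (defaults 4.6 / 300 bp;
blocks 2 / 10 000 bp), kept when they have ≥ 3 CpGs and
`|meanDiff| ≥ 0.10`. The mask requires ≥ 3 samples per group at coverage
≥ 2, so genotype-unique sites are never themselves region members in a
genotype-vs-genotype design — their influence is purely through imputation.

Significance: all group relabelings in which each pseudo-group receives
exactly half of every genotype, deduplicated under group-label swap and
excluding the observed assignment when it is itself balanced (a 4+4
two-genotype design yields C(4,2)·C(4,2)/2 = 18). Each permutation re-runs
the full t-statistic computation (including the sd floor) on the reused
smoothed values. A region's gFWER is the fraction of permutations
containing a null region with at least as many CpGs **and** at least as
large `|areaStat|` (ties count against the observed region — the
conservative reading). No significance threshold is imposed; reports
highlight gFWER = 0.

## Diagnostics

Global methylation is the unweighted mean of per-site proportions over
covered CpGs (counting CpGs, not reads, so it is robust to coverage
fluctuations). The wrong-reference simulator converts a
correctly-quantified matrix into what naive alignment to one genotype's
genome would produce: at reference-unique TG/CA sites the non-reference
samples gain full coverage with zero methylated calls (their reads align
mismatch-free); at other-mutation or unmappable reference-unique sites they
stay uncovered; their own private sites vanish. Group-level raw proportions
pool counts within group (ΣM/ΣCov), stable at coverage as low as 2.

At a genotype-unique CpG only one group has data, so the unique-site "mean
difference" of a region is formed across unique classes: mean methylation
of group 2 at group-2-genotype-unique sites minus mean of group 1 at
group-1-genotype-unique sites; when a region contains only one class, the
available side is compared against the other group's mean over the region's
shared CpGs. This rule is one of several defensible definitions; it is
antisymmetric under group swap (a tested property) and is implemented in
one switchable place.

## Synthetic data

The generator emulates a two-genotype divergent-strain experiment. Defaults
(the package's standard study conditions): a 2 Mb chromosome at ~1 CpG per
100 bp, a 10% per-CpG C→T/G→A loss rate in the second genotype (split
evenly between strands so both TG and CA arise), background SNVs at 2×10⁻³
per bp (kept off CpGs so the loss rate stays controlled), indels at 2×10⁻⁴
per bp with lengths 1–6, four samples per genotype, Poisson(15) coverage,
and a latent methylation logit field of mean logit(0.75) and sd 1.0 built
from box-filtered Gaussian noise with a 2 kb correlation length, shared
between genotypes and evaluated at each genotype's own CpG positions via
the coordinate map.

Two deliberate departures from a flat genome make the fixtures behave like
real data. First, the background base process never draws G after C, so CpG
density tracks the configured rate (mammalian genomes are CpG-depleted);
second, planted shared-target DMRs are embedded at island-like CpG density
(0.08/bp) because focal DMRs in real genomes overlap CpG islands/shores —
at background density a ~1 kb effect would be diluted below the 10%
mean-difference threshold by the ns = 70 window, which is itself a faithful
property of the method, not an artifact. Unique-target regions instead gain
genotype-B-unique CpGs by converting TG dinucleotides to CG (rate 0.5
inside the region; 0.01 genome-wide so both genotypes have private CpGs,
mirroring the symmetric unique-CpG structure of real strain pairs). Planted
shifts apply to genotype-B samples, restricted to the configured site class;
unique-region shifts are planted positive so the disparity signature of
unique-driven detection is positive, and shared-region shifts negative so a
|Δ| = 0.4 effect is not clipped against the 0.75 baseline.

What the generator does **not** model: read-level artifacts (M-bias,
conversion errors, mapping ambiguity), non-CpG methylation, biological
replicate variance beyond binomial sampling, CpG-island hypomethylation,
and mutation classes other than TG/CA and indels. Passing tests therefore
demonstrate the correctness and power of the *pipeline mechanics* —
coordinate handling, imputation, error control — not calibration against
real biological variance.

## Problem sizes

The acceptance study uses a 2 Mb genome pair (~22 000 union CpGs), 4+4
samples, ten planted shared-site DMRs (|Δ| = 0.4, ≥ 15 CpGs each) and three
unique-only regions, with both pipeline modes and all 18 balanced
permutations; this was chosen as the smallest instance on which every
phenomenon of interest (bias direction and reversal, restoration by
filtering, recall with family-wise control, unique-mode power gain) is
stably reproducible across seeds. The property suite runs 50 random
smoother instances and 100 random coordinate-map round-trips.

## Known limitations

- Maps come from curated variant sets only; arbitrary assembly-to-assembly
  alignment (chain/net) is out of scope.
- Two groups, no covariates or paired designs; the only error-control
  procedure is the permutation gFWER.
- The smoother is order-independent and exact for its stated fitting rule
  but is not bit-compatible with IRLS-based implementations.
- Heterozygous CpGs are handled by removal, not by diploid-aware
  quantification; phasing is out of scope.
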