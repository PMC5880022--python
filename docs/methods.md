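# Methods

## The MV statistic and preprocessing

Methylation variability (MV) is the per-probe sample standard deviation
(n−1 denominator) of beta-values across individuals; the mean and
variance are reported alongside. The analysis cohort is an equal number
of healthy males and females within an age window, matched by a greedy
rule: among all remaining male–female pairs, repeatedly take the pair
with the smallest absolute age difference (ties broken by sample ID).
The paper-style probe filters are applied as strict set rules — drop
probes on sex chromosomes, probes overlapping SNPs, cross-reactive
probes, and any probe with a missing value in the selected samples
(complete-case, since a variability statistic is meaningless over
shifting denominators). The exclusion tally counts a probe once under
every reason it triggers.

The optional white-blood-cell composition screen fits, per probe and per
purified cell type, a two-group comparison against PBMC (a
pooled-variance two-group linear model, i.e. an ordinary t-test — not an
empirical-Bayes moderated fit; with six samples per group and the
extreme default thresholds p < 1e-7 and |Δbeta| > 0.05 the shrinkage
detail is immaterial). It reports flags and removes nothing, matching an
analysis run without cell-composition correction.

## CpG cluster density

Regions are classified by three measures computed from sequence with N
bases excluded from all counts and from the effective length:
GC content, the Gardiner-Garden-style Obs/Exp CpG ratio
`N_CpG · L / (N_C · N_G)` (defined as 0 when a sequence lacks C or G),
and length (genomic span). HC requires GC > 0.55, Obs/Exp > 0.75,
length > 500; IC requires GC > 0.50, Obs/Exp > 0.48, length > 200. All
inequalities are strict: a region exactly at a boundary fails.

Discovery scans 200-bp windows at 50-bp steps; a window passing the IC
minima on GC and Obs/Exp seeds a region, touching seeds merge, and each
merged span is re-measured in full and classified (HC checked first).
Spans classifying to neither class are dropped. The published
island-density annotation was built by a different (unpublished here)
procedure; this deterministic scan honours the same printed thresholds
and is fully testable, and a precomputed region BED can be supplied to
the CLI (`methvar density --regions`) to bypass discovery when an
external annotation is preferred. Probes inside no HC/IC region are LC,
so the three classes partition the probe set. Near a cluster edge the
merged span can extend up to one window beyond the planted block, so a
discovered region is slightly wider than the truth interval; assignment
tests therefore check overlap, not exact coordinates.

## Conservation (ancient selection)

Probes take the score of the track interval containing them; probes
covered by no interval are dropped and counted rather than scored 0 —
absence of evidence is not a neutral score. Scores below zero are
removed (a negative rejected-substitutions score has no constraint
interpretation), zero is retained. Quartile boundaries use the
linear-interpolation percentile rule (numpy's default) at 25/50/75;
bins are left-closed, right-open, last bin closed. Degenerate
boundaries (coinciding percentiles) raise rather than silently merging
bins. The trend across quartiles is summarised by per-quartile
n/median/mean, a monotonicity flag on the medians, and Welch's
heteroscedastic one-way test — the reading of "one-way test" chosen
because R's `oneway.test` defaults to Welch; the statistic is computed
in closed form and cross-checked against an independent implementation
in the tests.

## Recent selection

The SNP filter is a strict conjunction of the twelve dbPSHP-style
criteria with the printed directions; a record missing any statistic
fails (the original pipeline filtered a complete database table). When
two per-population SNP tables are merged, duplicates are resolved by
rsid, preferring the copy that passes the filter, else the first by
input order; one rsid at two positions is a consistency error.

RSP-CpGs are probes within `half_window` of any passing SNP. The
"2000 base pairs around" phrasing is ambiguous between a 2000-bp total
span (±1000) and ±2000; the default is ±1000, mirroring the promoter
case where "3000 bp around the TSS" meant ±1500, and ±2000 is a
parameter away.

The bootstrap draws B = 10,000 subsets of size |RSP| without replacement
from the pooled probe set (a permutation-style null; with-replacement
and non-RSP-pool variants are flags) and reports the one-sided add-one
empirical p-value (count + 1)/(B + 1), so p is never zero and zero
exceedances report just under 1e-4. The RSP vs non-RSP conservation
comparison is a Welch two-sample t-test on GERP-RS scores.

## Promoter ranking and enrichment

Probes map to every gene whose TSS lies within ±1500 bp (symmetric
regardless of strand; a probe in two windows counts for both genes).
Per-gene MV is the arithmetic mean of promoter probes ("averaged" read
as mean; median is an option). z-scores use the mean and sample SD of
the gene-level values — the gene level keeps the ranking internally
consistent; probe-level standardisation would only rescale it
monotonically. Ties break alphabetically for a reproducible ranking.

The enrichment score is the signed maximum deviation of the weighted KS
running sum (hit steps |z|^weight normalised by the in-set total, miss
steps 1/(N − N_hits); weight 1). The null permutes gene-set labels:
n_perm random same-size sets per distinct size (or every same-size
subset with `exhaustive=True` on small instances). Nominal p is the
fraction of same-sign null ES at least as extreme; NES divides ES by
the mean same-sign |null ES|; FDR q compares each NES with the pooled
sign-normalised null over all tested sets, clipped to [0, 1]. Sets are
skipped below `min_size` (default 3 — the conventional 15 would empty
desk-scale runs) or above `max_size` (500), or when they cover the
whole list. ES values agree with an independent reference
implementation to 1e-9 in the tests.

## The synthetic-data generator

The generator emulates the statistical structure the analysis is meant
to detect, not the biology of any particular array. Default conditions
(one `SimulationConfig`): 5000 probes × 50 samples, a 3 Mb chr1 plus
20 kb chrX/chrY contigs, 350 HC and 400 IC clusters planted on an
AT-rich background (GC 0.30), cluster GC targets 0.66 (HC, 600–900 bp)
and 0.58 (IC, 250–400 bp) — i.i.d. draws at those compositions give
Obs/Exp ≈ 1, so each block verifiably satisfies its class triple and is
re-drawn on the rare failure. Probes sit only at true CpG dinucleotide
positions: at most 2 per planted cluster (arrays tile islands sparsely;
this also keeps any 2-kb window from capturing a large block of
same-class probes) and the rest on background CpGs, with a 3%
sex-chromosome quota and 2% SNP-overlap / cross-reactive flags.

Beta-values are Beta(mκ, (1−m)κ) with κ = 1/(4s²) − 1, giving SD exactly
2·s·√(m(1−m)): the dispersion parameter s is controlled directly, and
the √(m(1−m)) factor reproduces the observed peak of variability at
intermediate methylation. Class means are drawn low for HC (islands are
hypomethylated), intermediate for IC, high for LC. Dispersion composes
multiplicatively:

```
s = s_class × gene-set factor × RSP shrink × conservation factor × e^(τZ)
```

with s_class = 0.03/0.06/0.10 (HC/IC/LC), planted gene-set factors 1.6
(high-MV set) and 0.5 (low-MV set) on promoter probes of 20 + 20
designated genes, RSP shrink 0.77 inside selected-SNP windows (a ~23%
group-mean MV reduction, the magnitude of the reported RSP effect),
conservation factor 1 − slope·score/6.18 for positive scores
(slope 0.7), and i.i.d. lognormal heterogeneity τ = 0.5 (real MV
distributions are heavy-tailed; the median multiplier is 1 so class
ordering is preserved). Conservation scores are i.i.d. per probe —
positive U(0.1, 6.18) with probability `conserved_frac` = 0.5, else
negative — written as single-base bedGraph intervals. Of 600 SNPs, 25%
are constructed to pass all twelve criteria (each statistic drawn
strictly inside its passing region); each failing SNP takes passing
values and then has exactly one randomly chosen statistic pushed past
its cutoff, so every criterion is exercised. TSSs sit at 300 random
probe positions so promoters are never empty.

Two design points matter for the null behaviour. First, selected SNPs
are placed uniformly on the genome, which makes every probe's RSP
inclusion probability equal; second, per-probe dispersion is dominated
by i.i.d. terms at the 2-kb scale (the per-cluster probe cap and the
lognormal heterogeneity), so an RSP window behaves approximately like a
random probe subset. Without these, window sampling is cluster sampling
of spatially correlated dispersions, the simple-random-subset bootstrap
null understates the variance of the observed mean, and null p-values
are overdispersed; with them, replicate simulations at shrink = 1 give
uniform bootstrap p (KS) and ~α rejection for the conservation test at
slope = 0. The planted slope default 0.7 is set where the documented
contract — monotone-decreasing quartile medians whenever a coupling is
planted — holds with margin across seeds, not marginally.

What the generator does not emulate: probe-level technical noise models
(type I/II chemistry, batch), realistic linkage between SNPs, genomic
correlation of conservation scores, overlapping transcripts sharing
promoters, age/sex effects on methylation (metadata exist to exercise
the cohort selector, but betas are drawn independently of them). Passing
tests therefore demonstrate that the algorithms recover planted effects
of realistic magnitude under realistic marginal distributions — not that
the biological claims hold in any real cohort.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; stage seeds (bootstrap, enrichment null) are fixed
offsets of the run seed and echoed in the report's seed registry. All
writers use fixed float formats, so identical configuration and seed
give byte-identical TSV/JSON/FASTA outputs; the report's wall-clock
timestamp lives only in the Markdown rendering. p-values are reported at
full precision with an R-style "< 2.2e-16" display string alongside.
Degenerate inputs fail loudly: zero-variance groups, coinciding quantile
boundaries, empty or exhaustive RSP sets, σ = 0 rankings.

## Problem sizes

Packaged defaults run the whole pipeline in a few seconds. The
replicate-based checks (null calibration of the conservation test and
of the bootstrap) use a proportional miniature — 600 probes,
20 samples, 400 kb, 95 clusters, 20 selected-SNP windows, B = 200 —
chosen to preserve the default conditions' window/cluster/probe-density
ratios so that calibration measured at small scale is informative about
the default scale (which is itself verified directly in the acceptance
checks at B = 10,000).
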