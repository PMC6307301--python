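# Methods

## Scope and data model

The package analyses enrichment-culture time courses of sediment microbial
communities observed through 16S amplicon sequencing.  The substrate of
every statistic is a feature × sample table of non-negative integer read
counts (`CountMatrix`) with per-sample metadata: sediment source,
incubation day (0–30), and molecule (DNA = 16S rRNA gene, RNA = 16S rRNA).
All statistics operate on counts rarefied to a common depth — per molecule
for the activity ratio, since DNA and RNA libraries have unrelated
sequencing depths.

## Isolate recruitment

A cultured isolate's near-full-length 16S sequence is matched to amplicon
representative sequences with a semi-global (free-end-gap) alignment:
match +1, mismatch −1, a length-*L* gap costs 2 + *L* (the "open" cost of
2 is added on top of the per-column extension of 1).  Identity is
matches / aligned columns with terminal gaps excluded; `N` aligns like any
base but never counts as a match.  Tie-breaks are deterministic: among
equal-score alignments the one with fewer gap columns wins (carried
through the recursion as a lexicographic secondary objective), then a
diagonal step is preferred over a gap, then the first end cell in scan
order.  The free end gaps matter because isolates are near-full-length
while amplicon representatives are V4–V5 fragments.

A feature is "the same species" as the isolate when identity ≥ 0.99 over
≥ 200 aligned columns; all matching features' counts are summed (not
max-taken), because every library sequence above the identity gate is the
same species by definition.  An explicit identity + overlap gate replaces
an E-value threshold because E-values depend on the search tool's
statistics and database size and are therefore not reproducible as a
package contract.

A shared-k-mer prefilter skips alignments that cannot reach the gate: any
pair at ≥ 99% identity over ≥ 200 columns has at most ⌊0.01·L⌋
mismatch/gap columns, so by pigeonhole it must contain an exact match run
of ≥ 66 nt.  The screen length adapts to the thresholds (12 ≤ k ≤ 24,
never exceeding the guaranteed run) and the prefilter disables itself when
user-supplied thresholds void the guarantee, so it is behaviour-invisible
by construction.  The hot DP loop is numba-compiled with a pure-Python
fallback.

## The two headline ratios

**Degree of enrichment.** For each species and source,
ratio_t = (a_t + 1)/(a_0 + 1) where a_t is the recruited read count at
enrichment day t.  The species was *enriched at isolation* iff the ratio
at its isolation day is strictly > 1; equality is "not enriched" — a
species whose abundance merely held steady was not enriched.  The +1
pseudocount encodes that an isolated species must have carried at least
one latent read even when sequencing missed it.  The summary fraction of
not-enriched species is computed over species isolated *after* enrichment
(isolation day > 0); day-0 direct-plating isolates are excluded from the
denominator.

**Activity.** For each taxon and sample pair, ratio = (rna + 1)/(dna + 1);
active iff strictly > 1.  Rank-level ratios (order/family/genus) sum RNA
and DNA reads within the taxon *before* the ratio (sum-then-ratio), which
is the only aggregation consistent across ranks: the rank-level ratio then
equals the ratio of the rank's marginal counts exactly.  log10 ratios are
emitted alongside for plotting.  The community *active proportion* is the
fraction of present taxa (rna + dna > 0) called active, taxon-weighted by
default with a read-weighted variant alongside, since "percent of the
community" is ambiguous between the two.

## Diversity

Rarefaction subsamples each sample without replacement to a common depth
(default: the smallest library) via the multivariate hypergeometric
distribution; a single recorded-seed draw is used for normalization.
Estimators are the standard ones, implemented with explicit formulas so
their components (F1, F2, S_rare, S_abund, C_ace, γ²) can be reported:
Shannon −Σp·ln p (natural log); Simpson reported as Gini–Simpson 1 − Σp²
with the raw Σp² alongside (conventions differ between tools); Chao1 in
the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), which is defined at
F2 = 0; ACE per Chao & Lee with the conventional rare-abundance cutoff of
10 (undefined when every rare feature is a singleton).  Rarefaction curves
average nested prefixes of a shuffled read vector — a prefix of a random
permutation is exactly a uniform subsample without replacement, and
nesting makes the mean curve monotone in depth by construction rather
than up to Monte-Carlo noise.

The **novel-OTU gain** compares the day-0 detected feature set with the
union of enriched-stage sets at a common rarefaction depth.  Because "X%
more novel OTUs" admits two readings, both are emitted:
|novel| / |day-0 set| (primary) and the relative richness change; neither
is asserted as the canonical definition.

## Co-occurrence network

OTUs with more than 2 zero occurrences across the 15 samples, or with
total reads ≤ 1, are removed ("majority" interpreted as a total-abundance
floor, following the parameter's gloss in the source pipeline).  Counts
are log10-transformed with zeros kept blank; Pearson r is computed on
pairwise-complete samples; a signed edge requires |r| ≥ 0.7 and at least 9
complete pairs (the min-pairs guard is inert on filter-compliant inputs,
where every pair has ≥ 11 complete samples, and exists only to protect
degenerate user inputs).  No multiple-testing correction or random-matrix
thresholding is applied — the fixed cutoff *is* the method — but a
permutation-null edge-rate diagnostic is provided.  Family-level
associations tally positive and negative edges per family pair; the net
sign is the majority, with ties reported as "mixed".

One wording in the planning notes claimed the network is invariant to
scaling a *sample* by a power of 10; that is false (it adds a constant to
one coordinate of every log-row, which changes r).  The true and tested
invariance is to scaling any *feature*, which shifts a whole log-row.

## Cofactor prototrophy screen

A pathway is an ordered core gene list plus salvage transporters.  The
biotin core is bioC, bioH, bioF, bioA, bioD, bioB with the BioYM ECF-type
transporter as the salvage route and birA (the ligase) tracked but not
scored, since ligation is needed by auxotrophs too.  Completeness is the
fraction of core genes present; prototroph requires the complete core
(prototroph_min = 1.0, relaxable), otherwise a present salvage transporter
yields `auxotroph_salvage`, else `auxotroph`.  The strict-complete rule is
this package's documented choice; "unable to synthesise de novo" has no
universal missing-gene threshold.  The shipped ~20-gene anaerobic
corrinoid (cobalamin) list is an editorial default, not a measured set —
swap in your own YAML for serious use.  Syntrophy candidates are the
(prototroph donor → auxotroph recipient, cofactor) triples over positive
family associations only; mixed or negative associations never nominate.

## Synthetic community generator

The generator emulates the study design so that every downstream stage has
a planted answer: 3 sources × days (0, 5, 12, 21, 30) × 2 molecules,
default 200 taxa.  Guild fractions are 15% r-strategists, 15%
k-strategists, 70% inert.  Expected log10 relative trajectories are
piecewise linear: inert taxa constant with baselines log-uniform in
[−3.5, −1.5]; k-strategists start in [−3.5, −2.5] and grow at 0.04–0.08
log10/day; r-strategists start in the dormant seed bank ([−5, −4], below
detection at depth 10⁴), bloom to a peak of [−1.5, −0.5] at an interior
day, then collapse at half the bloom rate, floored at their seed-bank
level.  Each (taxon, source) carries a lognormal multiplier (σ = 0.2
log10) held constant across days, so within-source count *ratios* reflect
the expected dynamics; enrichment truth is defined on the expected
normalized trajectories, which that noise cancels out of.

RNA libraries scale each taxon's proportion by an activity factor (4.0
active, 0.2 dormant) and renormalize — a one-parameter stand-in for
ribosome content, sufficient because the analysis consumes only the
ratio's position relative to 1.  Activity truth is a nested, shrinking
random active set whose fraction declines linearly from 27% at day 0 to
13% at day 30, the study's observed span, taken here as the simulated
condition.  Counts are multinomial at exactly the requested depth, so
column sums are conserved.

Planted correlation pairs (defaults: two positive, one negative, each pair
in a private family) are set directly in *proportion* space: the driver
taxon's log10 abundance fluctuates per sample (σ = 0.5, clipped at ±1.6)
and the follower tracks or mirrors that deviation (residual σ = 0.05),
with the rest of the community rescaled to fill the remainder.  Planting
after compositional closure is essential: mirroring raw abundances and
then renormalising adds a shared −log(total) term to both members that
systematically attenuates *negative* correlations below any fixed edge
threshold.  Because these taxa fluctuate by design, they carry no
well-defined per-day enrichment truth and are excluded from the
enrichment-classifier evaluation (they keep their activity truth).

Isolates get one 16S reference per taxon (i.i.d. random sequences,
verified mutually < 97% identical under the package's own identity
definition) and a cultured-isolate variant with Binomial(L, divergence)
substitutions (default divergence 0.003, length 1400).  Isolation day and
source are uniform random — colonies are picked at every enrichment stage
regardless of the species' current abundance, which is what makes the
not-enriched fraction informative; it emerges at roughly 70–80% under the
defaults rather than being set anywhere.  Generated sequences use A/C/G/T
only; the matcher nevertheless accepts N.

What the generator does *not* emulate: sequencing error and chimeras,
taxon-correlated activity (activity truth is independent of guild),
mechanistic nutrient dynamics, and real phylogenetic structure in the
taxonomy (lineages are synthetic labels).  Passing truth-recovery tests
therefore demonstrates the statistics recover the signals they define on
clean compositional count data — not robustness to amplicon artefacts.

## Pipeline and reproducibility

`run_pipeline` executes the stages in dependency order, each writing into
its own subdirectory (write-once).  A single global seed fans out to
per-stage child seeds by stable SHA-256 hashing, so toggling one stage
never reshuffles another's randomness.  The manifest records every
parameter with provenance (study default vs user override) and a sha256
checksum per output file; identical config + seed reproduces byte-identical
outputs.  Defaults follow the study values throughout: identity 0.99 with
overlap 200, rarefaction to the smallest library, strict > 1 ratio
boundaries, |r| ≥ 0.7, max 2 zero occurrences, total-abundance floor 1.

## Problem sizes and numerical choices

Truth-recovery evaluations run at 200 taxa, depth 10⁴, 3 sources × 5 days,
with classifier scoring restricted to taxa reaching ≥ 1% latent relative
abundance (below that, a handful of multinomial reads cannot carry a ratio
signal either way), and association-sign recovery measured over 20
generator seeds.  Degenerate inputs fail loudly: all-zero columns are
undefined for diversity, empty sequences for alignment, unpaired RNA
samples and missing day-0 libraries raise consistency errors, rarefaction
names the sample that is too shallow.  Constant log-count vectors yield no
correlation edge (r undefined), and pairs with fewer than the minimum
complete samples are skipped and recorded rather than tested.
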