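# Methods

`phylocurate` implements the quantitative procedures used to curate a
candidate bacterial phylum from draft genomes: marker-based quality
recalibration, species delineation, rank-consistency auditing, nomenclature
screening, and ecology statistics (cell size from serial filtration, qSIP
activity).  This note records the models, the defaults and why, the
numerical choices, and what the synthetic-data scenarios do and do not
demonstrate.

## Genome quality from marker counts

Draft genomes (MAGs/SAGs) are scored against a set of genes expected to be
present exactly once per genome.  For a genome's copy-count row over the
non-excluded markers:

    completeness  = |{m : count_m >= 1}| / M
    contamination = sum_m max(0, count_m - 1) / M

These are plain set fractions, chosen for transparency over CheckM's
collocated marker-set weighting; copy counts are the input, no HMM
searching is performed.  Completeness lives in [0, 1]; contamination is
unbounded above.

**Phylogenetically constrained markers.**  A marker that is both rare and
confined to a short patch of the genome tree says little about completeness
of the rest of the lineage.  A marker is excluded when its presence
frequency is below `freq_threshold` (default 0.10) *and* the mean pairwise
patristic distance among its bearers falls below the `dist_quantile`
(default 0.25) quantile of that statistic across all markers with >= 2
bearers.  Markers in <= 1 genome are excluded outright.  Both thresholds
are exposed because "infrequent" is a judgment call; the defaults mark the
obviously pathological tail without touching typical markers.  Patristic
distances come from dendropy; tests cross-check them against brute-force
path summation.

**Auxiliary single-copy markers.**  Candidates are screened against the
count predicted from genome quality.  A genome with completeness c and
contamination k carries a true single-copy gene in exactly one copy with
probability p = c − k (it must be sampled, and not duplicated).  Across n
representative genomes the single-copy occurrence count of a true
single-copy marker is a sum of independent Bernoulli(p_g) draws:
mean μ = Σ p_g, variance σ² = Σ p_g(1 − p_g).  A marker is accepted when

    |obs − μ| <= 1.96 σ + 0.5,

the half-count term being the standard continuity correction for a normal
approximation to a discrete count — without it the band's true coverage
falls below its nominal 95% (the accept region clips asymmetrically to
whole counts, costing several coverage points at realistic n).  With
σ = 0 the rule degenerates to exact equality.  The occurrence statistic
counts genomes bearing *exactly one* copy (`occurrence="single_copy"`);
counting mere presence (`occurrence="presence"`) is available but is biased
upward by contamination relative to the c − k prediction and is not the
default.  Values of c − k outside [0, 1] (possible with real estimators)
are clipped with a warning.

**Genome size.**  Complete genome size is estimated as

    Size_est = (Size_obs − Size_obs × contamination) / completeness

i.e. strip the contaminating fraction of the assembly, then scale up by the
sampled fraction.  Size_est is decreasing in both completeness and
contamination for fixed Size_obs, and equals Size_obs for a perfect genome.
Quantile placement against a reference size collection uses the mid-rank
convention, (strictly smaller + half the ties)/n, which is symmetric under
ties and has no arbitrary endpoint behaviour.

**Quality tiers.**  Evaluated in order: *discard* below 10% completeness or
above 10% contamination; *high* above 90% complete, below 5% contaminated,
with 5S/16S/23S rRNAs and >= 18 tRNAs; *medium* above 50% complete and
below 10% contaminated; *low* at 10–50% complete and below 5% contaminated.
Strict and inclusive comparisons follow the rule text exactly (10% and 50%
completeness are inclusive for *low*); the leftover corner (10–50% complete
with 5–10% contamination) is discarded with a warning.  The assignment is
total on the quality plane — verified by a 0.01-resolution grid scan.

**Giant ORFs.**  ORFs strictly longer than 20 kb (nucleotide length; from
protein input, nt = 3×aa + 3 including the stop codon).  These are a
genomic signature of putative predatory/parasitic lineages.

**Group comparison** (genome sizes between lineages, AFE between guilds)
uses one-way ANOVA followed by Tukey's HSD (scipy).  Degenerate inputs are
flagged rather than erroring: all-identical data report F as undefined with
all adjusted p = 1; zero within-group variance with differing means reports
F infinite with p = 0 for differing pairs.

## Species delineation (ANI)

Species are single-linkage clusters at 95% ANI: connected components of the
graph with an edge wherever symmetrized ANI >= 95.0 (inclusive — the
conventional reading of "threshold of 95%").  Directed ANI pairs are
symmetrized by the arithmetic mean, a missing direction using the available
one, so the partition is independent of query/reference order; missing
pairs form no edge.  Components come from scipy's sparse graph machinery;
tests hold the partition equal to an independent union-find oracle and
check that raising the threshold only refines the partition.

Representatives are the most complete member (ties: lower contamination,
then larger assembly, then lexicographic id), restricted to high/medium-tier
members whenever any exist.

`compute_ani` is a desk-scale surrogate for FastANI, intended for small
simulated genomes and for plumbing tests; precomputed FastANI tables are
the primary input path.  The query is cut into non-overlapping 1 kb
fragments, each aligned to the reference with edlib in infix mode on both
strands; identity = 1 − edits/fragment_length, a fragment maps at >= 70%
identity, and ANI is the mean mapped identity.  Infix alignment spans the
entire fragment, so fragment coverage is complete by construction.  No
k-mer sketching is claimed; at planted divergences up to 10% the surrogate
tracks 100 − substitution% within about a point.

## AAI and rank consistency

AAI between two proteomes is the mean percent identity over
reciprocal-best-hit pairs from all-vs-all local alignments (BLOSUM62, gap
open 11 / extend 1 — blastp-style defaults).  Best hits break ties by
score, then alignment length, then protein id, keeping the computation
symmetric and deterministic.  An RBH pair contributes when identity >= 20%
(identities / alignment columns), the alignment covers >= 50% of the
shorter protein, and passes an optional minimum length.  Zero qualifying
pairs leave AAI undefined (None), never 0.

The rank-consistency report summarizes, per family, the distributions of
intra-genus and inter-genus AAI over species representatives and flags any
genus whose minimum intra-genus value falls below the family's maximum
inter-genus value.  It is a report only — renaming is a curatorial
decision, not an automated one.

## Nomenclature screening (bounded Damerau-Levenshtein)

Names are normalized first: case-fold, strip, expand a documented ligature
table (æ→ae, œ→oe, ß→ss, ø→o, ł→l, đ/ð→d, þ→th, ı→i), then NFKD-decompose
and drop combining marks.  Exact collisions are hash lookups on normalized
names.

Near collisions use the optimal-string-alignment (OSA) variant of
Damerau-Levenshtein distance — substitution, insertion, deletion and
adjacent transposition each cost one edit, with no substring edited twice.
OSA is the primary variant because the widely used Rcpp implementations are
OSA; the unrestricted Lowrance-Wagner distance is available via
`variant="dl"` and can differ from OSA at distance >= 2 (e.g. "ca"→"abc" is
2 unrestricted but 3 under OSA).

Screening a proposal against a large catalog applies two sound lower-bound
prefilters before any DP:

1. length: |len(a) − len(b)| <= D (every indel is an edit);
2. character set: |set(a) \ set(b)| <= D (every character of a absent from
   b forces an edit).  The symmetric form (both directions) is an equally
   valid bound and is available; the one-directional form is the default.

Survivors go to a band-limited DP restricted to |i − j| <= D, which returns
the exact OSA distance whenever it is <= D and a ">D" sentinel (None)
otherwise.  Kernels are numba-jitted; the catalog-side prefilters run
vectorized using length arrays and 63-bit character-membership masks
(characters hashed by code point mod 63 — collisions can only *under*count
exclusive characters, so the vectorized filter remains sound; for plain
a–z names it is exact).  Equivalence with a naive full-DP oracle, and zero
false rejections by the prefilters, are asserted over 10⁶ random pairs and
the exhaustive length <= 6 four-letter cross.

Genus names and species epithets should be screened as separate catalogs;
nothing in the machinery mixes namespaces.

## Filtration and qSIP

**Cell-size intervals.**  In a serial filter train (pore sizes strictly
decreasing along the flow), a taxon detected on a filter is at least that
pore's size and smaller than any upstream pore it passed.  With retaining
pores R: lower bound min(R); upper bound the smallest non-retaining pore
above max(R), open if none.  Detection on no filter gives [0, smallest
pore) flagged `all_passed`.  A retention run broken in its interior is
flagged `non_contiguous` — single cells cannot straddle a pore they passed,
aggregates can.  Nominal pore sizes are taken at face value; no membrane
deformation model.

**Abundance shifts.**  The 0.45 µm → 0.2 µm fraction comparison is a strict
inequality on relative abundances; an increase marks populations enriched
among ultra-small cells.  Rank-level aggregation sums abundances within
the rank (unmapped rows pooled as "unclassified") and renormalizes per
filter.

**Utilization calls.**  A taxon utilizes a labelled substrate when both
tails of the 95% confidence interval of its replicate AFE values exceed
zero, i.e. the CI lower bound is positive.  The default interval is the
Student-t interval of the mean.  With the typical 3 replicates this is a
deliberate choice: any taxon-local resampling interval (percentile
bootstrap included) has a null false-positive rate of at least 1/8, because
an all-positive triple — probability 2⁻³ under a symmetric null — yields an
all-positive bootstrap distribution whose lower percentile is positive.
The t interval keeps the null call rate at the nominal one-sided 2.5%.  The
flip side is power: at an effect of 3 replicate-SDs with n = 3 the exact
noncentral-t power of this rule is 0.745, and no taxon-local construction
can combine nominal error control with high power at that n (a z bound
would require the noise variance to be known).  More replicates, or
variance pooling across taxa, are the remedies; both are outside this
function's contract.  A seeded percentile bootstrap of the mean
(`method="bootstrap"`, default 1000 resamples) is retained for comparison
with bootstrap-based pipelines.  Fewer than two replicates: not evaluable,
flagged.

**Percent differences.**  For a focal taxon P and sample s:
100 × (AFE_P − AFE_NP)/AFE_NP, where AFE_NP aggregates (mean by default,
median available) the replicate-mean AFE of every non-predatory taxon in s.
The statistic is invariant to rescaling all AFE values of a sample.
Samples whose NP aggregate is <= 0 are excluded and reported rather than
producing unstable ratios.  The summary gives the median, inner quartiles
and a seeded percentile-bootstrap 95% CI of the median over samples.

## Synthetic scenarios: what they show and what they don't

Every generator takes an explicit integer seed; regeneration is
byte-identical and the planted truth serializes to a JSON sidecar.

* **Marker matrices** (default 100 genomes × 500 markers; completeness
  uniform on [0.5, 1], contamination uniform on [0, 0.1], capped at
  completeness; half the markers single-copy, a quarter clade-restricted on
  a random coalescent tree, a quarter multi-copy at 2 + Poisson(0.5)
  copies).  A single-copy marker is double w.p. k, single w.p. c − k,
  absent otherwise — so recomputed completeness/contamination are unbiased
  for (c, k) and the single-copy count matches the auxiliary-marker band
  exactly.  Observed assembly size is defined as
  size_true × c / (1 − k), making the size estimator exact under planted
  quality; real assemblies deviate from this identity (contamination is
  not a uniform inflation), so real-data size errors exceed the synthetic
  ones.
* **ANI matrices**: within/between-species blocks at Normal(98, 0.5) /
  Normal(80, 0.5).  Separation of several σ from the 95 threshold makes
  exact partition recovery the expected outcome; real ANI distributions
  near the species boundary are harder.
* **Proteome pairs**: gap-free point substitution at rate 1 − identity.
  Real orthologs diverge with indels and domain-level events, so AAI
  recovery there is rougher than the ±2-point synthetic tolerance.
* **Name catalogs**: pronounceable Latin-like strings; planted proposals
  are built by applying exactly d edits and verified against the full-DP
  oracle, including that no other catalog entry is closer.
* **Filtration**: noiseless retention on exactly the largest pore not
  exceeding the true size; noise flips flags independently.  Noiseless
  bracketing is provable pattern-by-pattern; with 5% noise ~90% of
  intervals still bracket and the flags concentrate on flipped taxa.
* **qSIP**: per-sample lognormal baseline AFE × guild multiplier, with
  multiplicative lognormal replicate noise (σ = 0.3); defaults 114
  samples, 3 replicates, guild multipliers 2.0 (focal, predatory) vs 1.0
  (non-predatory).

Passing tests on these scenarios demonstrate correctness of the
*procedures* under their stated models — not that real MAG collections
satisfy those models.  In particular the generators do not simulate reads,
assembly chimeras, database incompleteness, or isotope density gradients.

## Problem sizes

The test suite and `scripts/acceptance.py` exercise: 10⁶ random string
pairs plus the exhaustive length ≤ 6 four-letter cross for distance-oracle
equivalence; a 100,000-name catalog with 100 planted proposals; 100-genome
× 500-marker matrices; 200 random 25-genome ANI matrices plus an 80-genome
planted block matrix; 20 (tests) or 10 (script) replicates of 50-ortholog
proteomes per planted identity; 500 filtration taxa; 1000 qSIP taxa for
null and power rates.  These sizes were chosen so the whole suite runs in
a few minutes on one CPU while keeping every Monte-Carlo bound comfortably
away from its sampling noise.
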