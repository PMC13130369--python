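# Methods

## Problem setting

16S rRNA amplicon metabarcoding assigns sequencing reads to bacterial taxa
using a classifier (best-hit alignment, k-mer matching, or denoising plus
reference clustering). On highly complex communities — municipal wastewater
being the canonical case — classifiers fail in two characteristic ways:
they miss taxa that are present (false negatives, depressing sensitivity)
and they invent taxa that are not (false positives, depressing
selectivity). This package implements an evaluation framework for those
failure modes, plus the two filtering strategies that trade a little
sensitivity for a lot of selectivity, and enough simulation machinery to
exercise everything without running any external pipeline.

## Ground truth: the tiered mock community

The default community design holds 15 species per site in three abundance
tiers: five *main* taxa at 15% each (each drawn from three strain/subspecies
sequence variants at 5% apiece), five *mid* taxa at 4.5%, and five *rare*
taxa at 0.5%, summing to exactly 100%. The rare tier exists specifically to
probe sensitivity to low-density organisms. Analytically this vector has
Shannon entropy −Σ p ln p = 2.25 nats, Pielou evenness 2.25/ln 15 = 0.83 and
richness 15; these closed-form values anchor the acceptance checks.
Representative species for a site are pickable from pilot classifications:
mean relative abundance across replicates (absent = 0), descending, ties
lexicographic. Non-default tier geometries are available through explicit
`TierSpec` parameters; the defaults are the design above.

`emit_abundance_config` renders the per-sequence-variant abundance table
(variant ids `<species>|v1..vN`, fractions summing to 1) that community
read simulators take as input. Generating actual reads (ART error models,
fragment-length distributions) is out of scope; those are parameters of the
external simulator.

## The classifier simulator

`simulate_classification` pushes reads through a confusion channel.
Composition is deterministic: reads are allotted to taxa at exactly the
design proportions by largest-remainder rounding, because a constructed
read set *has* exact proportions — sampling error belongs to
classification, not to the benchmark's ground truth. Each taxon's reads
then split stochastically: correct with `p_correct`, unmapped with
`p_unmapped`, otherwise mis-assigned. Mis-assigned reads are spread over a
pool of reserved false-positive names (`fp_0001`…, disjoint from any real
species name, so scoring is unambiguous) by a multinomial draw on Zipf
weights with shape `fp_concentration`. Each true taxon independently drops
out entirely with `p_dropout` (database-gap model); its reads reroute
through the error channel. One seeded `numpy` generator drives every stage,
so a run is exactly reproducible from its seed, and mapped + unmapped reads
equal the input count exactly.

Defaults — `p_correct=0.8`, `p_unmapped=0.05`, `p_dropout=0`,
`fp_pool_size=50`, `fp_concentration=1.5` — describe a classifier in the
regime the framework targets: roughly a fifth of reads mis-assigned or
lost, with mis-assignments scattering thinly over many spurious taxa. No
quantitative false-positive read distribution is published for real
pipelines; only the qualitative tendency (false-positive taxa attract far
fewer reads than true taxa) is claimed, and under these defaults the median
false-positive read count sits below the median true-taxon count in
effectively every seed at 175k reads. The simulator does not model
sequencing error, chimeras or partial database incompleteness beyond what
`p_dropout` expresses; conclusions from it are about the *metrics and
filters*, not about any real pipeline's absolute accuracy.

`double_reads` represents the read-doubling transform at the profile level
(all counts and the read total ×2). It is exactly what concatenating a read
set onto itself does to a classification profile; the sensitivity gains
that doubling produces in real denoisers arise inside the denoiser and are
deliberately not simulated.

## Detection metrics

A taxon is detected iff ≥ 1 read maps to it; names on both sides are
canonicalized (lowercase, collapsed whitespace, strain/subspecies
designators stripped after the binomial, `Candidatus` preserved) before
comparison. Taxa sensitivity = 100·|TP|/|truth|; taxa selectivity =
100·|TP|/|detected|; read sensitivity = 100·(reads on TP)/(total input
reads); read selectivity = 100·(reads on TP)/(mapped reads). The mapped-read
denominator for read selectivity is the only choice consistent with the
framework's reference worked examples. When nothing is detected the
selectivities are undefined and reported as missing, never as zero.

The surveillance score — ½·(taxa_sens·taxa_sel + read_sens·read_sel)/100,
as a percentage — is a reconstruction: the mean of the two
sensitivity×selectivity products reproduces the reference composite values
to printed precision on the worked examples used in the acceptance checks.
It reaches 100 only for a perfect profile and is invariant under uniform
count scaling.

Improvement arithmetic is exposed in both conventions, explicitly labelled,
because published comparisons mix them: `relative_change` (growth relative
to baseline) and `absolute_error_reduction` (|baseline| − |improved| in
percentage points, for signed percent errors).

## Mapping-error family

Per-taxon signed errors e_i = observed − true over truth ∪ detected (absent
side = 0), on one of two scales: raw read counts (default variants) or
percent of total input reads (the `n` variants, invariant under uniform
scaling). The decomposition U = Σ max(−e_i, 0) (under-detection,
false-negative-derived; truth taxa only) and O = Σ max(e_i, 0)
(over-detection, false-positive-derived) is exact:
SAE = w·U + O with w = 1 for unweighted variants. RMSE variants take
sqrt((w·Σe_fn² + Σe_fp²)/N) with N = |truth ∪ detected| — that denominator
is deliberate, because it produces the documented pathology: adding
low-abundance false positives grows N faster than the numerator, so
unweighted nRMSE *falls* as a classifier invents more taxa.

The false-negative weight defaults to w = 2.0. Its published value is not
printed anywhere; 2.0 is the smallest integer up-weight and is exposed as a
parameter everywhere it appears.

### The modelling grid

`modelling_grid` evaluates all six variants on the full 6×6 cross of
(true taxa detected) × (false positives reported), levels 0–15 in steps of
3, each true-taxon step adding one main, one mid and one rare taxon. Two
observed-abundance allocation rules are provided:

- `"true_values"` — detected true taxa at exactly their true abundance,
  false positives sharing the missed taxa's mass evenly. Simple, but it
  makes the false-negative error component independent of the
  false-positive count, in which case *no* finite weight can turn the
  weighted nRMSE's correlation with false positives positive.
- `"diversion"` (default) — as above, plus each false-positive target
  diverts a fixed fraction (`diversion_rate`, default 0.0575) of every
  main-tier detected taxon's reads into the unclassified pool. This couples
  the false-negative error to the false-positive count the way real
  classifiers do: a read mis-assigned to a spurious taxon is a read missing
  from its true taxon, and the dominant taxa contribute most of the
  mis-assignable reads. The rate is a calibration of a free model constant:
  it is set so the grid sits squarely in the regime the weighting was
  designed to expose — unweighted nRMSE negatively correlated with the
  false-positive count, weighted nRMSE and weighted nSAE positively
  correlated with both error types, and weighted nSAE carrying the best
  average correlation. The grid is fully deterministic, so these signs are
  stable; the *magnitudes* of the correlations depend on the allocation
  constants and are not claimed.

`grid_correlations` reports each metric's Pearson R against the Type I
count (false positives) and Type II count (missed true taxa) across the 36
cells, plus their mean; a constant metric column yields missing values
rather than a spurious R.

## Diversity metrics

Shannon entropy uses the natural logarithm (scipy's `entropy`), matching
the analytic 2.25 for the tier design; a base-2 computation would give 3.25,
so the occasional "bits" label on such values is treated as a misnomer.
Chao1 uses the bias-corrected estimator S + F1(F1−1)/(2(F2+1)), finite when
no doubletons exist; after either selectivity filter no taxon has fewer
than three reads, so Chao1 degenerates to observed richness — an expected
and documented side effect of low-read-taxon removal. Bray–Curtis is
1 − Σ min(p, q) on union-aligned, renormalized profiles. The diversity
score is 100 − mean |percent error| over the richness, Shannon, evenness
and Bray–Curtis estimates (signed errors enter by absolute value, so over-
and under-estimation are penalized alike; the score can go negative for
estimates that are off by more than 100% on average). Replicate precision
is 100·mean(per-replicate values)/mean(per-site values), the site value for
richness being the union of taxa across the site's replicates.

## Filters

Both filters remove a detected taxon iff its read count is strictly below
the threshold (a count exactly at the threshold survives — "fewer than"):

- **z-score filter** — threshold μ − |z|·σ over the detected taxa's read
  counts, default z = −0.25. σ is the *population* standard deviation
  (deterministic on two-taxon profiles; the choice is not prescribed
  anywhere, so determinism decided it). Single-pass: the threshold is
  computed once on the unfiltered distribution — re-applying can remove
  more because μ and σ change, and the single-pass contract is the
  documented procedure. With one detected taxon σ is undefined; the profile
  passes through with a warning.
- **fraction filter** — threshold = fraction × total input reads; defaults
  0.004 (deep simulated read sets; 0.4% of 172k reads ≈ 688) and 0.00004
  (shallow, widely distributed real read sets). Idempotent.

`filter_diagnostics_with_truth` grades removals: the false-positive rate
among below-threshold taxa and the reads-correct percentage (read
selectivity) before and after. Filtering can only lower taxa sensitivity;
on profiles with the heavy-tailed false-positive tendency it raises
selectivity and reads-correct on average — asserted as a Monte-Carlo
property over 100 simulator seeds rather than as fixed numbers, because the
published diagnostic values came from real pipeline runs that are not
reproducible offline.

## Problem sizes and test design

The test suite and acceptance checks run at the design's native scale —
175k reads per profile, 100 simulator seeds for the Monte-Carlo filter
contract, 1000 random profiles for the SAE identity — which completes in
seconds because everything is vectorized count arithmetic. The acceptance
script's composite-score targets take published per-metric values as
inputs; the full measured tables they come from required live classifier
runs against reference databases and are explicitly not reproduced.

## Known limitations

- Canonicalization is heuristic; names whose third token is a legitimate
  lowercase epithet survive, but unusual strain designations without digits
  or markers may slip through.
- The simulator's Zipf false-positive allocation is a modelling choice; no
  published distribution family exists to check it against.
- The modelling grid's diversion rule (and its 0.0575 rate) is a calibrated
  stand-in for unpublished modelling constants; only the correlation sign
  structure and metric ordering it produces are contractual.
- Kraken report parsing takes the root clade-read count as the read total,
  so unclassified reads do not enter read-sensitivity denominators parsed
  from Kraken files; supply `#total_reads=` via the generic TSV format when
  the full input count matters.
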