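# Methods

## The locus model

The repeat is declared, not discovered: a `RepeatLocus` fixes the
genomic span (chr5:145,838,546–145,838,773, hg19; 228 bp = 38 hexamer
units), the unit (CAGGCC), the size and position of the central pure
run, and two flanking sequences.  Internally all coordinates are 0-based
half-open; the published 1-based inclusive coordinates are converted at
the I/O boundary.

Only the unit-level structure of the tract is published (38 units, a
central 6-unit pure run, QA translation with occasional valines), not
its base-level sequence.  The reference tract is therefore synthetic at
base level but structurally faithful: the 32 non-STR units are drawn
with a fixed seed from the twelve QA/VA-coding hexamers
({CAG,CAA,GTG} × {GCC,GCT,GCA,GCG}, excluding CAGGCC itself), with
valine units pinned at two positions.  The draw is deliberately
aperiodic: an early periodic layout made the tract self-similar under
unit shifts and produced spurious zero-mismatch alignment paths, which a
real quasi-tandem repeat's irregular unit sequence does not admit.  The
150 bp flanks are synthetic non-repetitive sequence (the true flanks are
published only as a figure); both are configurable.

The eight-allele inventory reproduces the published unit counts and
frequencies (A1 38/6 at 91.31% … A8 39/6 at 0.08%).  Length changes are
realised by adding/removing pure units at the left edge of the central
run (the leftmost equivalent placement), QTR-only changes by
adding/removing variant units immediately 3′ of the run, and A6 by a
synonymous third-position SNV whose default placement (tract offset 17,
GCA→GCG) is a documented stand-in for a detail published only as an
image.

## Read alignment and the mismatch error

A read is aligned to the locus window as a chain of "match pieces",
segments placed on single diagonals of the read-vs-reference match
matrix.  A rising diagonal jump between pieces skips reference bases (a
deletion in the read's source); a falling jump skips read bases (an
insertion).  The path score is

    M = m + Σᵢ Δᵢ · exp(5 − lᵢ),

with m the mismatching bases inside pieces, Δᵢ the gap height and lᵢ the
shorter adjoining piece.  The exponential discount lets a well-anchored
repeat-unit jump cost ~10⁻¹³ while an 18 bp jump anchored by only 5 bp
costs as much as 18 mismatches.

The search is exact over all paths with up to two gaps: candidate
diagonals are seeded from maximal exact runs (default minimum 8 bp,
capped at 64 diagonals), and breakpoints are enumerated by vectorised
prefix-sum arithmetic.  Stages run lazily — a perfect gapless hit ends
the search, and the (expensive) two-gap stage only runs when the best
one-gap score still exceeds a trigger (default 1.25, i.e. worse than a
single mismatch).  `max_gaps` defaults to 2 rather than something
larger because the caller's enumerate-then-realign architecture absorbs
multi-indel combinations into candidate haplotypes; single-read
alignment never needs deeper chains.  Ties break deterministically:
fewer gaps, then leftmost reference placement.

**Gap credibility cap.** One addition is ours: a single gap may
contribute at most `max_gap_penalty` (default 10⁻⁴) to M, equivalent to
requiring anchors of l ≥ 5 + ln(Δ/10⁻⁴) for a gap of height Δ (≈17 bp
for one unit).  The error function is calibrated for random sequence,
where a 14 bp anchor is essentially unambiguous; inside a quasi-repeat
whose units differ by one or two bases, coincidental 12–15 bp anchors
are common, and without the cap a tall gap over such an anchor outscores
a single honest mismatch.  The resulting phantom-insertion candidates
then absorb every read in the region (observed as a concrete miscall
mode for the SNV allele A6).  The cap removes those paths while leaving
every genuine inventory indel reachable from reads with ordinary
anchoring; it is exposed in configuration and can be set to infinity to
recover the unrestricted formula.

Indel events harvested from paths are left-normalised (shifted left
while the flanking base matches the end of the shifted block), making
repeat-indel positions canonical and comparable across reads.

## The caller

`call_genotype` composes the steps: (i) align all reads to the reference
window and drop any with M above `m_max` (default 5); (ii) enumerate
candidate haplotypes from the observed indel signatures and their
pairwise-compatible combinations (deduplicated by sequence, capped at
64); (iii) realign every read to every candidate and keep the
smallest-M assignment, with exact float comparison — the true haplotype
may win by only ~10⁻¹³ — and ties resolving to the reference, then the
smaller indel; perfect reference alignments whose span avoids a
candidate's indels are reused by coordinate shift rather than realigned;
(iv) resolve remaining ties through the read's mate and flag
informative-vs-informative conflicts; (v) project all reads into one
asterisk-expanded frame in which insertions are reference asterisks and
deletions read asterisks, so every difference is a substitution;
(vi) split reads into allele groups; (vii) call one consensus allele per
group.

Informativeness is uniqueness of the minimal-M candidate, optionally
after establishing that tied candidates project the read onto identical
columns (a tie between haplotypes that are identical over the read's
span is not ambiguity).  Reads wholly inside the pure run tie across
run-length candidates and contribute to depth only — the structural
reason flank- and variant-unit-anchored indel signatures carry all the
length information when reads are shorter than the tract.

Allele separation works on **fragments** (mate pairs merged), because
pairs are what phase discordant regions further apart than a read
length, and only on discordant columns where at least `min_support`
(default 3) reads share the same alternative character — isolated
sequencing errors otherwise shatter the strict agreement requirement.
Grouping is greedy agglomerative with a final merge pass; more than two
supported incompatible groups raise a multiallelic/contamination error,
zero supported groups fall back to a homozygous-reference call.  Each
group's allele starts from its modal candidate **among uniquely
assigned reads** (equivalent-tie reads carry an arbitrary
reference-preferred label) and is overridden by the group's column-wise
majority at separation columns (ties → reference base).  QTR units are
the consensus tract length divided by six; STR units the longest pure
run.

The depth gate is mean fold-coverage of the tract itself (default 10×):
read counts overstate usable depth because flank-only reads carry no
length information, and a 2× sample must be uncallable.  A second
calling round adds candidates confirmed in other samples
(`cross_sample_correct`); a sample's call is replaced only when total
allele support does not decrease, and the round runs exactly once.

## Residuals, selection, and association

Expected onset is the Langbehn parametric mean, age = 21.54 +
exp(9.556 − 0.146·CAG), validated for CAG in [36, 60] by default and
replaceable by any model object.  Residual R = observed − expected;
positive means later than expected.

The selected population's residual density is p_N(R)·S(R) normalised to
unit mass, with S the sigmoid in |R| above.  (σ, R_thr, Δ) are fitted by
minimising the supremum distance D between the expected and empirical
CDFs of |R| (multi-start Nelder–Mead on (log σ, R_thr, log Δ); the
expected folded CDF is computed on a 4001-point cumulative-trapezoid
grid).  The one-sample KS p-value reported from (D, n) is flagged
approximate because the parameters are estimated from the same data.
The (σ, R_thr) pair trades off along a mild ridge, so single-fit
estimates at n = 5000 scatter by about ±1 y in R_thr; replicate fits
average out this noise and converge toward the truth as n grows.

The selection normaliser Z(μ) = ∫ N(μ, σ²)(R)·S(R) dR is evaluated by
48-node Gauss–Legendre panels split at the integrand's kinks
(R ∈ {0, ±R_thr}) over μ ± 10σ, vectorised over all distinct predictor
values at once; agreement with adaptive quadrature is ~10⁻¹⁵ relative
and a closed normal-CDF form takes over when Δ < 10⁻⁴σ.  We chose fixed
panels over adaptive quadrature for determinism and for vectorisation
across the thousands of likelihood evaluations the replicate studies
need.  With S ≡ 1 every per-record term reduces exactly to the ordinary
linear-regression log-likelihood.

`fit_regression_with_selection` maximises the summed log-likelihood over
(log σ, β₀, β₁) by multi-start Nelder–Mead from OLS-based starting
points (the predictor is centred internally; β₀ is reported on the raw
scale).  Significance is the likelihood-ratio test against the β₁ = 0
fit (χ²₁); the 95% CI is profile likelihood (bracket expansion plus
Brent root-finding on the deviance), preferred over Wald because the
likelihood is asymmetric near strong truncation.  The OLS engine
(`ols_association`) and extreme-group logistic engine
(`dichotomize_and_logistic`, late R > t vs early R < −t, middle
dropped, perfect separation flagged not raised) mirror the classical
analyses.  `compare_statistics` runs the pairwise nested F-tests over
{sum, diff, max, min, n3rep} and reports the best-fitting set (those no
other statistic improves at α = 0.05, rank-deficient additions reported
as p = 1); `conditional_association` reports each predictor's partial
p-value in the joint model, with either engine.  Bonferroni correction
defaults to k = 4, the four length statistics.

n3rep is the dosage of the three-repeat allele, judged by STR unit count
when available and otherwise by the QTR length (35 units) that uniquely
identifies it in the inventory.

## The synthetic generator

`simulate_reads` emulates 75 bp paired-end exome sequencing: fragments
of N(300, 50²) bp clipped to the haplotype, uniform placement, both ends
read at 75 bp, optional uniform substitution errors, 50:50 allele
balance at a total coverage default of 30×.  It does not model quality
ramps, indel errors, GC bias, duplicate reads or capture edge effects —
tests passing on it show the algorithmic machinery is correct under the
declared read geometry, not that real exome data are this clean.

`simulate_cohort` draws diploid genotypes from the inventory frequencies
under Hardy–Weinberg equilibrium, sets R = β₀ + β₁·(N_sum − E[N_sum]) +
N(0, σ²) (the effect acts on the centred sum so β₀ stays the mean
residual; the association engines regress on the raw sum), converts to
onset through the Langbehn expectation with CAG drawn uniformly from
40–50 (the real cohort's CAG distribution is unpublished; configurable),
applies selection by accept/reject with probability S(R), and generates
a tag-marker allele that copies the A2 indicator with probability equal
to the configured fidelity (0.99) and is otherwise an independent draw —
a mixture that makes the dosage/A2 correlation equal the fidelity by
construction.  Acceptance below 10⁻⁴ raises rather than loops forever.
Defaults are the study conditions throughout: n = 610, σ = 7.02 y,
R_thr = 17.6 y, Δ = 3.30 y, β₁ = −1.0 y/hexamer.

`end_to_end_fixture` couples the two so the caller's genotype table
feeds the association machinery directly (default n = 60 for speed).

## Problem sizes used by the test suite

Exact recovery runs all 36 ordered genotypes at 30×; robustness to 0.2%
substitution errors uses 60 replicate genotypes; selection-model
self-consistency averages 8 refits at n = 5000; effect-size recovery
uses 200 replicate cohorts at n = 610; LRT calibration 1000 replicates
at n = 610; model choice 11 and conditional analysis 15 replicates; CI
coverage and pipeline checks use reduced cohorts (n = 8–12).  These
sizes were chosen so the full suite completes in well under half an
hour while keeping Monte-Carlo error far from each assertion's margin.

## Known limitations

- The base-level tract and flank sequences, and the exact placement of
  A6's SNV and A5/A7/A8's non-STR differences, are structural stand-ins.
- Gap chains deeper than two per single-read alignment are not searched;
  alleles needing them must arise through candidate combination.
- The caller assumes a diploid sample localised to one declared locus;
  there is no duplicate marking, quality-score modelling, or multi-locus
  discovery.
- The KS p-value after parameter fitting is optimistic (no
  estimation-aware null); it is labelled approximate in the output.
- Profile CIs assume a unimodal likelihood; with pathological data the
  bracket expansion flags rather than guarantees coverage.
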