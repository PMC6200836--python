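# Methods

somascape characterizes somatic tumor genomes downstream of variant calling:
it consumes per-sample SNV, copy-number-segment, and SV-breakpoint call sets
and produces mutation spectra, de-novo mutational signatures, catastrophe
calls (kataegis, chromothripsis, breakage–fusion–bridge), SCNA summaries,
and two-cohort comparison statistics. A synthetic cohort generator with a
ground-truth table drives all testing, since real comparative WGS call sets
of this kind are controlled-access.

## Coordinate and channel conventions

Inputs follow their formats' conventions (VCF/MAF/SEG 1-based, SEG
inclusive; BEDPE 0-based half-open); internally all intervals are 0-based
half-open and point positions 1-based. All records are stored on the
reference strand.

Substitutions are collapsed so the mutated base is reported as A or C: a
record with a G or T reference is reverse-complemented together with its
3-mer context. Six collapsed types (A>C, A>G, A>T, C>A, C>G, C>T) × 16
flanks give 96 channels; the map from the 192 raw (ref, alt, context)
combinations onto channels is exactly 2-to-1. Channel order is fixed:
type-major, then 5' base A<C<G<T, then 3' base. This A/C-reference collapse
is the native convention (it makes "A>C at AA sites" — A[A>C]N with a 5'
adenine — directly readable); `to_cosmic_convention` is the lossless
involutive permutation onto the pyrimidine convention used by published
reference-signature tables, under which A[A>C]A reads as T[T>G]T.

Mutation burden is mutations per megabase over an explicit denominator. The
callable denominator of real WGS is pipeline-specific, so the package
requires it as an argument, defaulting to 2,800 Mb for a human genome;
synthetic cohorts use their exact genome length.

## Signature model

The spectrum V (samples × 96 counts) is factorized as V ≈ E·P with E ≥ 0
(exposures, samples × k) and P ≥ 0 (profiles, k × 96, rows normalized to
sum 1, scale absorbed into E) under the generalized Kullback–Leibler
divergence with multiplicative updates (scikit-learn's `mu` solver), 10
random restarts keeping the lowest divergence, max 5,000 iterations,
relative tolerance 1e-6. NMF is run on raw counts (burden-weighted); a
caller can normalize rows first if equal weighting is wanted.

Rank selection: for each candidate k, each sample's counts are resampled
multinomially with the sample's total, each resample is factorized, and the
pooled resampled profiles are partitioned into k clusters by cosine distance
(spherical k-means on L2-normalized vectors). Stability is the mean cosine
silhouette of that partition; reconstruction error is the median Frobenius
error of the resample fits. The resample fits use deterministic NNDSVD
initialization (max 1,000 iterations, tolerance 1e-5) so the stability
estimate measures resampling variability, not restart variability. The
silhouette is undefined at k = 1, where stability is defined as the mean
pairwise cosine similarity of the pooled vectors (≈1 for homogeneous data).
The selected rank maximizes stability(k) − ε(k)/ε(k_min), ties toward
smaller k; the full diagnostic table is always emitted so the choice can be
overridden.

Assignment labels each extracted profile with the reference signature of
highest cosine similarity, reporting the runner-up, and "unknown" below a
threshold (default 0.85). Per-sample refitting against a fixed catalogue
uses forward selection: starting empty, repeatedly add the reference whose
inclusion (weights re-optimized by NNLS over the selected set, then
normalized to sum 1) most reduces the SSE against the normalized sample
spectrum, stopping at `limit` signatures (default 3) or when the
improvement falls below 1e-4; weights under `cutoff` (default 0.15) are
zeroed and the rest renormalized. This NNLS re-optimization replaces the
per-signature golden-section search of the classical refitting tool: same
constrained objective, simpler and deterministic.

The packaged reference table (`data/reference_signatures_synthetic.tsv`) is
a stylized synthetic catalogue — S1-like (C>T at NpCpG), S2-like (APOBEC
C>T/C>G at TpC), S3-like (near-uniform), S17-like (T>G at 3'T, i.e. A>C at
AA on the native strand), U2-like (T>C at 5'A) — constructed for simulation
and testing. It is not the published Alexandrov/COSMIC data; analyses of
real cohorts should load a published table via `load_reference_signatures`.

## Catastrophe detection

Kataegis. Candidate clusters are maximal runs of ≥ 4 consecutive SNVs with
every adjacent inter-variant distance < 2 kb. A cluster is reported when its
hyperscore exceeds 5, where hyperscore = (k/w)/(M/G): cluster SNV density
(k SNVs over span w) over the sample's genome-wide density (M SNVs over
genome length G). The original tool's hyperscore additionally adjusts for
trinucleotide composition; this density-ratio form is the simplest statistic
consistent with its intent, and both thresholds are arguments.

Chromothripsis, per chromosome and sample: (1) breakpoint density ≥ 3× the
sample's genome-wide density (the "breaks equally distributed" uniform
null); (2) breakpoint clustering within the chromosome by a two-sided
one-sample Kolmogorov–Smirnov test against Uniform(0, chrom length) at
α = 0.01; (3) ≥ 10 switches between rounded integer copy-number states of
adjacent segments. Chromosomes with < 10 breakpoints are reported unverdicted
(False, with reason). "Breaks" are SV breakpoints (each SV contributes both
ends); CN segment boundaries are not counted as breaks. The verdict is
invariant to chromosome relabeling and uniform coordinate scaling.

BFB, per arm: telomeric loss (a segment overlapping the terminal 1 Mb of
the arm at state ≤ baseline − 1), a neighboring amplification (a segment
within 10 Mb of the lost region at state ≥ baseline + 3), and breakpoint
clustering on the chromosome (KS p < 0.01, ≥ 10 breakpoints). Baseline
ploidy defaults to 2 (per-sample ploidy can come from the manifest). Arms
are delimited by a centromere table when given, else the chromosome
midpoint — synthetic genomes carry no centromeres. Windows and thresholds
are explicit arguments; they formalize what is, in practice, a manual
review step.

## SCNA classification

Copy-number states are banker's roundings of total copy number. A segment
is a gain at ≥ baseline + 1, a loss at ≤ baseline − 1, and LOH when minor
copy number rounds to 0 on a segment with state ≥ 1 (so a homozygous
deletion is loss, not LOH); labels may co-occur. Per-class lengths are sums
over labeled segments; the fraction of genome altered uses the union of
altered bases so multi-labeled segments count once. Region features for
clustering are +1/−1/0 by ≥ 50% coverage of an amp/del-tagged region with
gain/loss bases. Hierarchical clustering is agglomerative with Euclidean
distance and complete linkage (both configurable), deterministic given
input order.

## Comparison statistics

Wilcoxon rank-sum: exact two-sided p by full enumeration of the rank-sum
distribution (dynamic program) when the pooled size is ≤ 20 with no ties;
otherwise the normal approximation with midranks, tie-corrected variance,
and 0.5 continuity correction. The method used is recorded per row. Fisher
exact two-sided p sums hypergeometric point probabilities ≤ that of the
observed table (relative tolerance 1e-7) — the convention that reproduces
the published p = 0.19 for the 6/16 vs 1/10 BFB table. P-values are not
multiplicity-adjusted by default (matching common practice for a handful of
planned contrasts); a Benjamini–Hochberg column is available by flag.

## Synthetic cohorts

Reference sequences are i.i.d. bases at a configurable GC fraction (default
0.41). Per sample, exposures are Dirichlet draws over the group's signature
set, totals are lognormal burden (mutations/Mb) times genome size, channels
are multinomial from the exposure-weighted mixture, and positions are drawn
uniformly among genome sites whose collapsed trinucleotide context matches
the channel (an index is built once per genome), so every record's context
matches its channel by construction. Kataegis foci are 6–12 SNVs with gaps
uniform in [50, 1500) bp, re-placed until the hyperscore clears the
threshold with a 3× margin. A chromothriptic chromosome gets 40–80
breakpoints confined to a random 20% window plus a 16-segment two-state
oscillation (15 switches); a BFB q-arm gets a terminal 1-Mb segment at
baseline − 1, an amplified segment at baseline + 4 within 10 Mb, and 30
breakpoints in a 1.2-Mb window beside it. Background SVs are uniform
(80% intra-chromosomal deletions, 20% translocations).

The two-group preset (10 "low" vs 16 "high" samples on the 10 × 10 Mb
"mini" genome) plants medians near 2.5 vs 10 mutations/Mb (lognormal σ =
0.5), an S17-like exposure with Dirichlet mean 0.3 only in the high group,
kataegis means 0.5 vs 3 foci/sample, chromothripsis probability 0 vs 0.3,
BFB probability 0.1 vs 0.375, and disjoint per-group recurrent SCNA
regions. Everything is deterministic per seed.

What the generator does not emulate: sequence context biases of real
genomes (repeats, CpG depletion), clonal structure and purity, germline
variation, calling errors, and realistic SV topologies. Passing tests
therefore demonstrate the correctness of the implemented rules and their
detection margins under the generative model, not detector performance on
real tumors. The chromothripsis margin in particular is relative to the
sample's genome-wide breakpoint density, so it is guaranteed only at the
default genome geometry — on a much smaller genome the planted breakpoints
themselves would dominate the null.

## Problem sizes

The test-suite and the acceptance script run on the mini genome (100 Mb):
26-sample cohorts at full planted burden, 30-sample × ~3,000-mutation
spectra for the 20-seed rank-selection study, 200 null replicates for the
rank-sum type-I check, and 1,000 random profiles for the CN-switch oracle.
These sizes make every property measurable in minutes on a single core
while keeping all planted margins at their default values.

## Known limitations

- The hyperscore is a density ratio, not the original trinucleotide-adjusted
  statistic; absolute values are not comparable to that tool's scores.
- Exact rank-sum p-values are limited to untied pools of ≤ 20 values; ties
  always route to the midrank normal approximation.
- LOH calls require minor-allele copy number; segments without it are
  excluded from LOH totals and counted as undetermined.
- The packaged signature catalogue is synthetic (see above); assignments
  against it are only meaningful for synthetic data generated from it.
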