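# Methods

`secmx` analyses two-condition SEC co-fractionation experiments quantified
with isobaric (TMT) reporter ions.  Native protein assemblies are separated
by size-exclusion chromatography into ~55 fractions; fractions are pooled
into TMT mixes so that each reporter channel maps back to one fraction of
one condition and replicate.  The package turns the resulting peptide-level
reporter table into *assembly states* — elution peaks of a protein, each
interpreted as a distinct molecular assembly (monomer, subcomplex, complex)
— maps phosphopeptide elution peaks onto those states, and quantifies
differential state abundance and phosphorylation between conditions.

## Signal processing

1. **Filtering.** Only proteotypic, non-decoy peptides are kept.  Each
   peptide is assigned a single representative protein accession, the
   lexicographically first of its protein group (deterministic and stable
   across runs and search-engine orderings).
2. **MS1 normalization.** Within one TMT spectrum (one precursor of one
   peptidoform in one mix) the reporter channels are rescaled to sum to the
   precursor's MS1 intensity: `reporter_c / Σ_c reporter_c × MS1`.  This
   anchors the relative reporter pattern to the more quantitative MS1 signal
   while preserving channel proportions.  Spectra with all-zero reporters
   yield zeros.
3. **Matrix construction.** Records pivot to entity × fraction matrices per
   (dataset, condition, replicate); duplicate spectra for one cell are
   summed and unobserved cells are zero.  In full-overlap designs each
   interior fraction is measured in two adjacent mixes, so the mix dimension
   is kept until batch correction.
4. **Batch correction (full-overlap designs).** For each adjacent mix pair
   the correction factor is the mean over shared fractions of the median
   over peptides (nonzero in both mixes) of the intensity ratio
   mix[n+1]/mix[n].  Mix n+1 is **divided** by the factor — division, not
   multiplication, is what re-centres the post-correction overlap ratio at
   exactly 1 — and corrections chain left-to-right, anchored on the first
   mix.  The duplicated overlap measurements are then averaged; when one
   mix's measurement is missing the surviving value is used as-is rather
   than being halved by a zero.  Zeros are excluded from the ratio medians
   because a zero denominator or numerator carries no scale information.
5. **Condition normalization.** Per dataset and replicate the comparison
   condition is divided by the ratio of nonzero-intensity medians
   (median(B)/median(A)); the reference condition is never rescaled.
   Medians are over nonzero cells only, since the zero-filled missingness
   pattern would otherwise dominate.
6. **Replicate averaging.** Union-based: the averaged matrix covers every
   entity seen in any replicate, and each cell averages only the replicates
   in which the entity was identified at all, so single-replicate entities
   are not diluted toward zero.
7. **Smoothing.** A zero-phase two-pass moving average of width 2
   (`b = [1/2, 1/2]`, `a = [1]`, forward-backward), equivalent to the
   symmetric kernel [0.25, 0.5, 0.25] in the interior: unit DC gain, no
   phase shift, apexes of symmetric peaks unmoved.  Boundaries use odd
   (antisymmetric) signal extension with pad length 3; tiny negative
   boundary artifacts are clipped to zero to preserve the nonnegativity
   contract.
8. **Protein collapse.** The global dataset is collapsed to protein level by
   summing, per fraction, the three peptides with the largest
   all-fraction total intensity (all peptides when a protein has three or
   fewer).  The phospho dataset stays at peptide level, with alternative
   phosphosite placements of one stripped sequence summed into one entity.

## Molecular-weight calibration and monomer calls

A standard of known molecular weights fitted by ordinary least squares gives
`log10(MW) = intercept + slope × fraction` (slope < 0; a nonnegative slope is
rejected as a mis-oriented standard).  When the standard is injected more
than once the pooled points are fitted together and the residual SD exposes
drift.  A peak is called **monomeric** when its apex elutes at or after the
fraction where the calibrated MW equals `multiplier ×` the protein's monomer
mass; the default multiplier 1.5 buffers wide or slightly shifted peaks.
The boundary itself is inclusive (monomeric) — it already lies inside that
buffer.  Base-10 logarithms are used throughout; any base yields identical
classifications, the choice is fixed only for reproducibility.

## Peak detection

Peaks are detected on the smoothed, replicate-averaged profiles with
`scipy.signal.find_peaks` under three constraints, all configurable:
prominence ≥ 0.05 × the profile maximum (standard topographic prominence),
apex separation ≥ 3 fractions (the higher of two closer maxima survives),
and apex intensity ≥ 1000.  Widths are measured at half prominence
(`scipy.signal.peak_widths`).  The intensity floor applies to the smoothed,
MS1-normalized scale; synthetic data are generated on a comparable scale so
the detection floor is exercised from both sides.  Entities in which no peak
can be modeled are dropped as noise.  Plateau and tie handling follow the
detector's documented semantics (plateaus report their middle sample);
smoothed floating-point profiles make exact ties a measure-zero event, and
the test suite cross-checks the detector apex-for-apex against an
independent exhaustive scan.

## Peak alignment across samples

Peaks of one entity in *n* samples (here: the two conditions) are matched by
enumerating *alignment paths*.  Each sample's peak list is augmented with
one missing marker; every element of the Cartesian product (except the
all-missing path) is a candidate path scored by a threshold-penalized
variance:

    mean  = (Σ non-missing apexes) / m
    var   = (1/n) [ Σ_present (apex − mean)² + (n − m) · T² ]
    score = 1 / (var + 1)

with T = 3 fractions by default.  A peak further than T from the path mean
costs more than leaving the sample unmatched, so distant peaks break into
separate states; for n = 2 the crossover sits at an apex gap of T·√2.
Selection is greedy: the best-scoring path becomes an assembly state, every
path sharing one of its concrete peaks is discarded, and the process repeats
until all peaks are covered — a partition of the peak set.  Ties are broken
deterministically (more matched peaks, then smaller mean, then
lexicographically smaller elements).  Only samples in which the entity was
measured count toward n.  The consensus apex of a state is the mean of its
member apexes; states present in every condition are flagged `mutual`.

**Phosphopeptide mapping** is deliberately asymmetric: each phosphopeptide
peak is assigned to the nearest same-condition peak of its parent protein's
global states within 3 fractions, and the annotation *adopts the global
apex*, so many phosphopeptides can share one assembly state.  Ties go to the
taller global peak.  Peptides whose parent protein has no global peaks are
flagged orphans.  The 3-fraction cutoff can be examined with the
replicate-vs-random apex-difference diagnostic (`threshold_evaluation`),
which tallies nearest-apex differences for the same entity across replicates
against a derangement of entity labels.

## Differential quantification

Per assembly state aligned in both conditions, the fold change is
`log2(height_B / height_A)` of the smoothed replicate-averaged peak heights,
each condition read at its own member apex (configurable to consensus-apex
reading).  Phospho fold changes are computed per phosphopeptide and only
when the peptide mapped to the same global state in both conditions.
Crossing the global and phospho calls at a ±2-fold cutoff (strict
inequalities; |log2 fc| exactly 1 is not significant) yields the 3×3
response-group grid, lettered A–I row-major from (phospho up-in-B, global
up-in-A) to (phospho up-in-A, global up-in-B); E is the doubly-unchanged
center.  Group tables are reported per (state, peptide) pair; protein-level
deduplication is left to the consumer because a protein with several states
legitimately occupies several groups.  Fraction-summed abundance ratios
(one value per protein per condition, replicate-averaged, ratio over shared
proteins) provide the compression-style bulk comparison, and Pearson
profile correlations the profile-similarity views.

## Synthetic data generator

The generator emulates the study conditions: 54 fractions, two conditions,
two replicates, 200 proteins by default.  Each protein elutes in 1–3
Gaussian states; the latest state sits at the fraction the planted
calibration line (`log10 MW = 7.0 − 0.06 × fraction`) predicts for the
monomer (monomer mass jittered ×[0.85, 1.15] around the prediction), and
earlier complex states sit 12–15 fractions earlier — far enough apart that
state tails do not contaminate each other's apex heights.  Peptide
amplitudes are log-uniform on [5×, 100×] the detection floor of the peak
caller; state occupancies are uniform on [0.4, 1].  30% of states carry a
planted fold change of 1.6–3-fold (random sign); 30% of proteins carry 1–3
phosphopeptides, each pinned to one state with its own planted phospho fold
change.  The global dataset uses the full-overlap TMT scheme (18-channel
mixes, stride 9) with optional per-mix batch scale factors; the phospho
dataset always uses the no-overlap scheme whose mixes pool the same
fractions of both conditions — the layout that makes phospho fold changes
immune to mix-level batch effects and mirrors how phosphopeptide enrichment
is multiplexed in practice.  Reporter values receive multiplicative
log-normal noise (σ = 0.1 by default), a detection-floor censor at 100
intensity units, and 2% random missingness, emulating stochastic sampling.
MS1 intensities are the summed reporters of each spectrum, making the MS1
normalization an exact inverse on clean data.  A small set of decoy and
non-proteotypic filler records exercises the filter stage.

One subtlety is ground truth for fold changes.  Median-ratio condition
normalization under asymmetric regulation rescales *every* ratio by a small
data-dependent constant (the shift of the nonzero-median); this is a
well-known property of median normalization, not a pipeline defect.  The
truth table therefore records both the drawn fold change and the expected
fold change on the normalized scale — drawn minus the median shift computed
exactly on the noise-free, floor-censored signal — and recovery metrics
score against the latter, isolating pipeline error from normalization bias.
With the defaults the shift is below 0.06 log2 units.

What the generator does **not** emulate: reporter-ion interference and
ratio compression, isotopic impurities, co-eluting interference, retention
drift between replicates, peptide-specific digestion/ionization biases that
differ between conditions, and non-Gaussian (tailing) peak shapes.  Passing
recovery tests therefore demonstrate correctness of the computations under
the stated elution model, not robustness to every artifact of real data.

## Numerical choices and degenerate inputs

- Fractions are 1-based integers in collection order; all apexes use this
  coordinate.
- Entity ids with tabs/newlines are rejected at serialization; matrices
  round-trip bit-exactly (shortest-repr writing, round-trip float parsing).
- All-zero profiles yield no peaks; peakless entities are dropped with a
  logged count; an all-zero condition matrix is a hard error for
  normalization.
- Zero peak heights are excluded from ratios (flagged, logged).
- Batch correction with no usable overlap peptide raises an error naming
  the mix pair.
- Profiles shorter than 2 samples are returned unsmoothed with a warning.
- Constant profiles have undefined Pearson correlation, reported as NaN.

## Problem sizes

Recovery checks run at 200 proteins (≈350–400 states, ≈100k reporter
records) per condition pair, which gives the batch-correction medians and
normalization factors dense support (relative factor error well under 1% at
σ = 0.05) while keeping a full pipeline run around a second.  The
exhaustive alignment cross-check covers every instance with ≤3 samples and
≤3 peaks per sample over a 4-apex domain (2,954 instances).

## Known limitations

- Exactly two conditions are supported end-to-end (the alignment algebra
  itself is n-sample).
- Greedy path selection is not globally optimal; with the default threshold
  and realistic peak densities the exhaustive cross-check shows no
  divergence at small n, but no optimality guarantee exists.
- Condition normalization assumes globally comparable intensity
  distributions; grossly asymmetric regulation shifts all ratios (see
  above).
- The monomer boundary relies on monomer masses being on the same scale as
  the calibration standard; glycosylation or intrinsic disorder that alters
  hydrodynamic radius will misclassify.
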