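# Methods

## Overview

`cdtaseq` implements the computational side of a metabolic-labeling
mRNA-quantification experiment: cells are pulsed with 4-thiouracil
(4tU), which is incorporated into nascent RNA and, after alkylation,
read as C instead of T by the sequencer. A fixed quantity of a second
yeast species is spiked into every sample before RNA extraction as an
internal standard. The pipeline turns 3′-end, UMI-barcoded reads into
per-transcript recent fractions, degradation rates and half-lives, and
per-sample absolute (spike-normalized) mRNA levels, and analyses
perturbation time courses built from many such samples.

## Reference handling

**Three-letter conversion.** A labeled read carries T→C mismatches
that defeat ordinary alignment, so alignment is done against a
reference in which every T is rewritten to C, separately per strand:
each contig yields `<name>__fwd` (plus strand, T→C) and `<name>__rev`
(reverse complement, T→C). Reads are T→C-collapsed the same way before
alignment (the aligner itself is external; the package prepares its
input and consumes its output). Back-conversion restores original
coordinates and strand and classifies every mismatch of the *original*
read against the *original* reference: reference-T/read-C on the
transcribed strand is a conversion; anything else is an error.

**Spike-genome redaction.** Reads from sequence shared between the
host and spike species would be mis-assigned, so the spike genome is
redacted before use: every spike position covered by an 18-mer that
occurs anywhere in the host genome — on either strand, a deliberate
choice since read strandness does not constrain the shared sequence —
is masked to `N`. Masking rather than deletion preserves coordinates,
and aligners treat `N` as unmatchable, so the redacted genome admits
only spike-specific alignments. On real yeast genome pairs a few
percent of the spike genome is lost this way; the package's toy-genome
checks verify the exhaustive property (zero shared 18-mers survive)
rather than the genome-scale fraction.

## Read processing

Trailing polyA runs are stripped and reads with ≤ 25 remaining bases
discarded. Records keep the genomic-T count `X` of the aligned span,
the conversion count `Y`, the non-conversion error count `E` and the
reported locus count. Filters (all inclusive): `X ≤ 30`, ≤ 5 loci,
`E ≤ 3` — conversions deliberately do not count toward the error cap.
Duplicates sharing (contig, strand, 5′ position, UMI) collapse to the
record with the fewest total deviations `E + Y`, with a lexicographic
read-id tie-break for determinism; conversions *do* count as
deviations here, since among copies of one molecule the
least-converted read is the least damaged, while the error filter's
exclusion of conversions is about not penalizing genuine labeling.
Reads are assigned to every transcript whose TTS window (300 bases
upstream to 100 downstream of the termination site, in transcription
orientation, matching strand) they intersect; a unique-assignment mode
(largest overlap, then lexicographic id) is available since overlap
resolution is not canonical. The 5′ alignment position anchors
deduplication because 3′-end libraries share their fragmentation site.

## The binomial mixture

Read statistics pool into tables `n[X][Y]` per transcript, transcript
group or transcriptome. With global per-batch conversion rates —
background ε for old molecules, incorporation ξ for recent ones — the
likelihood of a table is

L(p_r) = Σ n[X][Y] · log( p_r·Bin(Y;X,ξ) + (1−p_r)·Bin(Y;X,ε) ).

Each term is the log of a function affine in p_r, so L is concave and
bounded Brent search (absolute tolerance 1e-8, endpoints checked
explicitly because the bounded method can stall short of a boundary
optimum) finds the global maximum. The 95% CI is the profile-likelihood
interval (drop of 1.92 = χ²₁(0.95)/2), clipped to [0,1]. Reads with
X = 0 carry no information; tables containing only such reads are
flagged `defined=False` rather than given an arbitrary estimate. The
model is fixed at two components; a goodness-of-fit table of expected
versus observed counts per (X, Y) cell with a Pearson-χ² summary serves
as the diagnostic.

**Global parameters.** ε is the pooled binomial MLE ΣY/ΣX over
unlabeled (no-4tU or t = 0) samples. ξ is estimated by alternating
maximization: fit p_r per table at the current ξ, then maximize the
summed likelihood over ξ at the current recent fractions, to a 1e-6
tolerance; the scheme is flagged non-identifiable when every table
lands near p_r = 0. This alternating scheme is this package's own
design for a step whose canonical procedure is not standardized; it is
validated against 2-D grid searches in the test suite.

## Kinetics

The steady-state model is Ṙ = π − (δ + γ)R per transcript, giving
R_ss = π/(δ + γ) and a recent fraction p_r(t) = 1 − e^{−(t−t₀)(δ+γ)}
after a pulse of duration t. The conversion lag t₀ enters as an
effective-time offset (t − t₀, floored at 0): a delay before
incorporated label becomes detectable is the natural reading of a
conversion lag, and with t₀ ≈ 1 min against 6–10 min pulses the
placement has little leverage. Inversion yields
δ = −ln(1 − p_r)/(t − t₀) − γ and half-life ln2/δ.

**Censoring.** Half-lives above 180 min (`too_stable`) or below 1 min
(`too_volatile`) are outside the pulse's dynamic range; δ ≤ 0
(`negative_delta`) marks transcripts whose apparent decay is slower
than dilution alone. These are reported, never clipped, so counts of
"completely stable" transcripts stay explicit. Because the inversion
subtracts γ from a log term, an exactly-zero δ is unreachable in
floating point; deltas below 1e-12·(γ + 1/(t−t₀)) are classified as
the `negative_delta` boundary.

Two estimation modes exist: single-sample inversion, and a joint mode
that fits one δ per gene by least squares of the expected labeling
curve across a time course. The joint objective plateaus once
δ ≫ 1/t, so it is bracketed on a logarithmic grid before the bounded
scalar search — golden-section search alone stalls on the plateau.

**Normalization and growth.** The relative mRNA level is host
TTS-assigned reads / (OD × spike-genome reads); zero spike reads is an
error, not infinity. Time courses are smoothed with a third-order
Savitzky–Golay filter spanning a 120-minute window, implemented as a
local polynomial regression at each sample point so irregular grids
are handled identically to uniform ones (on a uniform grid it
reproduces the classical filter exactly; windows with fewer than four
points pass through with a warning). Growth rates come from ordinary
least squares of log(OD) over every run of 10 consecutive points, a
Bonferroni-corrected 5% slope test, and the maximum passing slope;
γ may instead be supplied per condition, and an explicit value takes
precedence over the OD fit.

## Time-course analyses

Depletion of a degradation factor produces an accumulation →
adaptation → reversion trajectory. Defaults follow that phase
structure: accumulation window 0–55 min, adaptation 55–95 min, both
configuration-exposed since they are data-derived labels, not
constants of nature. Per-transcript accumulation slopes are OLS fits
with the F-test p-value for a non-zero slope, Benjamini–Hochberg
q-values across transcripts, and selection at 10% FDR. The correlation
of slopes with pre-perturbation production rates is reported both raw
and as a partial correlation controlling for log expression
(residual-on-residual), because expression level confounds both.

The global recently-transcribed series is level × p_r per replicate,
scaled to its own t = 0 value, smoothed, and averaged across
replicates *after* smoothing. Its response half-time is the first
linear-interpolated crossing of the midpoint between the initial value
and the plateau, with the plateau estimated as the mean of the last
two samples — a minimal-assumption choice, overridable. Cross-strain
comparison computes per transcript Δnew (difference of cumulative
recently-transcribed changes, trapezoid over t < 60 min) and Δmax
(difference of peak total-mRNA changes over t < 90 min) plus their
Pearson correlation; trapezoid quadrature on the observed grid is the
minimal choice for an unspecified integral.

## Simulator

The generator exists so every stage has ground truth. Its defaults are
the study conditions the package targets: 9-minute pulse, 1-minute
lag, ε = 1e-3, ξ = 0.05, growth at a 90-minute doubling time, per-read
genomic-T counts X ~ Binomial(45, 0.3) (45-nt reads over ~30% T
sequence; a fixed-X mode supports analytic tests), 2000 reads per
gene, 3% spike fraction, UMI duplication factor 1.3. Per-gene rates
are log-normal: δ centered on the fast-turnover median half-life of
8.2 min (log-scale spread 0.5, truncated to the 1–180 min dynamic
range so the cohort is informative), π independent log-normal in
arbitrary units.

Three levels: (i) conversion tables drawn directly from the mixture
with membership probability p_r(t); (ii) full reads from TTS windows
of a toy genome with polyA tails, UMIs, planted conversions,
sequencing errors on non-T positions, and spike reads carrying only
background conversions; (iii) perturbation time courses with
piecewise-constant rates — degradation multiplied by a shutdown
factor at t = 0, transcription multiplied by an adaptation factor at
an onset time — solved exactly segment-by-segment, including the
exact labeled-molecule integral over each sample's pulse window
(production times survival, honoring every rate segment the window
spans). Scenario presets order the depletions along the 5′-3′ decay
pathway: the terminal exonuclease preset (`xrn1-like`,
shutdown × 0.05, onset 70 min), decapping (`dcp2-like`, × 0.40,
52 min) and deadenylation-scaffold (`not1-like`, × 0.70, 33 min)
depletions shut degradation down progressively less but adapt earlier;
all reduce transcription by 50% at onset.

**What the simulator does not emulate.** Real-data features outside
its scope: non-polyadenylated species that accumulate under
degradation-factor depletion but are invisible to a polyA protocol;
transcriptional bursting and cell-to-cell variability; cell-cycle
structure; per-position conversion-rate heterogeneity and
quality-score information; spliced alignments. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
model, not robustness to these phenomena. The true joint (π, δ)
distribution across genes is data-derived in practice; the log-normal
defaults are a plausible stand-in.

## Problem sizes and numerical choices

The recovery studies run at desk scale by design: 200 genes × 2000
reads/gene for read-level end-to-end checks (median relative error on
δ ≈ 5%), 1e5 reads per table for the recent-fraction sweep, 100-gene
cohorts for time-course orderings, 5000 transcripts × 20 replicates
for null FDR calibration. Optimization tolerances: 1e-8 for p_r, 1e-6
for ξ, 1e-10 for the joint δ fit; grid comparisons use a 1e-4 step.
Ties and degenerate inputs are deterministic throughout
(lexicographic tie-breaks, explicit flags instead of NaN surprises,
mandatory seeds in the simulator).

## Known limitations

ε and ξ are batch-global; per-position or per-sample rate variation
biases p_r where it exists. The profile-likelihood CI is asymptotic
and can be short at hard boundaries (p_r near 0 or 1 with few
informative reads). OD is taken as the biomass normalizer as given;
converting between OD, cell counts and volume is out of scope. The
alternating ξ estimator assumes at least some tables with substantial
labeling. Multi-assignment of reads overlapping several TTS windows
double-counts those reads unless unique mode is chosen.
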