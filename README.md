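# cdtaseq

Quantification of **total and recently-transcribed mRNA** from metabolic
RNA labeling (4tU / T→C conversion) sequencing with cross-species
spike-in normalization, and downstream analysis of mRNA-buffering
time-course experiments.

The package is aimed at researchers running SLAM-seq/cDTA-style
experiments in budding yeast (or any system with a 3′-end, UMI-barcoded
library and a spike-in species): it covers reference preparation for
conversion-aware alignment, read filtration and UMI handling, the
statistical model that separates old from recently transcribed
molecules, first-order kinetic half-life estimation, and the analyses
of perturbation time courses (e.g. acute depletion of mRNA degradation
factors). A seeded simulator generates reads, conversion tables and
perturbation trajectories with the same statistical structure, so the
entire pipeline is testable without sequencing data.

## The model

Each read is summarized by `X`, the number of genomic Ts in its aligned
span, and `Y`, the number of those read as C. Reads arise from a
two-component **binomial mixture**: old molecules convert at a
background rate ε, recently transcribed molecules at the 4tU
incorporation rate ξ > ε,

```
Pr(Y | X) = p_r · Bin(Y; X, ξ) + (1 − p_r) · Bin(Y; X, ε)
```

With ε and ξ global per batch, the per-transcript likelihood depends on
the single recent-fraction parameter `p_r ∈ [0, 1]`; it is log-concave,
so a bounded scalar search finds the MLE, and a profile-likelihood drop
of 1.92 gives the 95% CI.

Under first-order kinetics with growth dilution, `Ṙ = π − (δ + γ)R`
(π production, δ degradation, γ growth rate), the recent fraction after
a pulse of duration `t` with conversion lag `t₀` is

```
p_r(t) = 1 − exp(−(t − t₀)(δ + γ))
```

which inverts to `δ = −ln(1 − p_r)/(t − t₀) − γ` and a half-life
`ln 2 / δ`. Estimates outside the pulse's dynamic range are censored
(`too_stable` > 180 min, `too_volatile` < 1 min, `negative_delta`)
rather than clipped. Relative mRNA levels are host TTS reads divided by
(OD × spike-genome reads); the spike genome is first *redacted* by
masking every 18-mer shared with the host genome so spike alignments
are species-specific.

## Worked example

Simulate an acute degradation-factor depletion and analyse it:

```
$ cdta simulate --scenario xrn1-like --genes 30 --seed 3 --out traj.tsv
simulated 30 genes under 'xrn1-like' to traj.tsv
$ cdta dynamics --trajectories traj.tsv --out fits.tsv
recently-transcribed response half-time: 88.5 min
30/30 transcripts selected at 10% FDR
```

The first command integrates `Ṙ = π − (δ + γ)R` per gene with a
near-complete degradation shutdown at t = 0 and a 50% transcription
reduction at 70 min; the second fits the accumulation phase
(0–55 min) per transcript with Benjamini–Hochberg selection at 10% FDR
and reports when the smoothed global recently-transcribed series
crosses the midpoint between its initial level and late plateau — the
transcription-adaptation response half-time.

Fitting recent fractions from conversion tables and converting to
half-lives:

```
$ cdta fit-pr --tables tables.tsv --eps 0.001 --xi 0.05 --out pr.tsv
fitted 2 tables
$ cdta halflife --pr-table pr.tsv --t-label 9 --t0 1 --out hl.tsv
median half-life 15.4 min (2/2 uncensored)
```

(two tables with planted recent fractions 0.2 and 0.6 at a 9-minute
pulse; the fitted `p_r` values invert to half-lives of ~24.9 and
~6.0 min)

Library use mirrors the CLI: see `cdtaseq.mixturemodel.fit_pr`,
`cdtaseq.kinetics.pr_to_delta`, `cdtaseq.pipeline.quantify_sample`, and
`cdtaseq.simulator` for the generative models.

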