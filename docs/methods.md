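# Methods

## Signal model

Limited heat-alkaline deamination converts 5-methylcytosine (m5C) directly
to thymine at a small per-molecule rate, while unmethylated cytosines
deaminate to uracil and are excised before amplification. Per read-level
observation of a cytosine, the probability of reading T instead of C is

```
P(C->T) = e + d * 1[site methylated]
```

with `d` the deamination rate (default 0.01) and `e` the residual
background substitution rate (default 1e-5), a ~1000-fold signal-to-noise
ratio. 5hmC deaminates at the same rate as m5C and the two are deliberately
indistinguishable; the package reports their sum. Methylation is assumed
concerted within a region, so counts are pooled over all CpG sites of a
region before estimation — the package never claims base resolution.

The protocol's signature is read-asymmetric. The package models and counts
it as: Read1 carries deamination as C→T at top-strand CpG cytosines;
Read2 carries it as G→A at bottom-strand CpG cytosines; sequencing error
contributes C→T and G→A to both mates symmetrically. Two consequences are
used throughout:

- the pooled two-channel count (Read1 refC→T plus Read2 refG→A) measures
  `e + d·m` for a region of methylation `m`;
- the per-cycle difference between Read1's and Read2's C→T rate at
  reference-C positions (the "imbalance") cancels the shared error and
  isolates the deamination signal, context by context.

This is a deliberately phenomenological placement of events. A fully
mechanistic account of template strand inheritance through amplification
would either symmetrise the signal across mates or halve the pooled
channel rate, both of which contradict the observable signature the
protocol produces (Read1-specific C→T excess *and* a pooled rate equal to
`d` in fully methylated regions); the simulator therefore reproduces the
signature directly at read level. Pairs are emitted in FR orientation
with Read1 forward. CpG methylation is symmetric across strands (one
Bernoulli draw per CpG dinucleotide, as maintenance methylation implies).

## Counting and filters

Counting walks aligned read bases (CIGAR-aware) rather than a samtools
pileup, which makes plain SAM input and per-observation metadata (read
number, machine cycle, base quality) directly available. Filters, all
configurable on `CountingFilters`:

| parameter | default | why |
|---|---|---|
| min_mapq | 10 | mapping-quality operating point with the best accuracy for this library type |
| min_baseq | 30 | rejects most sequencer miscalls, which would otherwise swamp a 1e-5 background |
| excluded cycles | first 2 + last 2 of each read | transition rates are depressed at read edges |
| snp_mask | none | C→T and G→A SNPs mimic 100% methylation; mask from a VCF (DP ≥ 5 recommended) |

Denominators count only {C, T} bases at reference C (resp. {G, A} at
reference G): other bases are not cytosine-informative. Bases adjacent to
indels are skipped. Machine cycle for reverse-aligned reads runs from the
stored 3' end. Overlapping mate footprints are removed beforehand by
masking the overlapped Read2 bases to base quality 0 — the records stay
valid SAM, Read1 (the primary signal channel) is never touched, and the
counting BQ filter enforces the exclusion; the operation is idempotent.
Insertions inside the overlap are masked with their anchor base.

## Benchmark integration

Three per-region methylation measurements (e.g. WGBS, EM-seq, Nanopore;
coverage pre-filter 50/50/20) are combined as: coverage is normalised
within each method across regions (`P_{n,i} = C_{n,i}/Σ_m C_{m,i}`), each
region's proportions are renormalised to weights summing to one, and the
two closest measurements are averaged with those weights (BM). Argmin
ties go to the pair with larger combined weight. Regions are binned into
`n_bin = 10` equal-width bins — membership `[LB, UB)` with the last bin
closed at 1.0, so boundary values (notably BM = 1) are kept — and the bin
rate pools raw counts, `R_k = ΣError/ΣTotal`, so deeply covered regions
carry their evidence. OLS of `R_k` on the bin mean `ABM_k` (statsmodels)
summarises linearity; on simulated defaults the slope recovers `d` with
R² > 0.99. A degenerate flat response is reported as R² = 0. Quadrant
consistency between two call sets defaults to cuts (0.3, 0.7), following
the common <30% hypomethylation convention, with Pearson correlation
reported alongside.

## Calibration and RAML

`R0` pools all non-CpG cytosine observations in the control regions;
per-upstream-base stratification (the ApCpG effect is real but subtle) is
available via the recorded `upstream_base` but off by default. `R100`
adjusts each control's Error by its known methylation `WM` (only the
numerator is adjusted, as the estimator is defined). Estimates are clamped
to [0, 1] and flagged when clamping fired. Every estimate carries a
binomial standard error `se = sqrt(R(1−R)/Total)/(R100−R0)`; the point
estimate is the published quantity, but the DMR test needs a variance
notion and this keeps the two consistent. Regions with fewer than 100
combined CpG sites are flagged low-confidence rather than suppressed —
below that, a 1% deamination rate leaves too few expected events.
Calibration is run-specific by design: simulating with a different `d`
and recalibrating recovers the same methylation truth.

## DMR testing

Replicate estimates are pooled per region exactly like the
cross-technology benchmark (closest pair, coverage weights; ties to the
pair containing the largest-Total replicate; two replicates use both, one
passes through with a warning). The one-sided two-proportion z-test
compares pooled condition summaries against a margin `δ = 0.1`: the
printed form of the statistic is implemented with a square root over the
pooled variance term, as the use of the normal CDF requires a standard
error. `MeanBM` of exactly 0 or 1 gives zero variance; such regions are
flagged untestable. No multiple-testing correction is applied by default
(a Benjamini–Hochberg option exists), matching the convention of
correcting only the reference caller. Confusion scoring against a
reference label set keeps an explicit `not_evaluated` category for
regions failing the evaluable filter.

## Simulator scope

`simulate_reference` builds regions as repeats of an 8-bp unit
(`TACGTTCA`: one symmetric CpG, one CpA cytosine) separated by
cytosine-free spacers, so CpG and non-CpG channels are exactly countable
by construction. Fully methylated control regions (WM = 1) are appended.
Homozygous SNPs are substituted into reads (not the reference FASTA) and
emitted as a plain-text VCF. Qualities are flat Q37, optionally degraded
at read ends to exercise the cycle filter.

Two fidelity levels share the same truth: full SAM read pairs (fragment
length 160 bp by default, so 100-bp mates overlap by 40 bp and exercise
the trimming path), and per-site binomial pileup counts, roughly two
orders of magnitude faster, used for statistical and acceptance checks.
`coverage` means informative observations per cytosine site in the
counting channel.

Not emulated: realistic genome composition and mappability, PCR
duplicates, quality-score error profiles beyond the flat model,
alignment errors, heterozygous SNPs, or strand-asymmetric methylation.
Passing tests therefore demonstrate the correctness of the counting,
calibration and testing machinery under the stated signal model — not
robustness to alignment artefacts in real data.

## Problem sizes and numerical choices

Acceptance-style computations use: 1000 pileup replicates of one
100-CpG region at 30× for the expected-event count; ~1e8 background and
~1e8 methylated observations for the calibration fold (binomial draws,
seconds of runtime); 500 regions × 100 CpG × 50× for the binned
regression. These sizes put Monte-Carlo error comfortably inside the
claimed tolerances while running in seconds. All randomness flows through
`numpy.random.default_rng` seeded from the user seed plus a fixed stream
tag per stage, so reference, pileup and read simulation are independently
reproducible. Coordinates are 0-based half-open internally; VCF input is
converted at the boundary. Known limitation: the variance model treats
calibrated methylation as a binomial proportion of `Total` trials, which
ignores calibration-anchor uncertainty; with the recommended control-set
sizes that contribution is second-order.
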