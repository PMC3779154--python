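# Methods

## Screen architecture

The pipeline models a qHTS cytotoxicity screen in 1536-well format with
inter-plate titration: each compound keeps one well position across a
stack of plates, and each plate carries one concentration of a descending
geometric series (default 8 points, 57 µM → 0.7 nM in 1:5 steps; a
12-point 1:3 confirmation series and the 15-plate 1:2.236 stock series
are the same `ConcentrationSeries` primitive). Columns 1 and 3 of every
compound plate are DMSO (negative control), column 2 a doxorubicin 1:2
titration from 10 µM to 5 nM, column 4 doxorubicin at 10 µM (full-kill
positive control); columns 5–48 hold 1408 library compounds. A 2,816
compound library therefore occupies two plate positions of 8 plates each,
bracketed by one compound-free DMSO plate at each end of the stack.

Two points in the protocol description are ambiguous and were resolved as
follows. The compound area is taken as columns 5–48 (the per-column
control enumeration is explicit; the alternative reading "column 4 to 48"
would overlap the positive control column). The column-2 titration
reaches its stated 5 nM floor after 12 points; the remaining 20 wells of
the column cycle the 12-point block rather than extending below the
stated floor.

## Signal model of the synthetic screen

Raw luminescence is generated as

    raw(w) = baseline × (1/sb + (1 − 1/sb) · s(w)) × spatial(w) × ε(w)

where `s(w) = max(1 + y(c_w)/100, 0)` is the surviving-cell fraction
under the planted 4PL response `y`, `sb` the DMSO-to-full-kill signal
ratio (default 11.2), `spatial` a mean-1 multiplicative artifact field
(corner-to-corner gradient plus edge depression, default amplitude 10%)
and `ε` log-normal well noise with mean exactly 1 (default CV 5%).
The additive-background form encodes that a fully killed well still emits
the assay's background luminescence `baseline/sb`; it also makes
control-anchored normalization an exact inverse of generation, so the
noiseless pipeline round-trip recovers planted parameters to machine
precision. The alternative "clamp viability at 1/sb" form was considered
and rejected: with the −100% anchor at `baseline/sb` it stretches
normalized responses by `1/(1 − 1/sb)` ≈ 1.10, biasing recovered
asymptotes by ~10 points and midpoints by ~17% at Hill slope 1. A
consequence of the physical model is that planted kill saturates at
−100%: archetypes are drawn with `y∞ ≥ −100`.

Planted archetypes (default mix 70% inactive, 12% pan-cytotoxic, 8%
partial-efficacy, 5% top-concentration-only, 5% CLL-selective) define the
ground truth. Potency centers are drawn per compound (pan/partial/
selective: 0.1–2 µM log-uniform; top-only: 35–60 µM with steep slopes)
and per-sample values log-normally around the center with σ = 0.3 log10
units — the paper-scale inter-patient spread is not published, and this
value was chosen once to reproduce a 30-fold-ish extreme spread across
eleven samples (the anthracycline-type tail). Selective compounds get a
10–50-fold potency shift in normal samples plus reduced efficacy
(−45…−25%), so they are discoverable through either selectivity clause.
The generator does not emulate: donor covariates, plate-to-plate drift
beyond the spatial ramp option, liquid-handling failures (dead rows,
dispenser streaks), edge evaporation beyond the static edge term, or
compound fluorescence/luciferase interference. Passing recovery tests
therefore validates the analysis machinery, not robustness to every
real-screen pathology.

## Normalization, pattern correction, QC

Anchors are per-plate medians (columns 1/3 for DMSO, column 4 for
full-kill; the column-2 titration is excluded), robust to occasional dead
wells; the Z′-factor uses means and sample SDs per the standard formula.
Normalized activity is `100 (raw − µn)/(µn − µp)`, so killing is negative
and −100% matches the doxorubicin control — the cytotoxicity-negative
figure convention.

Pattern correction divides raw values by a per-well relative background
`b_k(w) = dmso_k(w)/median(dmso_k)` from the bracketing DMSO plates,
linearly interpolated in stack position. Division exactly removes any
multiplicative field shared between DMSO and compound plates, leaves
plate medians unchanged, and is idempotent (the corrected DMSO plates are
flat, so a second pass divides by 1). DMSO-only plates carry no positive
controls and are excluded from normalization and QC output.

## Dose-response fitting

`y(c) = y0 + (y∞ − y0)/(1 + (AC50/c)^h)`, fitted by bounded trust-region
least squares (scipy) with an analytic Jacobian, the midpoint optimized
as log10 AC50. Initialization is deterministic and derivative-free: `y0`
from the two lowest-concentration responses, `y∞` from the two highest,
`h = 1`, and log-AC50 from the best of a 20-point log-spaced grid over
[c_min/10, c_max·10] by residual sum of squares. Bounds: `h ∈ [0.3, 10]`,
`AC50 ∈ [c_min/100, c_max·100]`, `y∞ ∈ [−120, 30]`, `y0 ∈ [−30, 30]`
(prevents pathological extrapolation on incomplete curves). Curves whose
observed span is below 5 points are flat: `converged = False`, efficacy
0, AC50 NaN. Efficacy is `|y∞ − y0|` from the fitted asymptotes, clamped
to [0, 120]. No outlier masking is performed — single-point rejection
would trade reproducibility for marginal robustness. Optimizer tolerances
are 1e−12 (xtol/ftol/gtol), giving ≤ 1e−6 relative parameter error on
noiseless curves.

## Curve classification

Decision cascade, in order: (a) class 4 when no observed response
reaches 25 points toward kill (configurable `act_threshold`; responses in
the +% direction never count); (b) class 3 when activity exists but the
fit is unusable (unconverged), significant response occurs only at the
single highest concentration, r² < 0.3, or the Hill slope sits at its 0.3
floor (shallow/single-point-extrapolated curves); (c) otherwise complete
vs incomplete by whether the fitted response at the top tested
concentration is within 5% of span of `y∞`, crossed with the 80% efficacy
boundary → 1.1/1.2/2.1/2.2. The 25-point threshold, r² floor and
plateau tolerance operationalize qualitative descriptions ("significant
activity", "poorly fit", "lacking the lower asymptote") and are exposed
in `ScreenConfig`; the numeric boundary between class 3 and a shallow
2.2 is our choice, as no published rule quantifies it.

Categories: active = class 1.1/1.2/2.1/2.2 **and** efficacy > 60%;
inactive = class 4; inconclusive otherwise.

## Hit calling and selectivity

Consensus hits must be active in every CLL sample with each IC50 below
30 µM; per-compound potency across samples is aggregated by geometric
mean (potencies are log-distributed). Selectivity is an OR over three
clauses, each reported separately: normal/CLL GM-IC50 ratio > 5; mean
kill-magnitude difference > 40 points at the two highest tested
concentrations; and "low or no activity in a majority of normal donors",
encoded as ≥ ⌈n_normal/2⌉ normal samples whose category is not active
(an inconclusive normal-donor curve counts as "low activity"). The OR
reading follows the source phrasing ("either differential efficacy or a
considerable IC50 shift").

Activity profiles are integer-coded (active 1, inconclusive 2, inactive
3, untested 4) and clustered with average linkage on the fraction of
commonly tested assays whose codes disagree; untested cells are
non-informative and excluded from the distance (pairs sharing no tested
assay get distance 1). Rows are pre-sorted by compound id so leaf order
is deterministic.

## Caspase module

Activation is normalized as `100 (raw − µ_DMSO)/µ_DMSO` (0% = DMSO, 100%
= 2-fold induction), sharing the 0% anchor with the viability scale.
Bell-shaped curves (cytotoxic compounds kill cells faster than the
caspase signal develops at high dose) are handled by peak detection: when
any post-peak point falls below 50% of the peak, all post-peak points are
masked — always a suffix, never the peak — and a rising 4PL is fitted to
the ascending limb; the 50% mask fraction is configurable. Flat curves
(caspase-8/9-type) return `converged = False` rather than an error.

## Problem sizes and reproducibility

Unit tests run on a 64-compound mini screen (6 CLL + 5 normal samples,
seeded); recovery benchmarks use 200 single-archetype compounds; the
full-scale configuration (2,816 compounds × 8 concentrations × 11
samples, ~31k curve fits) runs end to end in minutes on one CPU and is
exercised by the acceptance suite. All randomness flows from explicit
integer seeds (per-sample streams derived via CRC of the sample id), and
`run_pipeline` artifacts are byte-identical across reruns for a fixed
config and seed.

## Known limitations

IC50s of incomplete (class 2) curves are extrapolations; they are
reported with the class label carrying the confidence qualification, not
suppressed. The published patient-screen counts (actives per sample,
consensus and selective totals) depend on unreleased primary patient
data and are not reproducible from this package; the tests instead
validate the machinery on synthetic screens with known truth, plus the
protocol arithmetic and worked numeric examples that are computable
exactly. No B-score/median-polish correction variants, no 5PL or
biphasic viability models, and no statistical testing of selectivity
(point rules only, as in the source analysis).
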