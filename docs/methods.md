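# Methods

`isletwave` decomposes pancreatic-islet Ca²⁺ recordings into the waveform
parameters that describe β-cell electrical bursting, correlates those
parameters with islet protein abundances across genetically diverse mouse
strains, and nominates candidate genes by overlap with human glycemic-trait
GWAS signals. This note records the models, the numerical choices, and
their limits.

## The signal model

An islet's Ca²⁺ proxy is a fluorescence ratio (bound/free dual-excitation
dye; the ratio rises with Ca²⁺) sampled every 6 s (0.1 min) through four
40-min perifusion conditions: 8 mM glucose (8G), 8G plus
glutamine/leucine/alanine (8G/QLA), plus 10 nM GIP (8G/QLA/GIP), and 2 mM
basal glucose (2G). Within a condition the signal is modelled as

    x(t) = baseline + amplitude · b(t) + drift · t + ε(t)

where `b(t)` is a square-like burst train with period `T` and duty cycle
`d` (active-phase share), `drift` is slow linear baseline movement, and
`ε` is i.i.d. Gaussian measurement noise. Square-like bursts — not
sinusoids — are the empirically observed shape of islet oscillations, and
they make the duty cycle and the half-maximum "active duration"
definitions coincide.

## Waveform parameters

Per segment, six parameters are estimated:

| symbol | name              | definition                                             |
|--------|-------------------|--------------------------------------------------------|
| peak   | oscillation peak  | mean per-pulse maximum (ratio units)                   |
| T      | period            | mean spacing of consecutive complete pulses (min)      |
| A_D    | active duration   | mean per-pulse time above 50% of peak amplitude (min)  |
| P_D    | pulse duration    | mean pulse width at a near-baseline level (min)        |
| S_D    | silent duration   | T − A_D, exactly (min)                                 |
| P_F    | plateau fraction  | A_D / T, the secretory-phase share                     |

Edge regimes use fixed numeric codes so they can enter animal-level means:
a segment that plateaus (elevated, no oscillation) gets P_F = 1, T = 0,
A_D = P_D = 40 min; a silent (basal-flat) segment gets P_F = 0,
A_D = P_D = 0, T = 40 min. Oscillating segments with period < 2 min are
classed *fast*, 2–10 min *slow* — the boundary separating electrically
driven from metabolically driven oscillations.

### Detrending

Default trend removal is a two-stage robust filter: a centred moving
average over exactly one dominant period (estimated from the segment's
periodogram; fallback 10 min), followed by a centred moving median over
three periods (capped at half the segment). The order matters: averaging
over one full period cancels the oscillation itself deterministically
while preserving linear drift, and the median then rejects residual
transients. Applying a median directly to the raw wave is unstable near
duty 0.5, where the window's active fraction hovers at ½ and the median
flips between burst top and baseline. The series is reflect-padded so
windows stay full at segment edges; truncated windows would bias the trend
over the first/last half-window and leak into the percentile thresholds.
With `preserve_mean` (default) the segment mean is restored, keeping
average-signal statistics comparable across segments. A plain
least-squares linear detrend is available by flag.

### Pulse detection

1. Coarse levels: baseline = 10th percentile, robust peak = 90th
   percentile of the detrended segment.
2. Refinement: frames are split at the coarse midline; baseline is re-set
   to the median of the lower partition (the silent-phase mode — immune to
   residual detrending dips) and the peak level to the 90th percentile of
   the upper partition. This second pass is what keeps the 50% line
   correctly placed at extreme duty cycles, where a global percentile can
   land on a burst edge.
3. Detectability floor: no pulses are reported unless the amplitude
   exceeds `max(0.05 ratio units, 6·σ̂)`, where σ̂ is a robust noise sigma
   taken as the smaller of (a) the MAD of first differences (exact for
   slow signals, inflated by fast transitions) and (b) the median
   periodogram ordinate scaled by `n_bins/ln 2` (immune to periodic
   signals whose harmonics occupy sparse bins, inflated by isolated
   transients). A flat segment with pure noise shows a spurious
   percentile span of ≈2.6σ, so the 6σ margin cleanly separates noise
   from real oscillations; signals below ~6σ amplitude are reported as
   flat, a deliberate detectability limit.
4. Pulses are maximal runs above `baseline + 0.5·amplitude` containing at
   least one local maximum with prominence ≥ 0.25·amplitude
   (`scipy.signal.find_peaks`). A run with several prominent maxima is one
   pulse whose peak is the larger maximum (earlier on an exact tie). Runs
   clipped by a segment edge are kept but marked incomplete.
5. Crossing times are linearly interpolated between frames, giving
   sub-frame accuracy for durations.

### Parameter estimation choices

* **Period** is the mean spacing between the 50%-threshold onsets of
  consecutive complete pulses. For stationary trains this equals the mean
  peak-to-peak interval, but it is far more robust: on noisy flat-topped
  bursts the argmax peak position jitters uniformly over the active
  phase, while the onset edge is steep and interpolates to a fraction of
  a frame.
* **P_D** is the pulse width at `baseline + 0.10·amplitude`, capturing the
  Ca²⁺-extrusion tail below the half-maximum line; by construction
  P_D ≥ A_D.
* **Single-pulse segments**: a period needs two reference points, so T,
  S_D, and P_F are reported missing (and excluded from animal averages);
  A_D/P_D come from the one pulse. This also covers the strong
  single-pulse response of diabetic-model islets.
* **Plateau vs silent** (zero pulses): the segment is a plateau when its
  mean exceeds the islet's basal reference by half the amplitude floor,
  where the reference is the median of the same islet's 2G segment.
  Without a basal segment the classifier falls back to the segment's own
  baseline and cannot distinguish an elevated plateau from a basal flat —
  supply the 2G segment whenever plateau detection matters.
* Animal-level summaries are unweighted means over islets within animal,
  per parameter × segment; edge codes enter as numbers.

## Spectral summary

Each detrended segment gets a mean-removed rectangular-window
periodogram on the grid k/(N·Δt), k = 1…N/2, normalised so total power
equals the signal variance (Parseval; verified against
`scipy.signal.periodogram` with spectrum scaling). The summary keeps the
top two component frequencies and their powers; the second component must
lie at least 2 bins from the first so it is not a leakage sidelobe.
"Amplitude" is the periodogram power at the selected bin (not
square-rooted, not normalised to total power). Ties resolve to the lower
frequency. Welch averaging is available by flag but off by default —
segments are only 400 frames and resolution (0.025 min⁻¹ at 40 min)
matters more than variance. Plateau/silent segments still get a spectrum;
their leading power is simply near zero.

## Phenotype–proteome integration

Animal-level traits are standardized as z = (x − μ)/σ with μ, σ over all
animals (pooled sexes, sample SD with n−1). Correlations are Pearson on
pairwise-complete data, computed per parameter × protein pair; fewer than
three complete pairs, or a constant column, yields a missing value, never
a number. Because Pearson r is affine-invariant the Z-scoring does not
change r — it is kept because downstream consumers use the Z-scored
matrices directly. When the imaging and proteomic animals differ (separate
cohorts), the matrices align on strain-by-sex means instead of animal keys
(`align="group"`).

A protein is flagged as a candidate regulator when |r| ≥ 0.5 against at
least 3 of the six focus parameters (basal average Ca²⁺ and the 8G
active/pulse/silent plus 8G/QLA and 8G/QLA/GIP silent durations). The
boundary is inclusive (≥ 0.5) and no multiple-testing correction is
applied to this filter; it is a screening rule, not an inference.

The rank-based inverse normal transform (`normal_scores`) maps average
ranks (ties shared) to normal quantiles at r/(n+1), then rescales to the
original sample mean and variance, making it a fixed point on data already
at normal-quantile positions.

`term_effects` fits trait ~ strain + sex + strain:sex by OLS and reports,
per term, √(term mean square)/raw SD with a partial (type II) F-test
p-value, plus a composite *signal*: the joint F test of all
strain-involving terms against the sex-only model. With per-segment traits
there is no condition factor in the design, so strain + strain:sex are the
strain-involving terms.

## GWAS overlap

SNPs pass the significance filter iff −log10(p) > 8, strictly; the
boundary p = 10⁻⁸ is excluded. Assignment routes:

* **window**: SNP (1-based input position, converted to 0-based) within
  the gene body extended ±100 kbp — one contiguous interval, not two
  disjoint flanks; route `body` when inside the gene proper. Implemented
  with an interval tree; tests verify it against an all-pairs brute-force
  scan on random fixtures.
* **loop**: a chromatin loop (promoter-capture HiC, BEDPE) with one anchor
  overlapping the gene's promoter anchor and the other containing the SNP.
  Explicit promoter anchors are preferred; otherwise TSS ± 2 kbp derived
  from strand. Containment is exact and half-open.

A gene is nominated when ≥1 passing SNP reaches it by either route; SNPs
are deduplicated per gene, all routes recorded, and the best −log10(p)
carried. Chromatin-state evidence, if supplied, rides along as annotation
and never filters. Unknown trait labels warn rather than fail.

## The synthetic-data generator

The generator is phenomenological — it produces the statistical structure
the analysis assumes, not β-cell electrophysiology:

* **Archetypes** mirror the strain classes: *slow* (period 2–10 min,
  classical strains), *fast* (< 2 min, wild-derived), *plateau*, *silent*
  (diabetic/basal), and *mixed* (slow bursts plus an always-on fast
  component at 2:1 amplitude, the NOD-like pattern). Bursts are
  logistic-edged square waves (edge time constant 1% of the period) so the
  programmed duty equals the empirical above-midline fraction to within a
  frame per cycle.
* **Defaults** match the study conditions where stated: 0.1-min sampling,
  four 40-min segments, strain × sex × animal × islet nesting. Amplitude
  and noise are not reported anywhere for real strains, so defaults are a
  package choice: baseline 1.0, amplitude 0.5, noise SD 0.05 ratio units
  (10% of amplitude), zero drift.
* **Seeding** is counter-based: each islet × segment derives its seed from
  `SeedSequence([cohort_seed, islet_index, segment_index])`, so any
  sub-cohort regenerates identically in isolation and the whole cohort is
  a pure function of its spec.
* **Protein matrices**: a planted protein is the target parameter's
  Z-score (or the unit-variance composite of several parameters'
  Z-scores) scaled by t and mixed with N(0, σ) noise, with
  t = σρ/√(1−ρ²) so the expected Pearson r equals the target. Planting
  one protein at |r| = 0.9 against three parameters is only possible when
  those parameters are themselves correlated (with independent targets
  the maximum is 1/√3), so the planted-regulator fixture builds the three
  8G duration parameters on a shared latent factor with empirical pairwise
  r = 0.75 — constructed exactly via QR-orthonormalized noise — mirroring
  the near-identical correlation structure those durations show in real
  islet data. At these settings the expected number of null proteins
  (of 95, n = 16) co-hitting three correlated focus parameters is ≈2.
* **Genomic fixtures** place non-overlapping genes on a toy chromosome
  with SNPs at controlled offsets (in-body, inside the 100-kbp flank,
  outside it) and loops from promoters to distal anchors each holding a
  dedicated SNP.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: amplitude rundown and photobleaching beyond
linear drift, islet-to-islet waveform heterogeneity within an animal,
correlated (non-white) noise, the metabolic/electrical coupling that makes
real periods drift within a segment, missing frames, and real LD structure
or orthologue mapping on the genomics side.

## Problem sizes and reproducibility

The bundled checks run at desk scale by design: recovery grids of 25
(period, duty) combinations, 50 noise seeds per period, cohorts of tens of
islets, 100 proteins, 100 random genomic fixtures. The full pipeline is
deterministic — identical inputs give byte-identical output tables — and
every stochastic fixture takes an explicit seed. `scripts/acceptance.py
--seed N --out results/acceptance.json` re-runs every stage from scratch
and writes the measured quantities as JSON.

## Known limitations

* The 50%-of-amplitude convention references a robust (percentile-based)
  peak, not the absolute maximum; sharp overshoots on burst onset would
  raise an absolute-maximum threshold but barely move this one.
* Oscillations slower than ~3 cycles per segment leave too few complete
  pulses for stable period averages; periods near the 40-min segment
  length are unmeasurable by construction.
* Plateau detection needs the islet's own basal segment; cross-islet
  baselines are not used.
* `term_effects` assumes a crossed strain × sex design; heavily unbalanced
  designs fall back to missing values for inestimable terms rather than
  refitting a reduced model.
* The GWAS stage takes orthologue identity and SNP catalogues as given
  inputs; it performs no liftover, LD expansion, or orthologue inference.
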