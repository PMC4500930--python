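# Methods

`neuromea` analyzes extracellular multielectrode-array (MEA) recordings of
cultured cortical networks: per-unit spike trains are reduced to bursts, a
204-feature multiparametric description, group statistics, and a
pattern-recognition verdict on whether two experimental groups are
functionally distinguishable. A seeded generator of developing-network
activity provides the test substrate, and a small deterministic model
documents the timing of a pulsed electromagnetic exposure protocol. This
note records the models, the conventions that verbal definitions in the
field leave open, and what the tests do and do not establish.

## Units, windows, binning

All times are milliseconds (float64) from the start of the recording
window; every window and bin is half-open `[start, end)`, so bin membership
is never ambiguous. Analysis operates on the *stable activity phase*: the
final 30 min of a recording (`AnalysisWindowPolicy`), re-referenced to
start at 0. Stability itself is not re-validated — the tail is taken by
definition. Per-bin statistics use 60 s bins; a trailing partial bin is
dropped everywhere, because rate estimates from partial bins are biased
(the default 30 min / 60 s layout divides evenly anyway). Units with zero
spikes stay in the recording and enter network denominators.

## Burst detection (ISI method)

A two-threshold ("max-interval") reading of the interspike-interval
criteria, with defaults 40 ms (maximum ISI to start), 200 ms (minimum ISI
to end), 100 ms (minimum interval between bursts), 10 ms (minimum burst
duration), 2 (minimum spikes):

1. **Seed/extend** — a burst opens at a spike pair with ISI ≤ 40 ms and
   appends spikes while the ISI stays < 200 ms; an ISI ≥ 200 ms closes it.
   The two thresholds act as hysteresis: a pair at 100 ms cannot start a
   burst but does continue one.
2. **Merge** — consecutive bursts separated by < 100 ms merge,
   transitively.
3. **Filter** — only then are the spike-count and duration floors applied.
   Merging first prevents a long burst split by one sparse gap from being
   discarded as two sub-threshold fragments.

Boundary semantics are fixed so an independent reimplementation can match
bit-exactly: `≤` for maxima, `≥` for minima, strict `<` for the merge gap;
burst start/end are the first/last member spikes, no padding. The order of
merge vs. filter and the boundary inclusivities are this package's
documented choices, not an inference about any upstream software. The test
suite holds the detector to exact agreement with an exhaustive
segment-split + merge-closure oracle on 1000 randomized trains seeded with
near-threshold ISIs.

## The 204-feature registry

The registry (`neuromea-204-v1`, manifest in `docs/feature_registry.tsv`)
is an explicit, versioned composition — the field's commercial tools ship
similar but undocumented lists, so the exact membership here is a package
choice and analyses are comparable only within one registry version.

* **44 binnable primaries** — statistics of one unit in one time span
  (rates, ISI-distribution stats, burst timing, and statistics over
  per-burst scalars). Each is emitted 4 ways: plain value (stable phase),
  `_sd` (SD across 60 s bins of the per-bin network mean → *oscillation*),
  `_cvtime` (mean over units of each unit's CV across bins → *oscillation*),
  `_cvnet` (CV of per-unit values across the network → *synchronization*,
  since spatial spread is an inverse synchrony proxy).
* **8 burst-profile primaries** (below) × {plain, `_cvnet`}.
* **12 network-level features**: `syn_all`, `syn_share`, `event_rate`,
  `hamming_factor`, population-burst shape/timing stats, and the active
  unit fraction.

Conventions: sample SDs use n−1 throughout; a CV is NaN with fewer than
two values or zero mean; unit-level primaries average over units while
per-burst statistics pool over all bursts of the network ("mean length of
bursts" is a mean over bursts, "spike rate averaged over all spike trains"
a mean over units); an ISI belongs to the bin of its leading spike, a
burst to the bin of its first spike; undefined values are NaN, never 0,
and imputation is left to the classification stage where it is logged.

**Spike contrast.** Verbal definitions describe presence/absence of spikes
in neighboring segments. Implemented as: split the span into consecutive
500 ms segments; for adjacent pairs with `n_i + n_{i+1} > 0`, contrast is
`|n_i − n_{i+1}| / (n_i + n_{i+1})`; average over pairs, then units. The
absolute scale is implementation-defined; only within-pipeline comparisons
are meaningful.

**Burst profile (amplitude / area / plateau).** Each burst's spikes are
aligned at burst onset, binned at 1 ms, averaged over the unit's bursts
and smoothed with a 10 ms Gaussian kernel into a rate profile (spikes/s);
unit profiles average into the network profile. Amplitude is the profile
peak, area its integral (≈ mean spikes per burst), plateau the contiguous
width ≥ 90 % of peak; rise time, half-width, support width, skew, and
peak-to-mean ratio complete the family. Spikes more than 3 s after onset
are ignored (profiles of rare giant bursts would otherwise dominate the
grid). The histogram + Gaussian-filter route is numerically equivalent to
a direct Gaussian kernel sum to ~1 %, which the tests check against a
direct evaluation.

**Population bursts and events.** `B(t)` counts units with a burst
overlapping the sliding window `[t, t + 300 ms)`; a population burst is a
maximal region with `B(t)/N ≥ 0.5` (overlapping regions merge). Its center
is the spike-count-weighted mean of member-burst midpoints; `syn_all` is
the mean absolute distance of member midpoints from the center (reported
raw, in ms — larger means looser synchrony), `syn_share` the mean
participating fraction, and the event rate counts the same detections at
the 50 % / 300 ms setting per second. One mechanism serves all three on
purpose.

**Hamming factor.** Units become binary vectors over 10 s bins (1 if any
burst overlaps the bin); the factor is the mean over unit pairs of the
fraction of agreeing bins (1 − normalized Hamming distance). A pairwise
mean is used rather than distance to a template train; it is 1 exactly
when all vectors are identical.

## Classification

Feature vectors are standardized per fold (centering/scaling by the
training subset, zero-variance features dropped identically across folds,
NaNs imputed by training means with the count logged — the held-out sample
never touches the statistics). The classifier is a perceptron with no
hidden units: 204 inputs map straight onto one logistic output node per
group, one-hot targets, summed cross-entropy, arg-max prediction. Hidden
layers are deliberately absent (high-variance, small-n data) and are out
of scope.

Training uses iRprop−: per-weight step sizes multiply by 1.2 while the
gradient sign is stable and by 0.5 on a sign change (step sizes in
[1e−6, 50], initial 0.1); on a sign change the gradient is zeroed for that
step, and there is no weight backtracking. Weights initialize uniformly in
[−0.1, 0.1] from the seeded generator; training stops when the loss change
drops below 1e−6 or after 1000 epochs. Everything is bit-reproducible
given the seed (per-fold seeds derive deterministically from the base
seed).

Cross-validation is leave-one-out by default (the natural choice for
cohorts of 8–12 networks per group), k-fold configurable. Recognition
counts accumulate into a confusion matrix; the χ² statistic compares
observed counts to chance expectation *within each true-group row*
(uniform over predicted classes, i.e. 50 % per cell for two groups;
group-size-proportional expectation available as an option), with
`rows × (cols − 1)` degrees of freedom and an upper-tail p. Two-group
comparisons default to a 2-output net; a 4-output net over four groups is
supported but not the default. Caveat established by simulation: under
label permutation, leave-one-out accuracy of this overfitting-prone
classifier sits slightly *below* 50 % on average (the held-out sample's
class is always the training minority), so pooled null accuracy is checked
against a binomial band around chance rather than asserted at exactly 50 %.

## Group statistics and morphometry

Comparisons report mean ± SEM and n per group, the treatment mean as
percent of the concurrent control mean (scale-invariant; undefined and
flagged when the control mean is 0), and an unpaired t-test —
pooled-variance Student's form by default since that is the test named in
this literature, Welch behind a flag. Stars follow *p ≤ 0.05,
**p ≤ 0.01, ***p ≤ 0.001. No multiple-testing correction is applied by
default, mirroring per-parameter testing practice; across 204 features
this does **not** control family-wise error, and a Benjamini–Hochberg
helper is provided. Normality is not re-tested per comparison; a
Shapiro–Wilk report is optional output only.

Morphometry ratios from per-image counts: % neurons = neurons/cells,
neurites per neuron, synapses per neurite, % GABAergic of neurons.
Invariants (neurons ≤ cells, GABAergic ≤ neurons, counts ≥ 0) are enforced
at construction; zero denominators yield NaN, except % neurons which is 0
when cells exist but neurons do not.

## Synthetic networks

The generator is a stated world, not a fit to data: population events are
homogeneous Poisson (default 0.1 Hz network-wide); each of 24 units joins
an event with probability 0.8 and bursts at the event time plus N(0, 50 ms)
jitter; burst spike counts are 2 + Poisson(10) (floor 2), intra-burst ISIs
gamma(shape 2, mean 15 ms); independent bursts (0.02 Hz/unit) and tonic
background spikes (0.3 Hz/unit) add non-population activity; recordings
last 30 min. These defaults put per-unit burst rates at 0.1 Hz (6/min),
burst durations around 165 ms and unit rates near 1.5 Hz — the scales
reported for such cultures at two weeks in vitro. `DIV28_MATURATION`
(population events ×2, spikes per burst ×1.5, background ×3) approximates
four weeks: spiking ≈ ×3, bursting ≈ ×2. Treatment effects are
multiplicative factors on named fields; `SPIKE_DRIVERS` collects the three
fields that directly scale the overall spike rate. Exact spike-time
collisions are dropped (keeping trains strictly ascending) rather than
jittered. Per-network streams spawn from one base `SeedSequence`, so
cohorts are reproducible and order-independent.

What the generator does *not* emulate: electrode noise and unit-separation
errors, slow developmental drift within a recording, refractory structure,
bursts with non-stationary intra-burst rate, or any transduction mechanism
of the exposure itself. A green parameter-recovery test therefore
establishes that the pipeline recovers planted multiplicative effects at
realistic scales and sample sizes — not that it would detect any
particular real-world effect.

## Stimulus timing model

The exposure is a 150 MHz carrier pulse-modulated at 10 Hz then 16 Hz
(30 min each, 50 % duty): cycles of 100 ms (50 ms on / 50 ms off) and
62.5 ms (31.25 ms on). Only the envelope timing is computed; the carrier
is metadata (sampling a 150 MHz waveform would add nothing). A final cycle
cut short by the session end is emitted truncated rather than dropped, so
total on-time equals duty × duration up to one truncation.

## Numerical and degenerate-input choices

* Logits are clipped at ±30 before the logistic to keep cross-entropy
  finite; a NaN loss aborts training with diagnostics rather than
  propagating.
* `%.17g` on write and round-trip float parsing on read make text
  recording round-trips exact.
* Networks with < 2 units have no pairwise synchrony; units with < 2
  bursts contribute nothing to burst-period means (contributing counts are
  implicit in the NaN bookkeeping); fewer than 2 complete bins make all
  oscillation features NaN.
* The pipeline manifest contains versions, seed, and a config hash but no
  timestamps, so identical configs yield byte-identical bundles.

## Known limitations

The registry composition beyond the twelve canonical parameters is a
package convention; absolute values of `spike_contrast` and the profile
family depend on segment length and kernel bandwidth and are only
comparable within a configuration. The χ² test treats cross-validation
folds as independent trials, which leave-one-out violates mildly; p-values
near the threshold deserve skepticism (the permutation machinery in the
test suite shows how to calibrate empirically). The pooled t-test assumes
equal variances; use the Welch flag when group spreads differ visibly.
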