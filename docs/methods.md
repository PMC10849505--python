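# Methods

## Protocol model

A session is a deterministic timetable of events on a continuous frame
clock. Sequences are four-letter strings over {A, B, C, D}; each element
lasts `element_duration_ms` (default 250 ms) and every presentation closes
with `gray_duration_ms` of gray screen (default 800 ms), so a presentation
spans 1800 ms. Baseline and test sessions interleave blocks of all three
sequences (ABCD×100, ABBD×100, ACBD×100, repeated five times → 500
presentations per sequence and 1500 intersequence gray periods); training
sessions show only the standard sequence. Ten-second interblock rests and
one-minute lead-in/lead-out gray periods are explicit events of kind
`interblock`, so event tables tile the session with no gaps and frame
indices never need re-anchoring.

Frames are assigned by **start time**: frame *f* covers
`[f·Δ, (f+1)·Δ)` with `Δ = 1000/frame_rate` ms, and a frame belongs to an
event iff its start lies in `[onset, offset)`. All bin arithmetic uses
exact rational comparisons (`Fraction`), so the 250 ms / 30 Hz mismatch is
represented faithfully: element windows alternate between 8 and 7 frames
(onsets at 0, 7.5, 15, 22.5, 30 frames within a presentation) and every
800 ms gray period is exactly 24 frames. The ~67 ms retina→L2/3 latency is
represented everywhere as a 2-frame offset.

Two window conventions coexist and both are implemented, selected per
stage: *shift* (the offset moves the window without shrinking it — used
for selectivity) and *truncate* (the first two frames are dropped — used
for PE ratios, correlations and decoder features). Trial tensors use the
minimum window length across their events (7 frames pre-offset for
elements) so trials align without padding bias.

## Synthetic-activity model

The generator produces nonnegative "deconvolved amplitude" traces with
planted, recoverable structure:

* **Cell classes** per mouse are multinomial around configured fractions.
  Defaults mirror the per-day selectivity census of the study population
  (baseline: A 6.1 %, B 10.0 %, C 6.1 %, D 9.2 %, gray 9.4 %; after
  training: 2.7 / 7.1 / 2.7 / 4.3 / 10.3 %), with the gray fraction split
  60/40 between onset-responsive and ramping cells and the remainder
  background. Cell counts default to 8 mice × 171 cells ≈ the ~1400-cell
  sessions the protocol was designed for.
* **Element cells** emit a Gaussian bump (amplitude lognormal around 5
  a.u., σ = 40 ms) at latency τ after each *visual transition* to their
  letter, truncated to the driving event's frames. Baseline latencies are
  drawn with linearly increasing density over (67, 250] ms (slow build-up
  toward element offset); post-training latencies come from a bimodal
  mixture concentrated near onset (~87 ms) and near element offset
  (~235 ms) — the learned stimulus-locked pattern.
* **Omission response**: when a cell's letter repeats with no transition
  (the held B of ABBD), the cell emits a sustained response plus a small
  bump at its usual latency — the time the next transition was expected.
  The planted `omission_gain` ρ (defaults 1.10 baseline, 1.44 after
  training) is defined on the scale the PE statistic measures: the
  response is scaled so the *expected measured* activity (signal +
  baseline + mean truncated noise) in the offset analysis window is
  exactly ρ times that of the preceding standard window. This makes the
  PE stage's group mean an unbiased estimate of ρ, which is what the
  parameter-recovery tests exploit.
* **Context gain**: responses to a preferred element outside its trained
  sequence position (C in ACBD) are multiplied by `substitution_gain`
  (0.88 / 0.84) — a plain multiplier, so its recovered PE is approximate
  within ~0.02 at default amplitudes.
* **Drift** is a per-cell multiplicative gain `exp(η·W_t)` with `W` a
  standard random walk over the session's presentation index
  (η = 0.01/presentation by default, chosen so correlations decline
  visibly across a 1500-presentation session while block decoding remains
  well above chance). Because the gain is per-cell, drift survives
  per-trial vector normalisation — matching the normalised-vector control
  in the block decoder. A `latency_swap_fraction` optionally lets a
  fraction of cells switch preferred latency mid-session (a rotation
  component); it defaults to 0.
* **Noise** is additive per-frame Gaussian truncated at zero
  (σ = 0.5 a.u.): deconvolution emits spurious nonnegative events, never
  negative ones. A constant baseline rate (0.1 a.u./frame) keeps silent
  periods weakly active.

What the generator does **not** emulate: calcium indicator kinetics and
deconvolution artifacts, correlated (shared-arousal) noise across cells,
orientation tuning beyond the four letters, inhibitory dynamics, and
cross-day tracking of single cells (populations are redrawn per day, as in
the experiment). Passing tests therefore certify the *analysis machinery* —
window accounting, statistics, decoders, resampling — under a structurally
faithful model, not the biological effect sizes themselves, which are
planted.

## Analysis conventions and numerical choices

* **Selectivity**: the "2 SD above the other stimuli" rule is implemented
  in both readings — SD across the other-stimulus *means* (default) and
  per-stimulus *trial* SDs (`sd_mode="across_trials"`). The mean-SD
  reading compares a value against the spread of only four other means and
  therefore admits ~8 % false positives per stimulus on non-selective
  cells; the pipeline uses the trial-SD reading when building
  PE-responsive sets (the deterministic replacement for the manual
  curation of mixed-selectivity cells), and ties always resolve to
  "none". Responsive sets are recomputed per day.
* **PE ratios**: cells whose standard-window mean falls below
  `1e-6 ×` the session mean amplitude are excluded and counted, never
  silently dropped. The held-element deviant window applies the same
  2-frame offset as visible transitions (symmetry).
* **Dedicated PE-cell screen**: a cell counts as omission-exclusive only
  if its deviant-window mean clears `session mean + 2 SD` *and* exceeds
  every other stimulus-window mean threefold — ordinary responsive cells
  (deviant/standard ≈ the PE ratio, near 1) can never reach that bar.
* **Hierarchical bootstrap**: mice resampled with replacement (same
  count), cells pooled and resampled to pool size; 1000 iterations;
  percentile 2.5/97.5 intervals. Works identically for scalar ratios and
  per-frame traces.
* **PCA**: traces are centred per cell but not variance-scaled —
  deconvolved amplitudes are in meaningful common units.
* **Drift curves**: distance bins default to 50 trials; callers may pass
  true session positions so interleaved-block designs use real distances.
* **Decoders**: `StandardScaler` fit on the training fold only, then
  `LinearSVC(C=1)` one-vs-rest; unstated hyperparameters pinned to library
  defaults. Per-class half/half splits (stimulus), 50-per-block training
  splits (block), and splits **by gray period, never by frame** (time) —
  splitting by frame would leak period identity into both folds, and a
  dedicated test confirms period-level splitting decodes structureless
  data at chance. Label-shuffled runs permute labels each iteration.
* **Time fields**: even/odd groups are the 2nd/4th/… and 1st/3rd/…
  trials by within-condition order; peak ties break to the earliest frame;
  all-zero half-traces are inconsistent by convention. Under pure noise
  the consistency rate has the exact value
  `#{(i,j): |i−j| ≤ 4}/T²` (196/576 ≈ 0.34 for 24-frame gray windows),
  which the implementation reproduces.
* Degenerate inputs (empty selections, single-class designs, empty trial
  subsets, windows emptied by the offset) raise `ValueError` with the
  offending quantity named.

## Reproducibility and problem sizes

All randomness flows from `numpy` `SeedSequence` children spawned in a
fixed order, so a config plus master seed reproduces every summary number
exactly. The test suite and the acceptance script run reduced problem
sizes that keep the full protocol structure — three interleaved sequences,
five blocks, interblock rests — while shrinking block sizes (typically
6–50 presentations per block) and populations (tens of cells): the checked
quantities are either structural counts at full scale (which use the full
500-presentation protocol with a small population), analytic chance levels
(independent of scale), or planted-parameter recoveries whose tolerances
the reduced scales already satisfy. The acceptance script uses 250
trials per class for the stimulus-decoder null and 375 gray periods for
the time-decoder null, with 100 split iterations each.

## Known limitations

* Planted effect sizes are point parameters, not biological variability:
  per-cell PE ratios cluster tightly around ρ, so day-comparison KS tests
  are better powered than on real data at the same n.
* The substitution gain is recovered only approximately (see above).
* The trial-SD selectivity reading is near-perfect on synthetic data
  because planted classes are disjoint; real mixed-selectivity cells would
  land in "none" rather than being curated.
* Frame rates that are not exactly representable as rationals are rounded
  to the nearest rational with denominator ≤ 10⁶ before bin arithmetic.
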