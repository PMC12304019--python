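# Methods

## Pattern encodings

Both entropy measures reduce each `m`-tuple of the signal (stride `τ`,
`k = N − (m−1)τ` tuples) to an integer symbol.

**Ordinal patterns (Lehmer code).** The rank ordering of a tie-free
tuple is identified by its right inversion counts
`r_i = #{j > i : x_i > x_j}`; since `r_i ∈ {0, …, m−i}`, the sequence
`(r_1)(r_2)…(r_m)` is an `m`-digit factoradic numeral and
`n = Σ_{i<m} (m−i)!·r_i` is a bijection onto `{0, …, m!−1}`. Codes are
0-based. The integer capacity caps the order at `m = 20` (`20!` still
fits 64 bits; `21!` does not).

**Difference patterns (binary code).** The sign string of consecutive
differences, bit `i` set iff `x_i > x_{i+1}`, read most-significant
first, preserves the lexicographic order of sign strings. Internally
codes are 0-based like the ordinal ones; the public scalar
`difference_code` and `PatternSequence.external_codes` add 1, so the
all-ascending pattern prints as 1 and the all-descending one as
`2^(m−1)` (8 at `m = 4`). Orders up to 64 fit the 63 available sign
bits.

**Ties.** All comparisons are strict `>`: a tie `x_i = x_j` (`i < j`)
behaves as ascending. Under `tie_policy="discard_window"` a window is
invalidated when *any* pair inside *any* of its `m`-tuples is tied (not
only consecutive samples). This any-pair reading makes the set of
retained windows depend on `m` — longer tuples are more likely to
contain a tie — and keeps PeEn and EoD defined on identical window
sets for a given `m`. Uniform white noise at double precision is
tie-free with probability one; `synthetic.quantize` injects ties
deliberately for testing.

## Plain vs incremental encoders, and why counts not clocks

Each kind has a plain encoder (every tuple independently: `m(m−1)/2`
or `m−1` comparisons per tuple) and an incremental one exploiting the
`m−1`-value overlap of adjacent tuples (`τ = 1` only; for `τ > 1` the
plain encoders are used):

| encoder               | comparisons                 | complexity |
|-----------------------|-----------------------------|------------|
| ordinal plain         | `k·m(m−1)/2`                | `O(Nm²)`   |
| ordinal overlap       | `m(m−1)/2 + (k−1)(m−1)`     | `O(Nm)`    |
| difference plain      | `k(m−1)`                    | `O(Nm)`    |
| difference iterative  | `(m−1) + (k−1)`             | `O(N)`     |

The overlap encoder is implemented through the lag comparisons
`c_d[p] = [x_p > x_{p+d}]`, `d = 1..m−1`, from which every tuple's
inversion counts are prefix sums; this evaluates exactly the
overlap-recurrence comparison set (each comparison shared by all
tuples containing the pair) while remaining vectorizable. Every
`PatternSequence` records its exact comparison count, so the
complexity claims are asserted as integer identities instead of
hardware-dependent wall-clock measurements; the `benchmark` CLI
reports wall time only as an informational column. A lookup-table
encoder is deliberately not provided (its table grows too large in
memory beyond `m ≈ 9`).

## Entropies, normalization, feasibility

`PeEn = −Σ p(π) log2 p(π)` over ordinal patterns and
`EoD = −Σ p(δ) log2 p(δ)` over sign patterns, with `0·log 0 := 0` and
probabilities `count/k`. The logarithm base defaults to 2 (bits) and is
configurable. Normalization divides by the maximum, `log2(m!)` and
`m−1`, mapping both to `[0, 1]` for cross-order comparison.

Reliable estimation demands `k ≥` alphabet size, i.e. `N > m! + m`
(ordinal) and `N > 2^(m−1) + m` (difference). `check_feasibility`
returns the largest admissible order (6 and 12 for `N = 2500`) and
*warns* rather than fails on requests beyond it: undersampled orders
remain computable, and the resulting PeEn depression is informative —
on a 1000-sample window at `m = 7` at most 994 of the 5040 ordinal
patterns can occur, so raw PeEn is bounded by `log2(994)` no matter
the signal. Windowing is non-overlapping, aligned to `t = 0` and to
the label-epoch grid; a trailing partial window is dropped.

### EoD of white noise is not maximal

For i.i.d. (exchangeable) noise every *ordinal* pattern is equally
likely, so normalized PeEn converges to 1 at every feasible order. The
same is **not** true of sign patterns: the probability of a sign
string equals the fraction of permutations of `m` elements with that
descent set, which is non-uniform for `m ≥ 3` (at `m = 3`:
`[+,+]` and `[−,−]` occur with probability 1/6 each, `[+,−]` and
`[−,+]` with 2/6). The exact normalized limits, by enumeration, are
0.959 at `m = 3` and 0.923 at `m = 7`; the test suite pins the
implementation to this combinatorial oracle. Consequently normalized
EoD of a random signal sits measurably below 1 — which is arguably a
feature (distance-from-randomness is resolvable) but must be kept in
mind when comparing absolute PeEn and EoD levels.

## Signal ingestion and preprocessing

EDF reading uses mne with a channel-preference list (frontal
`Fp2-F4`/`F2-F4` first, centrally located channels as fallback);
amplitudes are returned in µV. A minimal single-channel 16-bit EDF
*writer* (1 s records, integer sampling rate) exists for fixture
generation; round-trips are exact within the format's 16-bit
quantization. Stage annotations use a one-token-per-epoch text dialect
with an `epoch_seconds=` header; unknown tokens (e.g. `MT`) are
reported and their epochs excluded. R&K → AASM merging maps S3 and S4
to NREMS3 (idempotent, count-conserving).

The named preprocessing is a 30 Hz lowpass at 200 Hz (sleep) or
resampling to 100 Hz plus 30 Hz lowpass (anesthesia). Realizations are
deliberately conventional, since entropy conclusions should not hinge
on filter sharpness: a 4th-order Butterworth applied forward-backward
(zero phase, so window/label alignment is exact) and polyphase
resampling with built-in anti-aliasing.

## Classification and agreement

A single entropy feature is scored per state pair with LDA under
seeded, stratified 10-fold cross-validation. The per-fold decision
score is oriented along the ascending feature axis (sign of the
discriminant coefficient); for a one-dimensional feature the fold AUC
then equals the Mann–Whitney AUC of the raw feature, label swap maps
`auc → 1 − auc`, and AUC is invariant under strictly monotone feature
transforms — all asserted in tests. Point AUC is the mean of fold
AUCs; the 95% CI is the normal approximation
`mean ± 1.96·sd(folds)/√folds`, clipped to `[0, 1]`, and an effect is
claimed iff 0.5 lies outside it. In null simulations this CI covers
0.5 in ≈91% of replicates — slightly anticonservative, as expected of
a 10-sample normal approximation, but adequate for the screening use
here. Fold assignment is deterministic per seed. Optional seeded
down-sampling of the majority class is available for heavily
imbalanced cohorts (off by default). Classes smaller than the fold
count reduce the fold count with a warning.

PeEn–EoD agreement is the Pearson correlation of per-window normalized
values over jointly valid windows, reported per recording with a
cohort median. Correlations are meaningful *within* a recording (or
state): pooling distinct states inflates r through between-state
separation regardless of order.

## Synthetic data

`white_noise` draws i.i.d. uniform(0, 1) samples from a seeded
Mersenne-Twister generator; the benchmark design is a 14.4×10⁶-sample
vector with seeds 1–20 (no test depends on a particular RNG stream,
only on distributional properties).

`synthetic_vigilance_recording` emulates the single robust feature of
vigilance-state EEG that entropy measures exploit: spectral slowing.
Each state is 1/f^α Gaussian noise lowpassed (4th-order-like spectral
rolloff) at a state corner frequency, scaled to a state amplitude,
plus a 0.5 µV white measurement-noise floor. Defaults: 2 states × 100
epochs × 30 s at 200 Hz — wake-like: 30 Hz corner, α = 1, 15 µV rms;
deep-like (NREMS3): 4 Hz corner, α = 2, 75 µV rms. The amplitude
contrast matters, not just the corner: slow-wave sleep EEG is
high-amplitude, and it is that amplitude that keeps its smooth
trajectories above the amplifier-noise floor and hence low-entropy; at
equal amplitudes the noise floor would dominate the slow state's
sample-to-sample differences and *raise* its pattern entropy. Epoch
corners are jittered by 2^U(−0.5, 0.5) for within-state variability,
epochs are shuffled per seed, and the whole recording is bit-exact per
seed. The generator makes no attempt at real EEG morphology — no
spindles, K-complexes, eye movements, artifacts or burst-suppression
alternation — so passing pipeline tests demonstrate that the method
chain is sound on spectrally plausible signals, not that clinical AUC
levels are reproduced; real-data AUCs require real recordings.

Problem sizes used by the test and acceptance runs (chosen to keep the
full suite in the tens of seconds while leaving every asymptotic or
distributional effect visible): 10⁶-sample noise for the entropy
limits, 200 × 300-sample windows for encoder equivalence, 200-epoch
synthetic cohorts for classification, 15 × 120 s single-state
recordings for the correlation-vs-order comparison.

## Known limitations

- The incremental encoders require `τ = 1`; other delays fall back to
  the plain algorithms.
- The CAP database's native annotation export is not parsed in full
  generality; the canonical input is the documented per-epoch text
  dialect (a converter is a one-liner per export flavour).
- The EDF writer is a fixture tool: single channel, integer sampling
  rate, whole-second duration.
- `PatternDistribution.probabilities` densifies only below ~4×10⁶
  symbols; beyond that (ordinal `m ≥ 10`) use the sparse
  `nonzero_codes`/`nonzero_probs` representation.
- Multiclass classification, patient-grouped cross-validation and
  weighted/amplitude-aware pattern variants are out of scope;
  `pairwise_state_aucs` evaluates state pairs with pooled-window CV.
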