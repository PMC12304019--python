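# eegentropy

Permutation entropy (PeEn) and entropy of difference (EoD) for
windowed single-channel EEG, with the pattern-encoding algorithms,
sample-size feasibility rules, tie handling and LDA/cross-validated-AUC
evaluation used to discriminate vigilance states (sleep stages,
anesthesia levels).

## The measures

A signal `(x_t), t = 1..N` is split, for an order `m` and delay `τ`,
into `k = N − (m−1)τ` overlapping tuples of length `m`. Each tuple is
reduced to a symbol:

* **ordinal pattern** — the rank ordering of its amplitudes, one of
  `m!` possibilities, encoded as a Lehmer code: the right inversion
  counts `r_i = #{j > i : x_i > x_j}` read as a factoradic numeral
  `n = Σ_i (m−i)!·r_i`;
* **difference (sign) pattern** — the signs of its consecutive
  differences, one of `2^(m−1)` possibilities, read as a binary numeral
  `n = 1 + Σ_i 2^(m−i−1)·[x_i > x_{i+1}]` (so `[+,+,+] → 1`,
  `[−,−,−] → 8` at `m = 4`).

The entropies are the Shannon entropies of the empirical pattern
distributions,

    PeEn = −Σ_i p(π_i) log2 p(π_i)        ∈ [0, log2(m!)]
    EoD  = −Σ_l p(δ_l) log2 p(δ_l)        ∈ [0, m−1]

normalized by their maxima to `[0, 1]`. Reliable estimation needs at
least as many tuples as possible patterns, giving the feasibility rules
`N > m! + m` (PeEn) and `N > 2^(m−1) + m` (EoD): a 10 s window at
250 Hz admits at most `m = 6` for PeEn but `m = 12` for EoD — the
practical advantage of difference patterns, along with cheaper
encoding. Each encoder exists in a plain and an incremental variant
(`O(Nm²)` vs `O(Nm)` for ordinal, `O(Nm)` vs `O(N)` for difference),
and every `PatternSequence` carries an exact comparison count so the
complexity claims are testable without wall clocks.

Ties are compared strictly (`x_i = x_j` behaves as ascending); windows
containing any tied tuple can instead be discarded wholesale
(`tie_policy="discard_window"`).

## Worked example

```python
import numpy as np
import eegentropy as ee
from eegentropy.evaluation import lda_cv_auc

# single pattern codes
ee.difference_code([1, 2, 4, 1])            # 2   (signs [+, +, -])
ee.lehmer_code([2, 4, 1])                   # 3   (inversions (1, 1, 0))
ee.check_feasibility(2500, "ordinal").max_m # 6

# a synthetic two-state recording: 100 wake-like + 100 deep-sleep-like
# 30 s epochs at 200 Hz, scored with both measures and classified
sig, stages = ee.synthetic_vigilance_recording(ee.SyntheticStudySpec(seed=42))
labels = np.array(stages.labels)
for m in (3, 7):
    peen = ee.windowed_entropy(sig, 30.0, ee.PatternConfig(m), "peen")
    eod = ee.windowed_entropy(sig, 30.0, ee.PatternConfig(m, kind="difference"), "eod")
    for name, series in (("PeEn", peen), ("EoD ", eod)):
        res = lda_cv_auc(series.normalized, labels, seed=0)
        print(f"m={m} {name} wake={series.normalized[labels=='WAKE'].mean():.3f} "
              f"nrems3={series.normalized[labels=='NREMS3'].mean():.3f} "
              f"AUC={res.auc:.3f} ({res.ci_low:.3f} {res.ci_high:.3f})")
```

prints

```
m=3 PeEn wake=0.821 nrems3=0.715 AUC=1.000 (1.000 1.000)
m=3 EoD  wake=0.924 nrems3=0.836 AUC=1.000 (1.000 1.000)
m=7 PeEn wake=0.626 nrems3=0.359 AUC=1.000 (1.000 1.000)
m=7 EoD  wake=0.862 nrems3=0.594 AUC=1.000 (1.000 1.000)
```

Both measures order the states the same way (wake-like activity is
higher-entropy than slow-wave activity), separate them perfectly on
this clean synthetic cohort, and the 95% CIs exclude 0.5. Note how the
PeEn level drops much more than EoD from `m = 3` to `m = 7`: at high
orders many of the `m!` ordinal patterns cannot occur in a 6000-sample
window, depressing PeEn, while the `2^(m−1)` difference patterns remain
well sampled.

## Command line

```sh
eegentropy simulate --subjects 3 --out-dir fixtures     # synthetic EDF study
eegentropy compute fixtures/*.edf --orders 3,4,5,6,7    # feature tables
eegentropy evaluate eegentropy-out/features.csv         # AUC + correlations
eegentropy benchmark --orders 3,5,7,9 --length 1000000  # comparison counts
eegentropy feasibility 2500                             # max m per rule
```

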