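"""Shannon entropies of pattern distributions: PeEn and EoD.

Permutation entropy (PeEn) is the Shannon entropy of the distribution
of ordinal patterns of order ``m`` extracted from a signal,

    PeEn = - sum_i p(pi_i) log2 p(pi_i),      range [0, log2(m!)],

and the entropy of difference (EoD) is the analogue over sign patterns
of consecutive differences,

    EoD  = - sum_l p(delta_l) log2 p(delta_l), range [0, m - 1].

Both are normalized to [0, 1] by their maxima so values are comparable
across orders.  Reliable estimation requires the tuple count to be at
least the alphabet size, which yields the feasibility rules
``N > m! + m`` (ordinal) and ``N > 2^(m-1) + m`` (difference); a 10 s
window at 250 Hz therefore admits at most m = 6 for PeEn but m = 12 for
EoD.  Violations warn rather than fail: running m = 7 on 1000-sample
windows is meaningful precisely because the resulting PeEn depression
is informative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import (
    CapacityError,
    MAX_DIFFERENCE_ORDER,
    MAX_ORDINAL_ORDER,
    PatternConfig,
    PatternSequence,
    encode,
    tuple_count,
    window_has_tie,
)

__all__ = [
    "PatternDistribution",
    "EntropySeries",
    "FeasibilityResult",
    "pattern_alphabet_size",
    "pattern_distribution",
    "shannon_entropy",
    "permutation_entropy",
    "entropy_of_difference",
    "check_feasibility",
    "windowed_entropy",
]

Measure = Literal["peen", "eod"]

#: Dense probability vectors are materialised only below this alphabet size.
_DENSE_ALPHABET_LIMIT = 1 << 22


class FeasibilityWarning(UserWarning):
    """Requested order exceeds the sample-size feasibility rule."""


@dataclass
class PatternDistribution:
    """Empirical distribution of pattern codes.

    Stores the observed (nonzero-probability) codes sparsely; the dense
    ``probabilities`` vector over the full alphabet is materialised on
    demand (ordinal alphabets grow as m! and quickly dwarf memory).
    """

    nonzero_codes: np.ndarray
    nonzero_probs: np.ndarray
    alphabet_size: int
    k: int

    def __post_init__(self) -> None:
        total = float(self.nonzero_probs.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        if np.any(self.nonzero_probs < 0):
            raise ValueError("negative probability")

    @property
    def support_count(self) -> int:
        """Number of distinct patterns actually observed."""
        return int(self.nonzero_codes.size)

    @property
    def probabilities(self) -> np.ndarray:
        """Dense probability vector over the whole alphabet."""
        if self.alphabet_size > _DENSE_ALPHABET_LIMIT:
            raise MemoryError(
                f"alphabet of size {self.alphabet_size} too large to densify; "
                "use nonzero_codes/nonzero_probs"
            )
        dense = np.zeros(self.alphabet_size, dtype=float)
        dense[self.nonzero_codes] = self.nonzero_probs
        return dense


@dataclass
class EntropySeries:
    """Per-window entropy values of one recording and one configuration.

    ``raw`` is in bits, ``normalized`` in [0, 1]; windows invalidated by
    the tie policy carry NaN and ``valid=False``.
    """

    window_start_times: np.ndarray  # seconds
    raw: np.ndarray
    normalized: np.ndarray
    valid: np.ndarray
    measure: Measure
    config: PatternConfig
    window_seconds: float
    recording_id: str = ""

    @property
    def n_windows(self) -> int:
        return int(self.raw.size)

    def to_frame(self) -> pd.DataFrame:
        """Feature-table rows (one per window)."""
        return pd.DataFrame(
            {
                "recording_id": self.recording_id,
                "window_index": np.arange(self.n_windows),
                "window_start_s": self.window_start_times,
                "measure": self.measure,
                "m": self.config.m,
                "tau": self.config.tau,
                "raw_bits": self.raw,
                "normalized": self.normalized,
                "valid": self.valid,
            }
        )


@dataclass(frozen=True)
class FeasibilityResult:
    """Outcome of the sample-size feasibility rule for one request."""

    n: int
    kind: str
    max_m: int
    requested_m: int | None = None

    @property
    def feasible(self) -> bool | None:
        if self.requested_m is None:
            return None
        return self.requested_m <= self.max_m


def pattern_alphabet_size(m: int, kind: str) -> int:
    """Number of possible patterns at order m: m! (ordinal) or 2^(m-1)
    (difference)."""
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    if kind == "ordinal":
        if m > MAX_ORDINAL_ORDER:
            raise CapacityError(f"ordinal alphabet overflows 64 bits for m={m}")
        return math.factorial(m)
    if kind == "difference":
        if m > MAX_DIFFERENCE_ORDER:
            raise CapacityError(f"difference alphabet overflows 64 bits for m={m}")
        return 2 ** (m - 1)
    raise ValueError(f"unknown pattern kind {kind!r}")


def pattern_distribution(ps: PatternSequence) -> PatternDistribution:
    """Relative pattern frequencies: p(c) = count(c) / k."""
    if ps.k < 1:
        raise ValueError("empty pattern sequence")
    codes, counts = np.unique(ps.codes, return_counts=True)
    return PatternDistribution(codes, counts / ps.k, ps.alphabet_size, ps.k)


def shannon_entropy(d: PatternDistribution, base: float = 2.0) -> float:
    """Shannon entropy of a pattern distribution (0 * log 0 := 0).

    Zero iff a single pattern occurs; log(alphabet_size) iff uniform.
    """
    return float(stats.entropy(d.nonzero_probs, base=base))


def _window_entropy(
    window,
    cfg: PatternConfig,
    normalized: bool,
    base: float,
) -> float:
    if cfg.tie_policy == "discard_window" and window_has_tie(window, cfg):
        return math.nan
    dist = pattern_distribution(encode(window, cfg))
    h = shannon_entropy(dist, base=base)
    if normalized:
        h /= math.log(cfg.alphabet_size, base)
    return h


def permutation_entropy(
    window,
    cfg: PatternConfig | None = None,
    normalized: bool = True,
    base: float = 2.0,
    *,
    m: int | None = None,
    tau: int = 1,
    tie_policy: str = "ascending",
) -> float:
    """Permutation entropy of one window.

    Composes ordinal encoding (incremental when tau = 1), pattern
    counting and Shannon entropy; ``normalized`` divides by log2(m!).
    Returns NaN when the tie policy discards the window.
    """
    if cfg is None:
        if m is None:
            raise ValueError("provide cfg or m")
        cfg = PatternConfig(m=m, tau=tau, kind="ordinal", tie_policy=tie_policy)
    elif cfg.kind != "ordinal":
        cfg = PatternConfig(cfg.m, cfg.tau, "ordinal", cfg.tie_policy)
    return _window_entropy(window, cfg, normalized, base)


def entropy_of_difference(
    window,
    cfg: PatternConfig | None = None,
    normalized: bool = True,
    base: float = 2.0,
    *,
    m: int | None = None,
    tau: int = 1,
    tie_policy: str = "ascending",
) -> float:
    """Entropy of difference of one window.

    Composes sign-pattern encoding (incremental when tau = 1), pattern
    counting and Shannon entropy; ``normalized`` divides by m - 1.
    Returns NaN when the tie policy discards the window.
    """
    if cfg is None:
        if m is None:
            raise ValueError("provide cfg or m")
        cfg = PatternConfig(m=m, tau=tau, kind="difference", tie_policy=tie_policy)
    elif cfg.kind != "difference":
        cfg = PatternConfig(cfg.m, cfg.tau, "difference", cfg.tie_policy)
    return _window_entropy(window, cfg, normalized, base)


def check_feasibility(
    n: int, cfg: PatternConfig | str, requested_m: int | None = None
) -> FeasibilityResult:
    """Largest reliably estimable order for a signal of length ``n``.

    The rule demands at least as many tuples as possible patterns:
    ``n > m! + m`` for ordinal patterns, ``n > 2^(m-1) + m`` for
    difference patterns.  A requested order above the limit triggers a
    :class:`FeasibilityWarning`, not an error — undersampled orders are
    computable and their entropy depression is itself informative.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if isinstance(cfg, PatternConfig):
        kind = cfg.kind
        if requested_m is None:
            requested_m = cfg.m
    else:
        kind = cfg
    if kind not in ("ordinal", "difference"):
        raise ValueError(f"unknown pattern kind {kind!r}")
    m = 2
    while True:
        cost = (math.factorial(m + 1) if kind == "ordinal" else 2**m) + m + 1
        if n <= cost or (
            kind == "ordinal" and m + 1 > MAX_ORDINAL_ORDER
        ) or (kind == "difference" and m + 1 > MAX_DIFFERENCE_ORDER):
            break
        m += 1
    result = FeasibilityResult(n=n, kind=kind, max_m=m, requested_m=requested_m)
    if requested_m is not None and requested_m > m:
        warnings.warn(
            f"order m={requested_m} exceeds the feasibility limit m={m} for "
            f"{kind} patterns on {n} samples; entropy will be depressed by "
            "non-occurring patterns",
            FeasibilityWarning,
            stacklevel=2,
        )
    return result


def windowed_entropy(
    signal,
    window_seconds: float,
    cfg: PatternConfig,
    measure: Measure | None = None,
    base: float = 2.0,
    recording_id: str | None = None,
) -> EntropySeries:
    """Entropy of consecutive non-overlapping windows of a recording.

    Windows are aligned to t = 0 and a trailing partial window is
    dropped.  Under tie policy ``discard_window``, windows containing a
    tied tuple get NaN values and ``valid=False``; they are excluded
    from exported feature tables downstream.
    """
    if measure is None:
        measure = "peen" if cfg.kind == "ordinal" else "eod"
    kind = "ordinal" if measure == "peen" else "difference"
    if cfg.kind != kind:
        cfg = PatternConfig(cfg.m, cfg.tau, kind, cfg.tie_policy)
    samples = np.asarray(getattr(signal, "samples", signal), dtype=float)
    fs = float(getattr(signal, "sampling_rate", 1.0))
    window_len = int(round(window_seconds * fs))
    if window_len < (cfg.m - 1) * cfg.tau + 1:
        raise ValueError(
            f"{window_seconds} s windows at {fs} Hz hold {window_len} samples, "
            f"fewer than one tuple of m={cfg.m}, tau={cfg.tau}"
        )
    check_feasibility(window_len, cfg)
    n_windows = samples.size // window_len
    raw = np.full(n_windows, np.nan)
    normalized = np.full(n_windows, np.nan)
    valid = np.zeros(n_windows, dtype=bool)
    log_max = math.log(cfg.alphabet_size, base)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FeasibilityWarning)
        for w in range(n_windows):
            window = samples[w * window_len : (w + 1) * window_len]
            h = _window_entropy(window, cfg, normalized=False, base=base)
            if not math.isnan(h):
                raw[w] = h
                normalized[w] = h / log_max
                valid[w] = True
    starts = np.arange(n_windows) * window_len / fs
    return EntropySeries(
        window_start_times=starts,
        raw=raw,
        normalized=normalized,
        valid=valid,
        measure=measure,
        config=cfg,
        window_seconds=window_seconds,
        recording_id=recording_id
        if recording_id is not None
        else str(getattr(signal, "channel_name", "")),
    )
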