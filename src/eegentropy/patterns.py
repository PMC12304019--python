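"""Ordinal (Lehmer-coded) and sign-difference pattern encoders.

A time series ``(x_t)`` of length ``N`` is split, for an embedding
dimension (order) ``m`` and time delay ``tau``, into

    k = N - (m - 1) * tau

overlapping tuples of length ``m``.  Each tuple is mapped to an integer
pattern code:

* *ordinal* patterns: the rank ordering of the tuple, encoded as a Lehmer
  code (the tuple of right inversion counts read as a factoradic numeral);
  ``m!`` possible codes.
* *difference* patterns: the string of signs of consecutive differences,
  read as a binary numeral; ``2^(m-1)`` possible codes.

For each pattern kind a plain (per-tuple) and an incremental encoder is
provided.  The incremental encoders exploit the overlap of adjacent
tuples and need only ``m - 1`` (ordinal) or one (difference) comparison
per new tuple.  Every encoder tallies the number of scalar ``>``
comparisons it performs in ``PatternSequence.comparison_count`` so the
O(N m^2) / O(N m) / O(N) complexity claims are testable without wall
clocks.

Ties are compared with strict ``>`` throughout: a tie ``x_i = x_j``
(``i < j``) behaves as if ``x_i < x_j`` (ascending).  Windows containing
ties can alternatively be invalidated wholesale via
:func:`window_has_tie` (tie policy ``discard_window``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "PatternConfig",
    "PatternSequence",
    "right_inversion_counts",
    "lehmer_code",
    "difference_code",
    "encode_ordinal_plain",
    "encode_ordinal_overlap",
    "encode_difference_plain",
    "encode_difference_iterative",
    "encode",
    "window_has_tie",
    "tuple_count",
    "MAX_ORDINAL_ORDER",
    "MAX_DIFFERENCE_ORDER",
]

#: Largest order whose ordinal codes (up to m! - 1) fit a 64-bit integer.
MAX_ORDINAL_ORDER = 20
#: Largest order whose m - 1 sign bits fit a 64-bit integer.
MAX_DIFFERENCE_ORDER = 64

PatternKind = Literal["ordinal", "difference"]
TiePolicy = Literal["ascending", "discard_window"]


class CapacityError(ValueError):
    """Requested order exceeds the integer capacity of the encoding."""


class UnsupportedConfigurationError(ValueError):
    """Encoder cannot honour the configuration (e.g. incremental tau != 1)."""


@dataclass(frozen=True)
class PatternConfig:
    """Embedding configuration for pattern extraction.

    Parameters
    ----------
    m : int
        Embedding dimension (order), at least 2.  Capped at 20 for
        ordinal patterns (``m!`` must fit 64 bits) and 64 for difference
        patterns (``m - 1`` sign bits).
    tau : int
        Time delay (index stride between tuple elements), at least 1.
    kind : {"ordinal", "difference"}
        Pattern family.
    tie_policy : {"ascending", "discard_window"}
        ``ascending`` resolves ties as strict ``>`` comparisons;
        ``discard_window`` marks whole windows containing any tied
        tuple as invalid.
    """

    m: int
    tau: int = 1
    kind: PatternKind = "ordinal"
    tie_policy: TiePolicy = "ascending"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"time delay tau must be >= 1, got {self.tau}")
        if self.kind not in ("ordinal", "difference"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.tie_policy not in ("ascending", "discard_window"):
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")
        if self.kind == "ordinal" and self.m > MAX_ORDINAL_ORDER:
            raise CapacityError(
                f"ordinal codes require m <= {MAX_ORDINAL_ORDER} "
                f"(m! must fit 64 bits), got m={self.m}"
            )
        if self.kind == "difference" and self.m > MAX_DIFFERENCE_ORDER:
            raise CapacityError(
                f"difference codes require m <= {MAX_DIFFERENCE_ORDER}, got m={self.m}"
            )

    @property
    def alphabet_size(self) -> int:
        """Number of possible patterns: ``m!`` or ``2^(m-1)``."""
        if self.kind == "ordinal":
            return math.factorial(self.m)
        return 2 ** (self.m - 1)


@dataclass
class PatternSequence:
    """Integer pattern codes of the tuples of a time series.

    ``codes`` are 0-based for both kinds.  The 1-based convention used
    for printed difference codes ([+,+,+] -> 1, [-,-,-] -> 2^(m-1)) is
    available through :attr:`external_codes`.
    """

    codes: np.ndarray
    alphabet_size: int
    comparison_count: int
    config: PatternConfig
    algorithm: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)

    @property
    def k(self) -> int:
        """Tuple count k = N - (m - 1) * tau."""
        return int(self.codes.size)

    @property
    def external_codes(self) -> np.ndarray:
        """Codes in the reporting convention (1-based for difference)."""
        if self.config.kind == "difference":
            return self.codes + 1
        return self.codes


def tuple_count(n: int, m: int, tau: int = 1) -> int:
    """Number of m-tuples at stride tau in a series of length n."""
    return n - (m - 1) * tau


def _as_samples(x) -> np.ndarray:
    samples = getattr(x, "samples", x)
    arr = np.ascontiguousarray(samples, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D sample vector, got shape {arr.shape}")
    return arr


def _check_length(n: int, cfg: PatternConfig) -> int:
    k = tuple_count(n, cfg.m, cfg.tau)
    if k < 1:
        raise ValueError(
            f"signal of length {n} too short for m={cfg.m}, tau={cfg.tau} "
            f"(needs at least {(cfg.m - 1) * cfg.tau + 1} samples)"
        )
    return k


def _tuple_view(x: np.ndarray, cfg: PatternConfig) -> np.ndarray:
    """(k, m) array whose row t is the tuple starting at t (stride tau)."""
    k = _check_length(x.size, cfg)
    cols = [x[j * cfg.tau : j * cfg.tau + k] for j in range(cfg.m)]
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# scalar codecs


def right_inversion_counts(t: Iterable[float]) -> np.ndarray:
    """Right inversion counts (r_1, ..., r_m) of one tuple.

    ``r_i`` counts the strictly smaller values to the right of position
    i: ``r_i = #{j > i : x_i > x_j}``.  Ties contribute zero.
    """
    values = np.asarray(list(t) if not isinstance(t, np.ndarray) else t, dtype=float)
    m = values.size
    if m < 2:
        raise ValueError(f"tuple must have at least 2 values, got {m}")
    return (values[:, None] > values[None, :]).sum(axis=1, where=np.triu(np.ones((m, m), bool), 1))


def lehmer_code(t: Iterable[float]) -> int:
    """Lehmer code of one tuple: its right inversion counts read as an
    m-digit factoradic numeral, ``sum_i (m - i)! * r_i`` (0-based codes,
    bijective over the m! orderings of tie-free tuples)."""
    r = right_inversion_counts(t)
    m = r.size
    if m > MAX_ORDINAL_ORDER:
        raise CapacityError(f"lehmer_code supports m <= {MAX_ORDINAL_ORDER}, got {m}")
    return int(sum(math.factorial(m - i) * int(r[i - 1]) for i in range(1, m)))


def difference_code(t: Iterable[float]) -> int:
    """Binary sign-pattern code of one tuple, 1-based.

    Bit ``i`` (most significant first) is set iff ``x_i > x_{i+1}`` (a
    "-" sign); ties count as "+".  The all-ascending pattern [+,...,+]
    maps to 1 and the all-descending one to 2^(m-1), with the
    lexicographic order of sign strings preserved in between.
    """
    values = np.asarray(list(t) if not isinstance(t, np.ndarray) else t, dtype=float)
    m = values.size
    if m < 2:
        raise ValueError(f"tuple must have at least 2 values, got {m}")
    if m > MAX_DIFFERENCE_ORDER:
        raise CapacityError(f"difference_code supports m <= {MAX_DIFFERENCE_ORDER}, got {m}")
    bits = values[:-1] > values[1:]
    return 1 + int(sum(int(b) << (m - 2 - i) for i, b in enumerate(bits)))


# ---------------------------------------------------------------------------
# sequence encoders


def encode_ordinal_plain(x, cfg: PatternConfig) -> PatternSequence:
    """Encode every m-tuple independently into its Lehmer code.

    Performs all m(m-1)/2 pairwise comparisons per tuple, i.e.
    ``k * m * (m - 1) / 2`` comparisons in total (the O(N m^2) route).
    """
    if cfg.kind != "ordinal":
        raise ValueError("encode_ordinal_plain requires kind='ordinal'")
    samples = _as_samples(x)
    tuples = _tuple_view(samples, cfg)
    k, m = tuples.shape
    fact = [math.factorial(j) for j in range(m + 1)]
    codes = np.zeros(k, dtype=np.int64)
    comparisons = 0
    for i in range(m - 1):  # position i (0-based); weight (m - 1 - i)!
        r_i = np.zeros(k, dtype=np.int64)
        for j in range(i + 1, m):
            r_i += tuples[:, i] > tuples[:, j]
            comparisons += k
        codes += fact[m - 1 - i] * r_i
    return PatternSequence(codes, cfg.alphabet_size, comparisons, cfg, "plain")


def encode_ordinal_overlap(x, cfg: PatternConfig) -> PatternSequence:
    """Incremental Lehmer encoder exploiting tuple overlap (tau = 1 only).

    Adjacent tuples share m - 1 values, so each comparison
    ``x_p > x_{p+d}`` (d = 1..m-1) is made once and reused by every
    tuple containing the pair: after the first tuple's m(m-1)/2
    comparisons, each further tuple costs exactly m - 1, for
    ``m(m-1)/2 + (k-1)(m-1)`` in total (the O(N m) route).  Codes are
    identical to :func:`encode_ordinal_plain`.
    """
    if cfg.kind != "ordinal":
        raise ValueError("encode_ordinal_overlap requires kind='ordinal'")
    if cfg.tau != 1:
        raise UnsupportedConfigurationError(
            "the overlap recurrence requires tau=1; use encode_ordinal_plain"
        )
    samples = _as_samples(x)
    n = samples.size
    k = _check_length(n, cfg)
    m = cfg.m
    # c[d-1, p] = [x_p > x_{p+d}]; the right inversion count of position
    # i (1-based) in the tuple starting at t is the prefix sum
    # r_i = sum_{d=1}^{m-i} c[d-1, t+i-1].
    c = np.zeros((m - 1, n), dtype=np.int16)
    comparisons = 0
    for d in range(1, m):
        c[d - 1, : n - d] = samples[: n - d] > samples[d:]
        comparisons += n - d
    prefix = np.cumsum(c, axis=0, dtype=np.int64)
    codes = np.zeros(k, dtype=np.int64)
    for i in range(1, m):  # 1-based position, weight (m - i)!
        length = m - i
        codes += math.factorial(length) * prefix[length - 1, i - 1 : i - 1 + k]
    return PatternSequence(codes, cfg.alphabet_size, comparisons, cfg, "overlap")


def encode_difference_plain(x, cfg: PatternConfig) -> PatternSequence:
    """Encode every tuple's sign string independently: ``k (m - 1)``
    comparisons (O(N m))."""
    if cfg.kind != "difference":
        raise ValueError("encode_difference_plain requires kind='difference'")
    samples = _as_samples(x)
    tuples = _tuple_view(samples, cfg)
    k, m = tuples.shape
    codes = np.zeros(k, dtype=np.int64)
    comparisons = 0
    for i in range(m - 1):
        codes += (tuples[:, i] > tuples[:, i + 1]).astype(np.int64) << (m - 2 - i)
        comparisons += k
    return PatternSequence(codes, cfg.alphabet_size, comparisons, cfg, "plain")


def encode_difference_iterative(x, cfg: PatternConfig) -> PatternSequence:
    """Incremental sign-pattern encoder (tau = 1 only).

    Consecutive codes share m - 2 sign bits; each sign ``x_p > x_{p+1}``
    is compared once, so after the first tuple's m - 1 comparisons every
    new tuple costs exactly one: ``(m - 1) + (k - 1)`` comparisons in
    total (O(N)).  Codes are identical to
    :func:`encode_difference_plain`.
    """
    if cfg.kind != "difference":
        raise ValueError("encode_difference_iterative requires kind='difference'")
    if cfg.tau != 1:
        raise UnsupportedConfigurationError(
            "the iterative recurrence requires tau=1; use encode_difference_plain"
        )
    samples = _as_samples(x)
    n = samples.size
    k = _check_length(n, cfg)
    m = cfg.m
    signs = (samples[:-1] > samples[1:]).astype(np.int64)  # n - 1 comparisons
    comparisons = n - 1  # == (m - 1) + (k - 1)
    windows = np.lib.stride_tricks.sliding_window_view(signs, m - 1)
    weights = (1 << np.arange(m - 2, -1, -1)).astype(np.int64)
    codes = windows @ weights
    return PatternSequence(codes, cfg.alphabet_size, comparisons, cfg, "iterative")


_ORDINAL_ENCODERS = {"plain": encode_ordinal_plain, "overlap": encode_ordinal_overlap}
_DIFFERENCE_ENCODERS = {
    "plain": encode_difference_plain,
    "iterative": encode_difference_iterative,
}


def encode(x, cfg: PatternConfig, algorithm: str = "auto") -> PatternSequence:
    """Encode with the named algorithm, or the cheapest valid one.

    ``auto`` selects the incremental encoder when tau = 1 and the plain
    one otherwise.
    """
    table = _ORDINAL_ENCODERS if cfg.kind == "ordinal" else _DIFFERENCE_ENCODERS
    if algorithm == "auto":
        if cfg.tau == 1:
            algorithm = "overlap" if cfg.kind == "ordinal" else "iterative"
        else:
            algorithm = "plain"
    try:
        encoder = table[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r} for kind {cfg.kind!r}; "
            f"choose from {sorted(table)} or 'auto'"
        ) from None
    return encoder(x, cfg)


def window_has_tie(window, cfg: PatternConfig) -> bool:
    """True iff any m-tuple (stride tau) of the window contains two
    equal values — any pair within the tuple, not only consecutive
    samples.  Used by tie policy ``discard_window``."""
    samples = _as_samples(window)
    if samples.size < (cfg.m - 1) * cfg.tau + 1:
        raise ValueError("window shorter than one tuple")
    tuples = _tuple_view(samples, cfg)
    ordered = np.sort(tuples, axis=1)
    return bool(np.any(np.diff(ordered, axis=1) == 0.0))
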