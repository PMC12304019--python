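"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's integer-code machinery:
patterns are identified by raw comparison profiles and tallied with a
Counter, so entropy values can be cross-checked against a second,
definition-level route.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest


def brute_ordinal_key(values) -> tuple:
    """Ordinal pattern of a tuple as its full pairwise > profile
    (ties behave as ascending, matching the package convention)."""
    values = list(values)
    m = len(values)
    return tuple(
        values[i] > values[j] for i in range(m) for j in range(i + 1, m)
    )


def brute_difference_key(values) -> tuple:
    """Sign pattern of a tuple: consecutive > comparisons."""
    values = list(values)
    return tuple(values[i] > values[i + 1] for i in range(len(values) - 1))


def brute_entropy(window, m: int, tau: int = 1, kind: str = "ordinal") -> float:
    """Shannon entropy (bits) of the pattern distribution, by direct
    enumeration of tuples and Counter tallying."""
    window = np.asarray(window, dtype=float)
    k = window.size - (m - 1) * tau
    assert k >= 1
    keyfn = brute_ordinal_key if kind == "ordinal" else brute_difference_key
    counts = Counter(
        keyfn(window[t + j * tau] for j in range(m)) for t in range(k)
    )
    return -sum((c / k) * math.log2(c / k) for c in counts.values())


def brute_window_has_tie(window, m: int, tau: int = 1) -> bool:
    """Tie check by explicit per-tuple pair scan."""
    window = np.asarray(window, dtype=float)
    k = window.size - (m - 1) * tau
    for t in range(k):
        tup = [window[t + j * tau] for j in range(m)]
        if len(set(tup)) < m:
            return True
    return False


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def noise_1e6():
    """One long white-noise recording shared across tests."""
    from eegentropy import white_noise

    return white_noise(1_000_000, seed=1)
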