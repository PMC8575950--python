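"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive everything base-by-base / pair-by-pair and make
no use of the library's interval arithmetic.
"""

from __future__ import annotations

import numpy as np


def walk_distance(from_pos: int, to_pos: int, direction: int, L: int) -> int:
    """Base-by-base walk from one position to another along a direction."""
    steps = 0
    p = from_pos
    while p != to_pos:
        p = (p + direction) % L
        steps += 1
        assert steps <= L
    return steps


def per_base_headful(site_pos: int, direction: int, H: int, n_max: int, L: int) -> np.ndarray:
    """For every base: its 1-based headful index from the site, 0 if out of reach."""
    positions = np.arange(L)
    if direction == +1:
        dist = (positions - site_pos) % L
    else:
        dist = (site_pos - positions) % L
    hf = dist // H + 1
    hf[hf > n_max] = 0
    return hf


def per_base_coverage(sites, models, L: int) -> np.ndarray:
    """Boolean per-base mask of the union LT reach of all prophages."""
    covered = np.zeros(L, dtype=bool)
    for site in sites:
        m = models[site.site_id]
        hf = per_base_headful(site.position, site.direction, m.headful_size, m.n_max, L)
        covered |= hf > 0
    return covered


def locus_bases(start: int, length: int, L: int) -> np.ndarray:
    return (start + np.arange(length)) % L


def per_base_locus_range(site, locus, model, L: int):
    """Min/max in-reach headful index over the locus bases, or None."""
    hf = per_base_headful(site.position, site.direction, model.headful_size, model.n_max, L)
    values = hf[locus_bases(locus.span.start, locus.span.length, L)]
    values = values[values > 0]
    if values.size == 0:
        return None
    return int(values.min()), int(values.max())


def two_pass_mean_sd(values):
    """Textbook two-pass mean / sample SD, independent of the implementation."""
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var**0.5


def truncated_geometric_pmf(q: float, n_max: int) -> np.ndarray:
    """P(series length = k), k = 1..n_max, continuation probability q."""
    pmf = np.array([q ** (k - 1) * (1 - q) for k in range(1, n_max + 1)])
    pmf[-1] = q ** (n_max - 1)  # truncation mass
    return pmf
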