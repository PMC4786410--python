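"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by enumeration or closed form,
never by calling the code paths they check.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_motifs(sequence: str, max_inner_gap: int = 2) -> list[tuple[int, int]]:
    """All maximal R-motif spans by exhaustive enumeration.

    Enumerates every pair of arginine positions (i, j), keeps pairs where
    every gap between consecutive arginines inside [i, j] is at most
    ``max_inner_gap`` (so i..j is a qualifying run with >= 2 arginines), and
    reduces to spans not contained in any larger qualifying span.  1-based
    inclusive coordinates.
    """
    r_pos = [k + 1 for k, aa in enumerate(sequence) if aa == "R"]
    qualifying = []
    for a in range(len(r_pos)):
        for b in range(a + 1, len(r_pos)):
            inner = r_pos[a:b + 1]
            if all(inner[k + 1] - inner[k] - 1 <= max_inner_gap for k in range(len(inner) - 1)):
                qualifying.append((r_pos[a], r_pos[b]))
    maximal = [
        (s, e) for s, e in qualifying
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in qualifying)
    ]
    return sorted(maximal)


def exact_fisher_two_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins.

    Sums the hypergeometric probability of every table at least as extreme
    (probability no larger than the observed table's) using exact integer
    arithmetic until the final division.
    """
    row1, row2 = n1, n2
    col1 = k1 + k2
    total = n1 + n2
    denom = comb(total, col1)

    def table_weight(x):  # x successes in set 1
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return 0
        return comb(row1, x) * comb(row2, col1 - x)

    observed = table_weight(k1)
    num = sum(w for x in range(col1 + 1) if (w := table_weight(x)) <= observed)
    return num / denom


@pytest.fixture
def motif_oracle():
    return brute_force_motifs


@pytest.fixture
def fisher_oracle():
    return exact_fisher_two_sided


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


# Worked-example peptides (multivalent R-motif peptides used throughout)
PEPTIDES = {
    "rpL5": "RRRREGKTDYYARKRLV",
    "rpL5-RA": "RRRREGKTDYYAAKALV",
    "GNL2": "RRRAVRQQRPKKVGVRYYETHNVKNRNR",
    "SURF6": "RRAQRQRRWEKRTAGVVEKMQQRQDRRR",
    "rpL23a": "RRPKTLRLRRQPKYPRKSAPRR",
    "polyR": "RRRRRR",
}


@pytest.fixture
def peptides():
    return dict(PEPTIDES)
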