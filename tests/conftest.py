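import numpy as np
import pytest

import bivalscore as bv


@pytest.fixture(scope="session")
def layout():
    """1 Mb over two chromosomes; all planted regions land on chrS1, so
    chrS2 is pure background."""
    return bv.make_genome(2, 500_000, 7)


@pytest.fixture(scope="session")
def truth(layout):
    return bv.plant_truth(layout, seed=1)


@pytest.fixture(scope="session")
def k4_tags(truth, layout):
    return bv.simulate_tags(truth, layout, "H3K4me3", seed=2)


@pytest.fixture(scope="session")
def k27_tags(truth, layout):
    return bv.simulate_tags(truth, layout, "H3K27me3", seed=3)


def brute_force_islands(mask, bridge):
    """O(n^2) independent enumerator of maximal bridged eligible runs.

    A candidate (i, j) is valid when mask[i] and mask[j] hold and every
    internal run of ineligible windows is no longer than ``bridge``; it is
    an island when no valid candidate strictly contains it.
    """
    n = len(mask)

    def valid(i, j):
        if not (mask[i] and mask[j]):
            return False
        run = 0
        for t in range(i, j + 1):
            if mask[t]:
                run = 0
            else:
                run += 1
                if run > bridge:
                    return False
        return True

    candidates = [(i, j) for i in range(n) if mask[i]
                  for j in range(i, n) if valid(i, j)]
    islands = [(i, j + 1) for i, j in candidates
               if not any((a <= i and j <= b and (a, b) != (i, j))
                          for a, b in candidates)]
    return sorted(set(islands))


def brute_force_overlap(win_start, win_end, intervals):
    """Base-position scan: does [win_start, win_end) share a base with any
    interval?  Independent of the interval-tree engine."""
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return any(b in covered for b in range(win_start, win_end))
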