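"""Exhaustive reference implementation of the non-wear rule.

Used only for validation: ``reference_bouts`` re-derives non-wear bouts
by scanning, for every candidate start epoch, every possible end epoch
and checking window qualification directly — no run-merging, no shared
code with :func:`vigortrend.processing.detect_nonwear`.  Numba is used
when available purely to make the O(n^2) scan affordable at scale; the
pure-Python path computes identical results.
"""

from __future__ import annotations

import numpy as np


def _scan(counts, min_bout, max_interrupt, cap):  # pragma: no cover - jitted
    n = counts.size
    starts = np.empty(n, np.int64)
    ends = np.empty(n, np.int64)
    interr = np.empty(n, np.int64)
    n_bouts = 0
    i = 0
    while i < n:
        if counts[i] != 0:
            i += 1
            continue
        # largest j such that the window [i, j] qualifies: endpoints zero,
        # <= max_interrupt nonzero epochs, every nonzero isolated (run of 1)
        best = -1
        best_nz = 0
        nz = 0
        run = 0
        j = i
        while j < n:
            c = counts[j]
            if c == 0:
                run = 0
                best = j
                best_nz = nz
            else:
                nz += 1
                run += 1
                if run >= 2 or nz > max_interrupt or (cap >= 0 and c > cap):
                    break
            j += 1
        if best >= 0 and best - i + 1 >= min_bout:
            starts[n_bouts] = i
            ends[n_bouts] = best + 1
            interr[n_bouts] = best_nz
            n_bouts += 1
            i = best + 1
        else:
            i += 1
    return starts[:n_bouts], ends[:n_bouts], interr[:n_bouts]


try:  # numba is optional; results are identical either way
    from numba import njit

    _scan_fast = njit(cache=True)(_scan)
except ImportError:  # pragma: no cover
    _scan_fast = _scan


def reference_bouts(
    counts,
    min_bout: int = 60,
    max_interrupt: int = 2,
    interrupt_max_cpm: int | None = None,
) -> list[tuple[int, int, int]]:
    """All greedy leftmost-maximal qualifying non-wear windows.

    Returns ``(start, end, n_interruptions)`` tuples with half-open epoch
    spans, directly comparable to ``detect_nonwear`` output.
    """
    counts = np.ascontiguousarray(np.asarray(counts, dtype=np.int64))
    cap = -1 if interrupt_max_cpm is None else int(interrupt_max_cpm)
    starts, ends, interr = _scan_fast(counts, min_bout, max_interrupt, cap)
    return [(int(s), int(e), int(k)) for s, e, k in zip(starts, ends, interr)]


def qualifying_windows(
    counts, min_bout: int = 60, max_interrupt: int = 2
) -> set[tuple[int, int]]:
    """Every qualifying window (half-open), regardless of overlap.

    A window qualifies when it starts and ends on zero epochs, spans at
    least ``min_bout`` epochs, contains at most ``max_interrupt`` nonzero
    epochs, and every nonzero epoch inside it is isolated.  This is the
    monotone object of the non-wear rule: adding counts to a series can
    only shrink this set.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.size
    out: set[tuple[int, int]] = set()
    for i in range(n):
        if counts[i] != 0:
            continue
        nz = 0
        run = 0
        for j in range(i, n):
            c = counts[j]
            if c == 0:
                run = 0
                if j - i + 1 >= min_bout:
                    out.add((i, j + 1))
            else:
                nz += 1
                run += 1
                if run >= 2 or nz > max_interrupt:
                    break
    return out
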