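"""Selection of visit pairs that mimic a trial's baseline / 1-year design.

Natural-history patients are observed at irregular times. To evaluate a
prognostic model under trial-like conditions, each patient's record is reduced
to the two visits whose gap is closest to one year (the pair plays the role of
inclusion and month-12 visits); anything earlier is kept as pre-inclusion
history and anything later is discarded.
"""

from __future__ import annotations

import numpy as np

#: Admissible gap window (years) for a "one-year" pair. The design targets the
#: pair closest to a 1.0-year gap; gaps outside [0.5, 1.5] are considered too
#: far from the trial design to stand in for a 1-year outcome.
DEFAULT_GAP_WINDOW = (0.5, 1.5)


def one_year_pair(times, gap_window=DEFAULT_GAP_WINDOW, target: float = 1.0):
    """Indices (i, j) of the visit pair with gap closest to ``target`` years.

    ``times`` must be sorted ascending. All ordered pairs are considered; the
    pair minimizing |gap - target| among gaps inside ``gap_window`` wins, with
    ties broken toward the earlier pair. Returns ``None`` when no pair falls
    in the window.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        return None
    lo, hi = gap_window
    best = None
    best_key = None
    for i in range(len(t) - 1):
        for j in range(i + 1, len(t)):
            gap = t[j] - t[i]
            if gap < lo or gap > hi:
                continue
            key = (abs(gap - target), t[i], t[j])
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
    return best
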