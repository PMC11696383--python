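"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the same contracts as the library from first
principles (plain Python loops, no shared code paths) so agreement is
evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(
    times, values, min_prominence=0.0, min_separation=0.0, min_height=-np.inf
):
    """O(n²) peak detection matching the documented semantics.

    A candidate is a sample strictly above its left neighbour and at least
    its right neighbour (leftmost sample of a plateau).  Prominence is height
    minus the higher of the two minima walked to the nearest strictly higher
    sample or the record edge.  After thresholding, peaks closer than
    ``min_separation`` are pruned greedily, higher first (ties: earlier).
    """
    v = list(map(float, values))
    t = list(map(float, times))
    n = len(v)
    survivors = []
    for i in range(1, n - 1):
        if not (v[i] > v[i - 1] and v[i] >= v[i + 1]):
            continue
        left_min = v[i]
        j = i - 1
        while j >= 0 and v[j] <= v[i]:
            left_min = min(left_min, v[j])
            j -= 1
        right_min = v[i]
        j = i + 1
        while j < n and v[j] <= v[i]:
            right_min = min(right_min, v[j])
            j += 1
        prominence = v[i] - max(left_min, right_min)
        if prominence >= min_prominence and v[i] >= min_height:
            survivors.append((i, prominence))

    kept: list[int] = []
    for i, _ in sorted(survivors, key=lambda pair: (-v[pair[0]], t[pair[0]])):
        if all(abs(t[i] - t[k]) >= min_separation for k in kept):
            kept.append(i)
    kept.sort()
    prom_by_index = dict(survivors)
    return kept, [prom_by_index[i] for i in kept]


def brute_force_confusion(true_labels, predicted, labels, reject):
    """Plain dict-of-dicts tally of (true, predicted) pairs."""
    counts = {y: {p: 0 for p in labels} for y in labels}
    rejects = {y: 0 for y in labels}
    for y, p in zip(true_labels, predicted):
        if p == reject:
            rejects[y] += 1
        else:
            counts[y][p] += 1
    return counts, rejects
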