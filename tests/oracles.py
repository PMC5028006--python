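"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_partition(events: np.ndarray, connectivity: int = 4) -> set[frozenset]:
    """Partition events by BFS flood fill over the spatio-temporal event graph.

    Two events are adjacent iff |dt| <= 1 and their pixels coincide or are
    spatial neighbours (4- or 8-connectivity).  Returns the partition as a
    set of frozensets of (t, y, x) tuples.
    """
    events = np.asarray(events, dtype=bool)
    t_max, h, w = events.shape
    if connectivity == 4:
        space = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        space = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
    offsets = [(dt, dy, dx) for dt in (-1, 0, 1) for dy, dx in space]
    offsets = [o for o in offsets if o != (0, 0, 0)]
    remaining = set(zip(*np.nonzero(events)))
    partition = set()
    while remaining:
        start = remaining.pop()
        comp = {start}
        queue = deque([start])
        while queue:
            t, y, x = queue.popleft()
            for dt, dy, dx in offsets:
                nb = (t + dt, y + dy, x + dx)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        partition.add(frozenset(comp))
    return partition


def labels_to_partition(labels: np.ndarray) -> set[frozenset]:
    """Partition implied by a label movie (0 = background)."""
    out: dict[int, set] = {}
    for t, y, x in zip(*np.nonzero(labels)):
        out.setdefault(int(labels[t, y, x]), set()).add((int(t), int(y), int(x)))
    return {frozenset(v) for v in out.values()}


def entropy_oracle(symbols) -> float:
    """Plug-in entropy by explicit counting (bits)."""
    from collections import Counter
    from math import log2

    counts = Counter(symbols)
    n = sum(counts.values())
    return -sum((c / n) * log2(c / n) for c in counts.values())


def box_average_oracle(frame: np.ndarray, kernel: int) -> np.ndarray:
    """Renormalised moving-average by explicit double loop."""
    h, w = frame.shape
    left = (kernel - 1) // 2   # window spans [i - left, i + right]
    right = kernel // 2
    out = np.zeros_like(frame, dtype=float)
    for y in range(h):
        for x in range(w):
            ys = slice(max(y - left, 0), min(y + right + 1, h))
            xs = slice(max(x - left, 0), min(x + right + 1, w))
            out[y, x] = frame[ys, xs].mean()
    return out
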