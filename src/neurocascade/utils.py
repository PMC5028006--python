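"""Small shared numerics: plug-in entropy, word encoding, union-find, seeds."""

from __future__ import annotations

import hashlib
import json

import numpy as np

__all__ = [
    "entropy_bits",
    "entropy_from_labels",
    "encode_words",
    "UnionFind",
    "spawn_seeds",
    "config_hash",
]


def entropy_bits(counts) -> float:
    """Shannon entropy in bits of a distribution given by counts or probabilities.

    Zero entries contribute nothing (0·log 0 = 0 convention).
    """
    c = np.asarray(counts, dtype=float).ravel()
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("empty distribution")
    p = c[c > 0] / total
    return float(-np.sum(p * np.log2(p)))


def entropy_from_labels(labels) -> float:
    """Plug-in entropy (bits) of the empirical distribution of a label sequence."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    return entropy_bits(counts)


def encode_words(bits: np.ndarray) -> np.ndarray:
    """Encode rows of a (T, n_bits) boolean array as integer word codes.

    Codes index the observed alphabet only (0..n_distinct-1); identical
    rows get identical codes.  Deterministic given the input.
    """
    bits = np.ascontiguousarray(np.asarray(bits, dtype=bool))
    if bits.ndim != 2:
        raise ValueError("expected a (T, n_bits) array")
    packed = np.packbits(bits, axis=1)
    # view each packed row as one void scalar so np.unique works row-wise
    rows = packed.view([("", packed.dtype)] * packed.shape[1]).ravel()
    _, codes = np.unique(rows, return_inverse=True)
    return codes.astype(np.int64)


class UnionFind:
    """Array-backed union-find with path halving; ids are 1-based, 0 unused."""

    def __init__(self, n: int = 0):
        self.parent = np.arange(n + 1, dtype=np.int64)
        self.merges = 0

    def grow(self, n_new: int) -> None:
        start = len(self.parent)
        self.parent = np.concatenate(
            [self.parent, np.arange(start, start + n_new, dtype=np.int64)]
        )

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return int(i)

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if ra > rb:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.merges += 1
        return True

    def roots(self) -> np.ndarray:
        """Root id for every element (vectorised full-path compression)."""
        p = self.parent.copy()
        while True:
            pp = p[p]
            if np.array_equal(pp, p):
                return p
            p = pp


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def config_hash(params: dict) -> str:
    """Stable short hash of a JSON-serialisable parameter dict."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
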