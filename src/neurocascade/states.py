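"""Cortical-state sequences: k-means clustering and entropy measures.

Per analysis window (default 50 s), cortex-wide point-process frames are
spatially downsampled by a factor of 2 (box kernel) and clustered with
k-means into k states.  Two entropies summarise the resulting label
sequence:

* H_state = −Σ_i p_i log2 p_i over the state-visitation probabilities,
  the size of the visited state repertoire (0..log2 k bits);
* H_trans, the same formula applied to the first-order Markov transition
  distribution over ordered state pairs (i, j), which — unlike H_state —
  is sensitive to the temporal order of visits (0..2 log2 k bits for the
  default joint reading).

Clustering is always performed separately per window so that the state
inventory of one window cannot bias another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .core import Mask, PointProcessMovie, VoltageMovie
from .utils import entropy_bits

__all__ = [
    "StateSequence",
    "TransitionModel",
    "downsample_spatial",
    "cluster_states",
    "state_visitation_entropy",
    "transition_entropy",
    "transition_model",
    "iter_windows",
]


@dataclass
class StateSequence:
    """Per-frame state indices in 1..k with optional centroids."""

    labels: np.ndarray
    k: int
    window_id: Optional[int] = None
    centroids: Optional[np.ndarray] = None
    inertia: Optional[float] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or len(self.labels) == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TransitionModel:
    """First-order Markov transition counts and probabilities."""

    counts: np.ndarray
    k: int
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.k, self.k):
            raise ValueError("counts must be k×k")
        if self.counts.min() < 0:
            raise ValueError("negative transition counts")
        total = self.counts.sum()
        if total == 0:
            raise ValueError("no transitions (sequence too short)")
        self.probabilities = self.counts / total


def downsample_spatial(obj, factor: int = 2):
    """Box-kernel spatial downsampling by an integer factor.

    Continuous movies get the block mean; binary point processes use the
    any-event rule (a downsampled pixel is active if any pixel of its
    block is).  Frames whose dimensions are not divisible by the factor
    are zero-padded on the bottom/right edge and the padding is flagged
    in the metadata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return obj
    if isinstance(obj, PointProcessMovie):
        arr = obj.events
    elif isinstance(obj, VoltageMovie):
        arr = obj.data
    else:
        raise TypeError("expected VoltageMovie or PointProcessMovie")
    t, h, w = arr.shape
    pad_h = (-h) % factor
    pad_w = (-w) % factor
    padded = pad_h or pad_w
    if padded:
        arr = np.pad(arr, ((0, 0), (0, pad_h), (0, pad_w)))
    hh, ww = arr.shape[1] // factor, arr.shape[2] // factor
    blocks = arr.reshape(t, hh, factor, ww, factor)
    if isinstance(obj, PointProcessMovie):
        out = blocks.any(axis=(2, 4))
        mask = None
        if obj.mask is not None:
            m = obj.mask.include
            if padded:
                m = np.pad(m, ((0, pad_h), (0, pad_w)))
            mask = Mask(
                m.reshape(hh, factor, ww, factor).any(axis=(1, 3)),
                provenance=obj.mask.provenance,
            )
        meta = dict(obj.meta, downsample_factor=factor, downsample_padded=bool(padded))
        return PointProcessMovie(out, obj.frame_rate, mask=mask,
                                 threshold_sd=obj.threshold_sd, meta=meta)
    out = blocks.mean(axis=(2, 4))
    return obj.copy_with(out, downsample_factor=factor, downsample_padded=bool(padded))


def cluster_states(
    frames: np.ndarray | PointProcessMovie,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    window_id: Optional[int] = None,
    mask: Mask | None = None,
) -> StateSequence:
    """k-means clustering of per-frame activity patterns into k states.

    ``frames`` is either a (T, n_features) pattern matrix or a point
    process, in which case each frame's (optionally masked) pixels form
    the pattern vector.  Standard squared-error k-means with ``n_restarts``
    seeded restarts; deterministic given ``seed``.
    """
    if isinstance(frames, PointProcessMovie):
        mask = mask or frames.mask
        ev = frames.events
        if mask is not None:
            x = ev[:, mask.include].astype(np.float64)
        else:
            x = ev.reshape(ev.shape[0], -1).astype(np.float64)
    else:
        x = np.asarray(frames, dtype=np.float64)
        if x.ndim != 2:
            raise ValueError("pattern matrix must be (T, n_features)")
    if x.shape[0] < k:
        raise ValueError(f"{x.shape[0]} frames < k={k} clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    return StateSequence(
        labels + 1,
        k=k,
        window_id=window_id,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def state_visitation_entropy(seq: StateSequence) -> float:
    """H_state in bits: entropy of the state-visitation distribution."""
    counts = np.bincount(seq.labels, minlength=seq.k + 1)[1:]
    return entropy_bits(counts)


def transition_model(seq: StateSequence) -> TransitionModel:
    """k×k first-order transition counts from consecutive label pairs."""
    if len(seq) < 2:
        raise ValueError("need at least 2 frames for transitions")
    counts = np.zeros((seq.k, seq.k), dtype=np.int64)
    np.add.at(counts, (seq.labels[:-1] - 1, seq.labels[1:] - 1), 1)
    return TransitionModel(counts, seq.k)


def transition_entropy(seq: StateSequence, kind: str = "joint") -> float:
    """H_trans in bits from the first-order Markov transition distribution.

    ``kind="joint"`` (default) applies the entropy formula to the joint
    distribution over ordered pairs (i, j), bounded by 2·log2(k);
    ``kind="conditional"`` gives the conditional entropy H(next | current)
    = H_joint − H_marginal, bounded by log2(k).
    """
    tm = transition_model(seq)
    h_joint = entropy_bits(tm.counts)
    if kind == "joint":
        return h_joint
    if kind == "conditional":
        h_from = entropy_bits(tm.counts.sum(axis=1))
        return h_joint - h_from
    raise ValueError("kind must be 'joint' or 'conditional'")


def iter_windows(pp: PointProcessMovie, window_s: float = 50.0):
    """Yield (window_id, PointProcessMovie) slices of fixed duration.

    A trailing partial window shorter than ``window_s`` is dropped.
    """
    n_per = int(round(window_s * pp.frame_rate))
    if n_per < 1:
        raise ValueError("window too short for the frame rate")
    n_win = pp.n_frames // n_per
    for i in range(n_win):
        sl = pp.events[i * n_per : (i + 1) * n_per]
        yield i, PointProcessMovie(
            sl, pp.frame_rate, mask=pp.mask, threshold_sd=pp.threshold_sd,
            meta=dict(pp.meta, window_id=i),
        )
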