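"""Conversion of a preprocessed movie into a binary point process.

A pixel is marked active only at frames where its trace crosses a
threshold of +1 S.D. (per pixel, above the pixel's temporal mean) from
below — i.e. at the upward crossing, not for the whole supra-threshold
excursion.  Because an event requires the previous frame to lie below
threshold, no pixel is ever active on two consecutive frames, and the
representation is invariant to rescaling the movie by any positive
constant.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Mask, PointProcessMovie, VoltageMovie

__all__ = ["to_point_process", "event_rate"]


def to_point_process(
    movie: VoltageMovie, mask: Mask | None = None, threshold_sd: float = 1.0
) -> PointProcessMovie:
    """Mark upward threshold crossings at +``threshold_sd`` per-pixel S.D.

    The threshold for each pixel is ``mean + threshold_sd * S.D.`` of its
    own trace over the analysed sequence.  An event occurs at frame t iff
    ``value(t) >= threshold`` and ``value(t-1) < threshold``; frame 0 is
    never an event.  Zero-variance pixels produce no events (a warning is
    emitted since they usually indicate dead pixels).
    """
    if isinstance(movie, PointProcessMovie):
        raise TypeError("input is already a point process")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    data = movie.data
    vals = np.unique(data)
    if len(vals) <= 2 and np.isin(vals, (0.0, 1.0)).all():
        raise ValueError(
            "movie is binary-valued; refusing to threshold an event movie"
        )
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    flat = sd == 0
    if mask is not None:
        flat = flat & mask.include
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance pixel(s) produce no events",
            RuntimeWarning,
            stacklevel=2,
        )
    thr = mean + threshold_sd * sd
    above = data >= thr
    # sd == 0 pixels satisfy data >= thr identically; suppress them
    above[:, sd == 0] = False
    events = np.zeros_like(above)
    events[1:] = above[1:] & ~above[:-1]
    if mask is not None:
        events &= mask.include
    return PointProcessMovie(
        events,
        movie.frame_rate,
        mask=mask,
        threshold_sd=threshold_sd,
        meta=dict(movie.meta),
    )


def event_rate(pp: PointProcessMovie) -> float:
    """Total event count divided by duration, in events per second."""
    return pp.n_events / pp.duration_s
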