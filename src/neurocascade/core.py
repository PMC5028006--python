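"""Core data containers shared across the pipeline.

The pipeline operates on three kinds of array data:

* :class:`VoltageMovie` — a T×H×W real-valued movie of fractional
  fluorescence change (ΔF/F), the raw input of the analysis.
* :class:`PointProcessMovie` — a T×H×W boolean movie marking, per pixel,
  the frames at which its trace crossed threshold from below.  All
  downstream statistics (cascades, entropies, mutual information) are
  computed from this representation.
* :class:`Mask` — an H×W boolean inclusion map restricting the analysis
  to pixels with adequate signal.

Containers are thin dataclasses around numpy arrays: they validate their
invariants on construction and carry acquisition metadata (frame rate,
optional pixel size) but do not own any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["VoltageMovie", "PointProcessMovie", "Mask"]


@dataclass
class Mask:
    """H×W boolean inclusion map.

    Parameters
    ----------
    include : ndarray of bool, shape (H, W)
        True for pixels included in the analysis.
    provenance : {"manual", "snr", "combined", "full"}
        How the mask was obtained.
    """

    include: np.ndarray
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.include.shape}")
        if not self.include.any():
            raise ValueError("mask excludes every pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.include.shape

    @property
    def n_pixels(self) -> int:
        return int(self.include.sum())

    @classmethod
    def full(cls, height: int, width: int) -> "Mask":
        """All-inclusive mask, used for synthetic data with no bone window."""
        return cls(np.ones((height, width), dtype=bool), provenance="full")


@dataclass
class VoltageMovie:
    """T×H×W real-valued fractional-fluorescence movie.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Fractional fluorescence change per pixel and frame (dimensionless).
        All values must be finite.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_size_um : float, optional
        Edge length of one pixel in micrometres (metadata only).
    meta : dict
        Free-form provenance metadata (preprocessing config hash, seeds...).
    """

    data: np.ndarray
    frame_rate: float
    pixel_size_um: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be T×H×W, got shape {self.data.shape}")
        if self.data.shape[0] < 1 or min(self.data.shape[1:]) < 1:
            raise ValueError("movie dimensions must all be >= 1")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def copy_with(self, data: np.ndarray, **meta) -> "VoltageMovie":
        """New movie with replaced data and updated metadata."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return VoltageMovie(data, self.frame_rate, self.pixel_size_um, new_meta)


@dataclass
class PointProcessMovie:
    """T×H×W boolean movie of threshold-crossing events.

    A pixel is marked active only at frames where its (preprocessed)
    trace crossed the threshold from below, so no pixel is active on two
    consecutive frames.

    Parameters
    ----------
    events : ndarray of bool, shape (T, H, W)
    frame_rate : float
        Hz.
    mask : Mask, optional
        Inclusion map the events were restricted to.
    threshold_sd : float, optional
        Threshold used for the conversion, in per-pixel S.D. units.
    """

    events: np.ndarray
    frame_rate: float
    mask: Optional[Mask] = None
    threshold_sd: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if self.events.ndim != 3:
            raise ValueError(f"events must be T×H×W, got shape {self.events.shape}")
        if self.events.dtype != bool:
            vals = np.unique(self.events)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("events array must be boolean (0/1)")
            self.events = self.events.astype(bool)
        if self.mask is not None:
            if self.mask.shape != self.events.shape[1:]:
                raise ValueError("mask shape does not match event frames")
            if self.events[:, ~self.mask.include].any():
                raise ValueError("events found at masked-out pixels")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.events.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.events.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def n_events(self) -> int:
        return int(self.events.sum())
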