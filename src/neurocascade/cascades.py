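"""Cascade detection and the κ deviation-from-power-law statistic.

A cascade is a spatiotemporally contiguous cluster of point-process
events: two events belong to the same cascade iff they are at most one
frame apart and at the same pixel or at 4-neighbouring pixels.  The
traditional avalanche definition (temporal contiguity only: maximal runs
of consecutive non-empty frames) is provided for comparison.

The size z of a cascade is its number of events (active pixels).  The
shape of the size distribution is summarised by κ: the empirical CDF of
sizes is compared to a discrete truncated power-law reference with
exponent −1.5 at m (default 10) logarithmically spaced sizes, and

    κ = 1 + (1/m) Σ_k [F_ref(β_k) − F_obs(β_k)].

κ ≈ 1 indicates a size distribution close to the scale-free reference;
κ > 1 an excess of large cascades (the empirical CDF lags the
reference); κ < 1 a deficit of large cascades.  κ measures deviation
from the reference; it is not a hypothesis test for power-law form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, special

from .core import PointProcessMovie

__all__ = [
    "Cascade",
    "CascadeSizeSample",
    "ReferenceCDF",
    "detect_cascades",
    "label_cascades",
    "detect_avalanches_temporal",
    "reference_cdf",
    "kappa",
    "kappa_from_cdf_values",
    "regional_kappa",
    "fit_powerlaw_mle",
]


@dataclass
class Cascade:
    """One detected cascade: size, temporal extent and truncation flag."""

    cascade_id: int
    size: int
    t_start: int
    t_end: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cascade size must be >= 1")
        if self.t_end < self.t_start:
            raise ValueError("t_end before t_start")


@dataclass
class CascadeSizeSample:
    """Multiset of cascade sizes z feeding the κ computation."""

    sizes: np.ndarray
    provenance: str = "cortex_wide"
    window_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim != 1:
            raise ValueError("sizes must be 1-D")
        if len(self.sizes) and self.sizes.min() < 1:
            raise ValueError("cascade sizes must be >= 1")

    def __len__(self) -> int:
        return len(self.sizes)


def _structure(connectivity: int) -> np.ndarray:
    """3-D adjacency structure: same spatial footprint at dt = -1, 0, +1."""
    if connectivity == 4:
        plane = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    elif connectivity == 8:
        plane = np.ones((3, 3), dtype=bool)
    else:
        raise ValueError("connectivity must be 4 or 8")
    return np.stack([plane, plane, plane])


def label_cascades(pp: PointProcessMovie, connectivity: int = 4) -> tuple[np.ndarray, int]:
    """Connected-component labels of the event movie (0 = no event)."""
    labels, n = ndimage.label(pp.events, structure=_structure(connectivity))
    return labels.astype(np.int32), int(n)


def _cascades_from_labels(labels: np.ndarray, n: int, t_last: int) -> list[Cascade]:
    if n == 0:
        return []
    tt, yy, xx = np.nonzero(labels)
    labs = labels[tt, yy, xx]
    sizes = np.bincount(labs, minlength=n + 1)[1:]
    t_start = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    t_end = np.full(n + 1, -1, dtype=np.int64)
    np.minimum.at(t_start, labs, tt)
    np.maximum.at(t_end, labs, tt)
    return [
        Cascade(
            cascade_id=i,
            size=int(sizes[i - 1]),
            t_start=int(t_start[i]),
            t_end=int(t_end[i]),
            truncated=(t_start[i] == 0 or t_end[i] == t_last),
        )
        for i in range(1, n + 1)
    ]


def detect_cascades(
    pp: PointProcessMovie,
    connectivity: int = 4,
    drop_truncated: bool = False,
) -> list[Cascade]:
    """Partition events into spatiotemporally contiguous cascades.

    Two events are adjacent iff |Δt| <= 1 and their pixels are identical
    or spatial neighbours (4-connectivity by default, 8 optional).
    Cascades touching the first or last frame are flagged truncated and
    kept unless ``drop_truncated``.
    """
    labels, n = label_cascades(pp, connectivity)
    out = _cascades_from_labels(labels, n, pp.n_frames - 1)
    if drop_truncated:
        out = [c for c in out if not c.truncated]
    return out


def detect_avalanches_temporal(pp: PointProcessMovie) -> list[Cascade]:
    """Traditional avalanches: maximal runs of consecutive non-empty frames.

    All events within one run form a single avalanche regardless of
    spatial position; its size is the total event count of the run.
    """
    per_frame = pp.events.reshape(pp.n_frames, -1).sum(axis=1)
    active = per_frame > 0
    if not active.any():
        return []
    padded = np.concatenate([[False], active, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0] - 1
    out = []
    for i, (a, b) in enumerate(zip(starts, ends), start=1):
        out.append(
            Cascade(
                cascade_id=i,
                size=int(per_frame[a : b + 1].sum()),
                t_start=int(a),
                t_end=int(b),
                truncated=(a == 0 or b == pp.n_frames - 1),
            )
        )
    return out


def sizes_of(cascades: Sequence[Cascade], **kw) -> CascadeSizeSample:
    """Collect cascade sizes into a sample."""
    return CascadeSizeSample(np.array([c.size for c in cascades], dtype=np.int64), **kw)


__all__.append("sizes_of")


@dataclass
class ReferenceCDF:
    """Discrete truncated power-law reference CDF on integer sizes [z_min, z_max].

    F(z) = Σ_{s=z_min..floor(z)} s^exponent / Σ_{s=z_min..z_max} s^exponent.
    """

    z_min: int
    z_max: int
    exponent: float = -1.5
    _cdf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.z_min < self.z_max:
            raise ValueError("need 1 <= z_min < z_max")
        support = np.arange(self.z_min, self.z_max + 1, dtype=np.float64)
        weights = support**self.exponent
        self._cdf = np.cumsum(weights) / weights.sum()

    def __call__(self, z) -> np.ndarray:
        """F(z) for scalar or array z (0 below z_min, 1 at/above z_max)."""
        z = np.asarray(z, dtype=float)
        idx = np.clip(np.floor(z).astype(np.int64) - self.z_min, -1, self.z_max - self.z_min)
        out = np.where(idx < 0, 0.0, self._cdf[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def ppf(self, q) -> np.ndarray:
        """Smallest integer z with F(z) >= q (inverse CDF for sampling)."""
        q = np.asarray(q, dtype=float)
        idx = np.searchsorted(self._cdf, q, side="left")
        idx = np.clip(idx, 0, self.z_max - self.z_min)
        out = idx + self.z_min
        return out if out.ndim else int(out)


def reference_cdf(z_min: int, z_max: int, exponent: float = -1.5) -> ReferenceCDF:
    """Construct the truncated power-law reference CDF."""
    return ReferenceCDF(z_min, z_max, exponent)


def _evaluation_points(z_min: int, z_max: int, m: int, spacing: str) -> np.ndarray:
    if spacing == "log":
        return np.logspace(np.log10(z_min), np.log10(z_max), m)
    if spacing == "linear":
        return np.linspace(z_min, z_max, m)
    raise ValueError("spacing must be 'log' or 'linear'")


def kappa_from_cdf_values(f_ref: np.ndarray, f_obs: np.ndarray) -> float:
    """κ = 1 + mean(F_ref − F_obs) over the evaluation points."""
    f_ref = np.asarray(f_ref, dtype=float)
    f_obs = np.asarray(f_obs, dtype=float)
    if f_ref.shape != f_obs.shape:
        raise ValueError("CDF value arrays must have equal shape")
    return float(1.0 + np.mean(f_ref - f_obs))


def kappa(
    sample: CascadeSizeSample | np.ndarray,
    exponent: float = -1.5,
    m: int = 10,
    spacing: str = "log",
) -> float:
    """κ statistic of a cascade-size sample against the power-law reference.

    The reference is the discrete truncated power law on the observed
    size range [min, max]; the empirical and reference CDFs are compared
    at ``m`` logarithmically spaced sizes.  Requires at least two
    distinct sizes (otherwise the size range is degenerate).
    """
    sizes = sample.sizes if isinstance(sample, CascadeSizeSample) else np.asarray(sample)
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.size == 0:
        raise ValueError("empty cascade-size sample")
    z_min, z_max = int(sizes.min()), int(sizes.max())
    if z_min == z_max:
        raise ValueError(
            f"all {sizes.size} cascade sizes equal {z_min}; κ undefined on a "
            "degenerate size range"
        )
    ref = ReferenceCDF(z_min, z_max, exponent)
    beta = _evaluation_points(z_min, z_max, m, spacing)
    sorted_sizes = np.sort(sizes)
    f_obs = np.searchsorted(sorted_sizes, np.floor(beta), side="right") / sizes.size
    return kappa_from_cdf_values(ref(beta), f_obs)


def regional_kappa(
    pp: PointProcessMovie,
    grid,
    exponent: float = -1.5,
    m: int = 10,
    connectivity: int = 4,
    min_cascades: int = 10,
) -> dict[int, dict]:
    """κ from cascades detected within each region of a RegionGrid.

    Cascade detection is re-run on the point process restricted to each
    region's pixels (a cortex-wide cascade contributes only its events
    inside the region).  Regions with fewer than ``min_cascades``
    cascades or without two distinct sizes get ``kappa = nan`` and a
    reason string.
    """
    out: dict[int, dict] = {}
    for region in grid.regions:
        y0, x0 = region.origin
        s = grid.region_size
        sub = PointProcessMovie(
            pp.events[:, y0 : y0 + s, x0 : x0 + s], pp.frame_rate
        )
        cascades = detect_cascades(sub, connectivity=connectivity)
        entry: dict = {"n_cascades": len(cascades), "kappa": np.nan, "reason": None}
        if len(cascades) < min_cascades:
            entry["reason"] = f"only {len(cascades)} cascades (< {min_cascades})"
        else:
            sizes = np.array([c.size for c in cascades])
            if np.unique(sizes).size < 2:
                entry["reason"] = "all cascade sizes identical"
            else:
                entry["kappa"] = kappa(sizes, exponent=exponent, m=m)
        out[region.region_id] = entry
    return out


def fit_powerlaw_mle(
    sizes: np.ndarray, z_min: int = 1, z_max: int | None = None
) -> float:
    """Maximum-likelihood exponent of a discrete power law P(z) ∝ z^−α.

    Fits sizes >= ``z_min`` (optionally truncated at ``z_max``) by
    maximising the discrete power-law likelihood; the normalisation uses
    the Hurwitz zeta function for the untruncated case.  Returns the
    signed exponent (e.g. −1.5).  Intended as a simulator-validation
    utility, not a power-law hypothesis test.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    sizes = sizes[sizes >= z_min]
    if z_max is not None:
        sizes = sizes[sizes <= z_max]
    if sizes.size < 10:
        raise ValueError(f"too few sizes ({sizes.size}) above z_min for a fit")
    sum_log = np.log(sizes).sum()
    n = sizes.size

    if z_max is None:
        def nll(alpha: float) -> float:
            return alpha * sum_log / n + np.log(special.zeta(alpha, z_min))
        lo, hi = 1.0 + 1e-6, 6.0
    else:
        support = np.arange(z_min, z_max + 1, dtype=np.float64)
        log_support = np.log(support)

        def nll(alpha: float) -> float:
            return alpha * sum_log / n + special.logsumexp(-alpha * log_support)
        lo, hi = 1e-6, 6.0

    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    if not res.success:
        raise RuntimeError("power-law MLE failed to converge")
    return float(-res.x)
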