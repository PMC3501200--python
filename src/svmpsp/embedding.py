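"""Feature-space embedding of spike patterns.

A pattern with spike times ``t_ij`` (neuron i, spike j) is mapped through a
PSP kernel ``k`` to the N-dimensional trajectory

    f(t) = (f_1(t), ..., f_N(t)),   f_i(t) = sum_j k(t - t_ij),

i.e. component ``i`` is the kernel-convolved spike train of input neuron
``i``.  Sampled on a time grid, the trajectory becomes a cloud of candidate
points for linear separation; its dot product with a synaptic weight vector
is exactly the membrane voltage of the leaky integrate-and-fire readout
(minus the resting potential).

For piecewise-linear kernels (RC, single exponential, triangular, square)
the trajectory is a chain of straight segments and only the kink points
need to be sampled (``kink_trajectory``); for the RC kernel that is two
points per presynaptic spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .kernels import KernelSpec, kink_times
from .patterns import SpikePattern

__all__ = [
    "Trajectory",
    "Rescaler",
    "embed",
    "sample_grid",
    "kink_trajectory",
    "fit_rescaler",
    "apply_rescaler",
]


@dataclass
class Trajectory:
    """Time-stamped feature points ``f(t_l)`` of one embedded pattern."""

    times: np.ndarray  # (L,)
    points: np.ndarray  # (L, N)
    label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] != self.times.shape[0]:
            raise ValueError(
                f"points shape {self.points.shape} inconsistent with "
                f"{self.times.shape[0]} sample times"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def n_dim(self) -> int:
        return self.points.shape[1]

    def to_frame(self):
        """Trajectory as a pandas DataFrame (time column + one per neuron)."""
        import pandas as pd

        cols = {"time_ms": self.times}
        for i in range(self.n_dim):
            cols[f"f{i}"] = self.points[:, i]
        return pd.DataFrame(cols)


def sample_grid(t_start: float, t_end: float, dt: float) -> np.ndarray:
    """Arithmetic grid ``t_start, t_start + dt, ...`` not exceeding ``t_end``."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not t_end > t_start:
        raise ValueError(f"require t_end > t_start, got [{t_start}, {t_end}]")
    n = int(np.floor((t_end - t_start) / dt + 1e-9))
    return t_start + dt * np.arange(n + 1)


def embed(p: SpikePattern, spec: KernelSpec, times: Sequence[float]) -> Trajectory:
    """Embed a pattern: point ``l``, dimension ``i`` is ``sum_j k(t_l - t_ij)``."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be nonempty")
    points = np.zeros((times.size, p.n_neurons))
    for i, spikes in enumerate(p.spikes):
        if spikes.size == 0:
            continue
        # (L, n_spikes) lags; causal kernel zeroes the negative lags
        lags = times[:, None] - spikes[None, :]
        points[:, i] = spec(lags).sum(axis=1)
    return Trajectory(times, points, label=p.label)


def kink_trajectory(
    p: SpikePattern, spec: KernelSpec, include_start: bool = True
) -> Trajectory:
    """Trajectory sampled only at kink times of the piecewise-linear kernel.

    ``t = 0`` is prepended (unless already a kink) so every trajectory has a
    defined start point; between consecutive kinks any linear functional of
    the trajectory is monotone, so the kink samples carry the full
    information needed for separation and for threshold crossing.
    """
    all_times = kink_times(p.all_times(), spec)
    if include_start:
        all_times = np.unique(np.concatenate([[0.0], all_times]))
    if all_times.size == 0:
        return Trajectory(np.empty(0), np.empty((0, p.n_neurons)), label=p.label)
    return embed(p, spec, all_times)


class Rescaler(TransformerMixin, BaseEstimator):
    """Per-dimension affine map sending the reference min/max to 0/1.

    Fit on the union of all training points, then reused unchanged on test
    points (which may therefore leave [0, 1]).  A constant dimension maps
    to 0 everywhere, keeping silent neurons inert.
    """

    def fit(self, X, y=None) -> "Rescaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("reference point set must be a nonempty 2-D array")
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        rng = self.max_ - self.min_
        self.scale_ = np.where(rng > 0, 1.0 / np.where(rng > 0, rng, 1.0), 0.0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.min_) * self.scale_

    def transform_trajectory(self, traj: Trajectory) -> Trajectory:
        return Trajectory(traj.times, self.transform(traj.points), label=traj.label)


def fit_rescaler(points: Iterable[np.ndarray] | np.ndarray) -> Rescaler:
    """Fit a :class:`Rescaler` on a point set or a collection of point sets."""
    if isinstance(points, np.ndarray):
        X = points
    else:
        parts = [np.asarray(p, dtype=float) for p in points]
        X = np.vstack(parts) if parts else np.empty((0, 0))
    return Rescaler().fit(X)


def apply_rescaler(r: Rescaler, points) -> np.ndarray:
    return r.transform(points)
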