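"""Pattern separability as a function of PSP kernel dynamics.

How well two spike patterns can be told apart depends on the kernel's time
constant relative to the pattern period, ``nu = tau / T``.  For very fast
kernels (small ``nu``) trajectories hug the asynchrony corners of feature
space and overlap heavily; for very slow kernels they all collapse onto
the synchrony direction ``f_s = (1, ..., 1)``.  Separability — the
normalized max-margin ``D_N`` of the single-target sweep — therefore rises
from zero, and for pulse-like kernels (alpha, double exponential) falls
again after a peak at intermediate ``nu``; the single exponential instead
keeps rising, because its step-like onset carries the trajectory from
corner to corner rather than along the diagonal.

``synchrony_deviation`` (``L_s``) is the largest per-time standard
deviation of the trajectory components, i.e. the (scaled) maximal distance
from the synchrony line; its peak over ``nu`` tracks the separability peak
and is far cheaper to compute.

The default ``nu`` grid is log-spaced over roughly tau = 0.25..66 ms (for
the 10-ms scan period) and contains the EPSP-matched reference value
``nu = 1.3`` as an exact grid point, so peak locations can be compared to
it without interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import Trajectory, embed, fit_rescaler, sample_grid
from .kernels import BIO_MIMETIC_RISE_RATIO, KernelSpec
from .patterns import BACKGROUND, TARGET, generate_constant_isi
from .separation import train_single_target

__all__ = [
    "ScanResult",
    "synchrony_deviation",
    "default_nu_grid",
    "separability_scan",
    "peak_nu",
]

#: Reference kernel-to-period ratio of the EPSP-fitted kernel.
NU_REFERENCE = 1.3


def synchrony_deviation(traj: Trajectory) -> float:
    """``L_s``: max over sample times of the std of the N components.

    Zero iff the trajectory lies on the synchrony line (all components
    equal) at every sample time.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    return float(np.max(np.std(traj.points, axis=1)))


def default_nu_grid(n_points: int = 25, nu_min: float = 0.025) -> np.ndarray:
    """Log-spaced ``nu`` grid anchored so that ``nu = 1.3`` is a grid point."""
    ratio = (NU_REFERENCE / nu_min) ** (1.0 / 17.0)
    return nu_min * ratio ** np.arange(n_points)


@dataclass
class ScanResult:
    """Trial-averaged separability curve over the ``nu`` grid."""

    nus: np.ndarray
    mean_dn: np.ndarray
    sd_dn: np.ndarray
    mean_ls: np.ndarray
    family: str
    n_neurons: int
    n_targets: int
    n_backgrounds: int
    n_trials: int
    period: float
    dn: np.ndarray = field(repr=False, default=None)  # (n_nu, n_trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nu": self.nus,
                "tau_ms": self.nus * self.period,
                "mean_DN": self.mean_dn,
                "sd_DN": self.sd_dn,
                "mean_Ls": self.mean_ls,
                "n_trials": self.n_trials,
            }
        )


def _scan_spec(family: str, tau: float, tau_r_ratio: float) -> KernelSpec:
    if family in ("double_exp", "rc"):
        return KernelSpec(family, tau=tau, tau_r=tau_r_ratio * tau)
    return KernelSpec(family, tau=tau)


def separability_scan(
    family: str = "double_exp",
    nus: np.ndarray | None = None,
    n_neurons: int = 32,
    n_backgrounds: int = 1,
    n_trials: int = 10,
    period: float = 10.0,
    dt: float = 0.1,
    tau_r_ratio: float = BIO_MIMETIC_RISE_RATIO,
    seed=None,
) -> ScanResult:
    """Measure mean/sd of ``D_N`` and mean ``L_s`` over a ``nu`` grid.

    Per trial, one target and ``n_backgrounds`` background constant-ISI
    patterns are drawn on ``[0, period]``; per ``nu``, they are embedded
    with ``tau = nu * period`` on the window ``[0, tau + period]`` at
    resolution ``dt``, rescaled to the unit hypercube, and separated by the
    max-margin candidate sweep.  The same trial reuses the same pattern
    draw at every ``nu`` (common random numbers), so the curve over ``nu``
    is measured on identical task instances; trials are independent.
    """
    nus = default_nu_grid() if nus is None else np.asarray(nus, dtype=float)
    if np.any(nus <= 0):
        raise ValueError("nu values must be > 0")
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(n_trials)

    dn = np.empty((nus.size, n_trials))
    ls = np.empty((nus.size, n_trials))
    for j, nu in enumerate(nus):
        tau = nu * period
        spec = _scan_spec(family, tau, tau_r_ratio)
        times = sample_grid(0.0, tau + period, dt)
        for i in range(n_trials):
            rng = np.random.default_rng(trial_seeds[i])
            target = generate_constant_isi(n_neurons, 0.0, period, rng, label=TARGET)
            bgs = [
                generate_constant_isi(n_neurons, 0.0, period, rng, label=BACKGROUND)
                for _ in range(n_backgrounds)
            ]
            t_traj = embed(target, spec, times)
            b_trajs = [embed(p, spec, times) for p in bgs]
            rescaler = fit_rescaler(
                [t_traj.points] + [b.points for b in b_trajs]
            )
            t_scaled = rescaler.transform_trajectory(t_traj)
            b_scaled = [rescaler.transform_trajectory(b) for b in b_trajs]
            res = train_single_target(t_scaled, b_scaled)
            dn[j, i] = res.margin_normalized
            ls[j, i] = synchrony_deviation(t_scaled)
    return ScanResult(
        nus=nus,
        mean_dn=dn.mean(axis=1),
        sd_dn=dn.std(axis=1, ddof=1) if n_trials > 1 else np.zeros(nus.size),
        mean_ls=ls.mean(axis=1),
        family=family,
        n_neurons=n_neurons,
        n_targets=1,
        n_backgrounds=n_backgrounds,
        n_trials=n_trials,
        period=period,
        dn=dn,
    )


def peak_nu(scan: ScanResult, measure: str = "dn") -> float:
    """Grid arg-max of the trial-averaged curve; ties go to the smaller nu.

    ``measure='dn'`` locates the separability peak directly; ``'ls'`` uses
    the synchrony-deviation curve instead — the cheap surrogate whose peak
    coincides with the separability peak and is far less noisy around the
    flat top (the recommended way to fix a kernel's time constant).
    """
    if scan.nus.size == 0:
        raise ValueError("scan is empty")
    if measure == "dn":
        curve = scan.mean_dn
    elif measure == "ls":
        curve = scan.mean_ls
    else:
        raise ValueError("measure must be 'dn' or 'ls'")
    return float(scan.nus[int(np.argmax(curve))])
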