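"""Postsynaptic-potential (PSP) kernel families.

A presynaptic spike at time ``t_s`` deflects the membrane potential of the
readout neuron by ``w * k(t - t_s)`` where ``k`` is a causal kernel
(``k(t) = 0`` for ``t < 0``).  The kernel families implemented here fall in
two groups:

* *curved* kernels — the alpha function and the double exponential (the
  "bio-mimetic" kernel when the rise constant is ``0.09 τ``, fitted to a
  cortical EPSP) — which trace curved trajectories in feature space and
  need dense time sampling;
* *piecewise-linear* kernels — single exponential, triangular, square and
  the RC kernel (an RC circuit charged by a current pulse of duration
  ``T_pulse``) — whose feature-space trajectories are piecewise straight,
  so only the derivative-discontinuity times ("kinks") matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "KernelSpec",
    "FAMILIES",
    "PIECEWISE_LINEAR_FAMILIES",
    "eval_kernel",
    "pulse_duration",
    "kink_times",
    "bio_mimetic",
    "rc_kernel",
]

FAMILIES = ("single_exp", "alpha", "double_exp", "rc", "triangular", "square")

#: Families whose trajectories are piecewise straight lines between kinks.
PIECEWISE_LINEAR_FAMILIES = frozenset({"rc", "single_exp", "triangular", "square"})

#: Rise/decay ratio of the EPSP-fitted double exponential, tau_r = 0.09 tau.
BIO_MIMETIC_RISE_RATIO = 0.09


def pulse_duration(tau: float, tau_r: float) -> float:
    """Peak time of the double exponential ``e^{-t/tau} - e^{-t/tau_r}``.

    ``T_pulse = tau * tau_r * log(tau / tau_r) / (tau - tau_r)``.  This is
    also the charging-pulse duration that makes the RC kernel peak where
    the matching double exponential peaks.
    """
    if not 0 < tau_r < tau:
        raise ValueError(f"require 0 < tau_r < tau, got tau={tau}, tau_r={tau_r}")
    return tau * tau_r * math.log(tau / tau_r) / (tau - tau_r)


@dataclass(frozen=True)
class KernelSpec:
    """A PSP kernel family with its time constants (ms).

    Parameters
    ----------
    family : one of ``FAMILIES``.
    tau : decay time constant, ms (> 0).
    tau_r : rise time constant, ms (double_exp and rc only; 0 < tau_r < tau).
    t_pulse : RC charging-pulse duration, ms.  For ``rc`` it defaults to
        ``pulse_duration(tau, tau_r)``; if neither ``tau_r`` nor ``t_pulse``
        is given, ``tau_r = 0.09 tau`` so the RC kernel is the drop-in
        substitute for the bio-mimetic double exponential.
    """

    family: str
    tau: float
    tau_r: float | None = None
    t_pulse: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.family in ("double_exp", "rc"):
            tau_r = self.tau_r
            if self.family == "rc" and tau_r is None and self.t_pulse is None:
                tau_r = BIO_MIMETIC_RISE_RATIO * self.tau
                object.__setattr__(self, "tau_r", tau_r)
            if tau_r is not None and not 0 < tau_r < self.tau:
                raise ValueError(
                    f"require 0 < tau_r < tau, got tau_r={tau_r}, tau={self.tau}"
                )
            if self.family == "double_exp" and tau_r is None:
                raise ValueError("double_exp requires tau_r")
            if self.family == "rc" and self.t_pulse is None:
                object.__setattr__(self, "t_pulse", pulse_duration(self.tau, tau_r))
        if self.family == "rc" and not self.t_pulse > 0:
            raise ValueError(f"t_pulse must be > 0, got {self.t_pulse}")

    # -- evaluation ----------------------------------------------------

    def __call__(self, t) -> np.ndarray:
        return eval_kernel(self, t)

    @property
    def is_piecewise_linear(self) -> bool:
        return self.family in PIECEWISE_LINEAR_FAMILIES

    @property
    def peak_time(self) -> float:
        """Time at which the kernel attains its maximum."""
        if self.family == "single_exp" or self.family == "square":
            return 0.0
        if self.family == "alpha":
            return self.tau
        if self.family == "triangular":
            return self.tau
        if self.family == "double_exp":
            return pulse_duration(self.tau, self.tau_r)
        return self.t_pulse  # rc

    # -- serialization -------------------------------------------------

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "tau_ms": self.tau,
            "tau_r_ms": self.tau_r,
            "t_pulse_ms": self.t_pulse,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "KernelSpec":
        return cls(
            family=obj["family"],
            tau=obj["tau_ms"],
            tau_r=obj.get("tau_r_ms"),
            t_pulse=obj.get("t_pulse_ms"),
        )


def bio_mimetic(tau: float = 23.0) -> KernelSpec:
    """EPSP-fitted double exponential with ``tau_r = 0.09 tau``."""
    return KernelSpec("double_exp", tau=tau, tau_r=BIO_MIMETIC_RISE_RATIO * tau)


def rc_kernel(tau: float, tau_r: float | None = None) -> KernelSpec:
    """RC-circuit kernel whose pulse ends at the matching double-exp peak."""
    return KernelSpec("rc", tau=tau, tau_r=tau_r)


def eval_kernel(spec: KernelSpec, t) -> np.ndarray:
    """Evaluate the kernel at time(s) ``t`` (ms); 0 for ``t < 0``.

    Family formulas (t >= 0):

    - ``single_exp``:  exp(-t/tau)
    - ``alpha``:       (t/tau) exp(-t/tau)
    - ``double_exp``:  exp(-t/tau) - exp(-t/tau_r)
    - ``rc``:          1 - exp(-t/tau) while the pulse is on (t <= t_pulse),
      then (1 - exp(-t_pulse/tau)) exp(-(t - t_pulse)/tau)
    - ``triangular``:  rises 0 -> 1 over [0, tau], falls 1 -> 0 over [tau, 2 tau]
    - ``square``:      1 on [0, tau], else 0
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    tau = spec.tau
    if spec.family == "single_exp":
        out[pos] = np.exp(-tp / tau)
    elif spec.family == "alpha":
        out[pos] = (tp / tau) * np.exp(-tp / tau)
    elif spec.family == "double_exp":
        out[pos] = np.exp(-tp / tau) - np.exp(-tp / spec.tau_r)
    elif spec.family == "rc":
        t_pulse = spec.t_pulse
        charging = tp <= t_pulse
        vals = np.empty_like(tp)
        vals[charging] = 1.0 - np.exp(-tp[charging] / tau)
        peak = 1.0 - math.exp(-t_pulse / tau)
        vals[~charging] = peak * np.exp(-(tp[~charging] - t_pulse) / tau)
        out[pos] = vals
    elif spec.family == "triangular":
        rise = tp <= tau
        fall = (tp > tau) & (tp <= 2 * tau)
        vals = np.zeros_like(tp)
        vals[rise] = tp[rise] / tau
        vals[fall] = 2.0 - tp[fall] / tau
        out[pos] = vals
    elif spec.family == "square":
        out[pos] = (tp <= tau).astype(float)
    return out[0] if scalar else out


def kink_times(spikes: Iterable[float], spec: KernelSpec) -> np.ndarray:
    """Derivative-discontinuity times of the summed-kernel response.

    Between consecutive kinks every feature component has the form
    ``A + B e^{-t/tau}`` (or is affine, for triangular/square), so a linear
    functional of the trajectory is monotone there and attains its extrema
    at kink times.  Per family:

    - ``rc``:          spike times and spike times + t_pulse (2 per spike)
    - ``single_exp``:  spike times (the trajectory decays along a ray
      toward the origin between spikes)
    - ``square``:      spike times and spike times + tau
    - ``triangular``:  spike times, + tau, + 2 tau

    Duplicates are removed; the result is sorted.
    """
    if not spec.is_piecewise_linear:
        raise ValueError(
            f"kernel family {spec.family!r} is curved; kink sampling applies "
            f"only to {sorted(PIECEWISE_LINEAR_FAMILIES)}"
        )
    s = np.asarray(list(spikes), dtype=float)
    if s.size == 0:
        return np.empty(0)
    if spec.family == "rc":
        times = np.concatenate([s, s + spec.t_pulse])
    elif spec.family == "single_exp":
        times = s
    elif spec.family == "square":
        times = np.concatenate([s, s + spec.tau])
    else:  # triangular
        times = np.concatenate([s, s + spec.tau, s + 2 * spec.tau])
    return np.unique(times)
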