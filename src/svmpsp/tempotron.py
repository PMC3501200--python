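"""Tempotron baselines: the original discrete rule and a voltage-margin variant.

The Tempotron trains the same LIF readout as the max-margin method, but by
error-driven weight updates instead of an explicit margin optimization.
With membrane voltage

    V(t) = V_rest + sum_i w_i sum_j k(t - t_ij),

a training cycle visits every pattern: a target whose voltage maximum
stays below threshold gets ``w += lambda * f(t_max)``; a background whose
maximum reaches threshold gets ``w -= lambda * f(t_max)`` (``f`` is the
kernel-embedded feature vector, so one update is an exact vector step of
size ``lambda`` along the trajectory point at the voltage peak).  Training
stops at the first cycle with no updates — i.e. as soon as *any*
separating weight vector is found, with no attempt to optimize it.

The voltage-margin variant re-runs the rule against the stricter
thresholds ``theta + M_V`` (targets) and ``theta - M_V`` (backgrounds),
raising ``M_V`` in fixed steps each time a separation is found and
stopping after ``patience`` consecutive cycles without one.  The number of
weight vectors it evaluates along the way is used elsewhere as the
evaluation budget for the genetic search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .embedding import embed, sample_grid
from .kernels import KernelSpec
from .patterns import SpikePattern
from .separation import SynapticWeights, _coerce_patterns

__all__ = [
    "TempotronConfig",
    "TempotronResult",
    "membrane_voltage",
    "tempotron_update",
    "tempotron_train",
    "vm_tempotron_train",
    "TempotronClassifier",
    "VoltageMarginTempotronClassifier",
]


@dataclass
class TempotronConfig:
    """Training parameters; defaults follow the common benchmark setting."""

    lambda_: float = 0.1  # learning rate
    theta: float = 1.0  # firing threshold
    v_rest: float = 0.0  # resting potential
    max_cycles: int = 10_000  # cycle cap for the original rule
    margin_step: float = 0.01  # voltage-margin increment Delta_MV
    patience: int = 100  # consecutive failed cycles before stopping

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if self.margin_step <= 0:
            raise ValueError("margin_step must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TempotronResult:
    weights: SynapticWeights
    converged: bool
    n_cycles: int
    n_hyperplanes: int  # weight vectors evaluated (initial + one per update)
    margin: float = 0.0  # achieved voltage margin (voltage-margin rule only)


def membrane_voltage(
    p: SpikePattern,
    w: SynapticWeights | np.ndarray,
    spec: KernelSpec,
    times: Sequence[float],
) -> np.ndarray:
    """LIF voltage trace ``V(t_l) = V_rest + sum_i w_i sum_j k(t_l - t_ij)``."""
    if isinstance(w, SynapticWeights):
        vec, v_rest = w.w, w.v_rest
    else:
        vec, v_rest = np.asarray(w, dtype=float), 0.0
    traj = embed(p, spec, times)
    return traj.points @ vec + v_rest


def tempotron_update(
    w: np.ndarray, f_at_tmax: np.ndarray, direction: int, lambda_: float
) -> np.ndarray:
    """One weight step ``w' = w + direction * lambda * f(t_max)``.

    ``direction = +1`` for a missed target, ``-1`` for a false-positive
    background.
    """
    return np.asarray(w, dtype=float) + direction * lambda_ * np.asarray(f_at_tmax)


def _argmax_time(v: np.ndarray, M: np.ndarray) -> int:
    """Voltage arg-max; exact ties go to the strongest-drive sample.

    With zero initial weights the voltage trace is flat: every sample ties,
    and updating at one where ``f = 0`` (before the first spike) would be a
    no-op forever.  Among tied maxima the sample with the largest input
    drive ``||f||^2`` is used (earliest such sample if that also ties),
    which bootstraps the rule at the trajectory peak instead of biasing all
    weights onto the earliest-firing neurons.
    """
    m = v.max()
    ties = np.flatnonzero(v == m)
    if ties.size == 1:
        return int(ties[0])
    drive = np.einsum("ij,ij->i", M[ties], M[ties])
    return int(ties[int(np.argmax(drive))])


def _run_cycles(
    w: np.ndarray,
    target_mats: list[np.ndarray],
    bg_mats: list[np.ndarray],
    theta_pos: float,
    theta_neg: float,
    lambda_: float,
    v_rest: float,
    max_cycles: int,
) -> tuple[np.ndarray, bool, int, int]:
    """Run training cycles in place until a clean (update-free) cycle.

    Patterns are visited in fixed order, targets first; the arg-max time of
    the voltage breaks ties to the earliest sample.  Returns
    (weights, converged, cycles_run, updates_made).
    """
    updates_total = 0
    for cycle in range(1, max_cycles + 1):
        updates = 0
        for M in target_mats:
            v = M @ w + v_rest
            if v.max() < theta_pos:
                w = w + lambda_ * M[_argmax_time(v, M)]
                updates += 1
        for M in bg_mats:
            v = M @ w + v_rest
            if v.max() >= theta_neg:
                w = w - lambda_ * M[_argmax_time(v, M)]
                updates += 1
        updates_total += updates
        if updates == 0:
            return w, True, cycle, updates_total
    return w, False, max_cycles, updates_total


def _embed_matrices(
    patterns: Sequence[SpikePattern], spec: KernelSpec, times
) -> list[np.ndarray]:
    return [embed(p, spec, times).points for p in patterns]


def tempotron_train(
    targets: Sequence[SpikePattern],
    backgrounds: Sequence[SpikePattern],
    spec: KernelSpec,
    cfg: TempotronConfig | None = None,
    times: Sequence[float] | None = None,
) -> TempotronResult:
    """Original rule: train from ``w = 0`` until the stop condition holds.

    Converged means every target's voltage maximum is >= theta and every
    background's stays < theta on the training grid.
    """
    cfg = cfg or TempotronConfig()
    times = sample_grid(0.0, 40.0, 0.1) if times is None else np.asarray(times)
    tmats = _embed_matrices(targets, spec, times)
    bmats = _embed_matrices(backgrounds, spec, times)
    n = targets[0].n_neurons if targets else backgrounds[0].n_neurons
    w, converged, cycles, updates = _run_cycles(
        np.zeros(n), tmats, bmats, cfg.theta, cfg.theta,
        cfg.lambda_, cfg.v_rest, cfg.max_cycles,
    )
    return TempotronResult(
        SynapticWeights(w, theta=cfg.theta, v_rest=cfg.v_rest),
        converged, cycles, 1 + updates,
    )


def vm_tempotron_train(
    targets: Sequence[SpikePattern],
    backgrounds: Sequence[SpikePattern],
    spec: KernelSpec,
    cfg: TempotronConfig | None = None,
    times: Sequence[float] | None = None,
) -> TempotronResult:
    """Voltage-margin rule: push the margin up in ``margin_step`` increments.

    Starting at ``M_V = 0`` and from the current weights at each level, the
    plain rule runs against thresholds ``theta + M_V`` / ``theta - M_V``.
    Each separation found raises the margin by one step; ``patience``
    consecutive cycles without a separation end the search.  Returns the
    last *successful* margin and its weights; ``converged`` is False only
    when not even ``M_V = 0`` was separated.
    """
    cfg = cfg or TempotronConfig()
    times = sample_grid(0.0, 40.0, 0.1) if times is None else np.asarray(times)
    tmats = _embed_matrices(targets, spec, times)
    bmats = _embed_matrices(backgrounds, spec, times)
    n = targets[0].n_neurons if targets else backgrounds[0].n_neurons

    # Phase 1: the plain rule must first separate at M_V = 0; the patience
    # rule only decides whether a *broader* margin is still reachable.
    w, converged0, cycles_total, updates_total = _run_cycles(
        np.zeros(n), tmats, bmats, cfg.theta, cfg.theta,
        cfg.lambda_, cfg.v_rest, cfg.max_cycles,
    )
    best: tuple[float, np.ndarray] | None = (0.0, w.copy()) if converged0 else None
    margin = cfg.margin_step if converged0 else 0.0
    failures = 0
    while best is not None and failures < cfg.patience and margin <= cfg.theta:
        w, converged, cycles, updates = _run_cycles(
            w, tmats, bmats, cfg.theta + margin, cfg.theta - margin,
            cfg.lambda_, cfg.v_rest, max_cycles=1,
        )
        updates_total += updates
        cycles_total += cycles
        if converged:
            best = (margin, w.copy())
            margin = round(margin + cfg.margin_step, 12)
            failures = 0
        else:
            failures += 1
    if best is None:
        return TempotronResult(
            SynapticWeights(w, theta=cfg.theta, v_rest=cfg.v_rest),
            False, cycles_total, 1 + updates_total, margin=0.0,
        )
    m, w_best = best
    return TempotronResult(
        SynapticWeights(w_best, theta=cfg.theta, v_rest=cfg.v_rest),
        True, cycles_total, 1 + updates_total, margin=m,
    )


# ----------------------------------------------------------------------
# Estimators
# ----------------------------------------------------------------------


class TempotronClassifier(ClassifierMixin, BaseEstimator):
    """LIF detector trained with the original Tempotron rule.

    Shares the kernel/grid parameters of
    :class:`~svmpsp.separation.SVMPSPClassifier`; training starts from zero
    weights and stops at the first separating weight vector.

    Attributes: ``weights_`` (:class:`SynapticWeights`), ``converged_``,
    ``n_cycles_``, ``n_hyperplanes_``.
    """

    def __init__(
        self,
        kernel: str | KernelSpec = "double_exp",
        tau: float = 1.5,
        tau_r: float | None = 1.0,
        t_pulse: float | None = None,
        dt: float = 0.1,
        t_start: float = 0.0,
        t_end: float = 40.0,
        lambda_: float = 0.1,
        theta: float = 1.0,
        v_rest: float = 0.0,
        max_cycles: int = 10_000,
    ):
        self.kernel = kernel
        self.tau = tau
        self.tau_r = tau_r
        self.t_pulse = t_pulse
        self.dt = dt
        self.t_start = t_start
        self.t_end = t_end
        self.lambda_ = lambda_
        self.theta = theta
        self.v_rest = v_rest
        self.max_cycles = max_cycles

    def _spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel
        kwargs = {}
        if self.kernel in ("double_exp", "rc"):
            kwargs["tau_r"] = self.tau_r
        if self.kernel == "rc":
            kwargs["t_pulse"] = self.t_pulse
        return KernelSpec(self.kernel, tau=self.tau, **kwargs)

    def _config(self) -> TempotronConfig:
        return TempotronConfig(
            lambda_=self.lambda_, theta=self.theta, v_rest=self.v_rest,
            max_cycles=self.max_cycles,
        )

    def _train(self, targets, backgrounds) -> TempotronResult:
        return tempotron_train(
            targets, backgrounds, self.spec_, self._config(), self.times_
        )

    def fit(self, X, y=None) -> "TempotronClassifier":
        patterns, labels = _coerce_patterns(X, y)
        targets = [p for p, l in zip(patterns, labels) if l == 1]
        backgrounds = [p for p, l in zip(patterns, labels) if l == 0]
        if not targets or not backgrounds:
            raise ValueError("need at least one target and one background pattern")
        self.spec_ = self._spec()
        self.times_ = sample_grid(self.t_start, self.t_end, self.dt)
        res = self._train(targets, backgrounds)
        self.weights_ = res.weights
        self.converged_ = res.converged
        self.n_cycles_ = res.n_cycles
        self.n_hyperplanes_ = res.n_hyperplanes
        self.margin_ = res.margin
        self.n_neurons_ = targets[0].n_neurons
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Max membrane voltage minus threshold, per pattern."""
        patterns, _ = _coerce_patterns(X)
        return np.array(
            [
                membrane_voltage(p, self.weights_, self.spec_, self.times_).max()
                - self.weights_.theta
                for p in patterns
            ]
        )

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


class VoltageMarginTempotronClassifier(TempotronClassifier):
    """Tempotron variant that keeps widening the voltage margin.

    Extra attributes: ``margin_`` (achieved ``M_V``) and
    ``n_hyperplanes_`` (weight vectors evaluated — the budget handed to the
    genetic search in matched comparisons).
    """

    def __init__(
        self,
        kernel: str | KernelSpec = "double_exp",
        tau: float = 1.5,
        tau_r: float | None = 1.0,
        t_pulse: float | None = None,
        dt: float = 0.1,
        t_start: float = 0.0,
        t_end: float = 40.0,
        lambda_: float = 0.1,
        theta: float = 1.0,
        v_rest: float = 0.0,
        max_cycles: int = 10_000,
        margin_step: float = 0.01,
        patience: int = 100,
    ):
        super().__init__(
            kernel=kernel, tau=tau, tau_r=tau_r, t_pulse=t_pulse, dt=dt,
            t_start=t_start, t_end=t_end, lambda_=lambda_, theta=theta,
            v_rest=v_rest, max_cycles=max_cycles,
        )
        self.margin_step = margin_step
        self.patience = patience

    def _config(self) -> TempotronConfig:
        return TempotronConfig(
            lambda_=self.lambda_, theta=self.theta, v_rest=self.v_rest,
            max_cycles=self.max_cycles, margin_step=self.margin_step,
            patience=self.patience,
        )

    def _train(self, targets, backgrounds) -> TempotronResult:
        return vm_tempotron_train(
            targets, backgrounds, self.spec_, self._config(), self.times_
        )
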