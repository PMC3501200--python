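"""Maximum-margin spike-pattern separation (the SVM-PSP method).

The classification goal for a leaky integrate-and-fire (LIF) readout is:

* the target pattern must drive the membrane voltage above threshold at
  least once,
* every background pattern must keep it below threshold at all times.

Geometrically, with trajectories ``f(t_l)`` in the N-dimensional feature
space, this is linear separation of *at least one* target point from *all*
background points by the hyperplane ``<W, f> - b = 0``.  The method tries
every candidate target point ``f+(t_l)`` in turn, fits a soft-margin linear
SVM (liblinear: L2-regularized L1-loss dual, cost 10, stopping tolerance
1e-2, bias enabled) with that single point as the positive class against
all background points, scores the fit by the worst signed orthogonal
distance over the constraint set, and keeps the candidate with the largest
margin.  The winning hyperplane converts directly into synaptic weights
``w = (theta / b) W`` for the LIF neuron.

Margins are reported both as the raw feature-space distance ``D_S`` (after
per-dimension rescaling to [0, 1]) and as the dimension-free
``D_N = 2 D_S / sqrt(N)`` (the diameter of the unit hypercube is
``sqrt(N)``, so ``D_N = 1`` is the largest achievable separation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .embedding import Rescaler, Trajectory, embed, fit_rescaler, kink_trajectory, sample_grid
from .kernels import KernelSpec
from .patterns import PatternSet, SpikePattern, TARGET

__all__ = [
    "Hyperplane",
    "SeparationResult",
    "SynapticWeights",
    "DegenerateBiasError",
    "signed_distance",
    "negative_margin",
    "candidate_margin",
    "normalized_margin",
    "fit_hyperplane",
    "train_single_target",
    "to_synaptic_weights",
    "classify",
    "SVMPSPClassifier",
]

#: Paper-fixed liblinear contract: cost and stopping tolerance.
DEFAULT_C = 10.0
DEFAULT_TOL = 1e-2


class DegenerateBiasError(ValueError):
    """Hyperplane bias makes the synaptic-weight conversion undefined."""


@dataclass
class Hyperplane:
    """Linear decision boundary ``<W, f> - b = 0`` in feature space."""

    W: np.ndarray
    b: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = float(self.b)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.W))

    def rho(self, theta: float = 1.0) -> float:
        """Orthogonal distance ``theta / ||W||`` of the threshold plane from 0."""
        return theta / self.norm


def signed_distance(h: Hyperplane, f) -> np.ndarray | float:
    """Signed orthogonal distance ``(<W, f> - b) / ||W||`` (positive above)."""
    norm = h.norm
    if norm == 0:
        raise ValueError("hyperplane has zero-norm normal vector")
    f = np.asarray(f, dtype=float)
    d = (f @ h.W - h.b) / norm
    return float(d) if np.ndim(d) == 0 else d


def negative_margin(h: Hyperplane, negatives) -> float:
    """``D_S^- = -max_f D_S(h, f)`` over background points.

    Positive iff every background point lies strictly below the plane.
    """
    negatives = np.asarray(negatives, dtype=float)
    if negatives.size == 0:
        raise ValueError("negatives must be nonempty")
    return float(-np.max(signed_distance(h, negatives)))


def candidate_margin(h: Hyperplane, positive, negatives) -> float:
    """Worst-case margin ``min(D_S^+, D_S^-)`` of one candidate point."""
    return min(float(signed_distance(h, positive)), negative_margin(h, negatives))


def normalized_margin(d_s: float, n: int) -> float:
    """Dimension-free margin ``D_N = 2 D_S / sqrt(N)`` (``<= 1`` in [0,1]^N)."""
    if n < 1:
        raise ValueError(f"dimension must be >= 1, got {n}")
    return 2.0 * d_s / np.sqrt(n)


try:  # fast path: liblinear without the per-call estimator re-validation
    from sklearn.svm._base import _fit_liblinear
except ImportError:  # pragma: no cover - depends on sklearn internals
    _fit_liblinear = None

_MAX_ITER = 5000


def _solve_liblinear(X: np.ndarray, y: np.ndarray, C: float, tol: float):
    """L2-regularized L1-loss dual SVC with bias; fixed solver seed.

    The candidate sweep refits this problem hundreds of times per pattern,
    so the thin ``_fit_liblinear`` entry point is used when available, with
    the public ``LinearSVC`` as fallback.  The dual coordinate-descent
    shuffling is seeded (it is *not* deterministic otherwise).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if _fit_liblinear is not None:
            coef, intercept, _ = _fit_liblinear(
                X, y, C=C, fit_intercept=True, intercept_scaling=1.0,
                class_weight=None, penalty="l2", dual=True, verbose=0,
                max_iter=_MAX_ITER, tol=tol, random_state=0,
                multi_class="ovr", loss="hinge", epsilon=0.1,
                sample_weight=None,
            )
            return coef[0], float(np.atleast_1d(intercept)[0])
        clf = LinearSVC(
            loss="hinge", C=C, tol=tol, fit_intercept=True,
            max_iter=_MAX_ITER, random_state=0,
        ).fit(X, y)
        return clf.coef_[0], float(clf.intercept_[0])


def fit_hyperplane(
    positives: np.ndarray,
    negatives: np.ndarray,
    C: float = DEFAULT_C,
    tol: float = DEFAULT_TOL,
) -> Hyperplane:
    """Soft-margin linear separator, positives above, negatives below.

    liblinear L2-regularized L1-loss dual with bias (the ``LinearSVC``
    ``loss="hinge"`` problem); orientation is fixed so that the positive
    class has positive decision values.
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    X = np.vstack([negatives, positives])
    y = np.concatenate([np.full(len(negatives), -1.0), np.full(len(positives), 1.0)])
    coef, intercept = _solve_liblinear(X, y, C, tol)
    # decision = <coef, f> + intercept; plane form is <W, f> - b
    return Hyperplane(coef.copy(), -intercept)


@dataclass
class SeparationResult:
    """Outcome of the candidate-point sweep for one target pattern."""

    hyperplane: Hyperplane
    best_time: float
    best_index: int
    margin: float  # D_S of the winning candidate
    margin_normalized: float  # D_N = 2 D_S / sqrt(N)
    separating: bool
    candidate_times: np.ndarray | None = None
    candidate_margins: np.ndarray | None = None


def _candidate_indices(target: Trajectory) -> np.ndarray:
    """Sample indices worth testing: points where the trajectory is nonzero.

    Before the first spike ``f = 0``, which can never be separated from
    backgrounds that also pass through 0; skipping those samples cannot
    change the arg-max.
    """
    nz = np.flatnonzero(np.any(target.points != 0, axis=1))
    return nz if nz.size else np.arange(len(target))


def train_single_target(
    target: Trajectory,
    backgrounds: Sequence[Trajectory],
    C: float = DEFAULT_C,
    tol: float = DEFAULT_TOL,
    record_trace: bool = False,
) -> SeparationResult:
    """Sweep all candidate target points; keep the maximum-margin hyperplane.

    Each candidate time ``t_l`` of the target trajectory is tried as the
    single positive point against all background points; the hyperplane with
    the largest ``min(D_S^+, D_S^-)`` wins (ties broken to the earliest
    ``t_l``).  A best margin <= 0 flags the instance as non-separating.

    Trajectories are used as given — rescale them first (the estimator does
    this with a :class:`~svmpsp.embedding.Rescaler` fit on all training
    points).
    """
    if len(target) == 0:
        raise ValueError("target trajectory is empty")
    if not backgrounds:
        raise ValueError("backgrounds must be nonempty")
    n_dim = target.n_dim
    for bg in backgrounds:
        if bg.n_dim != n_dim:
            raise ValueError("trajectories disagree on dimension")
    negatives = np.vstack([bg.points for bg in backgrounds])

    cand = _candidate_indices(target)
    margins = np.full(cand.size, np.nan) if record_trace else None

    # Exact pruning: for candidate p and any hyperplane, the achievable
    # margin satisfies min(D_S^+, D_S^-) <= (D_S^+ + D_S^-)/2
    # <= ||p - n|| / 2 for every negative n.  Sweeping candidates in
    # decreasing order of this bound and stopping once it falls below the
    # best margin found cannot change the arg-max (ties: argsort is stable,
    # so equal bounds keep earlier-time priority).
    bounds = 0.5 * np.min(cdist(target.points[cand], negatives), axis=1)
    order = np.argsort(-bounds, kind="stable")

    best: tuple[float, int, Hyperplane] | None = None
    for k in order:
        if best is not None and bounds[k] < best[0] and not record_trace:
            break  # all remaining bounds are smaller still
        l = int(cand[k])
        point = target.points[l]
        h = fit_hyperplane(point[None, :], negatives, C=C, tol=tol)
        m = candidate_margin(h, point, negatives)
        if record_trace:
            margins[k] = m
        if best is None or m > best[0] or (m == best[0] and l < best[1]):
            best = (m, l, h)
    m, l, h = best
    return SeparationResult(
        hyperplane=h,
        best_time=float(target.times[l]),
        best_index=l,
        margin=m,
        margin_normalized=normalized_margin(m, n_dim),
        separating=m > 0,
        candidate_times=target.times[cand] if record_trace else None,
        candidate_margins=margins,
    )


@dataclass
class SynapticWeights:
    """LIF-ready weights: fires when ``<w, f(t)> + v_rest >= theta``."""

    w: np.ndarray
    theta: float = 1.0
    v_rest: float = 0.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)):
            raise ValueError("synaptic weights must be finite")

    def to_json(self) -> dict:
        return {"weights": self.w.tolist(), "theta": self.theta, "v_rest": self.v_rest}

    @classmethod
    def from_json(cls, obj: dict) -> "SynapticWeights":
        return cls(np.asarray(obj["weights"]), obj.get("theta", 1.0), obj.get("v_rest", 0.0))


def to_synaptic_weights(
    h: Hyperplane,
    theta: float = 1.0,
    rescaler: Rescaler | None = None,
) -> SynapticWeights:
    """Convert a hyperplane into LIF synaptic weights ``w = (theta / b) W``.

    If a rescaler is given, the affine per-dimension map is composed into
    the weights so that they apply to *raw* kernel features: the rescaled
    decision ``<W, (f - m) * s> - b`` becomes ``<W * s, f> - b'`` with
    ``b' = b + <W * s, m>``, and ``w = (theta / b') (W * s)``.  Requires
    ``b' > 0`` (the origin — silence — must lie below the plane; otherwise
    the threshold semantics cannot be preserved).
    """
    if rescaler is not None:
        W = h.W * rescaler.scale_
        b = h.b + float(W @ rescaler.min_)
    else:
        W, b = h.W, h.b
    if b == 0:
        raise DegenerateBiasError("hyperplane bias is zero; weights undefined")
    if b < 0:
        raise DegenerateBiasError(
            "hyperplane bias is negative (origin above the plane); the "
            "threshold-crossing conversion does not apply"
        )
    return SynapticWeights((theta / b) * W, theta=theta, v_rest=0.0)


def classify(
    p: SpikePattern,
    w: SynapticWeights,
    spec: KernelSpec,
    times: Sequence[float],
) -> tuple[bool, float | None]:
    """LIF decision: fired iff ``max_l <w, f(t_l)> + v_rest >= theta``.

    Returns (fired, earliest crossing time or None).
    """
    traj = embed(p, spec, times)
    v = traj.points @ w.w + w.v_rest
    above = np.flatnonzero(v >= w.theta)
    if above.size:
        return True, float(traj.times[above[0]])
    return False, None


# ----------------------------------------------------------------------
# Estimator
# ----------------------------------------------------------------------


def _coerce_patterns(X, y=None) -> tuple[list[SpikePattern], np.ndarray]:
    """Accept a PatternSet or sequence of SpikePattern, with optional labels.

    ``y`` entries may be 0/1, booleans, or the strings 'target'/'background';
    if omitted, each pattern's own label is used.
    """
    if isinstance(X, PatternSet):
        patterns = list(X.patterns)
    else:
        patterns = list(X)
    for p in patterns:
        if not isinstance(p, SpikePattern):
            raise TypeError(f"expected SpikePattern, got {type(p).__name__}")
    if y is None:
        labels = np.array([1 if p.is_target else 0 for p in patterns])
    else:
        labels = np.array(
            [1 if (v == 1 or v is True or v == TARGET) else 0 for v in y]
        )
        if labels.shape[0] != len(patterns):
            raise ValueError("y length does not match number of patterns")
    ns = {p.n_neurons for p in patterns}
    if len(ns) > 1:
        raise ValueError(f"patterns disagree on n_neurons: {sorted(ns)}")
    return patterns, labels


class SVMPSPClassifier(ClassifierMixin, BaseEstimator):
    """Spike-pattern detector trained by maximum-margin candidate sweep.

    Fit on one target pattern plus background patterns (for several target
    patterns use :class:`~svmpsp.genetic.GeneticSVMPSPClassifier`).  After
    fitting, ``predict`` reports 1 where the LIF readout would fire.

    Parameters
    ----------
    kernel : kernel family name or a :class:`~svmpsp.kernels.KernelSpec`.
    tau, tau_r, t_pulse : kernel time constants (ms), used when ``kernel``
        is a family name.
    dt : trajectory sampling period, ms (dense sampling).
    t_start, t_end : sampling window, ms.
    sampling : 'dense' (grid of period ``dt``) or 'kink' (only the
        derivative-discontinuity times of a piecewise-linear kernel).
    C, tol : liblinear cost and stopping tolerance.
    theta : LIF firing threshold for the exported synaptic weights.

    Attributes
    ----------
    result_ : :class:`SeparationResult` of the candidate sweep.
    hyperplane_ : winning hyperplane in rescaled feature space.
    margin_, margin_normalized_ : D_S and D_N of the winner.
    best_time_ : candidate time of the winning target point, ms.
    separating_ : whether the training set was separated (margin > 0).
    weights_ : :class:`SynapticWeights` on raw features, or None when the
        bias conversion is degenerate.
    rescaler_ : the per-dimension [0, 1] rescaler fit on training points.
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
        sampling: str = "dense",
        C: float = DEFAULT_C,
        tol: float = DEFAULT_TOL,
        theta: float = 1.0,
        record_trace: bool = False,
    ):
        self.kernel = kernel
        self.tau = tau
        self.tau_r = tau_r
        self.t_pulse = t_pulse
        self.dt = dt
        self.t_start = t_start
        self.t_end = t_end
        self.sampling = sampling
        self.C = C
        self.tol = tol
        self.theta = theta
        self.record_trace = record_trace

    # -- helpers -------------------------------------------------------

    def _spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel
        kwargs = {}
        if self.kernel in ("double_exp", "rc"):
            kwargs["tau_r"] = self.tau_r
        if self.kernel == "rc":
            kwargs["t_pulse"] = self.t_pulse
        return KernelSpec(self.kernel, tau=self.tau, **kwargs)

    def _trajectory(self, p: SpikePattern) -> Trajectory:
        if self.sampling == "kink":
            return kink_trajectory(p, self.spec_)
        return embed(p, self.spec_, self.times_)

    # -- sklearn API ---------------------------------------------------

    def fit(self, X, y=None) -> "SVMPSPClassifier":
        if self.sampling not in ("dense", "kink"):
            raise ValueError(f"sampling must be 'dense' or 'kink', got {self.sampling!r}")
        patterns, labels = _coerce_patterns(X, y)
        targets = [p for p, l in zip(patterns, labels) if l == 1]
        backgrounds = [p for p, l in zip(patterns, labels) if l == 0]
        if len(targets) != 1:
            raise ValueError(
                f"SVMPSPClassifier handles exactly one target pattern, got "
                f"{len(targets)}; use GeneticSVMPSPClassifier for several"
            )
        if not backgrounds:
            raise ValueError("at least one background pattern is required")

        self.spec_ = self._spec()
        self.times_ = (
            sample_grid(self.t_start, self.t_end, self.dt)
            if self.sampling == "dense"
            else None
        )
        target_traj = self._trajectory(targets[0])
        bg_trajs = [self._trajectory(p) for p in backgrounds]

        self.rescaler_ = fit_rescaler(
            [target_traj.points] + [t.points for t in bg_trajs]
        )
        target_scaled = self.rescaler_.transform_trajectory(target_traj)
        bg_scaled = [self.rescaler_.transform_trajectory(t) for t in bg_trajs]

        self.result_ = train_single_target(
            target_scaled, bg_scaled, C=self.C, tol=self.tol,
            record_trace=self.record_trace,
        )
        self.hyperplane_ = self.result_.hyperplane
        self.margin_ = self.result_.margin
        self.margin_normalized_ = self.result_.margin_normalized
        self.best_time_ = self.result_.best_time
        self.separating_ = self.result_.separating
        try:
            self.weights_ = to_synaptic_weights(
                self.hyperplane_, theta=self.theta, rescaler=self.rescaler_
            )
        except DegenerateBiasError:
            self.weights_ = None
        self.n_neurons_ = targets[0].n_neurons
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per pattern: max over sample times of ``<W, f~(t)> - b`` (rescaled)."""
        patterns, _ = _coerce_patterns(X)
        h = self.hyperplane_
        out = np.empty(len(patterns))
        for i, p in enumerate(patterns):
            traj = self.rescaler_.transform_trajectory(self._trajectory(p))
            out[i] = np.max(traj.points @ h.W - h.b) if len(traj) else -h.b
        return out

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)

    def fire_times(self, X) -> np.ndarray:
        """Earliest threshold-crossing time per pattern (NaN if silent)."""
        patterns, _ = _coerce_patterns(X)
        h = self.hyperplane_
        out = np.full(len(patterns), np.nan)
        for i, p in enumerate(patterns):
            traj = self.rescaler_.transform_trajectory(self._trajectory(p))
            above = np.flatnonzero(traj.points @ h.W - h.b >= 0)
            if above.size:
                out[i] = traj.times[above[0]]
        return out

    # -- persistence ---------------------------------------------------

    def save_weights(self, path) -> None:
        """Weight-file JSON for the LIF readout (raw-feature weights)."""
        if self.weights_ is None:
            raise DegenerateBiasError("no valid synaptic weights on this fit")
        record = {
            "method": "svm-psp",
            **self.weights_.to_json(),
            "bias_offset": self.hyperplane_.b,
            "kernel": self.spec_.to_json(),
            "n_neurons": self.n_neurons_,
            "best_time_ms": self.best_time_,
            "margin_DS": self.margin_,
            "margin_DN": self.margin_normalized_,
        }
        Path(path).write_text(json.dumps(record, indent=1))
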