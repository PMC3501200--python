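"""Genetic search over candidate-point tuples for multi-target separation.

With several target patterns, one candidate point must be chosen *per
target* so that a single hyperplane puts all chosen points above it and
every background point below.  Sweeping all n-tuples explodes
combinatorially, so a small genetic algorithm searches the tuple space: a
genotype holds one candidate time index per target pattern, and its
fitness is the worst normalized signed margin of the hyperplane fitted to
the gene points (positives) against all background points —

    Fit(g) = min( min_genes D_N(gene point), -max_negatives D_N ).

Each generation the population of M genotypes is ranked; the best quarter
is mutated (one gene's time index shifted by up to ±5 grid steps), the
next quarter recombined pairwise by exchanging a random split of genes,
and the worst half replaced by fresh uniform genotypes.  A pure stochastic
search (every generation fully random, same evaluation accounting) serves
as the control; both stop when the evaluation budget is exhausted, and the
global best genotype is tracked outside the population so reported
best-so-far fitness is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .embedding import Trajectory, fit_rescaler, kink_trajectory, embed, sample_grid
from .kernels import KernelSpec
from .separation import (
    DEFAULT_C,
    DEFAULT_TOL,
    DegenerateBiasError,
    Hyperplane,
    _candidate_indices,
    _coerce_patterns,
    fit_hyperplane,
    signed_distance,
    to_synaptic_weights,
)

__all__ = [
    "GAConfig",
    "GAResult",
    "ga_fitness",
    "ga_train",
    "stochastic_search",
    "GeneticSVMPSPClassifier",
]


@dataclass
class GAConfig:
    """Search parameters: population size M (divisible by 4) and budget."""

    population: int = 8
    budget: int = 400  # max genotype evaluations
    mutation_halfwidth: int = 5  # max |shift| of one gene's time index
    C: float = DEFAULT_C
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if self.population % 4 != 0 or self.population <= 0:
            raise ValueError("population must be a positive multiple of 4")
        if self.budget < self.population:
            raise ValueError("budget must be at least one population")
        if self.mutation_halfwidth < 1:
            raise ValueError("mutation_halfwidth must be >= 1")


@dataclass
class GAResult:
    genotype: tuple[int, ...]  # winning candidate time index per target
    hyperplane: Hyperplane
    fitness: float
    n_evaluations: int
    history: pd.DataFrame = field(repr=False)  # generation, evaluations, best_fitness


def ga_fitness(
    genotype: Sequence[int],
    target_trajs: Sequence[Trajectory],
    background_trajs: Sequence[Trajectory],
    C: float = DEFAULT_C,
    tol: float = DEFAULT_TOL,
) -> tuple[float, Hyperplane]:
    """Fitness of one genotype (time index per target trajectory).

    Fits one linear separator with the gene points as positives and all
    background points as negatives, then scores it by the worst normalized
    signed margin over the constraint set.  An infeasible fit simply yields
    a negative fitness.
    """
    if len(genotype) != len(target_trajs):
        raise ValueError("genotype needs exactly one gene per target pattern")
    if not background_trajs:
        raise ValueError("backgrounds must be nonempty")
    n = target_trajs[0].n_dim
    pos = np.array(
        [traj.points[int(l)] for traj, l in zip(target_trajs, genotype)]
    )
    neg = np.vstack([traj.points for traj in background_trajs])
    h = fit_hyperplane(pos, neg, C=C, tol=tol)
    scale = 2.0 / np.sqrt(n)  # D_S -> D_N
    d_pos = scale * np.asarray(signed_distance(h, pos))
    d_neg = scale * np.asarray(signed_distance(h, neg))
    return float(min(d_pos.min(), -d_neg.max())), h


class _Search:
    """Budgeted genotype evaluation with an elitist archive."""

    def __init__(self, target_trajs, background_trajs, cfg: GAConfig, rng):
        self.targets = list(target_trajs)
        self.backgrounds = list(background_trajs)
        self.cfg = cfg
        self.rng = rng
        # candidate time indices per target: samples with a nonzero point
        self.candidates = [_candidate_indices(t) for t in self.targets]
        self.evals = 0
        self.best: tuple[float, tuple[int, ...], Hyperplane] | None = None
        self.rows: list[dict] = []

    # genotypes are stored as positions into each target's candidate list
    def random_genotype(self) -> tuple[int, ...]:
        return tuple(int(self.rng.integers(len(c))) for c in self.candidates)

    def mutate(self, g: tuple[int, ...]) -> tuple[int, ...]:
        k = int(self.rng.integers(len(g)))
        hw = self.cfg.mutation_halfwidth
        shift = int(self.rng.integers(-hw, hw + 1))
        genes = list(g)
        genes[k] = int(np.clip(genes[k] + shift, 0, len(self.candidates[k]) - 1))
        return tuple(genes)

    def crossover(self, a: tuple[int, ...], b: tuple[int, ...]):
        if len(a) < 2:
            return a, b
        split = int(self.rng.integers(1, len(a)))
        return a[:split] + b[split:], b[:split] + a[split:]

    def evaluate(self, pop: list[tuple[int, ...]]) -> list[float]:
        fits = []
        for g in pop:
            if self.evals >= self.cfg.budget:
                break
            time_idx = tuple(
                int(c[p]) for c, p in zip(self.candidates, g)
            )
            fit, h = ga_fitness(
                time_idx, self.targets, self.backgrounds,
                C=self.cfg.C, tol=self.cfg.tol,
            )
            self.evals += 1
            if self.best is None or fit > self.best[0]:
                self.best = (fit, time_idx, h)
            fits.append(fit)
        return fits

    def run(self, reproduce: bool) -> GAResult:
        cfg = self.cfg
        m = cfg.population
        q = m // 4
        pop = [self.random_genotype() for _ in range(m)]
        generation = 0
        while self.evals < cfg.budget:
            fits = self.evaluate(pop)
            self.rows.append(
                {
                    "generation": generation,
                    "evaluations": self.evals,
                    "best_fitness": self.best[0],
                }
            )
            if self.evals >= cfg.budget:
                break
            if reproduce:
                order = np.argsort(fits[: len(pop)])[::-1]
                ranked = [pop[i] for i in order]
                nxt = [self.mutate(g) for g in ranked[:q]]
                parents = ranked[q : 2 * q]
                for i in range(0, len(parents) - 1, 2):
                    c1, c2 = self.crossover(parents[i], parents[i + 1])
                    nxt.extend([c1, c2])
                if len(parents) % 2 == 1:  # odd quarter: last parent carried over
                    nxt.append(parents[-1])
                nxt.extend(self.random_genotype() for _ in range(m - len(nxt)))
                pop = nxt
            else:
                pop = [self.random_genotype() for _ in range(m)]
            generation += 1
        fit, genotype, h = self.best
        history = pd.DataFrame(self.rows)
        return GAResult(genotype, h, fit, self.evals, history)


def ga_train(
    target_trajs: Sequence[Trajectory],
    background_trajs: Sequence[Trajectory],
    cfg: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GAResult:
    """Genetic search for the best candidate-point tuple (see module docs)."""
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(rng)
    return _Search(target_trajs, background_trajs, cfg, rng).run(reproduce=True)


def stochastic_search(
    target_trajs: Sequence[Trajectory],
    background_trajs: Sequence[Trajectory],
    cfg: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GAResult:
    """Control search: every generation fully uniform-random, same budget."""
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(rng)
    return _Search(target_trajs, background_trajs, cfg, rng).run(reproduce=False)


class GeneticSVMPSPClassifier(ClassifierMixin, BaseEstimator):
    """Multi-target spike-pattern detector: GA over candidate tuples + SVM.

    Same kernel/sampling parameters as
    :class:`~svmpsp.separation.SVMPSPClassifier`; accepts any number of
    target patterns.  ``search='stochastic'`` switches to the pure random
    control.

    Attributes: ``genotype_`` (winning time index per target),
    ``best_times_`` (ms), ``hyperplane_``, ``fitness_`` (normalized margin
    D_N of the constraint set), ``history_``, ``weights_``.
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
        population: int = 8,
        budget: int = 400,
        mutation_halfwidth: int = 5,
        search: str = "genetic",
        random_state=None,
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
        self.population = population
        self.budget = budget
        self.mutation_halfwidth = mutation_halfwidth
        self.search = search
        self.random_state = random_state

    def _spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel
        kwargs = {}
        if self.kernel in ("double_exp", "rc"):
            kwargs["tau_r"] = self.tau_r
        if self.kernel == "rc":
            kwargs["t_pulse"] = self.t_pulse
        return KernelSpec(self.kernel, tau=self.tau, **kwargs)

    def _trajectory(self, p):
        if self.sampling == "kink":
            return kink_trajectory(p, self.spec_)
        return embed(p, self.spec_, self.times_)

    def fit(self, X, y=None) -> "GeneticSVMPSPClassifier":
        if self.search not in ("genetic", "stochastic"):
            raise ValueError("search must be 'genetic' or 'stochastic'")
        patterns, labels = _coerce_patterns(X, y)
        targets = [p for p, l in zip(patterns, labels) if l == 1]
        backgrounds = [p for p, l in zip(patterns, labels) if l == 0]
        if not targets or not backgrounds:
            raise ValueError("need at least one target and one background pattern")
        self.spec_ = self._spec()
        self.times_ = (
            sample_grid(self.t_start, self.t_end, self.dt)
            if self.sampling == "dense"
            else None
        )
        t_trajs = [self._trajectory(p) for p in targets]
        b_trajs = [self._trajectory(p) for p in backgrounds]
        self.rescaler_ = fit_rescaler(
            [t.points for t in t_trajs] + [t.points for t in b_trajs]
        )
        t_scaled = [self.rescaler_.transform_trajectory(t) for t in t_trajs]
        b_scaled = [self.rescaler_.transform_trajectory(t) for t in b_trajs]
        cfg = GAConfig(
            population=self.population, budget=self.budget,
            mutation_halfwidth=self.mutation_halfwidth, C=self.C, tol=self.tol,
        )
        rng = np.random.default_rng(self.random_state)
        search = ga_train if self.search == "genetic" else stochastic_search
        res = search(t_scaled, b_scaled, cfg, rng)
        self.result_ = res
        self.genotype_ = res.genotype
        self.best_times_ = np.array(
            [t.times[l] for t, l in zip(t_scaled, res.genotype)]
        )
        self.hyperplane_ = res.hyperplane
        self.fitness_ = res.fitness
        self.separating_ = res.fitness > 0
        self.history_ = res.history
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
        patterns, _ = _coerce_patterns(X)
        h = self.hyperplane_
        out = np.empty(len(patterns))
        for i, p in enumerate(patterns):
            traj = self.rescaler_.transform_trajectory(self._trajectory(p))
            out[i] = np.max(traj.points @ h.W - h.b) if len(traj) else -h.b
        return out

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)
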