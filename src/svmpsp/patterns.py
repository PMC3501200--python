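"""Labeled spike patterns: generation, jitter, and plain-text / JSON I/O.

A spike pattern is the input to one classification trial: ``N`` input
neurons, each with one or more spike times (ms), labeled either ``target``
(the readout neuron should fire) or ``background`` (it should stay silent).

Two generators cover the study designs used throughout the package:

* ``generate_constant_isi`` — every neuron fires exactly once; the pooled
  spike times form an arithmetic grid over ``[t_min, t_max]`` (constant
  inter-spike interval) and the neuron -> slot assignment is a uniformly
  random permutation.  The pattern's identity is purely the firing order.
* ``generate_uniform`` — one spike per neuron, i.i.d. uniform on
  ``[t_min, t_max]`` (variable ISIs).

``jitter_pattern`` adds truncated Gaussian noise per spike, redrawing any
draw that leaves the admissible window — the noise model of the
generalization benchmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "SpikePattern",
    "PatternSet",
    "TARGET",
    "BACKGROUND",
    "generate_constant_isi",
    "generate_uniform",
    "jitter_pattern",
    "read_patterns",
    "write_patterns",
]

TARGET = "target"
BACKGROUND = "background"
_LABELS = (TARGET, BACKGROUND)

_MAX_REDRAWS = 100_000


@dataclass
class SpikePattern:
    """One labeled input pattern: per-neuron spike-time lists (ms)."""

    spikes: list[np.ndarray]
    label: str = BACKGROUND
    period: float | None = None

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")
        self.spikes = [np.atleast_1d(np.asarray(s, dtype=float)) for s in self.spikes]
        for i, s in enumerate(self.spikes):
            if s.size and (not np.all(np.isfinite(s)) or np.any(s < 0)):
                raise ValueError(f"neuron {i}: spike times must be finite and >= 0")

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(s.size for s in self.spikes))

    @property
    def is_target(self) -> bool:
        return self.label == TARGET

    def all_times(self) -> np.ndarray:
        """Pooled spike times of all neurons (unsorted)."""
        if not self.spikes:
            return np.empty(0)
        return np.concatenate(self.spikes)

    def copy(self, label: str | None = None) -> "SpikePattern":
        return SpikePattern(
            [s.copy() for s in self.spikes],
            label=self.label if label is None else label,
            period=self.period,
        )


@dataclass
class PatternSet:
    """A homogeneous collection of patterns plus generator metadata."""

    patterns: list[SpikePattern] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ns = {p.n_neurons for p in self.patterns}
        if len(ns) > 1:
            raise ValueError(f"patterns disagree on n_neurons: {sorted(ns)}")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[SpikePattern]:
        return iter(self.patterns)

    def __getitem__(self, i):
        return self.patterns[i]

    @property
    def n_neurons(self) -> int:
        return self.patterns[0].n_neurons if self.patterns else 0

    @property
    def targets(self) -> list[SpikePattern]:
        return [p for p in self.patterns if p.is_target]

    @property
    def backgrounds(self) -> list[SpikePattern]:
        return [p for p in self.patterns if not p.is_target]


def generate_constant_isi(
    n_neurons: int,
    t_min: float = 10.0,
    t_max: float = 20.0,
    rng: np.random.Generator | None = None,
    label: str = BACKGROUND,
) -> SpikePattern:
    """One spike per neuron on the arithmetic time grid over [t_min, t_max].

    Neuron ``i`` fires at ``t_min + (u_i - 1)(t_max - t_min)/(N - 1)`` where
    ``(u_1..u_N)`` is a uniformly random permutation of ``1..N``: pooled
    spike times have a constant ISI of ``(t_max - t_min)/(N - 1)`` and only
    the firing order distinguishes patterns.
    """
    if n_neurons < 2:
        raise ValueError("constant-ISI generation requires n_neurons >= 2")
    if not t_max > t_min:
        raise ValueError(f"require t_max > t_min, got [{t_min}, {t_max}]")
    rng = np.random.default_rng(rng)
    slots = rng.permutation(n_neurons)  # u_i - 1
    step = (t_max - t_min) / (n_neurons - 1)
    times = t_min + slots * step
    return SpikePattern(
        [np.array([t]) for t in times], label=label, period=t_max - t_min
    )


def generate_uniform(
    n_neurons: int,
    t_min: float = 10.0,
    t_max: float = 20.0,
    rng: np.random.Generator | None = None,
    label: str = BACKGROUND,
) -> SpikePattern:
    """One spike per neuron, i.i.d. uniform on [t_min, t_max]."""
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if not t_max > t_min:
        raise ValueError(f"require t_max > t_min, got [{t_min}, {t_max}]")
    rng = np.random.default_rng(rng)
    times = rng.uniform(t_min, t_max, size=n_neurons)
    return SpikePattern(
        [np.array([t]) for t in times], label=label, period=t_max - t_min
    )


def jitter_pattern(
    p: SpikePattern,
    sigma: float,
    rng: np.random.Generator | None = None,
    low: float = 0.0,
    high: float = 30.0,
) -> SpikePattern:
    """Add N(0, sigma^2) noise to every spike, rejecting moves out of (low, high].

    Each jittered time must satisfy ``low < t + eps <= high``; out-of-window
    draws are redrawn (truncated Gaussian).  With ``sigma = 0`` the pattern
    is returned unchanged, but a spike already outside the window is an
    error (rejection could never terminate).
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if not low < high:
        raise ValueError(f"require low < high, got ({low}, {high}]")
    rng = np.random.default_rng(rng)
    new_spikes: list[np.ndarray] = []
    for i, s in enumerate(p.spikes):
        out = np.empty_like(s)
        for j, t in enumerate(s):
            if not low < t <= high and sigma == 0:
                raise ValueError(
                    f"neuron {i}: spike at {t} ms outside ({low}, {high}] "
                    "with sigma=0 — rejection sampling cannot terminate"
                )
            if sigma == 0:
                out[j] = t
                continue
            for _ in range(_MAX_REDRAWS):
                cand = t + rng.normal(0.0, sigma)
                if low < cand <= high:
                    out[j] = cand
                    break
            else:  # pragma: no cover - requires pathological inputs
                raise ValueError(
                    f"neuron {i}: could not draw a jittered time in ({low}, {high}] "
                    f"for spike at {t} ms (sigma={sigma})"
                )
        new_spikes.append(out)
    return SpikePattern(new_spikes, label=p.label, period=p.period)


# ----------------------------------------------------------------------
# I/O.  Plain-text format: one block per pattern,
#   # n_neurons=N label=target|background
#   <neuron_index>\t<time_ms>
# JSON: a list of {"n_neurons": N, "label": ..., "spikes": [[...], ...]}.
# ----------------------------------------------------------------------


def write_patterns(pattern_set: PatternSet | Sequence[SpikePattern], path) -> None:
    path = Path(path)
    patterns = list(pattern_set)
    if path.suffix == ".json":
        payload = [
            {
                "n_neurons": p.n_neurons,
                "label": p.label,
                "spikes": [s.tolist() for s in p.spikes],
            }
            for p in patterns
        ]
        path.write_text(json.dumps(payload, indent=1))
        return
    lines = []
    for p in patterns:
        lines.append(f"# n_neurons={p.n_neurons} label={p.label}")
        for i, s in enumerate(p.spikes):
            for t in s:
                lines.append(f"{i}\t{float(t)!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_patterns(path) -> PatternSet:
    """Read a spike file (text or ``.json``); inverse of ``write_patterns``."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text() or "[]")
        patterns = [
            SpikePattern([np.asarray(s, dtype=float) for s in rec["spikes"]],
                         label=rec["label"])
            for rec in payload
        ]
        return PatternSet(patterns, metadata={"source": str(path)})

    patterns: list[SpikePattern] = []
    spikes: list[list[float]] | None = None
    label = BACKGROUND

    def flush():
        if spikes is not None:
            patterns.append(
                SpikePattern([np.asarray(s) for s in spikes], label=label)
            )

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            flush()
            fields = dict(
                tok.split("=", 1) for tok in line.lstrip("# ").split() if "=" in tok
            )
            try:
                n = int(fields["n_neurons"])
                label = fields["label"]
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed header {line!r}") from exc
            if label not in _LABELS:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            spikes = [[] for _ in range(n)]
            continue
        if spikes is None:
            raise ValueError(f"{path}:{lineno}: spike line before any header")
        parts = line.split()
        try:
            idx, t = int(parts[0]), float(parts[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed spike line {line!r}") from exc
        if not 0 <= idx < len(spikes):
            raise ValueError(
                f"{path}:{lineno}: neuron index {idx} outside 0..{len(spikes) - 1}"
            )
        spikes[idx].append(t)
    flush()
    return PatternSet(patterns, metadata={"source": str(path)})
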