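"""Openness simulation: gradual enrollment of subjects in random steps.

The size component ``T`` grows from ``T1`` to ``TR`` in ``R`` steps whose
increments follow a binomial step law, conditioned on (a) every step
enrolling at least one novel subject and (b) the increments summing
exactly to ``TR - T1``.  The label component ``L`` consists of ``M``
independent nested sequences of subject-label sets: at every step the
newly enrolled labels are drawn uniformly without replacement from the
subjects not yet in the system.

One master seed spawns independent sub-streams for the size sequence and
for each label sequence, so adding sequences never perturbs earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "OpennessConfig",
    "SizeSequence",
    "LabelSequences",
    "OpennessSimulation",
    "simulate_sizes",
    "simulate_labels",
    "simulate_openness",
]

_REJECTION_BUDGET = 200_000


@dataclass(frozen=True)
class OpennessConfig:
    """Parameters of the enrollment simulation.

    ``step_trials`` and ``step_prob`` parameterise the Binomial(n, p) step
    law; defaults reproduce a 5-to-97-subject ramp over 24 steps with
    Binomial(100, 0.04) increments, for a 108-subject population and 10
    independent sequences.
    """

    n_subjects: int = 108
    first_size: int = 5
    last_size: int = 97
    n_steps: int = 24
    step_trials: int = 100
    step_prob: float = 0.04
    n_sequences: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.first_size <= self.last_size):
            raise ValueError("need 1 <= first_size <= last_size")
        if self.last_size >= self.n_subjects:
            raise ValueError(
                f"last_size must be smaller than the population "
                f"({self.last_size} >= {self.n_subjects}); keeping unseen subjects "
                "makes distinct sequences overwhelmingly likely"
            )
        if self.n_steps < 1 or self.n_sequences < 1:
            raise ValueError("n_steps and n_sequences must be >= 1")
        if self.n_steps == 1 and self.first_size != self.last_size:
            raise ValueError("a single step requires first_size == last_size")
        if self.n_steps > 1 and (self.n_steps - 1) > (self.last_size - self.first_size):
            raise ValueError(
                f"infeasible: {self.n_steps - 1} steps must each enroll at least one "
                f"subject but only {self.last_size - self.first_size} enrollments remain"
            )
        if self.step_trials < 1 or not (0.0 < self.step_prob < 1.0):
            raise ValueError("step law requires trials >= 1 and 0 < p < 1")

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "first_size": self.first_size,
            "last_size": self.last_size,
            "n_steps": self.n_steps,
            "step_trials": self.step_trials,
            "step_prob": self.step_prob,
            "n_sequences": self.n_sequences,
            "seed": self.seed,
        }


@dataclass
class SizeSequence:
    """Strictly increasing subject counts T[0..R-1] from T1 to TR."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.sizes.ndim != 1 or self.sizes.size < 1:
            raise ValueError("sizes must be a nonempty 1-D integer vector")
        if self.sizes.size > 1 and np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return self.sizes.size


@dataclass
class LabelSequences:
    """M nested label-set sequences; sequences[i][n] is the set at step n."""

    sequences: list[list[frozenset[int]]]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)


@dataclass
class OpennessSimulation:
    """A complete simulation S = (T, L) together with its configuration."""

    config: OpennessConfig
    sizes: SizeSequence
    labels: LabelSequences

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "sizes": self.sizes.sizes.tolist(),
            "sequences": [
                [sorted(step) for step in seq] for seq in self.labels.sequences
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "OpennessSimulation":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            config=OpennessConfig(**payload["config"]),
            sizes=SizeSequence(np.asarray(payload["sizes"])),
            labels=LabelSequences(
                [[frozenset(step) for step in seq] for seq in payload["sequences"]]
            ),
        )


def _spawn_rngs(seed: int, count: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(count)
    return [np.random.default_rng(s) for s in seqs]


def simulate_sizes(cfg: OpennessConfig, rng: np.random.Generator | None = None) -> SizeSequence:
    """Draw the size sequence T.

    The R-1 increments are Binomial(step_trials, step_prob) draws with
    zeros redrawn (every step enrolls at least one subject); whole
    increment vectors are rejection-sampled until they sum exactly to
    ``last_size - first_size``, pinning both endpoints.
    """
    if rng is None:
        rng = _spawn_rngs(cfg.seed, 1)[0]
    r = cfg.n_steps
    if r == 1:
        return SizeSequence(np.array([cfg.first_size]))
    total = cfg.last_size - cfg.first_size
    for attempt in range(1, _REJECTION_BUDGET + 1):
        steps = rng.binomial(cfg.step_trials, cfg.step_prob, size=r - 1)
        while np.any(steps == 0):
            zeros = steps == 0
            steps[zeros] = rng.binomial(cfg.step_trials, cfg.step_prob, size=zeros.sum())
        if steps.sum() == total:
            sizes = cfg.first_size + np.concatenate([[0], np.cumsum(steps)])
            return SizeSequence(sizes)
    raise RuntimeError(
        f"could not match the endpoint sum {total} in {_REJECTION_BUDGET} attempts; "
        "the step law is badly matched to (first_size, last_size, n_steps)"
    )


def simulate_labels(
    cfg: OpennessConfig,
    sizes: SizeSequence,
    rngs: list[np.random.Generator] | None = None,
) -> LabelSequences:
    """Draw M independent nested label sequences over subjects 1..E.

    At each step the newly enrolled labels are a uniformly random
    combination (without replacement) of the still-unknown subjects.
    """
    if sizes.sizes[-1] > cfg.n_subjects:
        raise ValueError("size sequence exceeds the subject population")
    if rngs is None:
        rngs = _spawn_rngs(cfg.seed, 1 + cfg.n_sequences)[1:]
    if len(rngs) != cfg.n_sequences:
        raise ValueError("need one random stream per sequence")
    all_labels = np.arange(1, cfg.n_subjects + 1)
    sequences: list[list[frozenset[int]]] = []
    for rng in rngs:
        unknown = all_labels.copy()
        current: frozenset[int] = frozenset()
        steps: list[frozenset[int]] = []
        prev_size = 0
        for size in sizes.sizes:
            add = rng.choice(unknown, size=size - prev_size, replace=False)
            current = current | frozenset(int(a) for a in add)
            unknown = np.setdiff1d(unknown, add)
            steps.append(current)
            prev_size = size
        sequences.append(steps)
    return LabelSequences(sequences)


def simulate_openness(cfg: OpennessConfig) -> OpennessSimulation:
    """Draw S = (T, L) from one master seed."""
    rngs = _spawn_rngs(cfg.seed, 1 + cfg.n_sequences)
    sizes = simulate_sizes(cfg, rng=rngs[0])
    labels = simulate_labels(cfg, sizes, rngs=rngs[1:])
    return OpennessSimulation(config=cfg, sizes=sizes, labels=labels)
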