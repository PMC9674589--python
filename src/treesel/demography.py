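"""Piecewise-constant demography and simulation parameter containers.

A :class:`Demography` is a staircase of diploid effective population sizes
indexed by time in generations before present (0 = today).  It drives both
the synthetic-data generators and the frequency-trajectory model of the
selection likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Demography", "SimParams"]


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant diploid effective population size through time.

    Parameters
    ----------
    epochs
        Sequence of ``(start_generation, N)`` pairs, sorted by
        ``start_generation`` (generations before present).  The first epoch
        must start at 0; each ``N`` is a diploid size and applies from its
        start until the next epoch's start (the last epoch extends to
        infinity into the past).
    generation_time_years
        Years per generation, used only to convert ages to calendar time.
    """

    epochs: tuple[tuple[int, float], ...]
    generation_time_years: float = 28.0

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise ValueError("Demography needs at least one epoch")
        starts = [int(t) for t, _ in self.epochs]
        sizes = [float(n) for _, n in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start generations must be strictly increasing")
        if any(n < 2 for n in sizes):
            raise ValueError("all effective sizes must be >= 2 diploids")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be positive")
        object.__setattr__(self, "epochs", tuple((a, b) for a, b in zip(starts, sizes)))

    @classmethod
    def constant(cls, N: float, generation_time_years: float = 28.0) -> "Demography":
        """A single-epoch demography of constant diploid size ``N``."""
        return cls(epochs=((0, float(N)),), generation_time_years=generation_time_years)

    @property
    def starts(self) -> np.ndarray:
        return np.array([t for t, _ in self.epochs], dtype=float)

    @property
    def Ns(self) -> np.ndarray:
        return np.array([n for _, n in self.epochs], dtype=float)

    def size_at(self, t: float) -> float:
        """Diploid N at ``t`` generations before present."""
        idx = int(np.searchsorted(self.starts, t, side="right")) - 1
        return float(self.Ns[max(idx, 0)])

    def sizes(self, t: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`size_at` over an array of times (generations ago)."""
        idx = np.searchsorted(self.starts, np.asarray(t, dtype=float), side="right") - 1
        return self.Ns[np.clip(idx, 0, len(self.Ns) - 1)]

    def next_change_after(self, t: float) -> float:
        """Time (generations ago) of the next epoch boundary past ``t``, or inf."""
        later = self.starts[self.starts > t]
        return float(later[0]) if later.size else np.inf

    def generations_to_years(self, g: float | np.ndarray) -> float | np.ndarray:
        return g * self.generation_time_years


@dataclass(frozen=True)
class SimParams:
    """Parameters of a haplotype-level simulation.

    ``mutation_rate`` and ``recombination_rate`` are per site (bp) per
    generation; ``sequence_length`` in bp; ``n_samples`` counts haplotypes.
    """

    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    sequence_length: float = 1e5
    n_samples: int = 100
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least two sampled haplotypes")
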