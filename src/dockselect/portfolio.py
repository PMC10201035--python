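"""The candidate algorithm portfolio.

AutoDock's Lamarckian Genetic Algorithm (LGA) hybridizes a genetic algorithm
with a local searcher.  A portfolio of distinctly parameterized LGA variants
is the candidate set the per-instance selector chooses from.  Three LGA
parameters are varied:

* ``population_size`` — individuals (candidate poses) per generation,
* ``mutation_rate``   — probability that an individual is perturbed,
* ``window_size``     — size of the energy window selecting which
  individuals undergo local search,

plus the local-searcher variant itself: pseudo-Solis–Wets (``psw``, the
default) or the classical Solis–Wets (``sw``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

LOCAL_SEARCHERS = ("psw", "sw")


@dataclass(frozen=True)
class AlgorithmConfig:
    """One LGA parameterization, identified by a short label such as ``"A6"``."""

    id: str
    population_size: int
    mutation_rate: float
    window_size: int
    local_search: str = "psw"

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError(f"population_size must be >= 1, got {self.population_size}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError(f"mutation_rate must be in [0, 1], got {self.mutation_rate}")
        if self.window_size < 1:
            raise ValueError(f"window_size must be >= 1, got {self.window_size}")
        if self.local_search not in LOCAL_SEARCHERS:
            raise ValueError(
                f"local_search must be one of {LOCAL_SEARCHERS}, got {self.local_search!r}"
            )


@dataclass(frozen=True)
class AlgorithmPortfolio:
    """An ordered set of :class:`AlgorithmConfig` with unique ids."""

    configs: tuple[AlgorithmConfig, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.configs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate algorithm ids in portfolio: {dupes}")

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self) -> Iterator[AlgorithmConfig]:
        return iter(self.configs)

    def __getitem__(self, algorithm_id: str) -> AlgorithmConfig:
        for c in self.configs:
            if c.id == algorithm_id:
                return c
        raise KeyError(algorithm_id)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.configs]


# The canonical 28-entry portfolio: A1..A27 are the 27 distinct combinations
# of population {50, 150, 200} x mutation {0.02, 0.5, 0.8} x window
# {10, 30, 50} with the pseudo-Solis-Wets searcher, in the conventional A-label order;
# A28 repeats the AutoDock default parameters (150, 0.02, 10) with the
# classical Solis-Wets searcher.
_CANONICAL_ROWS: tuple[tuple[int, float, int, str], ...] = (
    (50, 0.02, 10, "psw"),   # A1
    (150, 0.02, 10, "psw"),  # A2  (AutoDock default parameters)
    (200, 0.02, 10, "psw"),  # A3
    (150, 0.5, 10, "psw"),   # A4
    (150, 0.8, 10, "psw"),   # A5
    (150, 0.02, 30, "psw"),  # A6
    (150, 0.02, 50, "psw"),  # A7
    (50, 0.02, 30, "psw"),   # A8
    (50, 0.02, 50, "psw"),   # A9
    (200, 0.02, 30, "psw"),  # A10
    (50, 0.5, 10, "psw"),    # A11
    (50, 0.5, 30, "psw"),    # A12
    (50, 0.5, 50, "psw"),    # A13
    (50, 0.8, 10, "psw"),    # A14
    (50, 0.8, 30, "psw"),    # A15
    (50, 0.8, 50, "psw"),    # A16
    (150, 0.5, 30, "psw"),   # A17
    (150, 0.5, 50, "psw"),   # A18
    (150, 0.8, 30, "psw"),   # A19
    (150, 0.8, 50, "psw"),   # A20
    (200, 0.02, 50, "psw"),  # A21
    (200, 0.5, 10, "psw"),   # A22
    (200, 0.5, 30, "psw"),   # A23
    (200, 0.5, 50, "psw"),   # A24
    (200, 0.8, 10, "psw"),   # A25
    (200, 0.8, 30, "psw"),   # A26
    (200, 0.8, 50, "psw"),   # A27
    (150, 0.02, 10, "sw"),   # A28
)


def build_portfolio() -> AlgorithmPortfolio:
    """Return the canonical 28-configuration LGA portfolio (A1..A28)."""
    configs = tuple(
        AlgorithmConfig(
            id=f"A{i + 1}",
            population_size=pop,
            mutation_rate=mut,
            window_size=win,
            local_search=ls,
        )
        for i, (pop, mut, win, ls) in enumerate(_CANONICAL_ROWS)
    )
    return AlgorithmPortfolio(configs=configs)
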