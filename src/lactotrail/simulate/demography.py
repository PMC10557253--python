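"""Demographic models: population trees with splits, size epochs and pulses.

Public times are years before present (BP); the engine works in generations,
converted via ``gen_time`` in exactly one place (:meth:`DemographicModel.to_generations`).
Splits are momi-style label merges: ``(T, derived, ancestral)`` means that,
looking backward in time, every lineage of ``derived`` joins ``ancestral`` at
time T; the ancestral label carries on. Pulses ``(t, source, dest, p)`` mean
that, forward in time, a fraction p of ``dest`` ancestry arrived from
``source`` at time t (implemented backward as lineage reassignment dest ->
source with probability p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# study conditions: dog mutation rate per bp per generation and generation time
DOG_MU = 4.5e-9
DOG_GEN_TIME = 3.0

__all__ = ["DemographicModel", "SampleConfig", "DOG_MU", "DOG_GEN_TIME",
           "tibetan_dog_model"]


@dataclass
class SampleConfig:
    """Number of sampled haplotypes per population (default 4 per population)."""

    n_haplotypes: dict[str, int]

    def __post_init__(self) -> None:
        for pop, n in self.n_haplotypes.items():
            if n < 1:
                raise ValueError(f"sample size for {pop!r} must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.n_haplotypes.values())


@dataclass
class DemographicModel:
    populations: list[str]
    splits: list[tuple[float, str, str]]          # (time BP, derived, ancestral)
    sizes: dict[str, list[tuple[float, float]]]   # pop -> [(epoch start BP, Ne)]
    pulses: list[tuple[float, str, str, float]] = field(default_factory=list)
    mu: float = DOG_MU
    gen_time: float = DOG_GEN_TIME

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def _availability(self) -> dict[str, float]:
        """Time BP at which each population label stops existing (inf = root)."""
        ends = {p: np.inf for p in self.populations}
        for t, derived, _anc in self.splits:
            ends[derived] = t
        return ends

    def validate(self) -> None:
        pops = set(self.populations)
        if len(pops) != len(self.populations):
            raise ValueError("duplicate population labels")
        for t, derived, anc in self.splits:
            if t <= 0:
                raise ValueError("split times must be positive")
            if derived not in pops or anc not in pops:
                raise ValueError(f"split refers to unknown population: {derived}/{anc}")
        ends = self._availability()
        roots = [p for p, e in ends.items() if np.isinf(e)]
        if len(roots) != 1:
            raise ValueError(f"model must have exactly one root population, got {roots}")
        # topological consistency: the ancestral label must outlive the split
        for t, derived, anc in self.splits:
            if ends[anc] <= t:
                raise ValueError(
                    f"population {anc!r} ends at {ends[anc]} BP but receives a "
                    f"split at {t} BP")
        for pop in self.populations:
            if pop not in self.sizes:
                raise ValueError(f"no size specified for population {pop!r}")
            for _, ne in self.sizes[pop]:
                if ne <= 0:
                    raise ValueError("Ne must be positive")
        for t, source, dest, p in self.pulses:
            if not 0 < p <= 1:
                raise ValueError(f"pulse proportion {p} outside (0, 1]")
            if source not in pops or dest not in pops:
                raise ValueError("pulse refers to unknown population")
            if t >= ends[source] or t >= ends[dest] or t <= 0:
                raise ValueError(
                    f"pulse at {t} BP outside the lifetime of {source!r}/{dest!r}")
        if self.mu <= 0 or self.gen_time <= 0:
            raise ValueError("mu and gen_time must be positive")

    # -- compilation -----------------------------------------------------
    def to_generations(self, t_bp: float) -> float:
        return t_bp / self.gen_time

    def compile_events(self):
        """Event arrays for the kernels, sorted by time in generations.

        Returns (init_sizes, ev_time, ev_kind, ev_a, ev_b, ev_x) with kinds
        0 = size change, 1 = pulse, 2 = split.
        """
        idx = {p: i for i, p in enumerate(self.populations)}
        events: list[tuple[float, int, int, int, float]] = []
        init = np.empty(len(self.populations))
        for pop, epochs in self.sizes.items():
            epochs = sorted(epochs)
            if epochs[0][0] != 0:
                raise ValueError(f"{pop!r}: first size epoch must start at 0 BP")
            init[idx[pop]] = epochs[0][1]
            for t_bp, ne in epochs[1:]:
                events.append((self.to_generations(t_bp), 0, idx[pop], -1, ne))
        for t_bp, source, dest, p in self.pulses:
            events.append((self.to_generations(t_bp), 1, idx[dest], idx[source], p))
        for t_bp, derived, anc in self.splits:
            events.append((self.to_generations(t_bp), 2, idx[derived], idx[anc], 0.0))
        # stable sort by (time, kind): pulses fire before a simultaneous split
        events.sort(key=lambda e: (e[0], e[1]))
        ev_time = np.array([e[0] for e in events], dtype=np.float64)
        ev_kind = np.array([e[1] for e in events], dtype=np.int64)
        ev_a = np.array([e[2] for e in events], dtype=np.int64)
        ev_b = np.array([e[3] for e in events], dtype=np.int64)
        ev_x = np.array([e[4] for e in events], dtype=np.float64)
        return init, ev_time, ev_kind, ev_a, ev_b, ev_x

    def sample_array(self, config: SampleConfig) -> np.ndarray:
        n = np.zeros(len(self.populations), dtype=np.int64)
        for pop, cnt in config.n_haplotypes.items():
            if pop not in self.populations:
                raise ValueError(f"sampled population {pop!r} not in model")
            n[self.populations.index(pop)] = cnt
        return n


def tibetan_dog_model(*,
                      n_eur: float = 20_000.0,
                      n_tib: float = 20_000.0,
                      n_sea: float = 20_000.0,
                      t_eurasia: float = 20_000.0,
                      t_tibsea: float = 4_500.0,
                      pulse_tib: tuple[float, float] | None = (3_600.0, 0.3),
                      pulse_sea: tuple[float, float] | None = (3_700.0, 0.3),
                      outgroup: bool = False,
                      t_outgroup: float = 2_000_000.0,
                      mu: float = DOG_MU,
                      gen_time: float = DOG_GEN_TIME) -> DemographicModel:
    """Three-population dog model (European breeds, (Tibetan dogs, SEAID)).

    Defaults encode the study conditions: splits ~2e4 and 4.5e3 BP and pulse
    gene flow from European breeds into Tibetan dogs (and optionally SEAID)
    ~3.6e3 BP at proportion 0.3, mu = 4.5e-9 per generation, 3-year
    generations. ``outgroup=True`` appends a deeply diverged fox outgroup.
    """
    pops = ["EUR", "TIB_DOG", "SEAID"]
    splits = [(t_tibsea, "TIB_DOG", "SEAID"), (t_eurasia, "SEAID", "EUR")]
    sizes = {"EUR": [(0.0, n_eur)], "TIB_DOG": [(0.0, n_tib)],
             "SEAID": [(0.0, n_sea)]}
    pulses = []
    if pulse_tib is not None:
        pulses.append((pulse_tib[0], "EUR", "TIB_DOG", pulse_tib[1]))
    if pulse_sea is not None:
        pulses.append((pulse_sea[0], "EUR", "SEAID", pulse_sea[1]))
    if outgroup:
        pops = pops + ["FOX"]
        splits = splits + [(t_outgroup, "EUR", "FOX")]
        sizes["FOX"] = [(0.0, n_eur)]
    return DemographicModel(populations=pops, splits=splits, sizes=sizes,
                            pulses=pulses, mu=mu, gen_time=gen_time)
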