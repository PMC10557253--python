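"""Forward diploid Wright-Fisher simulation with a single selected site.

Used to generate positive and null inputs for the haplotype-based selection
statistics (EHH/iHS) and for two-population ΔDAF contrasts. Fitness at the
focal site is multiplicative {1, 1+hs, 1+s}; recombination is uniform at rate
``r`` per bp per generation; mutation is infinite-sites on a finite grid of
``m_sites`` positions (a grid site is reused only after its derived allele has
been lost again, which approximates infinite sites at desk scale).

Populations are deliberately small (default N = 500 diploids) with rates meant
to be rescaled so that N*s and N*r match the process being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import HaplotypeMatrix

__all__ = ["SweepConfig", "SweepResult", "simulate_sweep"]


@dataclass
class SweepConfig:
    N: int = 500                 # diploid population size (per population)
    L: float = 1e6               # sequence length, bp
    r: float = 2e-7              # recombination rate per bp per generation
    s: float = 0.0               # selection coefficient of the derived focal allele
    h: float = 0.5               # dominance
    f0: float = 0.0              # focal-allele frequency when the sweep starts
    duration: int = 200          # generations simulated after the sweep starts
    seed: int = 0
    mu: float = 1e-8             # mutation rate per bp per generation
    m_sites: int = 1000          # potential mutation sites on the grid
    burn_in: int | None = None   # neutral generations before the sweep (default 4N)
    split_gen: int | None = None # generations after sweep start at which to split
    selected_pop: int = 0        # daughter population carrying selection (0 or 1)
    condition_segregating: bool = False
    condition_min_freq: float = 0.0
    condition_max_freq: float = 1.0
    stop_at_freq: float | None = None   # stop selecting once the focal allele
                                        # first reaches this frequency
    stop_on_absorption: bool = False    # stop once the focal allele fixes/is lost
    retry_cap: int = 20
    init: str = "monomorphic"    # or "random": sites start at U(0.1, 0.9) frequency
    record_het: bool = False
    pop_labels: tuple[str, ...] = ("POP1", "POP2")

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")
        if self.s < -1.0:
            raise ValueError("s must be >= -1")
        if self.N < 2:
            raise ValueError("N must be >= 2")


@dataclass
class SweepResult:
    hm: HaplotypeMatrix
    trajectory: np.ndarray            # focal derived frequency per generation
    focal_pos: int
    focal_index: int                  # column of the focal site in hm
    fixed: bool
    lost: bool
    het_trajectory: np.ndarray | None = None
    attempts: int = 1


def _gametes(H: np.ndarray, parents: np.ndarray, positions: np.ndarray,
             L: float, r: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete per entry of ``parents`` (diploid indices into H row pairs)."""
    n_gam = len(parents)
    start = rng.integers(0, 2, size=n_gam)
    n_x = rng.poisson(r * L, size=n_gam)
    out = H[2 * parents + start].copy()
    which = np.nonzero(n_x > 0)[0]
    for g in which:
        bp = np.sort(rng.uniform(0.0, L, size=n_x[g]))
        # phase at each site = start + number of breakpoints to its left (mod 2)
        phase = (start[g] + np.searchsorted(bp, positions)) % 2
        sel = np.nonzero(phase != start[g])[0]
        out[g, sel] = H[2 * parents[g] + 1 - start[g], sel]
    return out


def _next_generation(H: np.ndarray, focal: int, s: float, h: float,
                     positions: np.ndarray, L: float, r: float,
                     rng: np.random.Generator) -> np.ndarray:
    N = H.shape[0] // 2
    if s != 0.0:
        g = H[0::2, focal].astype(np.int64) + H[1::2, focal]
        w = np.choose(g, (1.0, 1.0 + h * s, 1.0 + s))
        p = w / w.sum()
    else:
        p = None
    mothers = rng.choice(N, size=N, p=p)
    fathers = rng.choice(N, size=N, p=p)
    parents = np.empty(2 * N, dtype=np.int64)
    parents[0::2] = mothers
    parents[1::2] = fathers
    return _gametes(H, parents, positions, L, r, rng)


def _mutate(H: np.ndarray, focal: int, mu: float, L: float,
            rng: np.random.Generator) -> None:
    nh, m = H.shape
    n_new = rng.poisson(mu * L * nh)
    if n_new == 0:
        return
    counts = (H == 1).sum(axis=0)
    free = np.nonzero(counts == 0)[0]
    free = free[free != focal]
    if len(free) == 0:
        return
    sites = rng.choice(free, size=min(n_new, len(free)), replace=False)
    haps = rng.integers(0, nh, size=len(sites))
    H[haps, sites] = 1


def simulate_sweep(cfg: SweepConfig) -> SweepResult:
    """Run the forward simulation; deterministic for a fixed ``cfg.seed``.

    The neutral burn-in is computed once per seed; when a segregation or
    frequency condition rejects an outcome, only the post-burn-in phase is
    re-run (conditioning on the same standing variation).
    """
    rng0 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77]))
    H_burn, positions, focal = _burn(cfg, np.random.default_rng(
        rng0.integers(2**31 - 1)))
    attempts = 0
    while True:
        attempts += 1
        if attempts > cfg.retry_cap:
            raise RuntimeError(
                f"focal allele failed the segregation condition in "
                f"{cfg.retry_cap} attempts")
        rng = np.random.default_rng(rng0.integers(2**31 - 1))
        res = _sweep_phase(cfg, H_burn.copy(), positions, focal, rng)
        if cfg.condition_segregating and (res.lost or res.fixed):
            continue
        f_end = res.trajectory[-1]
        if cfg.condition_min_freq > 0 and f_end < cfg.condition_min_freq:
            continue
        if f_end > cfg.condition_max_freq:
            continue
        res.attempts = attempts
        return res


def _burn(cfg: SweepConfig, rng: np.random.Generator):
    N, m = cfg.N, cfg.m_sites
    nh = 2 * N
    positions = np.sort(rng.choice(np.arange(1, int(cfg.L)), size=m, replace=False))
    focal = int(np.searchsorted(positions, cfg.L / 2))
    focal = min(focal, m - 1)
    H = np.zeros((nh, m), dtype=np.int8)
    if cfg.init == "random":
        freqs = rng.uniform(0.1, 0.9, size=m)
        H[:] = (rng.random((nh, m)) < freqs).astype(np.int8)
        H[:, focal] = 0
    burn = 4 * N if cfg.burn_in is None else cfg.burn_in
    for _ in range(burn):
        H = _next_generation(H, focal, 0.0, cfg.h, positions, cfg.L, cfg.r, rng)
        _mutate(H, focal, cfg.mu, cfg.L, rng)
    return H, positions, focal


def _sweep_phase(cfg: SweepConfig, H: np.ndarray, positions: np.ndarray,
                 focal: int, rng: np.random.Generator) -> SweepResult:
    N = cfg.N
    nh = 2 * N
    # introduce the focal derived allele at frequency f0
    n_copies = max(1, round(cfg.f0 * nh)) if cfg.f0 > 0 else 0
    H[:, focal] = 0
    if n_copies:
        H[rng.choice(nh, size=n_copies, replace=False), focal] = 1

    pops = [H]
    traj = [H[:, focal].mean()]
    hets = [] if not cfg.record_het else [_mean_het(H)]
    reached = False
    for gen in range(cfg.duration):
        if reached:
            break
        if cfg.split_gen is not None and gen == cfg.split_gen and len(pops) == 1:
            pops = [pops[0].copy(), pops[0].copy()]
        new_pops = []
        for pi, P in enumerate(pops):
            s_here = cfg.s if (len(pops) == 1 or pi == cfg.selected_pop) else 0.0
            P = _next_generation(P, focal, s_here, cfg.h, positions, cfg.L,
                                 cfg.r, rng)
            _mutate(P, focal, cfg.mu, cfg.L, rng)
            new_pops.append(P)
        pops = new_pops
        f_now = pops[0][:, focal].mean()
        traj.append(f_now)
        if cfg.record_het:
            hets.append(_mean_het(pops[0]))
        if cfg.stop_at_freq is not None and f_now >= cfg.stop_at_freq:
            reached = True
        if cfg.stop_on_absorption and f_now in (0.0, 1.0):
            reached = True

    Hs = np.concatenate(pops, axis=0)
    labels = cfg.pop_labels[:len(pops)]
    sample_ids, pop_of = [], {}
    for pi, lab in enumerate(labels):
        for i in range(N):
            sid = f"{lab}_{i}"
            sample_ids.append(sid)
            pop_of[sid] = lab
    traj = np.asarray(traj)
    f_final = pops[0][:, focal].mean()
    hm = HaplotypeMatrix(chrom="sweep", positions=positions.astype(np.int64),
                         H=Hs, sample_ids=sample_ids, pop_of=pop_of,
                         polarized=True,
                         meta={"seed": cfg.seed, "engine": "forward-wf",
                               "focal_pos": int(positions[focal])})
    return SweepResult(hm=hm, trajectory=traj, focal_pos=int(positions[focal]),
                       focal_index=focal, fixed=bool(f_final >= 1.0),
                       lost=bool(f_final <= 0.0),
                       het_trajectory=np.asarray(hets) if cfg.record_het else None)


def _mean_het(H: np.ndarray) -> float:
    p = (H == 1).mean(axis=0)
    return float(np.mean(2 * p * (1 - p)))
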