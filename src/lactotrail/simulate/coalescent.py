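"""Multi-locus coalescent simulation and Monte-Carlo expected branch lengths.

Loci are independent and non-recombining (discrete-event Hudson coalescent per
locus); mutations follow the infinite-sites model, Poisson-placed on branches
with rate mu * locus_len per generation. Haplotypes come back polarized
(0 = ancestral, 1 = derived) because the simulator knows the ancestral state.
"""

from __future__ import annotations

import numpy as np

from ..io import HaplotypeMatrix
from . import _kernels
from .demography import DemographicModel, SampleConfig

__all__ = ["simulate_coalescent", "branch_spectrum"]


def _kernel_seed(seed: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31 - 1))


def branch_spectrum(model: DemographicModel, config: SampleConfig,
                    tally_pops: list[str], n_genealogies: int, seed: int):
    """Expected branch length per derived-leaf configuration of the tally pops.

    Returns (B, total_mean): B[i, j, k] is the Monte-Carlo mean branch length
    (generations) subtending i, j, k sampled leaves of the up-to-three tally
    populations; total_mean is the mean total tree length.
    """
    if len(tally_pops) > 3:
        raise ValueError("at most 3 tally populations")
    n_by_pop = model.sample_array(config)
    init, *ev = model.compile_events()
    tally = np.full(3, -1, dtype=np.int64)
    for i, pop in enumerate(tally_pops):
        tally[i] = model.populations.index(pop)
    B, total, err = _kernels.branch_length_spectrum(
        n_by_pop, tally, *ev, init, n_genealogies, _kernel_seed(seed))
    if err == 1:
        raise RuntimeError("unreachable common ancestor: populations never merge")
    return B, total


def simulate_coalescent(model: DemographicModel, config: SampleConfig,
                        n_loci: int, locus_len: float, seed: int,
                        chrom: str = "sim") -> HaplotypeMatrix:
    """Simulate phased haplotypes at ``n_loci`` independent loci.

    Locus ``l`` occupies coordinates ``[l * locus_len + 1, (l+1) * locus_len]``
    so downstream block resampling by genomic coordinate groups whole loci.
    Samples are emitted as diploids named ``<POP>_<i>`` (two consecutive
    haplotype rows each); odd sample counts are rejected.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if config.total > 64:
        raise ValueError("at most 64 sampled haplotypes supported")
    for pop, cnt in config.n_haplotypes.items():
        if cnt % 2:
            raise ValueError(f"odd haplotype count for {pop!r}; diploid output "
                             "needs even counts")
    n_by_pop = model.sample_array(config)
    init, *ev = model.compile_events()
    theta = model.mu * locus_len

    # generous buffer: E[S] per locus = theta * E[T_total]; retry bigger on overflow
    cap = max(10_000, int(4 * theta * 10 * float(np.max(init)) * n_loci) + 1000)
    kseed = _kernel_seed(seed)
    for _attempt in range(6):
        masks, counts, used, err = _kernels.simulate_loci(
            n_by_pop, *ev, init, n_loci, theta, cap, kseed)
        if err == 1:
            raise RuntimeError("unreachable common ancestor: populations never merge")
        if err == 0:
            break
        cap *= 4
    else:
        raise RuntimeError("mutation buffer overflow persisted")

    n = int(n_by_pop.sum())
    # expand bitmasks into a haplotype matrix, dropping sites fixed in the sample
    masks = masks[:used]
    bits = np.arange(n, dtype=np.uint64)
    H = ((masks[:, None] >> bits[None, :]) & np.uint64(1)).astype(np.int8).T

    # positions: uniform within each locus, strictly increasing via re-draw
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    positions = np.empty(used, dtype=np.int64)
    off = 0
    L = int(locus_len)
    for l, c in enumerate(counts):
        c = int(c)
        if c == 0:
            continue
        base = l * L
        while True:
            pos = np.sort(rng.integers(1, L + 1, size=c))
            if len(np.unique(pos)) == c:
                break
        positions[off:off + c] = base + pos
        off += c

    # kernel order within a population follows model population order
    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    for pi, pop in enumerate(model.populations):
        for i in range(int(n_by_pop[pi]) // 2):
            sid = f"{pop}_{i}"
            sample_ids.append(sid)
            pop_of[sid] = pop

    hm = HaplotypeMatrix(
        chrom=chrom, positions=positions, H=H, sample_ids=sample_ids,
        pop_of=pop_of, polarized=True,
        meta={"seed": seed, "n_loci": n_loci, "locus_len": L,
              "engine": "hudson-coalescent"},
    )
    return hm
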