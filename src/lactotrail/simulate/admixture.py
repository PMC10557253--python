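"""Mosaic admixed-haplotype generator with tract-level ground truth.

Each target haplotype is a mosaic of tracts copied from two reference panels:
tract breakpoints follow a Poisson process of rate ``g_adm * r`` per bp (the
expected tract structure ``g_adm`` generations after a single admixture
event), and each tract copies a uniformly chosen haplotype from panel A with
probability ``q``, otherwise from panel B. The returned truth painting is the
gold standard for validating the local-ancestry stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..io import HaplotypeMatrix

__all__ = ["AdmixtureTruth", "simulate_admixed"]


@dataclass
class AdmixtureTruth:
    """Per-target-haplotype donor label (0 = panel A, 1 = panel B) per site."""

    donor: np.ndarray          # (n_targets, n_sites) int8
    positions: np.ndarray
    q: float
    generations: float
    breakpoints: list[np.ndarray]

    def donor_fraction_a(self) -> float:
        """Mean fraction of sites painted donor A across target haplotypes."""
        return float((self.donor == 0).mean())

    def to_tracts(self, chrom: str = "sim") -> list[tuple[str, str, int, int, str]]:
        """BED-like tract rows (haplotype, chrom, start, end, donor), half-open."""
        rows = []
        for h in range(self.donor.shape[0]):
            lab = self.donor[h]
            change = np.nonzero(np.diff(lab))[0]
            starts = np.r_[0, change + 1]
            ends = np.r_[change, len(lab) - 1]
            for s, e in zip(starts, ends):
                rows.append((f"hap{h}", chrom, int(self.positions[s]),
                             int(self.positions[e]) + 1,
                             "A" if lab[s] == 0 else "B"))
        return rows


def simulate_admixed(panel_a: HaplotypeMatrix, panel_b: HaplotypeMatrix,
                     q: float, generations: float, r: float,
                     n_targets: int, seed: int,
                     target_pop: str = "TARGET") -> tuple[HaplotypeMatrix, AdmixtureTruth]:
    """Build ``n_targets`` admixed haplotypes from two reference panels.

    Panels must share positions. Targets are emitted as diploids (n_targets
    must be even) labelled ``target_pop``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise ValueError("panels must share positions")
    if n_targets % 2:
        raise ValueError("n_targets must be even (diploid output)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    pos = panel_a.positions
    n_sites = len(pos)
    span = float(pos[-1] - pos[0]) if n_sites > 1 else 0.0
    rate = generations * r

    H = np.empty((n_targets, n_sites), dtype=np.int8)
    donor = np.empty((n_targets, n_sites), dtype=np.int8)
    breakpoints: list[np.ndarray] = []
    for h in range(n_targets):
        n_bp = rng.poisson(rate * span)
        bp = np.sort(rng.uniform(float(pos[0]), float(pos[-1]), size=n_bp))
        breakpoints.append(bp)
        # tract index per site; each tract draws a donor and a source haplotype
        tract = np.searchsorted(bp, pos, side="right")
        n_tracts = n_bp + 1
        tract_donor = (rng.random(n_tracts) >= q).astype(np.int8)  # 0=A w.p. q
        src_a = rng.integers(0, panel_a.n_haplotypes, size=n_tracts)
        src_b = rng.integers(0, panel_b.n_haplotypes, size=n_tracts)
        donor[h] = tract_donor[tract]
        row = np.where(donor[h] == 0,
                       panel_a.H[src_a[tract], np.arange(n_sites)],
                       panel_b.H[src_b[tract], np.arange(n_sites)])
        H[h] = row

    sample_ids = [f"{target_pop}_{i}" for i in range(n_targets // 2)]
    hm = HaplotypeMatrix(chrom=panel_a.chrom, positions=pos.copy(), H=H,
                         sample_ids=sample_ids,
                         pop_of={s: target_pop for s in sample_ids},
                         polarized=panel_a.polarized,
                         meta={"seed": seed, "q": q, "generations": generations})
    truth = AdmixtureTruth(donor=donor, positions=pos.copy(), q=q,
                           generations=generations, breakpoints=breakpoints)
    return hm, truth


def write_truth_tsv(truth: AdmixtureTruth, path: str, chrom: str = "sim") -> None:
    """Write the truth painting as `haplotype chrom start end donor` TSV."""
    with open(path, "w") as fh:
        for hap, c, s, e, d in truth.to_tracts(chrom):
            fh.write(f"{hap}\t{c}\t{s}\t{e}\t{d}\n")
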