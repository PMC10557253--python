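"""Haplotype-based selection statistics: EHH curves, iHS, and ΔDAF.

EHH (extended haplotype homozygosity) at marker x for a core allele is the
probability that two randomly drawn carrier haplotypes are identical over the
interval [core, x]:

    EHH(x) = sum_h C(n_h, 2) / C(n_c, 2)

over the distinct extended haplotypes h among the n_c carriers. iHH is the
trapezoidal integral of EHH over physical distance, computed outward on both
sides of the core until EHH falls below a truncation cutoff (default 0.05;
the first marker below the cutoff is included in the integral). The
unstandardized score ln(iHH_ancestral / iHH_derived) is z-normalized within
derived-allele-frequency bins (Voight's convention: strongly negative values
mean unusually long derived haplotypes). Cores whose EHH is still above the
cutoff at a chromosome end are flagged invalid rather than silently kept.

These functions expect the haplotypes of a single population; subset with
:meth:`HaplotypeMatrix.subset_pops` first. Unphased data never reach here
(the VCF reader rejects them).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import MISSING, HaplotypeMatrix

__all__ = ["EHHCurve", "IHSResult", "DeltaDafResult", "ehh", "ihs",
           "standardize_ihs", "delta_daf", "write_ihs_tsv"]


@dataclass
class EHHCurve:
    core_index: int
    core_pos: int
    allele: int
    positions: np.ndarray   # ascending, spans the computed extent incl. core
    values: np.ndarray      # EHH at each position; 1.0 at the core
    n_carriers: int
    truncated_left: bool    # hit chromosome start while EHH >= cutoff
    truncated_right: bool

    def at_core(self) -> float:
        return float(self.values[np.searchsorted(self.positions, self.core_pos)])


def _extend(H: np.ndarray, carriers: np.ndarray, core: int, step: int,
            cutoff: float) -> tuple[list[float], list[int], bool]:
    """Walk markers outward from the core; return (ehh values, indices, truncated)."""
    n_c = len(carriers)
    denom = n_c * (n_c - 1)
    group = np.zeros(n_c, dtype=np.int64)
    rows = carriers.copy()
    vals: list[float] = []
    idx: list[int] = []
    j = core + step
    n_sites = H.shape[1]
    while 0 <= j < n_sites:
        col = H[rows, j]
        keep = col != MISSING
        if not keep.all():
            rows, group, col = rows[keep], group[keep], col[keep]
        key = group * 2 + col
        counts = np.bincount(key)
        e = float((counts * (counts - 1)).sum() / denom)
        vals.append(e)
        idx.append(j)
        if e < cutoff:
            return vals, idx, False
        # relabel compactly; singleton groups can never merge again, drop them
        big = counts[key] > 1
        if not big.all():
            rows, key = rows[big], key[big]
        relabel = np.full(len(counts), -1, dtype=np.int64)
        occupied = np.nonzero(counts > 1)[0]
        relabel[occupied] = np.arange(len(occupied))
        group = relabel[key]
        j += step
    return vals, idx, True


def ehh(hm: HaplotypeMatrix, core: int, allele: int,
        cutoff: float = 0.05) -> EHHCurve:
    """EHH curve around the site at column index ``core`` for one allele class.

    Extends in both directions until EHH < ``cutoff`` or the chromosome end.
    Requires at least two carriers of ``allele`` at the core.
    """
    if not 0 <= core < hm.n_sites:
        raise IndexError("core site index out of range")
    carriers = np.nonzero(hm.H[:, core] == allele)[0]
    if len(carriers) < 2:
        raise ValueError(
            f"EHH undefined: {len(carriers)} carrier(s) of allele {allele}")
    rv, ri, rtrunc = _extend(hm.H, carriers, core, +1, cutoff)
    lv, li, ltrunc = _extend(hm.H, carriers, core, -1, cutoff)
    positions = np.concatenate([hm.positions[li][::-1],
                                [hm.positions[core]],
                                hm.positions[ri]])
    values = np.array(lv[::-1] + [1.0] + rv)
    return EHHCurve(core_index=core, core_pos=int(hm.positions[core]),
                    allele=allele, positions=positions, values=values,
                    n_carriers=len(carriers),
                    truncated_left=ltrunc, truncated_right=rtrunc)


def _ihh(curve: EHHCurve) -> float:
    """Trapezoidal integral of EHH over bp, both sides of the core."""
    return float(np.trapezoid(curve.values, curve.positions))


@dataclass
class IHSResult:
    index: int
    pos: int
    daf: float
    ihh_a: float
    ihh_d: float
    ihs_raw: float | None
    ihs_std: float | None = None
    bin_id: int | None = None
    valid: bool = True
    reason: str = ""


def ihs(hm: HaplotypeMatrix, maf_min: float = 0.05,
        ehh_cut: float = 0.05) -> list[IHSResult]:
    """Unstandardized iHS for every site passing the MAF filter.

    Sites at minor allele frequency <= ``maf_min`` are skipped entirely;
    sites whose EHH integral is truncated by a chromosome end, or with a
    degenerate carrier class, are returned flagged invalid.
    """
    if not hm.polarized:
        raise ValueError("iHS requires polarized haplotypes")
    d, n = hm.derived_counts()
    daf = np.where(n > 0, d / np.maximum(n, 1), np.nan)
    out: list[IHSResult] = []
    for j in range(hm.n_sites):
        f = daf[j]
        if not np.isfinite(f) or min(f, 1 - f) <= maf_min:
            continue
        res = IHSResult(index=j, pos=int(hm.positions[j]), daf=float(f),
                        ihh_a=np.nan, ihh_d=np.nan, ihs_raw=None)
        try:
            ca = ehh(hm, j, 0, cutoff=ehh_cut)
            cd = ehh(hm, j, 1, cutoff=ehh_cut)
        except ValueError:
            res.valid, res.reason = False, "too few carriers"
            out.append(res)
            continue
        res.ihh_a, res.ihh_d = _ihh(ca), _ihh(cd)
        if any((ca.truncated_left, ca.truncated_right,
                cd.truncated_left, cd.truncated_right)):
            res.valid, res.reason = False, "truncated at chromosome end"
        elif res.ihh_a <= 0 or res.ihh_d <= 0:
            res.valid, res.reason = False, "zero integrated EHH"
        else:
            res.ihs_raw = float(np.log(res.ihh_a / res.ihh_d))
        out.append(res)
    return out


def standardize_ihs(results: list[IHSResult], n_bins: int = 50,
                    min_bin: int = 20, mode: str = "binned") -> list[IHSResult]:
    """Z-score the raw scores within derived-allele-frequency bins.

    ``mode="binned"`` (default) uses ``n_bins`` equal DAF bins, merging bins
    with fewer than ``min_bin`` valid SNPs into their nearest neighbor;
    ``mode="global"`` z-scores all valid SNPs together. Population (ddof=0)
    standard deviation throughout.
    """
    valid = [r for r in results if r.valid and r.ihs_raw is not None]
    if not valid:
        raise ValueError("no valid SNPs to standardize")
    raw = np.array([r.ihs_raw for r in valid])
    if mode == "global":
        bins = np.zeros(len(valid), dtype=np.int64)
    elif mode == "binned":
        daf = np.array([r.daf for r in valid])
        bins = np.minimum((daf * n_bins).astype(np.int64), n_bins - 1)
        # merge undersized bins into their nearest occupied neighbor
        while True:
            uniq, counts = np.unique(bins, return_counts=True)
            if len(uniq) <= 1:
                break
            small = uniq[counts < min_bin]
            if len(small) == 0:
                break
            b = small[0]
            others = uniq[uniq != b]
            nearest = others[np.argmin(np.abs(others - b))]
            bins[bins == b] = nearest
    else:
        raise ValueError("mode must be 'binned' or 'global'")
    std = np.empty_like(raw)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = raw[sel].mean(), raw[sel].std()
        std[sel] = 0.0 if sd == 0 else (raw[sel] - mu) / sd
    out = []
    lookup = {id(r): (z, b) for r, z, b in zip(valid, std, bins)}
    for r in results:
        if id(r) in lookup:
            z, b = lookup[id(r)]
            out.append(replace(r, ihs_std=float(z), bin_id=int(b)))
        else:
            out.append(replace(r))
    return out


@dataclass
class DeltaDafResult:
    positions: np.ndarray
    daf_target: np.ndarray
    daf_reference: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.daf_target - self.daf_reference


def delta_daf(hm: HaplotypeMatrix, target_pop: str,
              reference_pop: str) -> DeltaDafResult:
    """Per-SNP derived-allele-frequency difference, target minus reference."""
    if not hm.polarized:
        raise ValueError("ΔDAF requires polarized haplotypes")
    ft = hm.frequencies(target_pop)
    fr = hm.frequencies(reference_pop)
    return DeltaDafResult(hm.positions.copy(), ft, fr)


def write_ihs_tsv(results: list[IHSResult], chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tdaf\tihh_a\tihh_d\tihs_raw\tihs_std\tbin\tvalid\n")
        for r in results:
            raw = "NA" if r.ihs_raw is None else f"{r.ihs_raw:.6g}"
            std = "NA" if r.ihs_std is None else f"{r.ihs_std:.6g}"
            b = "NA" if r.bin_id is None else str(r.bin_id)
            fh.write(f"{chrom}\t{r.pos}\t{r.daf:.6g}\t{r.ihh_a:.6g}\t"
                     f"{r.ihh_d:.6g}\t{raw}\t{std}\t{b}\t{int(r.valid)}\n")
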