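"""ABBA-BABA introgression statistics: genome-wide D with block-jackknife Z
and sliding-window D / f_dM scans with top-quantile outlier calling.

All statistics are frequency-based over an ordered quartet (P1, P2, P3, O)
of per-site derived-allele frequencies:

    ABBA = (1 - p1) * p2 * p3 * (1 - pO)
    BABA = p1 * (1 - p2) * p3 * (1 - pO)
    D    = sum(ABBA - BABA) / sum(ABBA + BABA)

Positive D means excess derived-allele sharing between P2 and P3. The window
statistic f_dM (Malinsky's symmetric variant of f_d) shares the numerator and
normalizes by the same quantity computed with the candidate donor frequency
substituted, giving a window-level introgressed-fraction estimate in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SiteFrequencies

__all__ = ["DStatResult", "WindowStat", "site_patterns", "genome_d",
           "window_stats", "top_windows", "write_windows_tsv"]


def _abba(p1, p2, p3, pO):
    return (1 - p1) * p2 * p3 * (1 - pO)


def _baba(p1, p2, p3, pO):
    return p1 * (1 - p2) * p3 * (1 - pO)


def site_patterns(freqs: SiteFrequencies):
    """Per-site ABBA, BABA and the f_dM dynamic-donor denominator terms.

    Sites with a missing frequency in any population contribute zeros.
    """
    p1, p2, p3, pO = freqs.p1, freqs.p2, freqs.p3, freqs.pO
    ok = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(pO))
    p1 = np.where(ok, p1, 0.0)
    p2 = np.where(ok, p2, 0.0)
    p3 = np.where(ok, p3, 0.0)
    pO = np.where(ok, pO, 0.0)
    abba = np.where(ok, _abba(p1, p2, p3, pO), 0.0)
    baba = np.where(ok, _baba(p1, p2, p3, pO), 0.0)
    # dynamic donor: the more derived of recipient/donor plays the donor role
    pD2 = np.maximum(p2, p3)
    pD1 = np.maximum(p1, p3)
    denom = np.where(
        p2 >= p1,
        _abba(p1, pD2, pD2, pO) - _baba(p1, pD2, pD2, pO),
        -(_abba(pD1, p2, pD1, pO) - _baba(pD1, p2, pD1, pO)))
    denom = np.where(ok, denom, 0.0)
    informative = ok & ((abba + baba) > 0)
    return abba, baba, denom, ok, informative


@dataclass
class DStatResult:
    D: float | None
    Z: float | None
    n_blocks: int
    abba_sum: float
    baba_sum: float
    n_informative: int
    block_d: np.ndarray | None = None
    block_weights: np.ndarray | None = None

    @property
    def defined(self) -> bool:
        return self.D is not None


def genome_d(freqs: SiteFrequencies, block_size: int = 5_000_000,
             min_blocks_for_z: int = 10) -> DStatResult:
    """Genome-wide Patterson's D with a weighted delete-one block jackknife Z.

    Blocks are fixed ``block_size`` bp intervals; block weights are their
    informative-site counts (Busing's weighted jackknife variance). Z is
    withheld when fewer than ``min_blocks_for_z`` blocks are non-empty.
    """
    abba, baba, _, _, info = site_patterns(freqs)
    num = float((abba - baba).sum())
    den = float((abba + baba).sum())
    if den == 0:
        return DStatResult(None, None, 0, 0.0, 0.0, 0)
    D = num / den

    block_of = (freqs.positions - 1) // block_size
    uniq = np.unique(block_of[info])
    g = len(uniq)
    if g < min_blocks_for_z:
        return DStatResult(D, None, g, float(abba.sum()), float(baba.sum()),
                           int(info.sum()))
    bl_num = np.array([float((abba - baba)[block_of == b].sum()) for b in uniq])
    bl_den = np.array([float((abba + baba)[block_of == b].sum()) for b in uniq])
    m = np.array([int(info[block_of == b].sum()) for b in uniq], dtype=float)
    n_tot = m.sum()
    d_del = (num - bl_num) / (den - bl_den)   # delete-one estimates
    h = n_tot / m
    pseudo = h * D - (h - 1.0) * d_del
    theta_j = g * D - float(((1.0 - m / n_tot) * d_del).sum())
    var = float((1.0 / g) * np.sum((pseudo - theta_j) ** 2 / (h - 1.0)))
    se = np.sqrt(var)
    Z = D / se if se > 0 else None
    block_d = np.where(bl_den > 0, bl_num / np.where(bl_den > 0, bl_den, 1.0),
                       np.nan)
    return DStatResult(D, Z, g, float(abba.sum()), float(baba.sum()),
                       int(info.sum()), block_d, m)


@dataclass
class WindowStat:
    chrom: str
    start: int            # 1-based, half-open [start, end)
    end: int
    n_snps: int
    D: float | None
    fdm: float | None
    abba_sum: float
    baba_sum: float
    denom_sum: float


def window_stats(freqs: SiteFrequencies, window: int = 100_000,
                 step: int = 20_000, min_snps: int = 100) -> list[WindowStat]:
    """Sliding-window D and f_dM on a fixed coordinate grid from position 1.

    Windows advance by ``step``; windows with fewer than ``min_snps``
    informative SNPs are omitted. An f_dM with zero denominator is emitted as
    None (undefined), never as 0.
    """
    if step > window:
        raise ValueError("step must not exceed window size")
    abba, baba, denom, ok, _ = site_patterns(freqs)
    pos = freqs.positions
    if len(pos) == 0:
        return []
    out: list[WindowStat] = []
    last = int(pos.max())
    start = 1
    while start <= last:
        end = start + window
        in_win = (pos >= start) & (pos < end) & ok
        n = int(in_win.sum())
        if n >= min_snps:
            a, b, dn = abba[in_win].sum(), baba[in_win].sum(), denom[in_win].sum()
            num = a - b
            D = float(num / (a + b)) if (a + b) > 0 else None
            fdm = float(num / dn) if dn != 0 else None
            out.append(WindowStat(freqs.chrom, start, end, n, D, fdm,
                                  float(a), float(b), float(dn)))
        start += step
    return out


def top_windows(stats: list[WindowStat], quantile: float = 0.01,
                statistic: str = "fdm") -> list[WindowStat]:
    """Windows at or above the (1 - quantile) empirical quantile, descending.

    Ties at the cut are kept. Windows where the statistic is undefined are
    ignored.
    """
    if not stats:
        raise ValueError("empty window list")
    if statistic not in ("fdm", "D"):
        raise ValueError("statistic must be 'fdm' or 'D'")
    vals = [(getattr(w, statistic), w) for w in stats
            if getattr(w, statistic) is not None]
    if not vals:
        return []
    arr = np.array([v for v, _ in vals])
    cut = np.quantile(arr, 1.0 - quantile)
    keep = [(v, w) for v, w in vals if v >= cut]
    keep.sort(key=lambda t: -t[0])
    return [w for _, w in keep]


def write_windows_tsv(stats: list[WindowStat], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_snps\tD\tfdM\n")
        for w in stats:
            d = "NA" if w.D is None else f"{w.D:.6g}"
            f = "NA" if w.fdm is None else f"{w.fdm:.6g}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{d}\t{f}\n")
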