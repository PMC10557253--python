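"""Haplotype I/O: VCF reading/writing, ancestral-allele polarization, frequencies.

The central container is :class:`HaplotypeMatrix`, a phased binary haplotype
matrix (rows = haplotypes, two consecutive rows per diploid individual;
columns = biallelic SNP sites). After :func:`polarize`, 0 means ancestral and
1 means derived; before polarization the coding is REF=0 / ALT=1 as in the
source VCF. Missing alleles are stored as -1 and are excluded from every
frequency denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

log = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "PopMap",
    "SiteFrequencies",
    "read_popmap",
    "write_popmap",
    "read_vcf",
    "write_vcf",
    "polarize",
    "site_frequencies",
]


@dataclass
class PopMap:
    """Mapping sample id -> population label (sample ids unique)."""

    pop_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.pop_of) == 0:
            raise ValueError("empty population map")

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.pop_of.items() if p == pop]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_of.values():
            seen.setdefault(p, None)
        return list(seen)


def read_popmap(path: str) -> PopMap:
    """Read a two-column headerless TSV ``sample<TAB>population``."""
    pop_of: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            sample, pop = parts
            if sample in pop_of:
                raise ValueError(f"{path}:{ln}: duplicate sample id {sample!r}")
            pop_of[sample] = pop
    return PopMap(pop_of)


def write_popmap(popmap: PopMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.pop_of.items():
            fh.write(f"{sample}\t{pop}\n")


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes x biallelic SNP sites.

    Attributes
    ----------
    chrom : chromosome label shared by all sites.
    positions : strictly increasing 1-based physical coordinates (bp).
    H : int8 array (n_haplotypes, n_sites); 0/1 alleles, -1 missing.
        Row ``2*i`` and ``2*i + 1`` are the two haplotypes of individual
        ``sample_ids[i]``.
    sample_ids : diploid individual ids, one per pair of rows.
    pop_of : sample id -> population label.
    polarized : True once 0/1 mean ancestral/derived rather than REF/ALT.
    ref, alt, ancestral : per-site allele strings (may be None for purely
        simulated data).
    """

    chrom: str
    positions: np.ndarray
    H: np.ndarray
    sample_ids: list[str]
    pop_of: dict[str, str]
    polarized: bool = False
    ref: list[str] | None = None
    alt: list[str] | None = None
    ancestral: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.H = np.asarray(self.H, dtype=np.int8)
        if self.H.ndim != 2:
            raise ValueError("H must be 2-D (haplotypes x sites)")
        if self.H.shape[1] != len(self.positions):
            raise ValueError("H column count != number of positions")
        if self.H.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected two haplotype rows per sample")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.H, (0, 1, MISSING))
        if bad.any():
            raise ValueError("H entries must be 0, 1 or -1 (missing)")
        for s in self.sample_ids:
            if s not in self.pop_of:
                raise ValueError(f"sample {s!r} has no population label")

    # -- basic accessors -------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_sites(self) -> int:
        return self.H.shape[1]

    def haplotype_rows(self, pop: str) -> np.ndarray:
        """Row indices of all haplotypes belonging to population ``pop``."""
        rows = []
        for i, s in enumerate(self.sample_ids):
            if self.pop_of[s] == pop:
                rows.extend((2 * i, 2 * i + 1))
        if not rows:
            raise KeyError(f"population {pop!r} not present")
        return np.asarray(rows, dtype=np.intp)

    def subset_pops(self, pops: list[str]) -> "HaplotypeMatrix":
        keep = [i for i, s in enumerate(self.sample_ids) if self.pop_of[s] in pops]
        rows = np.asarray([r for i in keep for r in (2 * i, 2 * i + 1)], dtype=np.intp)
        ids = [self.sample_ids[i] for i in keep]
        return replace(self, H=self.H[rows], sample_ids=ids,
                       pop_of={s: self.pop_of[s] for s in ids})

    def derived_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived count, non-missing haplotype count)."""
        sub = self.H if pop is None else self.H[self.haplotype_rows(pop)]
        nonmiss = (sub != MISSING).sum(axis=0)
        derived = (sub == 1).sum(axis=0)
        return derived.astype(np.int64), nonmiss.astype(np.int64)

    def frequencies(self, pop: str | None = None) -> np.ndarray:
        d, n = self.derived_counts(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, d / np.maximum(n, 1), np.nan)


@dataclass
class SiteFrequencies:
    """Per-site derived-allele frequencies for an ordered (P1, P2, P3, O) quartet."""

    chrom: str
    positions: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    pO: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n3: np.ndarray
    nO: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "pO"):
            p = getattr(self, name)
            ok = np.isnan(p) | ((p >= 0) & (p <= 1))
            if not ok.all():
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path: str, popmap: PopMap, *, max_missing: float = 0.2,
             require_pass: bool = True) -> HaplotypeMatrix:
    """Read phased diploid genotypes from a VCF into a :class:`HaplotypeMatrix`.

    Only biallelic SNP records are retained; multiallelic and non-SNP records
    are skipped (logged). Records with any unphased genotype are dropped and
    counted. Sites with more than ``max_missing`` missing haplotypes are
    dropped. Every VCF sample must appear in ``popmap``. The matrix is in
    REF/ALT coding; call :func:`polarize` to move to ancestral/derived.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError(f"{path}: no samples in VCF")
    for s in samples:
        if s not in popmap.pop_of:
            raise ValueError(f"sample {s!r} in VCF but absent from the population map")

    has_aa = "AA" in vf.header.info
    positions: list[int] = []
    cols: list[np.ndarray] = []
    refs: list[str] = []
    alts: list[str] = []
    aas: list[str | None] = []
    chrom = None
    n_skipped_nonsnp = n_unphased = n_missing_drop = 0
    nh = 2 * len(samples)
    max_miss_count = max_missing * nh

    for rec in vf:
        if chrom is None:
            chrom = rec.chrom
        elif rec.chrom != chrom:
            raise ValueError("multi-chromosome VCFs are read one chromosome at a time")
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped_nonsnp += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            n_skipped_nonsnp += 1
            continue
        if require_pass and rec.filter.keys() not in ([], ["PASS"]):
            n_skipped_nonsnp += 1
            continue
        col = np.empty(nh, dtype=np.int8)
        phased_ok = True
        for j, s in enumerate(samples):
            sm = rec.samples[s]
            gt = sm["GT"]
            if len(gt) != 2:
                phased_ok = False
                break
            if not sm.phased and None not in gt and gt[0] != gt[1]:
                phased_ok = False
                break
            for k in (0, 1):
                col[2 * j + k] = MISSING if gt[k] is None else gt[k]
        if not phased_ok:
            n_unphased += 1
            continue
        if (col == MISSING).sum() > max_miss_count:
            n_missing_drop += 1
            continue
        positions.append(rec.pos)
        cols.append(col)
        refs.append(ref)
        alts.append(alt)
        aas.append(rec.info.get("AA") if has_aa else None)
    vf.close()

    if n_skipped_nonsnp or n_unphased or n_missing_drop:
        log.info("read_vcf(%s): skipped %d non-biallelic-SNP, %d unphased, "
                 "%d high-missingness records", path, n_skipped_nonsnp,
                 n_unphased, n_missing_drop)

    H = (np.stack(cols, axis=1) if cols
         else np.empty((nh, 0), dtype=np.int8))
    hm = HaplotypeMatrix(
        chrom=chrom or "NA", positions=np.asarray(positions, dtype=np.int64),
        H=H, sample_ids=samples,
        pop_of={s: popmap.pop_of[s] for s in samples},
        ref=refs, alt=alts,
        meta={"skipped_nonsnp": n_skipped_nonsnp, "skipped_unphased": n_unphased,
              "skipped_missing": n_missing_drop},
    )
    hm.meta["aa"] = aas
    return hm


def write_vcf(hm: HaplotypeMatrix, path: str) -> None:
    """Write a HaplotypeMatrix as a phased VCFv4.2 file (deterministic output).

    Simulated matrices without allele strings use REF=A, ALT=G; polarized
    matrices emit the ancestral allele in the AA INFO field.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(f"##contig=<ID={hm.chrom}>")
    for s in hm.sample_ids:
        header.add_sample(s)
    out = pysam.VariantFile(path, "w", header=header)
    for j in range(hm.n_sites):
        ref = hm.ref[j] if hm.ref else "A"
        alt = hm.alt[j] if hm.alt else "G"
        rec = out.new_record(contig=hm.chrom, start=int(hm.positions[j]) - 1,
                             stop=int(hm.positions[j]), alleles=(ref, alt))
        if hm.polarized:
            rec.info["AA"] = hm.ancestral[j] if hm.ancestral else ref
        for i, s in enumerate(hm.sample_ids):
            a, b = hm.H[2 * i, j], hm.H[2 * i + 1, j]
            rec.samples[s]["GT"] = (None if a == MISSING else int(a),
                                    None if b == MISSING else int(b))
            rec.samples[s].phased = True
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize(hm: HaplotypeMatrix,
             ancestral: list[str | None] | str | None = None,
             outgroup_pop: str | None = None) -> HaplotypeMatrix:
    """Recode the matrix so 0 = ancestral and 1 = derived at every site.

    The ancestral state comes either from ``ancestral`` (per-site ancestral
    base, e.g. the VCF AA tag; ``"AA"`` selects the tags stored by
    :func:`read_vcf`) or from a named outgroup population whose fixed allele
    defines the ancestral state. Sites where the ancestral allele matches
    neither REF nor ALT, or where the outgroup is polymorphic or entirely
    missing, are removed and counted in ``meta['unpolarizable']``.
    """
    if hm.polarized:
        return hm
    if (ancestral is None) == (outgroup_pop is None):
        raise ValueError("give exactly one of `ancestral` or `outgroup_pop`")

    n_sites = hm.n_sites
    flip = np.zeros(n_sites, dtype=bool)
    keep = np.ones(n_sites, dtype=bool)
    anc_base: list[str | None] = [None] * n_sites

    if outgroup_pop is not None:
        og = hm.H[hm.haplotype_rows(outgroup_pop)]
        for j in range(n_sites):
            col = og[:, j]
            obs = np.unique(col[col != MISSING])
            if len(obs) != 1:  # polymorphic or all-missing outgroup
                keep[j] = False
                continue
            flip[j] = obs[0] == 1
            if hm.ref is not None:
                anc_base[j] = (hm.alt[j] if flip[j] else hm.ref[j])
    else:
        if isinstance(ancestral, str) and ancestral == "AA":
            ancestral = hm.meta.get("aa")
            if ancestral is None:
                raise ValueError("no AA annotations stored on this matrix")
        if hm.ref is None or hm.alt is None:
            raise ValueError("REF/ALT alleles required for base-wise polarization")
        for j in range(n_sites):
            aa = ancestral[j]
            aa = aa.upper() if isinstance(aa, str) else None
            if aa == hm.ref[j]:
                anc_base[j] = aa
            elif aa == hm.alt[j]:
                flip[j] = True
                anc_base[j] = aa
            else:
                keep[j] = False

    if not keep.any():
        raise ValueError("no site could be polarized")

    H = hm.H.copy()
    fl = np.where(flip)[0]
    sub = H[:, fl]
    miss = sub == MISSING
    H[:, fl] = 1 - sub
    H[:, fl][miss] = MISSING

    idx = np.where(keep)[0]
    new = replace(
        hm,
        positions=hm.positions[idx],
        H=H[:, idx],
        polarized=True,
        ref=[hm.ref[j] for j in idx] if hm.ref else None,
        alt=[hm.alt[j] for j in idx] if hm.alt else None,
        ancestral=[anc_base[j] for j in idx],
        meta=dict(hm.meta, unpolarizable=int((~keep).sum())),
    )
    return new


def site_frequencies(hm: HaplotypeMatrix,
                     quartet: tuple[str, str, str, str]) -> SiteFrequencies:
    """Per-site derived-allele frequencies for an ordered (P1, P2, P3, O) quartet."""
    freqs, nums = [], []
    for pop in quartet:
        d, n = hm.derived_counts(pop)  # raises KeyError for unknown pops
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, d / np.maximum(n, 1), np.nan)
        freqs.append(p)
        nums.append(n)
    return SiteFrequencies(hm.chrom, hm.positions.copy(),
                           freqs[0], freqs[1], freqs[2], freqs[3],
                           nums[0], nums[1], nums[2], nums[3])
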