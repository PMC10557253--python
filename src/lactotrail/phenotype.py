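"""Lactase-persistence phenotyping from hydrogen breath tests.

After a 50-g lactose challenge, undigested lactose is fermented by gut
bacteria with hydrogen as a by-product, so a rising breath-hydrogen curve
indicates lactase non-persistence (LNP). A subject is classified lactase
persistent (LP) iff the maximum increment over the fasting baseline across
all post-dose readings is strictly less than 20 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

LP_THRESHOLD_PPM = 20.0

__all__ = ["LP_THRESHOLD_PPM", "BreathTestRecord", "GenotypeCounts",
           "classify_lp", "allele_frequency", "percent", "cross_tab",
           "read_breath_csv", "classify_cohort"]


@dataclass
class BreathTestRecord:
    subject: str
    baseline: float
    readings: list[float]          # ppm at 30-min marks post dose
    genotype: str = "missing"      # GG / GA / AA / missing

    def __post_init__(self) -> None:
        if self.baseline is None:
            raise ValueError(f"{self.subject}: missing baseline reading")
        if len(self.readings) < 1:
            raise ValueError(f"{self.subject}: needs at least one reading")
        if any(r < 0 for r in self.readings) or self.baseline < 0:
            raise ValueError(f"{self.subject}: negative ppm reading")
        if self.genotype not in ("GG", "GA", "AA", "missing"):
            raise ValueError(f"{self.subject}: bad genotype {self.genotype!r}")

    @property
    def max_increment(self) -> float:
        return max(r - self.baseline for r in self.readings)

    @property
    def carrier(self) -> bool:
        return self.genotype in ("GA", "AA")


def classify_lp(record: BreathTestRecord) -> str:
    """"LP" iff the maximum rise over baseline is strictly below 20 ppm."""
    return "LP" if record.max_increment < LP_THRESHOLD_PPM else "LNP"


@dataclass
class GenotypeCounts:
    n_hom_derived: int
    n_het: int
    n_hom_ancestral: int
    n_missing: int = 0
    population: str = ""

    def __post_init__(self) -> None:
        if min(self.n_hom_derived, self.n_het, self.n_hom_ancestral,
               self.n_missing) < 0:
            raise ValueError("negative genotype count")

    @property
    def n_total(self) -> int:
        return (self.n_hom_derived + self.n_het + self.n_hom_ancestral
                + self.n_missing)


def allele_frequency(counts: GenotypeCounts) -> float:
    """Derived-allele frequency (2*hom + het) / (2 * non-missing individuals)."""
    denom = 2 * (counts.n_total - counts.n_missing)
    if denom == 0:
        raise ValueError("no genotyped individuals")
    return (2 * counts.n_hom_derived + counts.n_het) / denom


def percent(frequency: float) -> float:
    """Percentage rounded half-up to one decimal (7.3 for 6/82)."""
    return float(Decimal(repr(frequency * 100)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


def cross_tab(records: list[BreathTestRecord]) -> dict[str, int]:
    """2x2 carrier-by-phenotype table; genotype-missing subjects counted apart.

    No association test is performed: cohorts of this size do not support one.
    """
    if not records:
        raise ValueError("empty cohort")
    cells = {"carrier_lp": 0, "carrier_lnp": 0,
             "noncarrier_lp": 0, "noncarrier_lnp": 0,
             "missing_genotype": 0, "n_lp": 0, "n": len(records)}
    for rec in records:
        lp = classify_lp(rec) == "LP"
        cells["n_lp"] += lp
        if rec.genotype == "missing":
            cells["missing_genotype"] += 1
            continue
        key = ("carrier" if rec.carrier else "noncarrier") + \
              ("_lp" if lp else "_lnp")
        cells[key] += 1
    return cells


def read_breath_csv(path_or_df) -> list[BreathTestRecord]:
    """Read `subject,baseline,h30,...,h180,genotype` CSV (or a DataFrame)."""
    df = (path_or_df if isinstance(path_or_df, pd.DataFrame)
          else pd.read_csv(path_or_df))
    reading_cols = [c for c in df.columns if c.startswith("h") and
                    c[1:].isdigit()]
    if not reading_cols:
        raise ValueError("no post-dose reading columns (h30...h180) found")
    reading_cols.sort(key=lambda c: int(c[1:]))
    recs = []
    for _, row in df.iterrows():
        geno = row.get("genotype", "missing")
        geno = "missing" if pd.isna(geno) else str(geno)
        recs.append(BreathTestRecord(
            subject=str(row["subject"]), baseline=float(row["baseline"]),
            readings=[float(row[c]) for c in reading_cols], genotype=geno))
    return recs


def classify_cohort(records: list[BreathTestRecord]) -> pd.DataFrame:
    rows = [(r.subject, r.baseline, r.max_increment, r.genotype,
             classify_lp(r)) for r in records]
    return pd.DataFrame(rows, columns=["subject", "baseline", "max_increment",
                                       "genotype", "phenotype"])
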