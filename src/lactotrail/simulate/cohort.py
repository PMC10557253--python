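"""Synthetic hydrogen breath-test cohorts for the phenotype stage.

Each subject has a fasting baseline reading plus six post-dose readings at
30-minute marks over 3 hours (seven measurements in all). Lactase-persistent
(LP) subjects are built with a maximum rise over baseline strictly below the
20 ppm diagnostic threshold; non-persistent (LNP) subjects rise above it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TIMEPOINTS = (30, 60, 90, 120, 150, 180)
READING_COLS = tuple(f"h{t}" for t in TIMEPOINTS)
COLUMNS = ("subject", "baseline") + READING_COLS + ("genotype",)

__all__ = ["TIMEPOINTS", "READING_COLS", "COLUMNS",
           "simulate_breath_cohort", "synthetic_study_cohort"]


def _readings(baseline: float, peak_incr: float, rng: np.random.Generator) -> list[float]:
    """Six readings rising to baseline+peak_incr at a random 30-min mark."""
    peak_at = rng.integers(2, len(TIMEPOINTS))
    shape = np.exp(-0.5 * ((np.arange(len(TIMEPOINTS)) - peak_at) / 1.8) ** 2)
    vals = baseline + peak_incr * shape / shape.max()
    return [float(round(v, 1)) for v in vals]


def simulate_breath_cohort(n: int, carrier_freq: float,
                           lp_rate_carrier: float, lp_rate_noncarrier: float,
                           baseline_ppm_range: tuple[float, float],
                           seed: int) -> pd.DataFrame:
    """Generate ``n`` subjects with genotype at -13838 and breath readings.

    Carriers (heterozygote GA, probability ``carrier_freq``) are LP with
    probability ``lp_rate_carrier``; non-carriers (GG) with
    ``lp_rate_noncarrier``. The planted phenotype is recoverable exactly by
    the 20-ppm rule and echoed in a ``true_lp`` column.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for rate in (carrier_freq, lp_rate_carrier, lp_rate_noncarrier):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    rows = []
    for i in range(n):
        carrier = rng.random() < carrier_freq
        geno = "GA" if carrier else "GG"
        lp = rng.random() < (lp_rate_carrier if carrier else lp_rate_noncarrier)
        b0 = float(round(rng.uniform(*baseline_ppm_range), 1))
        peak = float(rng.uniform(0.0, 15.0)) if lp else float(rng.uniform(25.0, 80.0))
        rows.append([f"T{i+1:03d}", b0, *_readings(b0, peak, rng), geno, lp])
    return pd.DataFrame(rows, columns=list(COLUMNS) + ["true_lp"])


def synthetic_study_cohort(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the study's 32-person genotype-phenotype table.

    The real supplementary table is not redistributed here; this generator
    reproduces only its printed marginal counts: 32 adults, 2 LP phenotypes,
    2 heterozygote carriers of -13838G>A, with 1 subject in both groups.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 55]))
    rows = []
    # subject 1: carrier and LP; subject 2: carrier, LNP; subject 3: LP non-carrier
    plan = [("GA", True), ("GA", False), ("GG", True)] + [("GG", False)] * 29
    for i, (geno, lp) in enumerate(plan):
        b0 = float(round(rng.uniform(3.0, 12.0), 1))
        peak = float(rng.uniform(0.0, 15.0)) if lp else float(rng.uniform(25.0, 80.0))
        rows.append([f"T{i+1:03d}", b0, *_readings(b0, peak, rng), geno])
    return pd.DataFrame(rows, columns=list(COLUMNS))
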