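"""Joint-SFS demographic inference with pulse admixture.

The three-population joint site frequency spectrum (SFS) is fitted under a
multinomial composite likelihood: conditional on a site segregating in the
sample, its derived-copy configuration (i, j, k) has probability equal to the
expected genealogy branch length subtending that configuration divided by the
expected total polymorphic branch length. Expected branch lengths are
estimated by Monte Carlo over independent genealogies simulated under the
candidate demography (common random numbers across parameter values within an
optimization, so the likelihood surface is smooth in the parameters).

Three nested candidate models for the dog history are provided:

* M0 — null: (European breeds, (Tibetan dogs, SEAID)) with no gene flow
* M1 — one pulse: European breeds -> Tibetan dogs
* M2 — two pulses: European breeds -> Tibetan dogs and -> SEAID

Model selection follows the study's protocol: many independent optimization
runs per model, a Welch two-tailed t-test on the run log-likelihood
distributions, and block-bootstrap percentile confidence intervals (the SFS
split into contiguous equal-size blocks of sites, resampled with replacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import HaplotypeMatrix
from .simulate.coalescent import branch_spectrum
from .simulate.demography import (DOG_GEN_TIME, DOG_MU, DemographicModel,
                                  SampleConfig)

P_FLOOR = 1e-9  # floor for Monte-Carlo zero cells so log-likelihood stays finite

__all__ = [
    "JointSFS", "FitResult", "ModelComparison", "BootstrapCI", "ParamSpec",
    "ModelTemplate", "build_joint_sfs", "expected_sfs", "composite_loglik",
    "fit_model", "select_model", "bootstrap_ci", "dog_model_template",
    "dog_natural_params", "pulse1_time_bp", "tibsea_split_bp",
    "write_sfs_tsv", "read_sfs_tsv",
]


# ---------------------------------------------------------------------------
# Joint SFS
# ---------------------------------------------------------------------------

@dataclass
class JointSFS:
    pops: tuple[str, str, str]
    sample_sizes: tuple[int, int, int]
    site_configs: np.ndarray      # (S, 3) derived copies per population
    site_pos: np.ndarray          # (S,) genomic coordinate, ascending

    def __post_init__(self) -> None:
        self.site_configs = np.asarray(self.site_configs, dtype=np.int64)
        self.site_pos = np.asarray(self.site_pos, dtype=np.int64)
        n = np.asarray(self.sample_sizes)
        if self.site_configs.shape[0] != len(self.site_pos):
            raise ValueError("configs/positions length mismatch")
        if len(self.site_configs) and (
                (self.site_configs < 0).any() or (self.site_configs > n).any()):
            raise ValueError("derived counts outside [0, sample size]")
        tot = self.site_configs.sum(axis=1)
        if len(tot) and ((tot == 0).any() or (tot == n.sum()).any()):
            raise ValueError("monomorphic configurations must be excluded")

    @property
    def S(self) -> int:
        return self.site_configs.shape[0]

    def counts(self) -> np.ndarray:
        """Dense spectrum xi[i, j, k]; the all-zero/all-n cells stay zero."""
        n1, n2, n3 = self.sample_sizes
        xi = np.zeros((n1 + 1, n2 + 1, n3 + 1), dtype=np.int64)
        np.add.at(xi, tuple(self.site_configs.T), 1)
        return xi

    def resample_blocks(self, block_ids: np.ndarray, K: int) -> "JointSFS":
        """New JointSFS from drawing the given contiguous blocks (of K) again."""
        blocks = np.array_split(np.arange(self.S), K)
        idx = np.concatenate([blocks[b] for b in block_ids])
        return JointSFS(self.pops, self.sample_sizes,
                        self.site_configs[idx],
                        np.sort(self.site_pos[idx]))


def build_joint_sfs(hm: HaplotypeMatrix, pops: tuple[str, str, str]) -> JointSFS:
    """Tally the joint SFS over sites polymorphic within the three populations.

    Requires polarized input. Sites with missing haplotypes in any of the
    three populations are dropped (the configuration needs a fixed sample
    size); monomorphic sites are excluded by definition.
    """
    if not hm.polarized:
        raise ValueError("joint SFS requires polarized (ancestral/derived) input")
    cfg = []
    ns = []
    complete = np.ones(hm.n_sites, dtype=bool)
    for pop in pops:
        d, n = hm.derived_counts(pop)
        n_full = len(hm.haplotype_rows(pop))
        if n_full < 2:
            raise ValueError(f"population {pop!r} needs >= 2 haplotypes")
        complete &= n == n_full
        cfg.append(d)
        ns.append(n_full)
    cfg = np.stack(cfg, axis=1)
    tot = cfg.sum(axis=1)
    keep = complete & (tot > 0) & (tot < sum(ns))
    return JointSFS(tuple(pops), tuple(ns), cfg[keep], hm.positions[keep])


def write_sfs_tsv(sfs: JointSFS, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pops={','.join(sfs.pops)} "
                 f"n={','.join(map(str, sfs.sample_sizes))}\n")
        fh.write("i\tj\tk\tcount\n")
        xi = sfs.counts()
        for (i, j, k), c in np.ndenumerate(xi):
            if c:
                fh.write(f"{i}\t{j}\t{k}\t{c}\n")


def read_sfs_tsv(path: str) -> JointSFS:
    """Read the TSV written by :func:`write_sfs_tsv` (site positions become
    synthetic indices, so block bootstrap over the original layout is lost)."""
    with open(path) as fh:
        head = fh.readline().strip()
        if not head.startswith("#"):
            raise ValueError("missing SFS header line")
        fields = dict(tok.split("=") for tok in head[1:].split())
        pops = tuple(fields["pops"].split(","))
        sizes = tuple(int(x) for x in fields["n"].split(","))
        fh.readline()
        configs, positions = [], []
        pos = 1
        for line in fh:
            i, j, k, c = (int(x) for x in line.split())
            for _ in range(c):
                configs.append((i, j, k))
                positions.append(pos)
                pos += 1
    return JointSFS(pops, sizes, np.array(configs), np.array(positions))


# ---------------------------------------------------------------------------
# Expected SFS and composite likelihood
# ---------------------------------------------------------------------------

def _segregating_probs(B: np.ndarray) -> np.ndarray:
    """Normalize branch lengths to cell probabilities over segregating cells."""
    p = B.copy()
    p[0, 0, 0] = 0.0
    p[-1, -1, -1] = 0.0
    tot = p.sum()
    if tot <= 0:
        raise RuntimeError("no polymorphic branch length accumulated")
    return p / tot


def expected_sfs(model: DemographicModel, config: SampleConfig,
                 pops: tuple[str, str, str], n_genealogies: int, seed: int,
                 n_chunks: int = 4):
    """Monte-Carlo expected SFS cell probabilities with per-cell standard errors.

    Splits the genealogies into ``n_chunks`` independent batches; the returned
    SE is the standard error of the chunk means.
    """
    if n_genealogies < 1_000:
        raise ValueError("n_genealogies < 1000 is too noisy for fitting")
    per = n_genealogies // n_chunks
    ps = []
    for c in range(n_chunks):
        B, _ = branch_spectrum(model, config, list(pops), per, seed + 7919 * c)
        ps.append(_segregating_probs(B))
    ps = np.stack(ps)
    p = ps.mean(axis=0)
    se = ps.std(axis=0, ddof=1) / np.sqrt(n_chunks)
    return p, se


def composite_loglik(sfs: JointSFS, model: DemographicModel,
                     config: SampleConfig, n_genealogies: int, seed: int) -> float:
    """Multinomial composite log-likelihood of the observed SFS under ``model``."""
    B, _ = branch_spectrum(model, config, list(sfs.pops), n_genealogies, seed)
    p = _segregating_probs(B)
    xi = sfs.counts()
    mask = xi > 0
    return float(np.sum(xi[mask] * np.log(np.maximum(p[mask], P_FLOOR))))


# ---------------------------------------------------------------------------
# Model templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    name: str
    lo: float
    hi: float
    scale: str = "log"  # "log" or "lin"

    def from_unit(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        if self.scale == "log":
            return float(np.exp(np.log(self.lo) + u * (np.log(self.hi) - np.log(self.lo))))
        return float(self.lo + u * (self.hi - self.lo))

    def to_unit(self, v: float) -> float:
        if self.scale == "log":
            return float((np.log(v) - np.log(self.lo)) /
                         (np.log(self.hi) - np.log(self.lo)))
        return float((v - self.lo) / (self.hi - self.lo))


@dataclass
class ModelTemplate:
    """A parameterized demography: named bounded parameters plus a builder."""

    name: str
    params: list[ParamSpec]
    builder: "callable"
    n_pulses: int = 0
    fixed: dict[str, float] = field(default_factory=dict)

    def free_params(self) -> list[ParamSpec]:
        return [p for p in self.params if p.name not in self.fixed]

    def build(self, values: dict[str, float]) -> DemographicModel:
        full = dict(self.fixed)
        full.update(values)
        return self.builder(full)

    def values_from_unit(self, u: np.ndarray) -> dict[str, float]:
        return {p.name: p.from_unit(ui) for p, ui in zip(self.free_params(), u)}


def dog_natural_params(v: dict[str, float]) -> dict[str, float]:
    """Times in years BP implied by the fraction-parameterized fit values.

    The Tibetan/SEAID split is parameterized as a fraction of the
    European/Asian split (ordering holds by construction) and clipped to its
    own prior range [2e3, 1.5e4] BP; pulse times are fractions of the
    relevant split time.
    """
    out = dict(v)
    t_eur = v["T_EURASIA"]
    t_ts = float(np.clip(v["T_TIBSEA_FRAC"] * t_eur, 2e3,
                         min(1.5e4, 0.99 * t_eur)))
    out["T_TIBSEA"] = t_ts
    if "P1" in v:
        out["T_PULSE1"] = v["T_PULSE1_FRAC"] * t_ts
    if "P2" in v:
        out["T_PULSE2"] = v["T_PULSE2_FRAC"] * t_eur
    return out


def _dog_builder(v: dict[str, float]) -> DemographicModel:
    nat = dog_natural_params(v)
    t_eur = nat["T_EURASIA"]
    t_ts = nat["T_TIBSEA"]
    sizes = {
        "EUR": [(0.0, v["N_EUR"]), (t_eur, v["N_ROOT"])],
        "TIB_DOG": [(0.0, v["N_TIB"])],
        "SEAID": [(0.0, v["N_SEA"]), (t_ts, v["N_ANC"])],
    }
    pulses = []
    if "P1" in v and v["P1"] > 0:
        pulses.append((v["T_PULSE1_FRAC"] * t_ts, "EUR", "TIB_DOG", v["P1"]))
    if "P2" in v and v["P2"] > 0:
        pulses.append((v["T_PULSE2_FRAC"] * t_eur, "EUR", "SEAID", v["P2"]))
    return DemographicModel(
        populations=["EUR", "TIB_DOG", "SEAID"],
        splits=[(t_ts, "TIB_DOG", "SEAID"), (t_eur, "SEAID", "EUR")],
        sizes=sizes, pulses=pulses,
        mu=v.get("mu", DOG_MU), gen_time=v.get("gen_time", DOG_GEN_TIME))


def dog_model_template(name: str, fixed: dict[str, float] | None = None) -> ModelTemplate:
    """M0 (no pulses), M1 (one pulse EUR->TIB) or M2 (two pulses).

    Bounds follow the study protocol: Ne in [1e3, 5e5]; the European/Asian
    split in [1e4, 3.3e4] BP; the Tibetan/SEAID split in [2e3, 1.5e4] BP;
    pulse times as a fraction of the relevant split time; pulse proportions
    in (0, 1). Pass ``fixed`` to pin any subset of parameters.
    """
    if name not in ("M0", "M1", "M2"):
        raise ValueError("model name must be M0, M1 or M2")
    ne = dict(lo=1e3, hi=5e5, scale="log")
    params = [
        ParamSpec("N_EUR", **ne), ParamSpec("N_TIB", **ne),
        ParamSpec("N_SEA", **ne), ParamSpec("N_ANC", **ne),
        ParamSpec("N_ROOT", **ne),
        ParamSpec("T_EURASIA", 1e4, 3.3e4, "log"),
        ParamSpec("T_TIBSEA_FRAC", 0.07, 0.75, "lin"),
    ]
    n_pulses = {"M0": 0, "M1": 1, "M2": 2}[name]
    if n_pulses >= 1:
        params += [ParamSpec("T_PULSE1_FRAC", 0.02, 0.98, "lin"),
                   ParamSpec("P1", 0.01, 0.99, "lin")]
    if n_pulses >= 2:
        params += [ParamSpec("T_PULSE2_FRAC", 0.02, 0.98, "lin"),
                   ParamSpec("P2", 0.01, 0.99, "lin")]
    return ModelTemplate(name=name, params=params, builder=_dog_builder,
                         n_pulses=n_pulses, fixed=dict(fixed or {}))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    loglik: float
    start_index: int
    converged: bool
    n_evals: int


def fit_model(sfs: JointSFS, template: ModelTemplate, *, n_starts: int = 100,
              seed: int = 0, n_genealogies: int = 10_000,
              max_evals: int = 500, two_stage: bool = True,
              reeval_genealogies: int | None = 50_000,
              init_points: list[dict[str, float]] | None = None,
              config: SampleConfig | None = None) -> list[FitResult]:
    """Multi-start bounded derivative-free fit of ``template`` to ``sfs``.

    Each start draws a uniform point in the transformed unit cube (or takes
    one of ``init_points``, consumed first — useful for warm starts and for
    seeding a richer model from a nested model's optimum) and runs bounded
    Powell search: a coarse stage at a quarter of ``n_genealogies`` followed
    by a refinement stage at full precision from the coarse optimum. Common
    random numbers hold within each run (one Monte-Carlo seed per run, so the
    surface a run searches is deterministic), while different runs draw
    different surface realizations and are genuinely independent. Each run's
    final log-likelihood is then re-evaluated once at higher precision
    (``reeval_genealogies``) with a seed shared across all runs and models
    fitted with the same ``seed``, which makes the returned log-likelihoods
    directly comparable; pass None to keep the raw optimizer value. Returns
    every run, not just the best.
    """
    if sfs.S == 0:
        raise ValueError("degenerate SFS: no segregating sites")
    if config is None:
        config = SampleConfig(dict(zip(sfs.pops, sfs.sample_sizes)))
    free = template.free_params()
    d = len(free)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    xi = sfs.counts()
    mask = xi > 0
    xi_obs = xi[mask]

    def make_negloglik(ngen: int, kernel_seed: int):
        def negloglik(u: np.ndarray) -> float:
            u = np.clip(u, 0.0, 1.0)
            model = template.build(template.values_from_unit(u))
            B, _ = branch_spectrum(model, config, list(sfs.pops), ngen,
                                   kernel_seed)
            p = _segregating_probs(B)
            return -float(np.sum(xi_obs * np.log(np.maximum(p[mask], P_FLOOR))))
        return negloglik

    init_units = []
    for point in (init_points or []):
        init_units.append(np.array([p.to_unit(point[p.name]) for p in free]))

    results: list[FitResult] = []
    for si in range(n_starts):
        # common random numbers hold within a run; each run gets its own
        # surface realization so runs are genuinely independent
        kernel_seed = int(np.random.SeedSequence([seed, 17, si])
                          .generate_state(1)[0] % (2**31 - 1))
        if si < len(init_units):
            u0 = np.clip(init_units[si], 0.0, 1.0)
        else:
            u0 = rng.uniform(0.05, 0.95, size=d)
        if two_stage:
            coarse = optimize.minimize(
                make_negloglik(max(1000, n_genealogies // 4), kernel_seed),
                u0, method="Powell", bounds=[(0.0, 1.0)] * d,
                options={"maxfev": max_evals // 2, "xtol": 1e-3})
            u0 = np.clip(coarse.x, 0.0, 1.0)
            budget = max_evals - int(coarse.nfev)
        else:
            budget = max_evals
        res = optimize.minimize(
            make_negloglik(n_genealogies, kernel_seed), u0, method="Powell",
            bounds=[(0.0, 1.0)] * d,
            options={"maxfev": max(budget, 20), "xtol": 3e-4})
        values = template.values_from_unit(np.clip(res.x, 0.0, 1.0))
        values.update(template.fixed)
        ll = -float(res.fun)
        if reeval_genealogies is not None:
            reeval_seed = int(np.random.SeedSequence([seed, 53])
                              .generate_state(1)[0] % (2**31 - 1))

            def reeval(vals: dict[str, float]) -> float:
                B, _ = branch_spectrum(template.build(vals), config,
                                       list(sfs.pops), reeval_genealogies,
                                       reeval_seed)
                p = _segregating_probs(B)
                return float(np.sum(xi_obs *
                                    np.log(np.maximum(p[mask], P_FLOOR))))

            ll = reeval(values)
            if si < len(init_units):
                # a warm-started run must never regress below its seed point
                init_values = template.values_from_unit(init_units[si])
                init_values.update(template.fixed)
                ll_init = reeval(init_values)
                if ll_init > ll:
                    values, ll = init_values, ll_init
        results.append(FitResult(model=template.name, params=values,
                                 loglik=ll, start_index=si,
                                 converged=bool(res.success),
                                 n_evals=int(res.nfev)))
    if not any(np.isfinite(r.loglik) for r in results):
        raise RuntimeError("all optimization runs failed")
    return results


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    logliks: dict[str, np.ndarray]
    table: list[dict]
    selected: str


def _pulse_count(name: str) -> int:
    return {"M0": 0, "M1": 1, "M2": 2}.get(name, 0)


def select_model(fits: dict[str, list[FitResult]]) -> ModelComparison:
    """Welch two-sample two-tailed t-test over run log-likelihood vectors.

    The selected model has the highest mean log-likelihood, except that a
    simpler model (fewer pulses) is preferred whenever its log-likelihood
    distribution is not significantly different (p > 0.05) from the best.
    """
    if len(fits) < 2:
        raise ValueError("need at least two models to compare")
    ll = {m: np.array([r.loglik for r in rs]) for m, rs in fits.items()}
    for m, v in ll.items():
        if len(v) < 2:
            raise ValueError(f"model {m}: need >= 2 runs")
    table = []
    names = list(ll)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.allclose(ll[a], ll[b]):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(ll[a], ll[b], equal_var=False)
                if np.isnan(p):
                    t, p = 0.0, 1.0
            table.append({"a": a, "b": b, "t": float(t), "p": float(p),
                          "mean_a": float(ll[a].mean()),
                          "mean_b": float(ll[b].mean())})
    best = max(names, key=lambda m: ll[m].mean())
    selected = best
    for m in sorted(names, key=_pulse_count):
        if m == best:
            break
        row = next(r for r in table if {r["a"], r["b"]} == {m, best})
        if row["p"] > 0.05:
            selected = m
            break
    return ModelComparison(logliks=ll, table=table, selected=selected)


# ---------------------------------------------------------------------------
# Block bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapCI:
    params: list[str]
    estimates: np.ndarray              # (B, n_params)
    ci: dict[str, tuple[float, float]]  # 2.5% / 97.5% percentiles


def bootstrap_ci(sfs: JointSFS, template: ModelTemplate, *, B: int = 100,
                 K: int = 100, seed: int = 0, n_starts: int = 2,
                 n_genealogies: int = 10_000, max_evals: int = 500,
                 two_stage: bool = True,
                 init: dict[str, float] | None = None,
                 derived: dict[str, "callable"] | None = None) -> BootstrapCI:
    """Percentile 95% CIs from a contiguous-block bootstrap of the SFS.

    Sites (ordered by coordinate) are split into K near-equal contiguous
    blocks; each of the B replicates draws K blocks with replacement, rebuilds
    the SFS and refits ``template`` with a reduced number of starts,
    optionally warm-started from the full-data point estimate ``init``.
    ``derived`` maps extra report names to functions of the fitted parameter
    dict (e.g. the pulse time in years BP from its fraction
    parameterization).
    """
    if K > sfs.S:
        raise ValueError(f"K={K} exceeds the number of polymorphic sites ({sfs.S})")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    derived = derived or {}
    names = [p.name for p in template.free_params()] + list(derived)
    init_points = [init] if init else None
    rows = []
    for b in range(B):
        ids = rng.integers(0, K, size=K)
        boot = sfs.resample_blocks(ids, K)
        # refit seed is a pure function of the resample: identical block
        # draws refit identically (duplicated data -> zero-width CI)
        fit_seed = int(np.random.SeedSequence(
            [seed, *np.sort(ids).tolist()]).generate_state(1)[0] % (2**31 - 1))
        fits = fit_model(boot, template, n_starts=n_starts,
                         seed=fit_seed,
                         n_genealogies=n_genealogies, max_evals=max_evals,
                         two_stage=two_stage, reeval_genealogies=None,
                         init_points=init_points)
        bestfit = max(fits, key=lambda r: r.loglik)
        row = [bestfit.params[n] for n in
               (p.name for p in template.free_params())]
        row += [fn(bestfit.params) for fn in derived.values()]
        rows.append(row)
    est = np.asarray(rows)
    ci = {n: (float(np.percentile(est[:, i], 2.5)),
              float(np.percentile(est[:, i], 97.5)))
          for i, n in enumerate(names)}
    return BootstrapCI(params=names, estimates=est, ci=ci)


def pulse1_time_bp(params: dict[str, float]) -> float:
    """EUR->Tibetan-dog pulse time in years BP from the fitted parameters."""
    return dog_natural_params(params)["T_PULSE1"]


def tibsea_split_bp(params: dict[str, float]) -> float:
    """Tibetan-dog/SEAID split time in years BP from the fitted parameters."""
    return dog_natural_params(params)["T_TIBSEA"]
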