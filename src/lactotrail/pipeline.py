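"""End-to-end orchestration from a single YAML configuration.

Stage order mirrors the analysis: synthetic (or provided) genotypes feed the
introgression scan and SFS demographic fit; a forward sweep simulation feeds
the selection scan; a two-panel mosaic feeds the local-ancestry stage; and a
breath-test cohort feeds the phenotype stage. Every stage writes plain-text
outputs plus a log of parameters and seeds; re-running an identical config
reproduces identical bytes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import ancestry as anc
from . import introgression as intro
from . import phenotype as pheno
from . import selection as sel
from . import sfs as sfsmod
from .io import site_frequencies, write_popmap, write_vcf, PopMap
from .simulate import (SampleConfig, SweepConfig, simulate_admixed,
                       simulate_breath_cohort, simulate_coalescent,
                       simulate_sweep, tibetan_dog_model)

log = logging.getLogger(__name__)

STAGES = ("simulate_genotypes", "dstat", "windows", "sfs_fit",
          "selection", "ancestry", "breath")
DEPENDS = {"dstat": "simulate_genotypes", "windows": "simulate_genotypes",
           "sfs_fit": "simulate_genotypes"}

_SCHEMA: dict[str, dict[str, type]] = {
    "simulate_genotypes": {"enabled": bool, "n_loci": int, "locus_len": int,
                           "haplotypes_per_pop": int},
    "dstat": {"enabled": bool, "block_size": int},
    "windows": {"enabled": bool, "window": int, "step": int, "min_snps": int},
    "sfs_fit": {"enabled": bool, "models": list, "n_starts": int,
                "n_genealogies": int, "max_evals": int},
    "selection": {"enabled": bool, "n_diploids": int, "duration": int,
                  "s": float, "maf_min": float},
    "ancestry": {"enabled": bool, "q": float, "generations": int,
                 "n_targets": int, "window_snps": int},
    "breath": {"enabled": bool, "n": int, "carrier_freq": float,
               "lp_rate_carrier": float, "lp_rate_noncarrier": float},
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    """Validate and normalize a pipeline config; raises ConfigError with the
    offending key path."""
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key in cfg:
        if key not in ("seed", "outdir", "stages"):
            raise ConfigError(f"unknown top-level key: {key}")
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("seed: required integer")
    if "outdir" not in cfg:
        raise ConfigError("outdir: required")
    stages = cfg.get("stages", {})
    if not isinstance(stages, dict):
        raise ConfigError("stages: must be a mapping")
    for sname, sconf in stages.items():
        if sname not in _SCHEMA:
            raise ConfigError(f"stages.{sname}: unknown stage")
        if not isinstance(sconf, dict):
            raise ConfigError(f"stages.{sname}: must be a mapping")
        for k, v in sconf.items():
            if k not in _SCHEMA[sname]:
                raise ConfigError(f"stages.{sname}.{k}: unknown key")
            want = _SCHEMA[sname][k]
            if want is float and isinstance(v, int):
                v = float(v)
            if not isinstance(v, want):
                raise ConfigError(
                    f"stages.{sname}.{k}: expected {want.__name__}")
    return cfg


def load_config(path: str) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _stage_conf(cfg: dict, name: str, **defaults):
    conf = dict(defaults)
    conf.update(cfg.get("stages", {}).get(name, {}))
    return conf


def plan(cfg: dict) -> list[str]:
    """Resolved list of stages that would run, in order."""
    out = []
    for s in STAGES:
        conf = cfg.get("stages", {}).get(s, {})
        if conf.get("enabled", True):
            out.append(s)
    return out


def run_pipeline(cfg: dict, dry_run: bool = False) -> dict:
    """Run the enabled stages; returns the manifest of produced artifacts."""
    validate_config(cfg)
    todo = plan(cfg)
    if dry_run:
        return {"plan": todo, "outputs": {}}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest: dict[str, list[str]] = {}
    failed: set[str] = set()
    runlog: dict = {"seed": seed, "stages": {}}
    hm = None

    def record(stage: str, paths: list[Path], params: dict) -> None:
        manifest[stage] = [str(p.relative_to(outdir)) for p in paths]
        runlog["stages"][stage] = params

    for stage in todo:
        dep = DEPENDS.get(stage)
        if dep and (dep in failed or (dep not in todo and hm is None)):
            failed.add(stage)
            log.warning("skipping %s: dependency %s unavailable", stage, dep)
            continue
        try:
            if stage == "simulate_genotypes":
                c = _stage_conf(cfg, stage, n_loci=800, locus_len=20_000,
                                haplotypes_per_pop=8)
                model = tibetan_dog_model(outgroup=True)
                sc = SampleConfig({p: c["haplotypes_per_pop"]
                                   for p in model.populations})
                hm = simulate_coalescent(model, sc, c["n_loci"],
                                         float(c["locus_len"]), seed)
                vcf = outdir / "genotypes.vcf"
                pm = outdir / "popmap.tsv"
                write_vcf(hm, str(vcf))
                write_popmap(PopMap(hm.pop_of), str(pm))
                record(stage, [vcf, pm], c)
            elif stage == "dstat":
                c = _stage_conf(cfg, stage, block_size=1_000_000)
                fr = site_frequencies(hm, ("SEAID", "TIB_DOG", "EUR", "FOX"))
                d = intro.genome_d(fr, block_size=c["block_size"])
                p = outdir / "dstat.json"
                p.write_text(json.dumps(
                    {"D": d.D, "Z": d.Z, "n_blocks": d.n_blocks,
                     "abba": d.abba_sum, "baba": d.baba_sum}, indent=1) + "\n")
                record(stage, [p], c)
            elif stage == "windows":
                c = _stage_conf(cfg, stage, window=100_000, step=20_000,
                                min_snps=100)
                fr = site_frequencies(hm, ("SEAID", "TIB_DOG", "EUR", "FOX"))
                ws = intro.window_stats(fr, c["window"], c["step"],
                                        c["min_snps"])
                p = outdir / "windows.tsv"
                intro.write_windows_tsv(ws, str(p))
                record(stage, [p], c)
            elif stage == "sfs_fit":
                c = _stage_conf(cfg, stage, models=["M0", "M1"], n_starts=3,
                                n_genealogies=2000, max_evals=60)
                sfs = sfsmod.build_joint_sfs(hm, ("EUR", "TIB_DOG", "SEAID"))
                paths = [outdir / "joint_sfs.tsv"]
                sfsmod.write_sfs_tsv(sfs, str(paths[0]))
                fits = {}
                for mname in c["models"]:
                    tpl = sfsmod.dog_model_template(mname)
                    fits[mname] = sfsmod.fit_model(
                        sfs, tpl, n_starts=c["n_starts"], seed=seed,
                        n_genealogies=c["n_genealogies"],
                        max_evals=c["max_evals"])
                rep = {m: [{"loglik": r.loglik, "params": r.params}
                           for r in rs] for m, rs in fits.items()}
                if len(fits) >= 2:
                    cmpres = sfsmod.select_model(fits)
                    rep["selected"] = cmpres.selected
                p = outdir / "sfs_fit.json"
                p.write_text(json.dumps(rep, indent=1, default=float) + "\n")
                paths.append(p)
                record(stage, paths, c)
            elif stage == "selection":
                c = _stage_conf(cfg, stage, n_diploids=150, duration=150,
                                s=0.2, maf_min=0.05)
                res = simulate_sweep(SweepConfig(
                    N=c["n_diploids"], s=float(c["s"]), f0=0.05,
                    duration=c["duration"], seed=seed, m_sites=400,
                    condition_min_freq=0.5))
                scan = sel.standardize_ihs(sel.ihs(res.hm,
                                                   maf_min=c["maf_min"]))
                p1 = outdir / "ihs.tsv"
                sel.write_ihs_tsv(scan, res.hm.chrom, str(p1))
                record(stage, [p1], c)
            elif stage == "ancestry":
                c = _stage_conf(cfg, stage, q=0.3, generations=100,
                                n_targets=20, window_snps=20)
                panels = simulate_sweep(SweepConfig(
                    N=120, s=0.0, duration=240, split_gen=0, seed=seed + 1,
                    m_sites=600, pop_labels=("PANEL_A", "PANEL_B")))
                pa = panels.hm.subset_pops(["PANEL_A"])
                pb = panels.hm.subset_pops(["PANEL_B"])
                targets, truth = simulate_admixed(
                    pa, pb, c["q"], float(c["generations"]), 1e-8,
                    c["n_targets"], seed)
                model = anc.train_reference(pa, pb, w=c["window_snps"],
                                            generations=float(c["generations"]))
                tracks = anc.assign_ancestry(model, targets)
                p = outdir / "ancestry_summary.tsv"
                with open(p, "w") as fh:
                    fh.write("haplotype\tq_hat\n")
                    for i, q in enumerate(tracks.q_hat):
                        fh.write(f"hap{i}\t{q:.4f}\n")
                record(stage, [p], dict(c, true_q=truth.q))
            elif stage == "breath":
                c = _stage_conf(cfg, stage, n=32, carrier_freq=0.07,
                                lp_rate_carrier=0.5, lp_rate_noncarrier=0.03)
                df = simulate_breath_cohort(
                    c["n"], c["carrier_freq"], c["lp_rate_carrier"],
                    c["lp_rate_noncarrier"], (3.0, 12.0), seed)
                csv = outdir / "breath_cohort.csv"
                df.drop(columns=["true_lp"]).to_csv(csv, index=False)
                recs = pheno.read_breath_csv(str(csv))
                tab = pheno.cross_tab(recs)
                p = outdir / "breath_summary.json"
                p.write_text(json.dumps(tab, indent=1) + "\n")
                record(stage, [csv, p], c)
        except Exception:
            log.exception("stage %s failed", stage)
            failed.add(stage)
            if stage == "simulate_genotypes":
                hm = None

    runlog["failed"] = sorted(failed)
    (outdir / "run_log.json").write_text(
        json.dumps(runlog, indent=1, default=str) + "\n")
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {"plan": todo, "outputs": manifest, "failed": sorted(failed)}


def demo_config(outdir: str, seed: int = 1) -> dict:
    """All-synthetic demonstration configuration (runs in about a minute)."""
    return validate_config({
        "seed": seed, "outdir": outdir,
        "stages": {
            "simulate_genotypes": {"enabled": True, "n_loci": 600,
                                   "locus_len": 20_000,
                                   "haplotypes_per_pop": 8},
            "dstat": {"enabled": True, "block_size": 1_000_000},
            "windows": {"enabled": True, "window": 100_000, "step": 20_000,
                        "min_snps": 20},
            "sfs_fit": {"enabled": True, "models": ["M0", "M1"],
                        "n_starts": 2, "n_genealogies": 2000, "max_evals": 40},
            "selection": {"enabled": True},
            "ancestry": {"enabled": True},
            "breath": {"enabled": True},
        }})
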