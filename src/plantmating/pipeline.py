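"""Orchestration of the full mating-system analysis workflow.

Stages: diversity table -> structure (pairwise F_ST, hierarchical F,
permutation comparisons, IBD, PCA) -> per-population selfing profiles ->
hierarchical ecotype tests -> progeny-array mating parameters -> temporal
effective size.  Inputs are either files (Genepop/CSV + metadata) or a
synthetic-mode SimConfig; outputs are TSV/JSON tables in an output
directory.  Every stochastic step derives its seed from the master seed, so
a run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import geno_io, hier, netemporal, popstruct, progeny, selfing, synthdata

log = logging.getLogger("plantmating")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full analysis run."""

    out_dir: str = "results"
    seed: int = 0
    # input mode: either files or synthetic
    genepop_path: Optional[str] = None
    csv_path: Optional[str] = None
    metadata_path: Optional[str] = None     # CSV: population, ecotype, lat, lon
    progeny_path: Optional[str] = None
    synthetic: Optional[synthdata.SimConfig] = None
    # stage toggles
    run_diversity: bool = True
    run_structure: bool = True
    run_selfing: bool = True
    run_ecotype_test: bool = True
    run_progeny: bool = True
    run_ne: bool = True
    # analysis knobs (defaults are the standard workflow choices)
    n_permutations: int = 5000
    n_bootstrap: int = 1000
    grid_step: float = 0.001
    ne_cap: float = netemporal.DEFAULT_CAP

    @classmethod
    def from_yaml(cls, path):
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = synthdata.SimConfig(**syn)
        return cfg


def validate(cfg: PipelineConfig) -> dict:
    """Check config consistency; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    has_files = any([cfg.genepop_path, cfg.csv_path])
    if has_files and cfg.synthetic is not None:
        errors.append("choose either file inputs or synthetic mode, not both")
    if not has_files and cfg.synthetic is None:
        errors.append("no input: set genepop_path/csv_path or synthetic")
    for p in (cfg.genepop_path, cfg.csv_path, cfg.metadata_path, cfg.progeny_path):
        if p is not None and not Path(p).exists():
            errors.append(f"missing file: {p}")
    pops = None
    if not errors:
        pops, _, coords, _ = _load_inputs(cfg)
        locus_sets = {n: tuple(g.loci) for n, g in pops.items()}
        if len(set(locus_sets.values())) > 1:
            errors.append(f"locus lists differ between populations: "
                          f"{sorted(set(locus_sets.values()), key=len)}")
        if cfg.run_structure:
            missing = [n for n in pops if n not in (coords or {})]
            if missing:
                warnings_.append(
                    f"no GPS coordinates for {missing}; they are excluded "
                    "from isolation-by-distance")
    return {"errors": errors, "warnings": warnings_}


def _load_inputs(cfg: PipelineConfig):
    """Returns (pops, arrays, coords, truth)."""
    truth = None
    arrays = None
    coords = None
    if cfg.synthetic is not None:
        sim = dataclasses.replace(cfg.synthetic, seed=cfg.synthetic.seed)
        pops, truth = synthdata.sim_metapopulation(sim)
        arrays, ptruth = synthdata.sim_progeny_arrays(sim)
        truth = {"metapopulation": truth, "progeny": ptruth}
        # synthetic coordinates: a deterministic scatter around a site
        rng = np.random.default_rng(sim.seed + 9)
        coords = {n: (43.9 + rng.uniform(-0.15, 0.15),
                      3.6 + rng.uniform(-0.15, 0.15)) for n in pops}
    else:
        if cfg.genepop_path:
            pops = geno_io.read_genepop(Path(cfg.genepop_path).read_text())
        else:
            pops = geno_io.from_csv(cfg.csv_path)
        if cfg.metadata_path:
            md = pd.read_csv(cfg.metadata_path)
            coords = {}
            for _, row in md.iterrows():
                name = str(row["population"])
                if name in pops:
                    if "ecotype" in md.columns:
                        pops[name].meta.ecotype = row["ecotype"]
                    if "lat" in md.columns and pd.notna(row.get("lat")):
                        coords[name] = (float(row["lat"]), float(row["lon"]))
                        pops[name].meta.lat, pops[name].meta.lon = coords[name]
        if cfg.progeny_path:
            arrays = geno_io.progeny_from_csv(cfg.progeny_path)
    return pops, arrays, coords, truth


def run(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns a result bundle (also on disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate(cfg)
    if report["errors"]:
        raise ValueError("invalid config: " + "; ".join(report["errors"]))
    bundle: dict = {"config_seed": cfg.seed, "stages": {}}
    pops, arrays, coords, truth = _load_inputs(cfg)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    assignment = {n: (g.meta.ecotype or "all") for n, g in pops.items()}
    two_groups = len(set(assignment.values())) == 2

    def stage(name, enabled, fn):
        if not enabled:
            log.info("stage %s: skipped (disabled)", name)
            return
        t0 = time.time()
        try:
            fn()
            bundle["stages"][name] = "ok"
            log.info("stage %s: ok seed=%s wall=%.1fs", name, cfg.seed,
                     time.time() - t0)
        except Exception as e:  # downstream stages continue
            bundle["stages"][name] = f"failed: {e}"
            log.error("stage %s failed: %s", name, e)

    def do_diversity():
        dt = popstruct.diversity_table(pops, n_bootstrap=cfg.n_bootstrap,
                                       seed=cfg.seed + 1)
        dt.to_csv(out / "diversity.tsv", sep="\t", index=False,
                  float_format="%.6g")
        bundle["diversity"] = dt

    def do_structure():
        fst = popstruct.pairwise_fst(pops)
        fst.to_csv(out / "pairwise_fst.tsv", sep="\t", float_format="%.6g")
        bundle["pairwise_fst"] = fst
        if two_groups:
            hf = popstruct.hierarchical_f(pops, assignment,
                                          n_bootstrap=cfg.n_bootstrap,
                                          seed=cfg.seed + 2)
            hf.to_csv(out / "hierarchical_f.tsv", sep="\t", index=False,
                      float_format="%.6g")
            bundle["hierarchical_f"] = hf
            perms = {}
            for stat in ("H_obs", "H_exp", "F_IS", "F_ST"):
                obs, p = popstruct.permutation_compare(
                    stat, pops, assignment, n_perm=cfg.n_permutations,
                    seed=cfg.seed + 3)
                perms[stat] = {"difference": obs, "pvalue": p}
            (out / "ecotype_permutation_tests.json").write_text(
                json.dumps(perms, indent=1))
            bundle["permutation_tests"] = perms
        if coords:
            usable = {n: coords[n] for n in pops if n in coords}
            if len(usable) >= 3:
                dist = popstruct.geo_distances(usable)
                sub = fst.loc[dist.index, dist.index]
                r, p = popstruct.mantel(sub.values, dist.values,
                                        n_perm=cfg.n_permutations,
                                        seed=cfg.seed + 4)
                ibd = popstruct.ibd_regression(sub.values, dist.values,
                                               n_perm=cfg.n_permutations,
                                               seed=cfg.seed + 5)
                ibd.update(mantel_r=r, mantel_p=p)
                (out / "ibd.json").write_text(json.dumps(ibd, indent=1))
                bundle["ibd"] = ibd
        pc, inertia = popstruct.pca_freqs(pops)
        pc.to_csv(out / "pca_coordinates.csv", index=False,
                  float_format="%.6g")
        bundle["pca_inertia"] = inertia

    profiles = {}

    def do_selfing():
        rows = []
        for name, g in pops.items():
            prof = selfing.fit_selfing(g, grid_step=cfg.grid_step)
            profiles[name] = prof
            prof.to_frame().to_csv(out / f"selfing_profile_{name}.tsv",
                                   sep="\t", index=False, float_format="%.6g")
            rows.append({"population": name, "ecotype": assignment[name],
                         **prof.summary()})
        df = pd.DataFrame(rows)
        df.to_csv(out / "selfing_rates.tsv", sep="\t", index=False,
                  float_format="%.6g")
        bundle["selfing"] = df

    def do_ecotype_test():
        if not profiles:
            raise RuntimeError("selfing stage required before ecotype tests")
        if not two_groups:
            raise RuntimeError("ecotype test needs exactly two groups")
        plist = [profiles[n] for n in pops]
        assign = {i: assignment[n] for i, n in enumerate(pops)}
        ladder = hier.ecotype_pipeline(plist, assign)
        ladder.to_csv(out / "ecotype_model_ladder.tsv", sep="\t", index=False,
                      float_format="%.6g")
        bundle["ecotype_ladder"] = ladder
        # group mean selfing with likelihood CIs under the sigma=0 model
        spec0 = hier.HierModelSpec(assign, "per_group", "zero")
        fit0 = hier.fit_hier(plist, spec0)
        means = {}
        for grp in fit0.spec.group_labels:
            ci = hier.group_mean_ci(plist, spec0, fit0, grp)
            means[grp] = {"mean_selfing": fit0.mean_selfing[grp], "ci95": ci}
        (out / "ecotype_mean_selfing.json").write_text(json.dumps(means, indent=1))
        bundle["ecotype_means"] = means

    def do_progeny():
        if arrays is None:
            raise RuntimeError("no progeny arrays supplied")
        fit = progeny.fit_mating(arrays, n_bootstrap=cfg.n_bootstrap,
                                 seed=cfg.seed + 6)
        res = {"s_multi": fit.params.s_m, "t_m": fit.params.t_m,
               "t_s_mean": fit.params.t_s_mean,
               "biparental_inbreeding": fit.params.biparental_inbreeding,
               "r_t": fit.params.r_t, "r_p": fit.params.r_p,
               "F_p": fit.params.F_p,
               "effective_fathers": progeny.effective_fathers(fit.params.r_p)[0]
               if fit.params.r_p > 0 else None,
               "ci95": fit.ci95}
        (out / "mating_system.json").write_text(json.dumps(res, indent=1))
        bundle["mating"] = res

    def do_ne():
        if cfg.synthetic is not None:
            pair, _ = synthdata.sim_temporal(cfg.synthetic)
            pairs = {"synthetic": pair}
        else:
            # temporal mode expects per-population year metadata
            pairs = {}
            by_pop: dict = {}
            for n, g in pops.items():
                by_pop.setdefault(g.meta.population or n, {})[g.meta.year] = g
            for pname, years in by_pop.items():
                ys = sorted(y for y in years if y is not None)
                if len(ys) >= 2:
                    pairs[pname] = geno_io.TemporalPair(
                        years[ys[0]], years[ys[1]], 1)
        rows = []
        for name, pair in pairs.items():
            est = netemporal.fit_ne(pair, cap=cfg.ne_cap)
            rows.append({"population": name, "Ne_hat": est.ne_hat,
                         "ci_low": est.ci95[0], "ci_high": est.ci95[1],
                         "at_cap": est.at_cap})
        df = pd.DataFrame(rows)
        df.to_csv(out / "effective_size.tsv", sep="\t", index=False,
                  float_format="%.6g")
        bundle["ne"] = df

    stage("diversity", cfg.run_diversity, do_diversity)
    stage("structure", cfg.run_structure, do_structure)
    stage("selfing", cfg.run_selfing, do_selfing)
    stage("ecotype_test", cfg.run_ecotype_test and cfg.run_selfing, do_ecotype_test)
    stage("progeny", cfg.run_progeny and arrays is not None, do_progeny)
    stage("ne", cfg.run_ne, do_ne)
    (out / "stages.json").write_text(json.dumps(bundle["stages"], indent=1))
    failed = [k for k, v in bundle["stages"].items() if str(v).startswith("failed")]
    bundle["ok"] = not failed
    return bundle
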