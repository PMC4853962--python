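"""End-to-end orchestration: simulate -> prep -> fit -> back-solve ->
rotation test -> cross-trait overlap -> variance partitioning.

A single :class:`RunConfig` (YAML-loadable) drives all stages; every stage is
a pure function of its inputs and the configured seeds, so re-running a config
reproduces byte-identical outputs.  A JSON manifest records the config, the
package version, per-stage wall times and a SHA-256 checksum of every file
written.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gblup, genio, markerfx, overlap, pathassoc, phenoprep, synthdata, varpart
from .synthdata import SimConfig

log = logging.getLogger(__name__)


@dataclass
class TraitSpec:
    """One simulated trait: heritability, causal GO sets and preprocessing."""

    name: str
    h2: float = 0.5
    causal_sets: tuple[str, ...] = ()
    transform: str = "none"       # none | arcsine_sqrt | plate_equalize
    plate_column: str = "block"


@dataclass
class RunConfig:
    """Full configuration of a synthetic end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    traits: list[TraitSpec] = field(default_factory=lambda: [TraitSpec("trait1")])
    covariates: list[str] = field(default_factory=lambda: [
        "wolbachia", "inv1", "inv2", "inv3", "inv4", "inv5", "block"])
    maf_min: float = 0.05
    window_bp: int = 5000
    min_genes: int = 11
    min_markers: int = 200
    n_perm: int = 10_000
    n_boot: int = 0               # 0 disables the heritability bootstrap
    sig_threshold: float = 0.005
    overlap_threshold: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        for thr in (self.sig_threshold, self.overlap_threshold):
            if not 0 < thr < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        traits = [TraitSpec(**{**t, "causal_sets": tuple(t.get("causal_sets", ()))})
                  for t in raw.pop("traits", [])] or [TraitSpec("trait1")]
        return cls(sim=sim, traits=traits, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _apply_transform(pheno: pd.DataFrame, spec: TraitSpec) -> pd.DataFrame:
    if spec.transform == "none":
        return pheno
    out = pheno.copy()
    if spec.transform == "arcsine_sqrt":
        out["value"] = phenoprep.arcsine_sqrt(out["value"].to_numpy())
    elif spec.transform == "plate_equalize":
        out["value"] = phenoprep.plate_equalize(
            out["value"].to_numpy(), out[spec.plate_column].to_numpy())
    else:
        raise ValueError(f"unknown transform {spec.transform!r}")
    return out


def run(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "varpart").mkdir(exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": _config_dict(cfg), "stages": {}, "files": {}}
    t_all = time.perf_counter()

    def stage(name):
        manifest["stages"][name] = {"t_start": time.perf_counter() - t_all}

    def done(name):
        st = manifest["stages"][name]
        st["wall_s"] = time.perf_counter() - t_all - st.pop("t_start")

    # ---- simulate genotypes and annotation -------------------------------
    stage("simulate")
    sim = replace(cfg.sim, seed=cfg.seed)
    geno_full = synthdata.generate_genotypes(sim)
    genes, go = synthdata.generate_annotation(sim)
    genio.write_genotypes_tsv(geno_full, out / "genotypes.tsv", out / "markers.tsv")
    genio.write_genes_bed(genes, out / "genes.bed")
    go.to_csv(out / "go.tsv", sep="\t", index=False)
    done("simulate")

    # ---- marker filtering and SNP-set construction -----------------------
    stage("build_sets")
    geno = genio.filter_markers(geno_full, cfg.maf_min)
    w = gblup.scale_genotypes(geno)
    grm = gblup.compute_grm(w)
    gene_map = genio.map_snps_to_genes(geno, genes, cfg.window_bp)
    catalog = genio.build_snpsets(gene_map, go, cfg.min_genes, cfg.min_markers)
    done("build_sets")

    # ---- per-trait: simulate phenotype, fit, back-solve, rotation test ---
    results_by_trait: dict[str, pd.DataFrame] = {}
    fits: dict[str, gblup.LMMFit] = {}
    effects_cols: dict[str, np.ndarray] = {}
    for t_i, spec in enumerate(cfg.traits):
        stage(f"trait:{spec.name}")
        trait_rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed, 100 + t_i)))
        trait_sim = replace(sim, h2_target=spec.h2,
                            causal_sets=tuple(spec.causal_sets))
        pheno, truth = synthdata.simulate_trait(
            geno_full, genes, go, trait_sim, spec.name, trait_rng)
        pheno = _apply_transform(pheno, spec)
        pheno.to_csv(out / f"pheno_{spec.name}.csv", index=False)

        X, names = gblup.build_design(pheno, cfg.covariates)
        line_pos = {l: i for i, l in enumerate(grm.line_ids)}
        line_index = pheno["line_id"].map(line_pos).to_numpy()
        fit = gblup.reml_fit(pheno["value"].to_numpy(), X, grm, line_index,
                             x_names=names)
        fits[spec.name] = fit
        ci = None
        if cfg.n_boot > 0:
            ci = gblup.bootstrap_ci(pheno["value"].to_numpy(), X, grm,
                                    line_index, n_boot=cfg.n_boot,
                                    seed=int(np.random.SeedSequence(
                                        (cfg.seed, 200 + t_i)).generate_state(1)[0]
                                        % 2**31))
        eff = markerfx.backsolve(w, fit.g_blup.loc[w.line_ids].to_numpy(),
                                 trait=spec.name)
        effects_cols[spec.name] = eff.s
        res, _plan = pathassoc.pathway_test(
            eff, catalog, n_perm=cfg.n_perm,
            seed=int(np.random.SeedSequence((cfg.seed, 300 + t_i)
                                            ).generate_state(1)[0] % 2**31))
        results_by_trait[spec.name] = res
        res.to_csv(out / f"results_{spec.name}.tsv", sep="\t", index=False)

        fit_record = {
            "trait": spec.name,
            "beta": fit.beta.to_dict(),
            "g_blup": fit.g_blup.to_dict(),
            "sigma_g2": fit.sigma_g2, "sigma_e2": fit.sigma_e2,
            "h2_snp": fit.h2, "loglik": fit.loglik,
            "converged": fit.converged, "identifiable": fit.identifiable,
            "n_obs": fit.n_obs,
            "h2_ci": [ci.lower, ci.upper] if ci else None,
            "n_boot": cfg.n_boot,
            "truth": {"h2_realized": truth.h2, "sigma_g2": truth.sigma_g2,
                      "sigma_e2": truth.sigma_e2,
                      "causal_sets": list(truth.causal_set_ids)},
        }
        with open(out / f"fit_{spec.name}.json", "w") as fh:
            json.dump(fit_record, fh, indent=1)
        done(f"trait:{spec.name}")

    # combined marker-effect table
    eff_df = pd.DataFrame({"chrom": geno.chrom, "pos": geno.pos,
                           "marker_id": geno.marker_ids, **effects_cols})
    eff_df.to_csv(out / "effects.tsv", sep="\t", index=False)

    # ---- genomic correlations and cross-trait overlap --------------------
    stage("overlap")
    if len(cfg.traits) >= 2:
        corr_rows = []
        names_ = [t.name for t in cfg.traits]
        for i in range(len(names_)):
            for j in range(i + 1, len(names_)):
                rho, p = gblup.genomic_correlation(fits[names_[i]].g_blup,
                                                   fits[names_[j]].g_blup)
                corr_rows.append((names_[i], names_[j], rho, p))
        pd.DataFrame(corr_rows, columns=["trait_a", "trait_b", "rho", "p"]
                     ).to_csv(out / "genomic_correlations.tsv", sep="\t", index=False)

        ov_frames = []
        for go_class in catalog.classes():
            sub = {t: df[df["go_class"] == go_class] for t, df in
                   results_by_trait.items()}
            if next(iter(sub.values())).empty:
                continue
            inc = overlap.build_incidence(sub, cfg.overlap_threshold)
            ov = overlap.overlap_test(
                inc, n_perm=cfg.n_perm,
                seed=int(np.random.SeedSequence((cfg.seed, 400)
                                                ).generate_state(1)[0] % 2**31))
            ov.insert(0, "go_class", go_class)
            ov_frames.append(ov)
        if ov_frames:
            pd.concat(ov_frames).to_csv(out / "overlap.tsv", sep="\t", index=False)
    done("overlap")

    # ---- variance partitioning of significant sets -----------------------
    stage("varpart")
    for spec in cfg.traits:
        sig = pathassoc.significant_sets(results_by_trait[spec.name],
                                         cfg.sig_threshold)
        for go_id in sig["go_id"]:
            part = varpart.partition_set(w, effects_cols[spec.name], gene_map,
                                         catalog[go_id])
            safe = go_id.replace(":", "_")
            part.to_csv(out / "varpart" / f"{spec.name}_{safe}.tsv",
                        sep="\t", index=False)
    done("varpart")

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    manifest["wall_s"] = time.perf_counter() - t_all
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("pipeline finished in %.1f s; %d files written",
             manifest["wall_s"], len(manifest["files"]))
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"]["n_markers_per_chrom"] = dict(d["sim"]["n_markers_per_chrom"])
    d["sim"]["n_go_sets"] = dict(d["sim"]["n_go_sets"])
    d["sim"]["chrom_names"] = list(d["sim"]["chrom_names"])
    return d
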