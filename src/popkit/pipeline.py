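"""One-config orchestration of the full analysis.

Stages: (optional) simulate -> read & filter -> LD prune -> per-population
diversity -> metapopulation partition and pool optimisation -> sweep scan
-> deleterious summaries.  Every stage writes plain-text tables and the
run ends with a manifest (parameters, input checksums, per-stage row
counts) so a rerun with the same inputs and seed is byte-reproducible.

Two site-filter tiers are used: the MAF filter is applied for diversity,
partitioning, pruning and the sweep scan, but *not* for the deleterious
summaries — deleterious alleles are predominantly rare, and a MAF > 0.05
cut would empty the low-frequency bins the spectrum exists to show.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import deleterious as dele_mod
from . import diversity as div_mod
from . import metapop as meta_mod
from . import simdata
from . import sweep as sweep_mod
from . import variant_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameter set of a pipeline run; defaults follow common
    resequencing practice (call rate > 90%, MAF > 0.05, PLINK-style
    ``--indep-pairwise 50 5 0.2`` pruning, 10 kb windows, top 1%)."""

    outdir: str = "popkit_run"
    vcf: str | None = None
    popmap: str | None = None
    annotation: str | None = None
    genes: str | None = None
    outgroup: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig
    max_missing: float = 0.1
    min_maf: float = 0.05
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    run_prune: bool = True
    window_bp: int = 10_000
    sweep_quantile: float = 0.99
    min_snps: int = 10
    sift_threshold: float = 0.05
    rarefaction_g: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to
    ``manifest.json``).  Any stage error aborts with the stage name; the
    partial output directory is renamed with a ``.failed`` suffix."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "popkit_version": __version__,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
    }
    stage = "setup"
    try:
        t0 = time.time()
        if config.simulate:
            stage = "simulate"
            sim_cfg = simdata.SimulationConfig(**{**config.sim, "seed": config.seed})
            simdir = outdir / "simulated"
            gm, popmap, truth = simdata.simulate_dataset(sim_cfg, simdir)
            vcf_path = simdir / "genotypes.vcf"
            popmap_path = simdir / "populations.tsv"
            ann_path = simdir / "annotations.tsv"
            genes_path = simdir / "genes.bed"
            outgroup = sim_cfg.outgroup_label if sim_cfg.n_outgroup else None
            manifest["stages"]["simulate"] = {
                "n_variants": gm.n_variants,
                "n_samples": gm.n_samples,
                "sweep_windows": len(truth.sweep_windows),
                "seconds": round(time.time() - t0, 2),
            }
        else:
            for name in ("vcf", "popmap"):
                if getattr(config, name) is None:
                    raise ValueError(f"config field {name!r} is required for a "
                                     "non-simulated run")
            vcf_path = Path(config.vcf)
            popmap_path = Path(config.popmap)
            ann_path = Path(config.annotation) if config.annotation else None
            genes_path = Path(config.genes) if config.genes else None
            outgroup = config.outgroup

        for label, p in [("vcf", vcf_path), ("popmap", popmap_path),
                         ("annotation", ann_path), ("genes", genes_path)]:
            if p is not None and Path(p).exists():
                manifest["inputs"][label] = {"path": str(p), "sha256": _sha256(Path(p))}

        stage = "filter"
        t0 = time.time()
        gm = variant_io.read_vcf(vcf_path)
        popmap = variant_io.read_population_map(popmap_path, outgroup=outgroup)
        popmap.validate_against(gm)
        gm = gm.take_samples(list(popmap.sample_to_pop))
        gm_site, pre_report = variant_io.filter_sites(
            gm, config.max_missing, config.min_maf, apply_maf=False
        )
        gm_maf, report = variant_io.filter_sites(
            gm, config.max_missing, config.min_maf, apply_maf=True
        )
        with open(outdir / "filter_report.json", "w") as fh:
            json.dump({"maf_filtered": report.as_dict(),
                       "site_filtered_no_maf": pre_report.as_dict()}, fh, indent=1)
            fh.write("\n")
        manifest["stages"]["filter"] = {
            "input": report.input_count, "retained": report.retained,
            "retained_no_maf": pre_report.retained,
            "seconds": round(time.time() - t0, 2),
        }

        if config.run_prune:
            stage = "prune"
            t0 = time.time()
            kept = variant_io.ld_prune(gm_maf, config.prune_window,
                                       config.prune_step, config.prune_r2)
            pruned = gm_maf.take_variants(kept)
            pruned.variants.assign(kept_index=kept).to_csv(
                outdir / "pruned_sites.tsv", sep="\t", index=False)
            manifest["stages"]["prune"] = {
                "input": gm_maf.n_variants, "retained": len(kept),
                "seconds": round(time.time() - t0, 2),
            }

        stage = "diversity"
        t0 = time.time()
        study_pops = popmap.analysis_populations
        summary = div_mod.diversity_summary(gm_maf, popmap, study_pops,
                                            config.rarefaction_g)
        _write_tsv(summary, outdir / "diversity_summary.tsv")
        freqs = div_mod.allele_frequencies(gm_maf, popmap, study_pops)
        f = div_mod.coancestry(freqs)
        fst, n_trunc = div_mod.pairwise_fst(f)
        _write_tsv(fst, outdir / "pairwise_fst.tsv")
        _write_tsv(div_mod.nei_minimum_distance(f), outdir / "pairwise_dnei.tsv")
        _write_tsv(div_mod.pairwise_summary(f), outdir / "pairwise_averages.tsv")
        manifest["stages"]["diversity"] = {
            "populations": len(study_pops), "variants": gm_maf.n_variants,
            "negative_fst_truncated": n_trunc,
            "seconds": round(time.time() - t0, 2),
        }

        stage = "metapop"
        t0 = time.time()
        part = meta_mod.loo_contributions(freqs)
        _write_tsv(part.contributions, outdir / "loo_contributions.tsv")
        pool_h = meta_mod.optimize_pool(f=f, criterion="H", seed=config.seed)
        pool_k = meta_mod.optimize_pool(freqs=freqs, criterion="K", seed=config.seed)
        pool = pool_h.proportions.rename("H").to_frame()
        pool["K"] = pool_k.proportions
        _write_tsv(pool, outdir / "pool_contributions.tsv")
        with open(outdir / "partition.json", "w") as fh:
            json.dump({"components": part.components,
                       "A_T_pooled": part.a_t_pooled,
                       "loci_used": part.loci_used,
                       "objective_H": pool_h.objective,
                       "objective_K": pool_k.objective}, fh, indent=1)
            fh.write("\n")
        manifest["stages"]["metapop"] = {
            "loci_used": part.loci_used, "seconds": round(time.time() - t0, 2),
        }

        stage = "sweep"
        t0 = time.time()
        table = sweep_mod.window_scan(gm_maf, popmap, config.window_bp,
                                      config.min_snps)
        _write_tsv(table, outdir / "sweep_windows.tsv", index=False)
        calls = sweep_mod.call_sweeps(table, config.sweep_quantile)
        calls.merged.to_csv(outdir / "sweep_candidates.bed", sep="\t",
                            index=False, header=False)
        n_genes = 0
        if genes_path is not None and Path(genes_path).exists():
            bed = sweep_mod.read_bed4(genes_path)
            overlaps = sweep_mod.annotate_windows(calls, bed)
            _write_tsv(overlaps, outdir / "sweep_genes.tsv", index=False)
            n_genes = len(calls.genes)
        manifest["stages"]["sweep"] = {
            "windows": len(table),
            "unmasked": int((~table["masked"]).sum()),
            "candidates": len(calls.candidates),
            "genes": n_genes,
            "seconds": round(time.time() - t0, 2),
        }

        if ann_path is not None and Path(ann_path).exists():
            stage = "deleterious"
            t0 = time.time()
            ann = dele_mod.read_annotations(ann_path)
            table_d = dele_mod.classify_deleterious(ann, config.sift_threshold)
            spectrum = dele_mod.frequency_spectrum(table_d, gm_site, popmap)
            _write_tsv(spectrum, outdir / "sift_spectrum.tsv", index=False)
            subsets, per_pop = dele_mod.intersection_sets(table_d, gm_site, popmap)
            _write_tsv(subsets, outdir / "sift_intersections.tsv", index=False)
            _write_tsv(per_pop, outdir / "sift_per_population.tsv")
            manifest["stages"]["deleterious"] = {
                "variants_scored": len(table_d),
                "deleterious": int(table_d["deleterious"].sum()),
                "seconds": round(time.time() - t0, 2),
            }
    except Exception as exc:
        failed = outdir.with_name(outdir.name + ".failed")
        logger.error("stage %r failed: %s", stage, exc)
        if not failed.exists():
            try:
                outdir.rename(failed)
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
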