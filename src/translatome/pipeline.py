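"""End-to-end orchestration.

``run_all`` drives ingest -> differential expression (per species x assay) ->
remodeling -> concordance / translational component -> cross-species
statistics -> gene-set statistics on either a simulated dataset or a
directory of TSV inputs, and returns one structured report (JSON-ready dict)
holding every headline statistic. A single seed deterministically derives all
stage seeds, so two runs with the same inputs and seed produce byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from . import cross_species as xs
from . import genesets as gsets
from . import remodeling as rem
from .de import DEConfig, fold_change_table, write_fold_change_table
from .ingest import (
    OrthologMap,
    ValidationError,
    align_samples,
    read_count_matrix,
    read_gene_set,
    read_ortholog_map,
    read_sample_meta,
)
from .simulate import SimConfig, SimulatedDataset, simulate_dataset

logger = logging.getLogger(__name__)

REPORT_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``simulate`` (a SimConfig) or ``input_dir`` (a directory
    of TSVs in the layout written by ``simulate.write_dataset``) supplies the
    data. ``n_shuffles`` > 0 enables the divergence shuffle control.
    """

    simulate: SimConfig | None = None
    input_dir: str | None = None
    de: DEConfig = field(default_factory=DEConfig)
    outdir: str | None = None
    seed: int = 0
    n_shuffles: int = 0
    run_remodeling: bool = True
    run_concordance: bool = True
    run_cross_species: bool = True
    run_genesets: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValidationError("supply exactly one of simulate= or input_dir=")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValidationError(f"input directory not found: {self.input_dir}")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def load_dataset(input_dir) -> SimulatedDataset:
    """Load a dataset directory written by ``simulate.write_dataset``."""
    d = Path(input_dir)
    meta = read_sample_meta(d / "samples.tsv")
    species = sorted(meta["species"].unique())
    rpf, mrna = {}, {}
    for sp in species:
        rpf[sp] = read_count_matrix(d / f"counts_rpf_{sp}.tsv", "RPF")
        mrna[sp] = read_count_matrix(d / f"counts_mrna_{sp}.tsv", "mRNA")
    fw_path = d / "orthologs_fourway.tsv"
    omap = read_ortholog_map(fw_path if fw_path.exists() else None)
    gene_sets: dict = {}
    for path in sorted(d.glob("geneset_*_*.txt")):
        stem = path.stem[len("geneset_"):]
        name, sp = stem.rsplit("_", 1)
        gene_sets.setdefault(name, {})[sp] = read_gene_set(path, name, sp)
    return SimulatedDataset(
        rpf=rpf, mrna=mrna, meta=meta, orthologs=omap,
        gene_sets=gene_sets, truth=pd.DataFrame(), config=None,
    )


def _pc1_condition_separation(pca: xs.PCAResult, meta: pd.DataFrame) -> dict:
    m = meta.set_index("sample_id")
    conds = m.loc[pca.scores.index, "condition"]
    s_dia = pca.scores.loc[conds == "diapause", "PC1"]
    s_dev = pca.scores.loc[conds == "developing", "PC1"]
    lo = (float(s_dia.max()) < float(s_dev.min()))
    hi = (float(s_dev.max()) < float(s_dia.min()))
    return {
        "pc1_separates_conditions": bool(lo or hi),
        "pc1_gap": float(
            max(s_dev.min() - s_dia.max(), s_dia.min() - s_dev.max())
        ),
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute every enabled stage and return the structured report."""
    t0 = time.time()
    if cfg.simulate is not None:
        logger.info("stage simulate: drawing synthetic dataset")
        ds = simulate_dataset(cfg.simulate)
    else:
        logger.info("stage ingest: loading %s", cfg.input_dir)
        ds = load_dataset(cfg.input_dir)

    species = sorted(ds.rpf)
    report: dict = {
        "version": REPORT_VERSION,
        "seed": cfg.seed,
        "species": species,
        "per_species": {},
        "cross_species": None,
        "gene_sets": None,
    }
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    fc = {"mRNA": {}, "RPF": {}}
    aligned = {"mRNA": {}, "RPF": {}}
    for sp in species:
        for assay, mats in (("mRNA", ds.mrna), ("RPF", ds.rpf)):
            t = time.time()
            al = align_samples(mats[sp], ds.meta)
            table = fold_change_table(al, cfg.de)
            aligned[assay][sp] = al
            fc[assay][sp] = table
            logger.info("stage de_core %s/%s: %d genes (%.1fs)",
                        sp, assay, len(table), time.time() - t)
            if outdir:
                write_fold_change_table(table, outdir / f"fc_{assay.lower()}_{sp}.tsv")

    for sp in species:
        entry: dict = {}
        fm, fr = fc["mRNA"][sp], fc["RPF"][sp]
        if cfg.run_remodeling:
            entry["remodeling"] = rem.remodel_summary(
                fm, fr, aligned["mRNA"][sp], aligned["RPF"][sp], cfg.de
            )
        if cfg.run_concordance:
            te = conc.te_change(fm, fr)
            joint = fm.index[fm["de_flag"] & fr["de_flag"]]
            cr = conc.classify_concordance(te, joint)
            entry["concordance"] = {
                "n_concordant": cr["n_concordant"],
                "n_discordant": cr["n_discordant"],
                "n_ties": cr["n_ties"],
                "ratio": float(cr["ratio"]),
                "p_value": float(cr["p_value"]),
            }
            tc = conc.translational_component(te, fr.index[fr["de_flag"]])
            entry["translational_component"] = {
                "fractions": conc.tc_category_fractions(tc),
                "n": int((tc["category"] != "undefined").sum()),
            }
            if outdir:
                tc.to_csv(outdir / f"tc_{sp}.tsv", sep="\t")
        report["per_species"][sp] = entry

    if cfg.run_cross_species and len(species) >= 2 and ds.orthologs.n_groups >= 2:
        report["cross_species"] = _cross_species_stage(cfg, ds, fc)
    elif cfg.run_cross_species:
        logger.info("stage cross_species skipped: needs >=2 species and an ortholog map")
        report["cross_species"] = {"skipped": "needs >=2 species with orthologs"}

    if cfg.run_genesets and ds.gene_sets:
        report["gene_sets"] = _genesets_stage(ds, fc, species)
    elif cfg.run_genesets:
        logger.info("stage genesets skipped: no gene sets supplied")

    logger.info("pipeline complete (%.1fs)", time.time() - t0)
    if outdir:
        write_report(report, outdir / "report.json")
    return report


def _cross_species_stage(cfg: RunConfig, ds: SimulatedDataset, fc: dict) -> dict:
    t = time.time()
    out: dict = {"correlations": {"mrna": {}, "rpf": {}}}
    species = sorted(ds.rpf)
    for sp_a, sp_b in combinations(species, 2):
        pairs = ds.orthologs.pairs(sp_a, sp_b)
        if not len(pairs):
            continue
        key = f"{sp_a}|{sp_b}"
        out["correlations"]["mrna"][key] = xs.pairwise_fc_correlation(
            fc["mRNA"][sp_a], fc["mRNA"][sp_b], pairs
        )
        out["correlations"]["rpf"][key] = xs.pairwise_fc_correlation(
            fc["RPF"][sp_a], fc["RPF"][sp_b], pairs
        )
    div_m = xs.fourway_divergence(fc["mRNA"], ds.orthologs)
    div_r = xs.fourway_divergence(fc["RPF"], ds.orthologs)
    out["divergence"] = xs.divergence_compare(div_m, div_r)
    if cfg.n_shuffles > 0:
        pvals = xs.divergence_shuffle_control(
            fc["mRNA"], fc["RPF"], ds.orthologs,
            n_shuffles=cfg.n_shuffles,
            seed=stage_seed(cfg.seed, "shuffle"),
        )
        out["shuffle_control"] = {
            "n_shuffles": int(cfg.n_shuffles),
            "p_value_mean": float(np.mean(pvals)),
            "frac_p_below_05": float(np.mean(pvals < 0.05)),
        }
    out["pca"] = {}
    for assay, mats in (("mrna", ds.mrna), ("rpf", ds.rpf)):
        expr = xs.build_ortholog_expression(mats, ds.orthologs, cfg.de)
        pca = xs.pca_samples(expr)
        entry = {
            "variance_fraction": [float(v) for v in pca.variance_fraction[:5]],
        }
        entry.update(_pc1_condition_separation(pca, ds.meta))
        entry["n_high_loading_pc1"] = len(xs.high_loading_genes(pca, 1))
        out["pca"][assay] = entry
    logger.info("stage cross_species done (%.1fs)", time.time() - t)
    return out


def _genesets_stage(ds: SimulatedDataset, fc: dict, species: list) -> dict:
    t = time.time()
    out: dict = {}
    for name, per_sp in sorted(ds.gene_sets.items()):
        out[name] = {}
        for sp in species:
            if sp not in per_sp:
                continue
            gs = per_sp[sp]
            entry = {
                "comparison": gsets.geneset_fc_compare(
                    fc["mRNA"][sp], fc["RPF"][sp], gs
                ),
            }
            alloc = gsets.footprint_fraction(ds.rpf[sp], gs, ds.meta)
            entry["allocation"] = alloc["by_condition"]
            out[name][sp] = entry
    logger.info("stage genesets done (%.1fs)", time.time() - t)
    return out


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
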