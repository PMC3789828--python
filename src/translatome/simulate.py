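"""Synthetic multi-species paired RPF / mRNA-seq count datasets with ground
truth.

The generator emulates the statistical structure of a four-species L1
diapause-exit study: 4 species x 2 conditions (diapause, developing) x 3
replicates, for two assays (mRNA-seq and ribosome footprints), with
negative-binomially dispersed counts.

Latent structure, per four-way ortholog group (a fraction of genes shared by
all species; the rest are species-private):

* a log-normal baseline abundance shared across orthologs;
* shared condition effects on log2 mRNA abundance (``m``) and on log2
  translation efficiency (``t``), drawn bivariate normal with coupling
  ``rho_mt`` — positive coupling makes translational changes amplify mRNA
  changes, which is what produces concordant:discordant ratios near 3:1 as
  an *emergent* quantity rather than a drawn label;
* species-specific deviations drawn independently on the mRNA axis and on
  the RPF axis (the TE deviation is their difference, i.e. translational
  buffering). RPF changes end up more conserved between species than mRNA
  changes because the shared RPF signal (the coupled sum ``m + t``) is large
  relative to its species noise; lowering ``species_noise_rpf`` or raising
  ``species_noise_mrna`` each widen the conservation gap, and the two noises
  act independently on their respective correlations;
* named gene-set effects (e.g. ribosomal proteins: ~2-fold mRNA and ~10-fold
  RPF up-regulation on feeding), with the set's baseline abundance rescaled
  to a target share of diapause footprints.

The RPF log2 fold change of every gene is exactly ``m + t`` plus its species
deviations; ``SimTruth`` records the realized per-species effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ingest import (
    CountMatrix,
    GeneSet,
    OrthologMap,
    ValidationError,
    validate_sample_meta,
)


@dataclass
class GeneSetEffect:
    """A named gene set with fixed condition effects.

    n_genes members are taken from the four-way ortholog groups; the drawn
    shared effects are replaced by (mrna_lfc, te_lfc) plus a small per-gene
    scatter. ``baseline_fraction`` rescales the set's baseline abundance so
    the set carries that share of expected diapause footprints.
    """

    n_genes: int
    mrna_lfc: float
    te_lfc: float
    effect_sd: float = 0.25
    baseline_fraction: float | None = None


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults describe the emulated study: 4 species, 12000 genes per species
    of which 60% form four-way ortholog groups, 3 replicates per condition,
    NB dispersion 0.05, and shared condition effects whose coupling and
    species noise were calibrated once so the downstream statistics land in
    the published ranges (see the paperlike preset).
    """

    n_species: int = 4
    n_genes: int = 12000
    fourway_fraction: float = 0.6
    n_replicates: int = 3
    library_size_mean: float = 4e6
    library_size_cv: float = 0.15
    nb_dispersion: float = 0.05
    baseline_log2_sd: float = 1.8
    sigma_mrna: float = 0.7
    sigma_te: float = 0.6
    rho_mt: float = 0.85
    species_noise_mrna: float = 0.4
    species_noise_rpf: float = 0.5
    geneset_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_genes < 1 or self.n_replicates < 1:
            raise ValidationError("n_species, n_genes, n_replicates must be >=1")
        if not (0.0 <= self.fourway_fraction <= 1.0):
            raise ValidationError("fourway_fraction must be in [0, 1]")
        if not (-1.0 <= self.rho_mt <= 1.0):
            raise ValidationError("rho_mt must be in [-1, 1]")
        for name in ("sigma_mrna", "sigma_te", "species_noise_mrna",
                     "species_noise_rpf", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValidationError("nb_dispersion and library_size_mean must be positive")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


def paperlike_preset() -> SimConfig:
    """The calibrated study-condition preset.

    Effect scales are fixed so that, at default depth, the pipeline recovers
    a concordance ratio near 3:1, stronger cross-species correlation for RPF
    than mRNA changes, lower four-way divergence for RPF, clean PC1
    separation of conditions in RPF space, and a ribosomal-protein set with
    ~2-fold mRNA and >10-fold RPF up-regulation carrying ~3% of diapause
    footprints (>20% after feeding).
    """
    return SimConfig(
        geneset_effects={
            "ribosomal_proteins": GeneSetEffect(
                n_genes=80, mrna_lfc=1.0, te_lfc=2.4, baseline_fraction=0.03
            ),
            "translation_factors": GeneSetEffect(
                n_genes=60, mrna_lfc=0.8, te_lfc=0.8, baseline_fraction=0.015
            ),
        },
    )


@dataclass
class SimulatedDataset:
    """Counts, metadata, orthology, gene sets and latent truth of one draw."""

    rpf: dict  # species -> CountMatrix
    mrna: dict  # species -> CountMatrix
    meta: pd.DataFrame
    orthologs: OrthologMap
    gene_sets: dict  # set name -> {species -> GeneSet}
    truth: pd.DataFrame  # per (species, gene): lfc_mrna, lfc_te, lfc_rpf
    config: SimConfig


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB sample with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Draw one full dataset; bit-reproducible for a given config and seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    species = cfg.species
    n_fw = int(round(cfg.fourway_fraction * cfg.n_genes))
    n_priv = cfg.n_genes - n_fw

    # gene ids: the first n_fw genes of each species form the four-way groups
    gene_ids = {
        sp: [f"{sp}_g{i:05d}" for i in range(cfg.n_genes)] for sp in species
    }
    fourway = pd.DataFrame(
        {sp: [f"{sp}_g{i:05d}" for i in range(n_fw)] for sp in species}
    )

    # shared baselines and effects for four-way groups
    base_fw = 2.0 ** rng.normal(3.0, cfg.baseline_log2_sd, size=n_fw)

    def draw_mt(r: np.random.Generator, size: int) -> np.ndarray:
        """Coupled (mRNA, TE) shared effects; degenerate SDs allowed."""
        x1 = r.normal(size=size)
        x2 = r.normal(size=size)
        m = cfg.sigma_mrna * x1
        t = cfg.sigma_te * (cfg.rho_mt * x1 + np.sqrt(1 - cfg.rho_mt**2) * x2)
        return np.column_stack([m, t])

    mt_fw = draw_mt(rng, n_fw)

    # gene-set effects occupy the leading four-way slots (one block per set)
    gene_sets: dict[str, dict[str, GeneSet]] = {}
    cursor = 0
    set_slices: dict[str, slice] = {}
    for name, eff in cfg.geneset_effects.items():
        if cursor + eff.n_genes > n_fw:
            raise ValidationError("gene-set effects exceed the four-way gene pool")
        sl = slice(cursor, cursor + eff.n_genes)
        set_slices[name] = sl
        mt_fw[sl, 0] = eff.mrna_lfc + rng.normal(0, eff.effect_sd, eff.n_genes)
        mt_fw[sl, 1] = eff.te_lfc + rng.normal(0, eff.effect_sd, eff.n_genes)
        gene_sets[name] = {
            sp: GeneSet(name, sp, frozenset(fourway[sp].iloc[sl]))
            for sp in species
        }
        cursor += eff.n_genes
    # rescale set baselines to their target share of diapause abundance
    for name, eff in cfg.geneset_effects.items():
        if eff.baseline_fraction is None:
            continue
        sl = set_slices[name]
        others = np.ones(n_fw, dtype=bool)
        others[sl] = False
        # solve for scale c: c*S_set / (c*S_set + S_rest) = target, where
        # S_rest includes the (later-drawn) private genes in expectation
        s_set = base_fw[sl].sum()
        s_rest = base_fw[others].sum() + n_priv * (2.0 ** 3.0) * np.exp(
            0.5 * (cfg.baseline_log2_sd * np.log(2.0)) ** 2
        )
        f = eff.baseline_fraction
        c = f * s_rest / ((1.0 - f) * s_set)
        base_fw[sl] *= c

    rpf_mats: dict[str, CountMatrix] = {}
    mrna_mats: dict[str, CountMatrix] = {}
    meta_rows = []
    truth_rows = []
    n_samples = 2 * cfg.n_replicates

    for sp in species:
        sp_rng = np.random.default_rng(rng.integers(0, 2**31))
        base_priv = 2.0 ** sp_rng.normal(3.0, cfg.baseline_log2_sd, size=n_priv)
        mt_priv = draw_mt(sp_rng, n_priv)
        base = np.concatenate([base_fw, base_priv])
        m_shared = np.concatenate([mt_fw[:, 0], mt_priv[:, 0]])
        t_shared = np.concatenate([mt_fw[:, 1], mt_priv[:, 1]])
        # species deviations on the mRNA and RPF axes; TE deviation emerges
        dm = sp_rng.normal(0, cfg.species_noise_mrna, cfg.n_genes)
        dr = sp_rng.normal(0, cfg.species_noise_rpf, cfg.n_genes)
        lfc_mrna = m_shared + dm
        lfc_rpf = m_shared + t_shared + dr
        lfc_te = lfc_rpf - lfc_mrna

        abund = {
            ("mRNA", "diapause"): base,
            ("mRNA", "developing"): base * 2.0**lfc_mrna,
            ("RPF", "diapause"): base,
            ("RPF", "developing"): base * 2.0**lfc_rpf,
        }
        for assay, mats in (("RPF", rpf_mats), ("mRNA", mrna_mats)):
            cols = {}
            for cond in ("diapause", "developing"):
                rel = abund[(assay, cond)]
                rel = rel / rel.sum()
                for rep in range(1, cfg.n_replicates + 1):
                    sigma2 = np.log(1 + cfg.library_size_cv**2)
                    lib = cfg.library_size_mean * sp_rng.lognormal(
                        -0.5 * sigma2, np.sqrt(sigma2)
                    )
                    sid = f"{sp}_{assay}_{cond}_r{rep}"
                    cols[sid] = _nb_draw(sp_rng, rel * lib, cfg.nb_dispersion)
                    meta_rows.append((sid, sp, cond, rep, assay))
            mats[sp] = CountMatrix(
                counts=pd.DataFrame(cols, index=gene_ids[sp]), assay=assay
            )
        truth_rows.append(
            pd.DataFrame(
                {
                    "species": sp,
                    "gene_id": gene_ids[sp],
                    "lfc_mrna": lfc_mrna,
                    "lfc_te": lfc_te,
                    "lfc_rpf": lfc_rpf,
                }
            )
        )

    meta = validate_sample_meta(
        pd.DataFrame(
            meta_rows, columns=["sample_id", "species", "condition", "replicate", "assay"]
        )
    )
    truth = pd.concat(truth_rows, ignore_index=True)
    return SimulatedDataset(
        rpf=rpf_mats,
        mrna=mrna_mats,
        meta=meta,
        orthologs=OrthologMap(fourway=fourway),
        gene_sets=gene_sets,
        truth=truth,
        config=cfg,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset in the exact TSV dialects the readers use."""
    from pathlib import Path

    from .ingest import write_count_matrix, write_gene_set, write_ortholog_map, write_sample_meta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp, cm in ds.rpf.items():
        write_count_matrix(cm, out / f"counts_rpf_{sp}.tsv")
    for sp, cm in ds.mrna.items():
        write_count_matrix(cm, out / f"counts_mrna_{sp}.tsv")
    write_sample_meta(ds.meta, out / "samples.tsv")
    write_ortholog_map(ds.orthologs, out / "orthologs_fourway.tsv")
    for name, per_sp in ds.gene_sets.items():
        for sp, gs in per_sp.items():
            write_gene_set(gs, out / f"geneset_{name}_{sp}.txt")
    t = ds.truth.copy()
    t.to_csv(out / "truth.tsv", sep="\t", index=False)
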