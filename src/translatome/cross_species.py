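"""Cross-species conservation statistics.

Three views of how similar the feeding response is between species:
pairwise ortholog fold-change correlations (Spearman and Pearson), a
four-way expression-divergence statistic with a shuffle null, and a
sample-level PCA of ortholog abundances.

Divergence is computed per four-way ortholog group by first z-normalizing
each species' log2 fold changes over the four-way gene set (subtract mean,
divide by SD), then averaging the absolute z difference over the six
unordered species pairs. z-normalization makes the statistic invariant to
per-species affine rescaling of fold changes, so a lower divergence for RPF
than mRNA reflects genuine between-species conservation, not a narrower
fold-change scale; the shuffle control (ortholog slots resampled within each
species) verifies exactly this.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .de import DEConfig, estimate_size_factors
from .ingest import CountMatrix, OrthologMap, ValidationError


def pairwise_fc_correlation(
    fc_a: pd.DataFrame, fc_b: pd.DataFrame, pairs: pd.DataFrame
) -> dict:
    """Spearman/Pearson correlation of ortholog fold changes between two
    species, over pairs where both genes are present and well-expressed."""
    sel = pairs[
        pairs["gene_a"].isin(fc_a.index) & pairs["gene_b"].isin(fc_b.index)
    ]
    sub_a = fc_a.loc[sel["gene_a"]]
    sub_b = fc_b.loc[sel["gene_b"]]
    keep = sub_a["well_expressed"].to_numpy() & sub_b["well_expressed"].to_numpy()
    x = sub_a["lfc"].to_numpy()[keep]
    y = sub_b["lfc"].to_numpy()[keep]
    if x.size < 3:
        raise ValidationError(
            f"need >=3 well-expressed ortholog pairs, got {x.size}"
        )
    rho = stats.spearmanr(x, y)
    r = stats.pearsonr(x, y)
    return {
        "spearman_rho": float(rho.statistic),
        "pearson_r": float(r.statistic),
        "n_pairs": int(x.size),
    }


def _fourway_lfc_matrix(
    fc_tables: Mapping[str, pd.DataFrame], omap: OrthologMap, require_well_expressed: bool = True
) -> pd.DataFrame:
    """Group x species matrix of lfc values for four-way groups complete in
    every species (optionally requiring the well-expressed flag)."""
    fw = omap.fourway
    if not len(fw):
        raise ValidationError("ortholog map has no four-way groups")
    cols = {}
    keep = np.ones(len(fw), dtype=bool)
    for sp in fw.columns:
        if sp not in fc_tables:
            raise ValidationError(f"no fold-change table for species {sp!r}")
        fc = fc_tables[sp]
        genes = fw[sp]
        present = genes.isin(fc.index).to_numpy()
        keep &= present
        lfc = np.full(len(fw), np.nan)
        lfc[present] = fc["lfc"].reindex(genes[present]).to_numpy()
        if require_well_expressed:
            we = np.zeros(len(fw), dtype=bool)
            we[present] = fc["well_expressed"].reindex(genes[present]).to_numpy()
            keep &= we
        cols[sp] = lfc
    mat = pd.DataFrame(cols, index=fw.index)[list(fw.columns)]
    mat = mat[keep]
    if len(mat) < 2:
        raise ValidationError("fewer than 2 four-way groups with complete lfc")
    return mat


def _zscore_columns(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=0, keepdims=True)
    sd = mat.std(axis=0, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("a species has zero lfc variance over the four-way set")
    return (mat - mean) / sd


def _pair_mean_abs_diff(z: np.ndarray) -> np.ndarray:
    n_sp = z.shape[1]
    pairs = list(combinations(range(n_sp), 2))
    acc = np.zeros(z.shape[0])
    for i, j in pairs:
        acc += np.abs(z[:, i] - z[:, j])
    return acc / len(pairs)


def fourway_divergence(
    fc_tables: Mapping[str, pd.DataFrame], omap: OrthologMap
) -> pd.Series:
    """Per-group divergence: mean over species pairs of |z_a - z_b|."""
    mat = _fourway_lfc_matrix(fc_tables, omap)
    z = _zscore_columns(mat.to_numpy())
    return pd.Series(_pair_mean_abs_diff(z), index=mat.index, name="divergence")


def divergence_compare(div_mrna: pd.Series, div_rpf: pd.Series) -> dict:
    """KS comparison of the mRNA and RPF divergence distributions."""
    ks = stats.ks_2samp(div_mrna.to_numpy(), div_rpf.to_numpy())
    return {
        "median_mrna": float(np.median(div_mrna)),
        "median_rpf": float(np.median(div_rpf)),
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "n_groups_mrna": int(len(div_mrna)),
        "n_groups_rpf": int(len(div_rpf)),
    }


def divergence_shuffle_control(
    fc_tables_mrna: Mapping[str, pd.DataFrame],
    fc_tables_rpf: Mapping[str, pd.DataFrame],
    omap: OrthologMap,
    n_shuffles: int = 1000,
    seed: int | None = None,
    replace: bool = True,
) -> np.ndarray:
    """Shuffle-null for the divergence comparison.

    For each shuffle, ortholog groups are rebuilt by resampling each species'
    gene slot (with replacement by default; ``replace=False`` permutes,
    preserving the per-species lfc multiset). Divergence distributions are
    recomputed for both assays on the same shuffled grouping and compared by
    KS; the array of KS p-values is returned. With shuffled groupings the
    pairing carries no biology, so exchangeable mRNA/RPF effects give
    approximately uniform p-values.

    The per-species z-normalization constants are estimated once, from the
    observed four-way set, and held fixed across shuffles: with-replacement
    resampling then yields iid divergence draws and an exactly calibrated
    null, whereas re-estimating the constants inside each shuffle couples
    the resampled values and makes the KS p-values conservative.
    """
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    if seed is None:
        raise ValidationError("a seed is required for the shuffle control")
    rng = np.random.default_rng(seed)
    # restrict both assays to the groups complete in both, so the two KS
    # samples have equal size per shuffle
    mat_m = _fourway_lfc_matrix(fc_tables_mrna, omap)
    mat_r = _fourway_lfc_matrix(fc_tables_rpf, omap)
    common = mat_m.index.intersection(mat_r.index)
    zm_src = _zscore_columns(mat_m.loc[common].to_numpy())
    zr_src = _zscore_columns(mat_r.loc[common].to_numpy())
    n = len(common)
    n_sp = zm_src.shape[1]
    pvals = np.empty(n_shuffles)
    for k in range(n_shuffles):
        idx = np.empty((n, n_sp), dtype=np.intp)
        for j in range(n_sp):
            if replace:
                idx[:, j] = rng.integers(0, n, size=n)
            else:
                idx[:, j] = rng.permutation(n)
        zm = np.take_along_axis(zm_src, idx, axis=0)
        zr = np.take_along_axis(zr_src, idx, axis=0)
        ks = stats.ks_2samp(_pair_mean_abs_diff(zm), _pair_mean_abs_diff(zr))
        pvals[k] = ks.pvalue
    return pvals


@dataclass
class PCAResult:
    """Sample scores, gene loadings and variance fractions of a PCA."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray  # one entry per component, sums to 1

    def component_name(self, component: int) -> str:
        return f"PC{component}"


def build_ortholog_expression(
    count_matrices: Mapping[str, CountMatrix],
    omap: OrthologMap,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Four-way-group x sample matrix of log2(normalized count + pseudocount).

    Each species' samples are depth-normalized within species, then rows are
    stacked by four-way group so that every column (sample, from any species)
    is comparable gene-by-gene. Sample ids must be globally unique.
    """
    config = config or DEConfig()
    fw = omap.fourway
    if not len(fw):
        raise ValidationError("ortholog map has no four-way groups")
    blocks = []
    for sp in fw.columns:
        if sp not in count_matrices:
            raise ValidationError(f"no count matrix for species {sp!r}")
        cm = count_matrices[sp]
        sf = estimate_size_factors(cm)
        q = cm.counts / sf
        genes = fw[sp]
        if not genes.isin(q.index).all():
            missing = genes[~genes.isin(q.index)].tolist()
            raise ValidationError(
                f"four-way genes missing from {sp!r} counts: {missing[:5]}"
            )
        block = np.log2(q.reindex(genes).to_numpy() + config.pseudocount)
        blocks.append(pd.DataFrame(block, index=fw.index, columns=q.columns))
    out = pd.concat(blocks, axis=1)
    if out.columns.has_duplicates:
        raise ValidationError("sample ids must be unique across species")
    return out


def pca_samples(expr: pd.DataFrame, scale: bool = False) -> PCAResult:
    """PCA of samples over ortholog-group features.

    ``expr`` is a group x sample matrix of log-transformed normalized
    abundances. Features (groups) are mean-centered; optional unit-variance
    scaling. Full-rank decomposition, so variance fractions sum to 1.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise ValidationError("PCA needs >=2 ortholog groups and >=2 samples")
    X = expr.to_numpy().T  # samples x features
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValidationError("expression matrix is constant; PCA undefined")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=None)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=expr.index, columns=comp_names),
        variance_fraction=pca.explained_variance_ratio_,
    )


def high_loading_genes(pca: PCAResult, component: int = 1, k_sd: float = 2.0) -> list:
    """Features loading exceptionally strongly on one component.

    Returns features whose absolute loading exceeds mean + k_sd * SD of the
    component's absolute loadings (absolute values, since the sign of a
    principal component is arbitrary).
    """
    name = pca.component_name(component)
    if name not in pca.loadings.columns:
        raise ValidationError(f"component {component} not present")
    w = np.abs(pca.loadings[name].to_numpy())
    thr = w.mean() + k_sd * w.std(ddof=0)
    return list(pca.loadings.index[w > thr])
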