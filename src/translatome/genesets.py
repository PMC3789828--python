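"""Ribosome resource allocation and gene-set fold-change comparisons.

``footprint_fraction`` measures what share of all ribosome footprints map to
a gene set (e.g. ribosomal proteins) — a direct readout of how translational
capacity is allocated — using raw counts, since the fraction is internally
normalized. ``geneset_fc_compare`` contrasts a set's fold changes between
the RPF and mRNA assays with a paired t-test over genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import CountMatrix, GeneSet, ValidationError


def footprint_fraction(
    cm_rpf: CountMatrix, gene_set: GeneSet, meta: pd.DataFrame | None = None
) -> dict:
    """Fraction of total footprint counts on a gene set, per sample and
    (when metadata is given) averaged within condition. Raw counts are used."""
    missing = gene_set.gene_ids - set(cm_rpf.gene_ids)
    if missing:
        raise ValidationError(
            f"gene set {gene_set.name!r} has genes absent from the matrix: "
            f"{sorted(missing)[:5]}"
        )
    counts = cm_rpf.counts
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValidationError(f"samples with zero total counts: {zero}")
    set_counts = counts.loc[sorted(gene_set.gene_ids)].sum(axis=0)
    per_sample = (set_counts / totals).rename("fraction")
    out = {"set": gene_set.name, "per_sample": per_sample}
    if meta is not None:
        m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
        by_cond = {}
        for cond in ("diapause", "developing"):
            cols = [s for s in per_sample.index if m.loc[s, "condition"] == cond]
            if cols:
                by_cond[cond] = float(per_sample[cols].mean())
        out["by_condition"] = by_cond
    return out


def _summary(v: np.ndarray) -> dict:
    q1, q3 = np.percentile(v, [25, 75])
    return {
        "mean_lfc": float(np.mean(v)),
        "median_lfc": float(np.median(v)),
        "iqr_lfc": float(q3 - q1),
        "fold_change_of_mean": float(2.0 ** np.mean(v)),
        "mean_fold_change": float(np.mean(2.0 ** v)),
    }


def geneset_fc_compare(
    fc_mrna: pd.DataFrame,
    fc_rpf: pd.DataFrame,
    gene_set: GeneSet,
    paired: bool = True,
) -> dict:
    """Compare a gene set's RPF vs mRNA log2 fold changes.

    Reports per-assay summaries (on the log2 scale and both linear-scale
    averages: the fold change of the mean lfc and the mean of per-gene fold
    changes — the latter is the headline figure) and a two-tailed t-test,
    paired over genes by default. A zero-variance paired difference is
    degenerate: p is reported as 0.0 with ``zero_variance`` set.
    """
    genes = sorted(gene_set.gene_ids & set(fc_mrna.index) & set(fc_rpf.index))
    if len(genes) < 3:
        raise ValidationError(
            f"gene set {gene_set.name!r}: need >=3 genes with lfc in both assays, "
            f"got {len(genes)}"
        )
    lm = fc_mrna.loc[genes, "lfc"].to_numpy()
    lr = fc_rpf.loc[genes, "lfc"].to_numpy()
    zero_variance = False
    if paired:
        d = lr - lm
        if np.std(d, ddof=1) == 0.0 and d.mean() != 0.0:
            # constant nonzero shift: infinitely strong paired evidence
            zero_variance = True
            t_stat, p = np.inf * np.sign(d.mean()), 0.0
        elif np.std(d, ddof=1) == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(lr, lm)
            t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_ind(lr, lm)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "set": gene_set.name,
        "n_genes": len(genes),
        "mrna": _summary(lm),
        "rpf": _summary(lr),
        "mean_lfc_difference": float(np.mean(lr - lm)),
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "paired": paired,
        "zero_variance": zero_variance,
    }
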