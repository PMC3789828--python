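"""Genome-wide remodeling statistics.

Summaries of how broadly the transcriptome and translatome change on
diapause exit: fractions of well-expressed genes changing more than two-fold
in either direction, a distribution-breadth comparison between mRNA and RPF
fold changes, and a replicate-variability control that asks whether the
broader RPF distribution could be an artifact of noisier RPF measurements.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEConfig, normalized_counts
from .ingest import AlignedExperiment, ValidationError

MIN_BREADTH_N = 20


def twofold_fractions(fc: pd.DataFrame) -> tuple[float, float]:
    """(fraction up >2-fold, fraction down >2-fold) over well-expressed genes.

    Strict inequality: |lfc| must exceed 1 exactly.
    """
    well = fc[fc["well_expressed"]]
    if not len(well):
        raise ValidationError("no well-expressed genes")
    lfc = well["lfc"].to_numpy()
    return float(np.mean(lfc > 1.0)), float(np.mean(lfc < -1.0))


def breadth_test(lfc_mrna, lfc_rpf) -> dict:
    """Is the RPF fold-change distribution broader than the mRNA one?

    Two-sample Kolmogorov-Smirnov test on |lfc|, with the ratio of median
    absolute fold changes (RPF / mRNA) as the effect size.
    """
    a = np.asarray(lfc_mrna, dtype=float)
    b = np.asarray(lfc_rpf, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"lfc vectors differ in length: {a.shape} vs {b.shape}"
        )
    if a.size < MIN_BREADTH_N:
        raise ValidationError(
            f"breadth test needs >= {MIN_BREADTH_N} genes, got {a.size}"
        )
    ks = stats.ks_2samp(np.abs(a), np.abs(b))
    med_a = float(np.median(np.abs(a)))
    med_b = float(np.median(np.abs(b)))
    ratio = med_b / med_a if med_a > 0 else np.inf
    return {
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
        "median_abs_lfc_mrna": med_a,
        "median_abs_lfc_rpf": med_b,
        "median_ratio_rpf_over_mrna": float(ratio),
        "n": int(a.size),
    }


def replicate_variability(
    aligned: AlignedExperiment, config: DEConfig | None = None
) -> pd.Series:
    """Per-gene mean pairwise |log2 ratio| between replicates.

    For each gene, over every unordered pair of replicates within the same
    condition (pooled across the two conditions), the absolute log2 ratio of
    pseudocounted normalized counts is averaged. Identical replicates give 0.
    """
    config = config or DEConfig()
    q = normalized_counts(aligned)
    pc = config.pseudocount
    pair_vals = []
    for condition in ("diapause", "developing"):
        cols = aligned.condition_samples(condition)
        if len(cols) < 2:
            raise ValidationError(
                f"replicate variability needs >=2 replicates in {condition!r}"
            )
        for ci, cj in combinations(cols, 2):
            pair_vals.append(
                np.abs(np.log2(q[ci] + pc) - np.log2(q[cj] + pc))
            )
    return pd.concat(pair_vals, axis=1).mean(axis=1).rename("replicate_variability")


def remodel_summary(
    fc_mrna: pd.DataFrame,
    fc_rpf: pd.DataFrame,
    aligned_mrna: AlignedExperiment | None = None,
    aligned_rpf: AlignedExperiment | None = None,
    config: DEConfig | None = None,
) -> dict:
    """Headline remodeling statistics for one species.

    Fold-change fractions per assay, the mRNA-vs-RPF breadth test over genes
    well-expressed in both assays, and (when the aligned experiments are
    supplied) median replicate variability per assay.
    """
    up_m, down_m = twofold_fractions(fc_mrna)
    up_r, down_r = twofold_fractions(fc_rpf)
    common = fc_mrna.index[fc_mrna["well_expressed"]].intersection(
        fc_rpf.index[fc_rpf["well_expressed"]]
    )
    breadth = breadth_test(
        fc_mrna.loc[common, "lfc"], fc_rpf.loc[common, "lfc"]
    )
    out = {
        "mrna": {"frac_up_2fold": up_m, "frac_down_2fold": down_m},
        "rpf": {"frac_up_2fold": up_r, "frac_down_2fold": down_r},
        "breadth": breadth,
    }
    if aligned_mrna is not None and aligned_rpf is not None:
        rv_m = replicate_variability(aligned_mrna, config)
        rv_r = replicate_variability(aligned_rpf, config)
        out["replicate_variability"] = {
            "median_mrna": float(rv_m.loc[common].median()),
            "median_rpf": float(rv_r.loc[common].median()),
        }
    return out
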