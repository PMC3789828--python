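"""Translation-efficiency changes, concordance classification and the
translational component of regulation.

A gene's ribosome-footprint (RPF) fold change reflects both its mRNA
abundance change and its translation-efficiency (TE) change:
``lfc_rpf = lfc_mrna + lfc_te`` on the log2 scale, exactly, because both
assays share one pseudocount convention. For genes differentially expressed
in both assays, the change is *concordant* when the RPF change has the same
sign as and a greater magnitude than the mRNA change (translation amplifies
the mRNA-level response) and *discordant* when it is smaller or opposite
(translation opposes it); a binomial test asks whether concordant changes
outnumber discordant ones beyond chance.

The *translational component* score quantifies, per RPF-DE gene, how much of
the RPF change is attributable to TE versus mRNA abundance:
``tc_fraction = |lfc_te| / (|lfc_te| + |lfc_mrna|)``, with genes >75%
translational, <25% translational ("mostly mRNA") or mixed in between.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ValidationError

logger = logging.getLogger(__name__)

LOG2_3 = float(np.log2(3.0))  # tc_score at the 0.75 / 0.25 fraction boundaries


def te_change(fc_mrna: pd.DataFrame, fc_rpf: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TE change table: lfc_mrna, lfc_rpf, lfc_te = lfc_rpf - lfc_mrna."""
    if not fc_mrna.index.equals(fc_rpf.index):
        only_m = fc_mrna.index.difference(fc_rpf.index).tolist()
        only_r = fc_rpf.index.difference(fc_mrna.index).tolist()
        raise ValidationError(
            f"gene universes differ; mRNA-only: {only_m[:5]}, RPF-only: {only_r[:5]}"
        )
    te = pd.DataFrame(
        {
            "lfc_mrna": fc_mrna["lfc"],
            "lfc_rpf": fc_rpf["lfc"],
        }
    )
    te["lfc_te"] = te["lfc_rpf"] - te["lfc_mrna"]
    return te


def classify_concordance(te: pd.DataFrame, joint_de_genes: Iterable) -> dict:
    """Label jointly-DE genes concordant/discordant and test the ratio.

    concordant: same sign and |lfc_rpf| > |lfc_mrna|;
    discordant: opposite sign, or same sign with |lfc_rpf| < |lfc_mrna|;
    exact magnitude ties are excluded and counted separately. A DE gene with
    lfc_mrna == 0 is classified by the RPF change alone (degenerate, logged).
    """
    genes = pd.Index(joint_de_genes)
    missing = genes.difference(te.index)
    if len(missing):
        raise ValidationError(f"genes absent from TE table: {missing.tolist()[:5]}")
    sub = te.loc[genes]
    m = sub["lfc_mrna"].to_numpy()
    r = sub["lfc_rpf"].to_numpy()
    labels = np.full(len(sub), "discordant", dtype=object)
    zero_m = m == 0.0
    if zero_m.any():
        logger.info("%d jointly-DE genes with lfc_mrna == 0 classified by RPF sign alone",
                    int(zero_m.sum()))
    same_sign = np.sign(m) == np.sign(r)
    bigger = np.abs(r) > np.abs(m)
    tie = np.abs(r) == np.abs(m)
    labels[same_sign & bigger] = "concordant"
    labels[same_sign & tie] = "excluded_tie"
    # degenerate: mRNA change exactly zero -> concordant iff any RPF change
    labels[zero_m & (np.abs(r) > 0)] = "concordant"
    labels[zero_m & (r == 0)] = "excluded_tie"
    n_conc = int(np.sum(labels == "concordant"))
    n_disc = int(np.sum(labels == "discordant"))
    n_tie = int(np.sum(labels == "excluded_tie"))
    result = {
        "labels": pd.Series(labels, index=genes, name="concordance"),
        "n_concordant": n_conc,
        "n_discordant": n_disc,
        "n_ties": n_tie,
        "ratio": n_conc / n_disc if n_disc > 0 else np.inf,
        "p_value": concordance_binomial(n_conc, n_disc) if n_conc + n_disc >= 1 else np.nan,
    }
    return result


def concordance_binomial(n_conc: int, n_disc: int) -> float:
    """Exact two-sided binomial p-value at p0 = 0.5.

    Two-sided by summing the probability of every outcome no more likely
    than the observed count.
    """
    n = n_conc + n_disc
    if n < 1:
        raise ValidationError("need at least one classified gene")
    return float(stats.binomtest(n_conc, n, p=0.5, alternative="two-sided").pvalue)


def translational_component(te: pd.DataFrame, de_rpf_genes: Iterable) -> pd.DataFrame:
    """Translational-component table over RPF-DE genes.

    tc_fraction = |lfc_te| / (|lfc_te| + |lfc_mrna|) in [0, 1];
    tc_score = log2(|lfc_te| / |lfc_mrna|) (+-inf at the degenerate edges);
    category: mostly_translational (fraction > 0.75), mostly_mrna (< 0.25),
    else mixed; boundary values fall into mixed. Genes whose two components
    are both exactly zero are flagged undefined and excluded from category
    fractions. Sign-discordant genes are scored on magnitudes and carry a
    discordant_flag.
    """
    genes = pd.Index(de_rpf_genes)
    missing = genes.difference(te.index)
    if len(missing):
        raise ValidationError(f"genes absent from TE table: {missing.tolist()[:5]}")
    sub = te.loc[genes]
    am = np.abs(sub["lfc_mrna"].to_numpy())
    at = np.abs(sub["lfc_te"].to_numpy())
    both_zero = (am == 0) & (at == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(am + at > 0, at / (am + at), np.nan)
        score = np.where(
            (at > 0) & (am > 0), np.log2(at / np.where(am > 0, am, 1.0)),
            np.where(at > 0, np.inf, -np.inf),
        )
    score = np.where(both_zero, np.nan, score)
    category = np.full(len(sub), "mixed", dtype=object)
    category[frac > 0.75] = "mostly_translational"
    category[frac < 0.25] = "mostly_mrna"
    category[both_zero] = "undefined"
    return pd.DataFrame(
        {
            "lfc_mrna": sub["lfc_mrna"],
            "lfc_te": sub["lfc_te"],
            "tc_fraction": frac,
            "tc_score": score,
            "category": category,
            "discordant_flag": np.sign(sub["lfc_mrna"].to_numpy())
            * np.sign(sub["lfc_rpf"].to_numpy())
            < 0,
        },
        index=genes,
    )


def tc_category_fractions(tc: pd.DataFrame) -> dict:
    """Fractions of the three categories over genes with a defined category."""
    defined = tc[tc["category"] != "undefined"]
    if not len(defined):
        raise ValidationError("no categorized genes")
    counts = defined["category"].value_counts()
    n = len(defined)
    return {
        "mostly_translational": float(counts.get("mostly_translational", 0)) / n,
        "mixed": float(counts.get("mixed", 0)) / n,
        "mostly_mrna": float(counts.get("mostly_mrna", 0)) / n,
    }
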