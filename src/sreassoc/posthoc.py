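"""Multiple-testing control and per-locus contribution analysis.

BH-FDR ("fdr" = Benjamini–Hochberg in R's p.adjust) is applied within a
category mode, over exactly the genes that survived binning in that mode.
Genes with adjusted p < 0.05 are called significant, < 0.1 suggestive.

The leave-one-out analysis re-runs SKAT-O on a gene's bin with each locus
removed in turn, labelling each removal by whether the gene became less or
more significant without it — the per-locus contribution readout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .binning import GeneBin
from .skato import AssocConfig, AssocResult, NullModel, skat_o

__all__ = ["bh_fdr", "fdr_table", "leave_one_out", "drop_locus"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_table(results: list[AssocResult]) -> pd.DataFrame:
    """Per-gene results table with BH-adjusted p and significance calls."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "unique_loci": [r.m_loci for r in results],
            "variants_across_cohort": [r.total_allele_count for r in results],
            "skat_o_pvalue": [r.p_skato for r in results],
        }
    )
    if len(df):
        df["fdr_pvalue"] = bh_fdr(df["skat_o_pvalue"])
        df["significant"] = df["fdr_pvalue"] < 0.05
        df["suggestive"] = df["fdr_pvalue"] < 0.1
        df = df.sort_values("skat_o_pvalue", kind="stable").reset_index(drop=True)
    else:
        df["fdr_pvalue"] = []
        df["significant"] = []
        df["suggestive"] = []
    return df


def drop_locus(bin: GeneBin, index: int) -> GeneBin:
    """A copy of the bin with one locus column removed.

    The cohort allele total is reduced by the removed locus's observed minor
    alleles, so the reported bin size matches what re-binning without that
    locus would give.
    """
    if not 0 <= index < bin.m_loci:
        raise IndexError(f"locus index {index} out of range for {bin.m_loci} loci")
    keep = [j for j in range(bin.m_loci) if j != index]
    removed_alleles = int(round(float(np.sum(np.maximum(bin.G[:, index], 0)))))
    return GeneBin(
        gene_id=bin.gene_id,
        loci=[bin.loci[j] for j in keep],
        rsids=[bin.rsids[j] for j in keep],
        G=bin.G[:, keep].copy(),
        mafs=bin.mafs[keep].copy(),
        total_allele_count=bin.total_allele_count - removed_alleles,
    )


def leave_one_out(
    bin: GeneBin, null: NullModel, config: AssocConfig = AssocConfig()
) -> pd.DataFrame:
    """Per-locus contribution table: SKAT-O p after removing each locus.

    Requires m >= 2 loci. ``direction`` is "less significant" when the
    p-value rises after removal (the locus was carrying signal) and "more
    significant" when it falls.
    """
    if bin.m_loci < 2:
        raise ValueError(
            f"gene {bin.gene_id}: leave-one-out needs >= 2 loci, has {bin.m_loci}"
        )
    baseline = skat_o(bin, null, config)
    rows = []
    for j in range(bin.m_loci):
        sub = drop_locus(bin, j)
        res = skat_o(sub, null, config)
        rows.append(
            {
                "gene_id": bin.gene_id,
                "locus": bin.loci[j],
                "rsid": bin.rsids[j],
                "alleles_removed": bin.total_allele_count - sub.total_allele_count,
                "baseline_p": baseline.p_skato,
                "loo_p": res.p_skato,
                "direction": (
                    "less significant"
                    if res.p_skato > baseline.p_skato
                    else "more significant"
                    if res.p_skato < baseline.p_skato
                    else "unchanged"
                ),
            }
        )
    return pd.DataFrame(rows)
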