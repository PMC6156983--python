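"""End-to-end orchestration: annotate -> bin -> SKAT-O -> FDR -> leave-one-out.

Produces, per category mode, a results table shaped like the study's
gene-level tables (gene, unique loci, cohort allele count, SKAT-O p, FDR p),
a per-locus contribution table for every significant or suggestive gene, a
QC summary with exact variant accounting at each filter stage, and a run
manifest (config hash + seed) for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .annotate import (
    AnnotationQC,
    SREAnnotation,
    VariantRecord,
    annotate_variants,
    annotations_to_frame,
    read_motifs,
    read_vcf_records,
)
from .binning import CATEGORY_MODES, BinConfig, GeneBin, bin_by_gene, compute_maf
from .genemodels import read_gene_models
from .posthoc import fdr_table, leave_one_out
from .skato import AssocConfig, fit_null_model, skat_o

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "manhattan_data", "plot_manhattan"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    fasta: Path
    vcf: Path
    gene_models: Path
    motif_ese: Path
    motif_ess: Path
    motif_ise: Path
    phenotypes: Path
    out_dir: Path
    modes: tuple[str, ...] = ("coding", "intronic", "combined")
    maf_threshold: float = 0.01
    min_allele_count: int = 5
    min_size_unit: str = "alleles"
    assoc: AssocConfig = field(default_factory=AssocConfig)
    scan_alt: bool = False
    stranded: bool = False
    run_loo: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one category mode is required")
        for m in self.modes:
            if m not in CATEGORY_MODES:
                raise ValueError(f"unknown category mode {m!r}")
        for name in ("fasta", "vcf", "gene_models", "motif_ese", "motif_ess", "motif_ise", "phenotypes"):
            p = Path(getattr(self, name))
            object.__setattr__(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}
        d["assoc"] = dataclasses.asdict(self.assoc)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]  # mode -> FDR table
    contributions: dict[str, pd.DataFrame]  # mode -> leave-one-out table
    qc: dict
    annotations: pd.DataFrame
    manifest: dict


def _variant_accounting(
    variants: list[VariantRecord],
    annotations: list[SREAnnotation],
    mode: str,
    bins: list[GeneBin],
    maf_threshold: float,
) -> dict[str, int]:
    """Exact per-mode fate of every VCF variant.

    variants_in_vcf == retained + dropped_by_bin_size + dropped_by_region
    + dropped_by_category + dropped_by_maf + dropped_monomorphic.
    """
    wanted = CATEGORY_MODES[mode]
    ann_by_key: dict[str, list[SREAnnotation]] = {}
    for a in annotations:
        ann_by_key.setdefault(a.key, []).append(a)
    in_bins = {key for b in bins for key in b.loci}
    counts = dict.fromkeys(
        (
            "variants_in_vcf",
            "retained",
            "dropped_by_bin_size",
            "dropped_by_region",
            "dropped_by_category",
            "dropped_by_maf",
            "dropped_monomorphic",
        ),
        0,
    )
    for v in variants:
        counts["variants_in_vcf"] += 1
        anns = ann_by_key.get(v.key, [])
        if all(a.gene_id is None for a in anns):
            counts["dropped_by_region"] += 1
            continue
        if not any(a.categories & wanted for a in anns):
            counts["dropped_by_category"] += 1
            continue
        maf = compute_maf(v.dosages)
        if maf <= 0.0:
            counts["dropped_monomorphic"] += 1
        elif maf >= maf_threshold:
            counts["dropped_by_maf"] += 1
        elif v.key in in_bins:
            counts["retained"] += 1
        else:
            counts["dropped_by_bin_size"] += 1
    return counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for every requested category mode and write outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("loading inputs")
    genome = Fasta(str(config.fasta))
    models = read_gene_models(config.gene_models)
    motif_sets = {
        "ESE": read_motifs(config.motif_ese, "ESE"),
        "ESS": read_motifs(config.motif_ess, "ESS"),
        "ISE": read_motifs(config.motif_ise, "ISE"),
    }
    pheno = pd.read_csv(config.phenotypes, sep="\t")
    variants = list(read_vcf_records(config.vcf))
    logger.info("read %d biallelic SNPs", len(variants))

    qc_ann = AnnotationQC()
    annotations = list(
        annotate_variants(
            variants,
            genome,
            models,
            motif_sets,
            scan_alt=config.scan_alt,
            stranded=config.stranded,
            qc=qc_ann,
        )
    )
    ann_df = annotations_to_frame(annotations)
    ann_df.to_csv(out / "annotations.tsv", sep="\t", index=False)

    null = fit_null_model(pheno["phenotype"], pheno[["age", "sex"]])
    logger.info("null model on %d samples, sigma2=%.4f", null.n, null.sigma2)

    gene_pos = {
        m.gene_id: (m.contig, (m.span[0] + m.span[1]) // 2) for m in models
    }

    tables: dict[str, pd.DataFrame] = {}
    contributions: dict[str, pd.DataFrame] = {}
    qc: dict = {"annotation": dataclasses.asdict(qc_ann), "modes": {}}
    for mode in config.modes:
        logger.info("mode %s: binning", mode)
        bcfg = BinConfig(
            maf_threshold=config.maf_threshold,
            min_allele_count=config.min_allele_count,
            category_mode=mode,
            min_size_unit=config.min_size_unit,
        )
        bins = bin_by_gene(annotations, variants, bcfg)
        results = [skat_o(b, null, config.assoc) for b in bins]
        table = fdr_table(results)
        tables[mode] = table
        table.to_csv(out / f"results_{mode}.tsv", sep="\t", index=False, float_format="%.6g")

        qc["modes"][mode] = _variant_accounting(
            variants, annotations, mode, bins, config.maf_threshold
        )
        qc["modes"][mode]["bins_tested"] = len(bins)

        if config.run_loo and len(table):
            flagged = table.loc[table["suggestive"], "gene_id"]
            loo_frames = []
            bin_by_id = {b.gene_id: b for b in bins}
            for gid in flagged:
                b = bin_by_id[gid]
                if b.m_loci >= 2:
                    loo_frames.append(leave_one_out(b, null, config.assoc))
            if loo_frames:
                loo = pd.concat(loo_frames, ignore_index=True)
                contributions[mode] = loo
                loo.to_csv(out / f"contributions_{mode}.tsv", sep="\t", index=False, float_format="%.6g")

        mdata = manhattan_data(table, gene_pos)
        mdata.to_csv(out / f"manhattan_{mode}.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_samples": int(null.n),
        "n_variants": len(variants),
        "modes": list(config.modes),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "qc_summary.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)

    return PipelineResult(
        tables=tables, contributions=contributions, qc=qc,
        annotations=ann_df, manifest=manifest,
    )


def manhattan_data(
    results: pd.DataFrame, gene_positions: dict[str, tuple[str, int]]
) -> pd.DataFrame:
    """Per-gene plot table: contig, midpoint, -log10 raw p, reference lines.

    ``pvalue_line`` is -log10(0.05); ``fdr_line`` marks the raw-p level
    separating FDR-significant genes from the rest (NaN when nothing is
    significant). Genes without a known position are dropped with a warning.
    """
    rows = []
    for _, r in results.iterrows():
        pos = gene_positions.get(r["gene_id"])
        if pos is None:
            logger.warning("gene %s has no position; dropped from plot", r["gene_id"])
            continue
        rows.append(
            {
                "gene_id": r["gene_id"],
                "contig": pos[0],
                "position": pos[1],
                "neg_log10_p": -np.log10(r["skat_o_pvalue"]),
                "significant": bool(r["significant"]),
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "contig", "position", "neg_log10_p", "significant"])
    sig = results.loc[results["fdr_pvalue"] < 0.05, "skat_o_pvalue"]
    if len(sig):
        # drawn between the largest significant raw p and the smallest
        # non-significant one, so significant genes sit strictly above it
        rest = results.loc[results["fdr_pvalue"] >= 0.05, "skat_o_pvalue"]
        p_next = float(rest.min()) if len(rest) else 1.0
        fdr_line = -np.log10(np.sqrt(float(sig.max()) * p_next))
    else:
        fdr_line = np.nan
    df.attrs["pvalue_line"] = -np.log10(0.05)
    df.attrs["fdr_line"] = fdr_line
    df["pvalue_line"] = df.attrs["pvalue_line"]
    df["fdr_line"] = fdr_line
    return df


def plot_manhattan(mdata: pd.DataFrame, path: str | Path) -> None:
    """Render the Manhattan table (aesthetics untested; the table is the artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    contigs = list(dict.fromkeys(mdata["contig"]))
    offset, ticks = 0, []
    for i, c in enumerate(contigs):
        sub = mdata[mdata["contig"] == c]
        xs = sub["position"] + offset
        ax.scatter(xs, sub["neg_log10_p"], s=12, color="C0" if i % 2 else "C7")
        ticks.append((offset + (sub["position"] + offset).mean(), c))
        offset += sub["position"].max() + 1
    ax.axhline(mdata.attrs.get("pvalue_line", -np.log10(0.05)), color="blue", lw=0.8)
    fdr_line = mdata.attrs.get("fdr_line", np.nan)
    if np.isfinite(fdr_line):
        ax.axhline(fdr_line, color="red", lw=0.8)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_xticks([t for t, _ in ticks][:20])
    ax.set_xticklabels([c for _, c in ticks][:20], rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
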