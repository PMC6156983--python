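"""Gene-level binning of rare SRE variants.

Variants are kept when their SRE categories intersect the category mode
(coding = ESE+ESS, intronic = ISE, combined = all three), their cohort minor
allele frequency is strictly below the rarity threshold (default 0.01) and
they are polymorphic. Surviving variants are grouped by gene, and a bin
enters the association stage only if its total minor-allele count across the
cohort reaches the minimum bin size (default five variants across samples).

Missing genotypes are mean-imputed per locus (2*MAF) in the association
matrix but count as non-carriers in the cohort allele total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .annotate import SREAnnotation, VariantRecord

__all__ = ["BinConfig", "GeneBin", "CATEGORY_MODES", "compute_maf", "bin_by_gene"]

logger = logging.getLogger(__name__)

CATEGORY_MODES: dict[str, frozenset[str]] = {
    "coding": frozenset({"ESE", "ESS"}),
    "intronic": frozenset({"ISE"}),
    "combined": frozenset({"ESE", "ESS", "ISE"}),
}


@dataclass(frozen=True)
class BinConfig:
    maf_threshold: float = 0.01
    min_allele_count: int = 5
    category_mode: str = "coding"
    #: if "loci", the minimum-bin-size rule counts unique loci instead of the
    #: cohort minor-allele total (non-default alternative reading)
    min_size_unit: str = "alleles"

    def __post_init__(self) -> None:
        if not 0 < self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5]")
        if self.min_allele_count < 1:
            raise ValueError("min_allele_count must be >= 1")
        if self.category_mode not in CATEGORY_MODES:
            raise ValueError(
                f"category_mode must be one of {sorted(CATEGORY_MODES)}, "
                f"got {self.category_mode!r}"
            )
        if self.min_size_unit not in ("alleles", "loci"):
            raise ValueError("min_size_unit must be 'alleles' or 'loci'")


@dataclass
class GeneBin:
    """A gene's rare-variant genotype matrix (minor-allele dosage coding)."""

    gene_id: str
    loci: list[str]  # variant keys, ordered by position
    rsids: list[str]
    G: np.ndarray  # n_samples x m_loci, float (missing mean-imputed)
    mafs: np.ndarray  # per-locus MAF
    total_allele_count: int  # sum of observed minor-allele dosages

    @property
    def m_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from dosages in {0,1,2}, -1 = missing.

    Computes the alt-allele frequency over non-missing samples and folds it:
    returns min(p, 1-p).
    """
    d = np.asarray(dosages)
    obs = d >= 0
    n = int(obs.sum())
    if n == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    p = float(d[obs].sum()) / (2 * n)
    return min(p, 1.0 - p)


def _minor_dosages(dosages: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip to minor-allele coding if the alt allele is the major one."""
    d = np.asarray(dosages, dtype=float)
    obs = d >= 0
    p = d[obs].sum() / (2 * obs.sum())
    flipped = p > 0.5
    if flipped:
        d = np.where(obs, 2.0 - d, -1.0)
    return d, flipped


def bin_by_gene(
    annotations: Iterable[SREAnnotation],
    variants: Iterable[VariantRecord],
    config: BinConfig,
) -> list[GeneBin]:
    """Group rare SRE variants into per-gene bins under one category mode.

    ``annotations`` may contain several rows per variant (one per overlapping
    gene); a variant joins the bin of every gene under which its categories
    intersect the mode's category set. Output is sorted by gene id; loci
    within a bin are sorted by position.
    """
    wanted = CATEGORY_MODES[config.category_mode]
    by_key: dict[str, VariantRecord] = {}
    for v in variants:
        by_key[v.key] = v

    gene_loci: dict[str, list[tuple[int, SREAnnotation]]] = {}
    for a in annotations:
        if a.gene_id is None or not (a.categories & wanted):
            continue
        if a.key not in by_key:
            raise KeyError(f"annotation for {a.key} has no matching variant record")
        pos = int(a.key.rsplit(":", 1)[1])
        gene_loci.setdefault(a.gene_id, []).append((pos, a))

    bins: list[GeneBin] = []
    for gene_id in sorted(gene_loci):
        cols, mafs, keys, rsids = [], [], [], []
        observed_total = 0
        for pos, a in sorted(gene_loci[gene_id], key=lambda t: t[0]):
            v = by_key[a.key]
            maf = compute_maf(v.dosages)
            if maf <= 0.0 or maf >= config.maf_threshold:
                continue
            d, _ = _minor_dosages(v.dosages)
            obs = d >= 0
            observed_total += int(d[obs].sum())
            # mean-impute missing genotypes at 2*MAF
            d = np.where(obs, d, 2.0 * maf)
            cols.append(d)
            mafs.append(maf)
            keys.append(a.key)
            rsids.append(a.rsid or a.key)
        if not cols:
            continue
        size = len(cols) if config.min_size_unit == "loci" else observed_total
        if size < config.min_allele_count:
            logger.debug(
                "gene %s dropped: bin size %d < %d", gene_id, size, config.min_allele_count
            )
            continue
        bins.append(
            GeneBin(
                gene_id=gene_id,
                loci=keys,
                rsids=rsids,
                G=np.column_stack(cols),
                mafs=np.asarray(mafs, dtype=float),
                total_allele_count=observed_total,
            )
        )
    if not bins:
        logger.warning("no gene bin survived filtering in mode %s", config.category_mode)
    return bins
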