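"""SRE annotation of SNPs.

Each SNP is classified by genomic region against the gene models (exonic /
intronic / intergenic) and then tested for splicing-regulatory-element
membership by scanning the 11-mer reference window around the site (5 bp on
each side) for hexamer motifs: ESE and ESS catalogs apply to exonic SNPs,
the ISE catalog to intronic SNPs, whose gene is the one owning both exons
bordering the intron.

Windows are taken from the reference sequence only; the alternate allele is
not substituted (``scan_alt=True`` additionally scans the alt-substituted
window for exploratory use). Motifs are matched on the forward strand; with
``stranded=True`` minus-strand genes are scanned against reverse-complemented
motifs as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from .genemodels import GeneModel

__all__ = [
    "MotifSet",
    "VariantRecord",
    "SREAnnotation",
    "read_motifs",
    "read_vcf_records",
    "extract_window",
    "scan_sre",
    "classify_region",
    "annotate_variants",
    "annotations_to_frame",
]

logger = logging.getLogger(__name__)

_CATEGORIES = ("ESE", "ESS", "ISE")
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifSet:
    """A catalog of hexamer motifs for one SRE category."""

    category: str
    hexamers: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown SRE category {self.category!r}")
        for h in self.hexamers:
            if len(h) != 6 or set(h) - set("ACGT"):
                raise ValueError(f"motif {h!r} is not an ACGT hexamer")

    def reverse_complement(self) -> "MotifSet":
        return MotifSet(
            self.category, frozenset(h.translate(_COMP)[::-1] for h in self.hexamers)
        )


@dataclass
class VariantRecord:
    """One biallelic SNP with per-sample minor/alt-allele dosages (-1 = missing)."""

    contig: str
    pos: int  # 1-based
    rsid: str | None
    ref: str
    alt: str
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref == alt")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}"


@dataclass
class SREAnnotation:
    """Region and SRE-category call for one variant."""

    key: str
    rsid: str | None
    region: str  # exonic | intronic | intergenic
    gene_id: str | None
    categories: frozenset[str]
    window: str

    @property
    def is_sre(self) -> bool:
        return bool(self.categories)


def read_motifs(path: str | Path, category: str) -> MotifSet:
    """Read a plain-text motif list (one uppercase hexamer per line, # comments)."""
    hexamers = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if not line or line.startswith("#"):
                continue
            hexamers.add(line)
    return MotifSet(category, frozenset(hexamers))


def read_vcf_records(path: str | Path) -> Iterator[VariantRecord]:
    """Stream biallelic SNPs from a VCF; non-SNP or multi-allelic records are skipped."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            dosages = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages[i] = -1
                else:
                    dosages[i] = sum(gt)
            rsid = rec.id if rec.id not in (None, ".") else None
            yield VariantRecord(rec.contig, rec.pos, rsid, ref, alt, dosages)


def extract_window(
    genome: Fasta, contig: str, pos: int, flank: int = 5
) -> str:
    """Uppercase reference sequence of length 2*flank+1 centred on ``pos`` (1-based)."""
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not present in reference FASTA")
    length = len(genome[contig])
    if pos - flank < 1 or pos + flank > length:
        raise ValueError(
            f"window [{pos - flank}, {pos + flank}] for variant {contig}:{pos} "
            f"out of bounds (contig length {length})"
        )
    return str(genome[contig][pos - flank - 1 : pos + flank]).upper()


def scan_sre(window: str, motifs: MotifSet) -> bool:
    """True iff any of the six hexamer substrings of the 11-mer is in the catalog.

    Substrings containing N never match.
    """
    if len(window) != 11:
        raise ValueError(f"window must be an 11-mer, got length {len(window)}")
    for i in range(6):
        sub = window[i : i + 6]
        if "N" not in sub and sub in motifs.hexamers:
            return True
    return False


def classify_region(
    variant: VariantRecord, models: Sequence[GeneModel]
) -> list[tuple[str, str | None]]:
    """Region assignments for a variant: list of (region, gene_id).

    Exonic if the position lies inside an exon of a gene; intronic if it lies
    strictly between two consecutive exons of the same gene (the gene owning
    both bordering exons). A variant hitting no gene span is intergenic. A
    position can legitimately be exonic for one gene and intronic for an
    overlapping one; all assignments are returned.
    """
    hits: list[tuple[str, str | None]] = []
    for m in models:
        if m.contig != variant.contig:
            continue
        lo, hi = m.span
        if not lo <= variant.pos <= hi:
            continue
        if any(s <= variant.pos <= e for s, e in m.exons):
            hits.append(("exonic", m.gene_id))
        elif any(s <= variant.pos <= e for s, e in m.introns):
            hits.append(("intronic", m.gene_id))
    if not hits:
        return [("intergenic", None)]
    return hits


@dataclass
class AnnotationQC:
    """Counts accumulated while annotating a VCF."""

    n_variants: int = 0
    n_exonic: int = 0
    n_intronic: int = 0
    n_intergenic: int = 0
    n_sre: int = 0
    n_ref_mismatch: int = 0
    n_multi_gene: int = 0


def annotate_variants(
    variants: Iterable[VariantRecord],
    genome: Fasta,
    models: Sequence[GeneModel],
    motif_sets: dict[str, MotifSet],
    *,
    scan_alt: bool = False,
    stranded: bool = False,
    qc: AnnotationQC | None = None,
) -> Iterator[SREAnnotation]:
    """Annotate a stream of variants; one SREAnnotation per (variant, gene) hit.

    Variants whose window matches no appropriate catalog are emitted with an
    empty category set (downstream selection drops them). A mismatch between
    the VCF REF allele and the FASTA base raises a warning and keeps the
    FASTA base, since motif scanning is defined on the reference sequence.
    """
    strand_of = {m.gene_id: m.strand for m in models}
    for v in variants:
        window = extract_window(genome, v.contig, v.pos)
        if window[5] != v.ref.upper():
            warnings.warn(
                f"variant {v.key}: VCF REF {v.ref} differs from reference base "
                f"{window[5]}; scanning the FASTA window",
                stacklevel=2,
            )
            if qc is not None:
                qc.n_ref_mismatch += 1
        windows = [window]
        if scan_alt:
            windows.append(window[:5] + v.alt.upper() + window[6:])
        hits = classify_region(v, models)
        if qc is not None:
            qc.n_variants += 1
            if len(hits) > 1:
                qc.n_multi_gene += 1
        emitted_sre = False
        for region, gene_id in hits:
            if region == "exonic":
                applicable = ["ESE", "ESS"]
            elif region == "intronic":
                applicable = ["ISE"]
            else:
                applicable = []
            cats = set()
            for cat in applicable:
                if cat not in motif_sets:
                    continue
                ms = motif_sets[cat]
                sets = [ms]
                if stranded and gene_id is not None and strand_of.get(gene_id) == "-":
                    sets.append(ms.reverse_complement())
                if any(scan_sre(w, s) for w in windows for s in sets):
                    cats.add(cat)
            if qc is not None:
                if region == "exonic":
                    qc.n_exonic += 1
                elif region == "intronic":
                    qc.n_intronic += 1
                else:
                    qc.n_intergenic += 1
            if cats:
                emitted_sre = True
            yield SREAnnotation(v.key, v.rsid, region, gene_id, frozenset(cats), window)
        if qc is not None and emitted_sre:
            qc.n_sre += 1


def annotations_to_frame(annotations: Iterable[SREAnnotation]):
    """Tabulate annotations as a pandas DataFrame (one row per variant/gene hit)."""
    import pandas as pd

    rows = [
        {
            "key": a.key,
            "rsid": a.rsid or ".",
            "gene_id": a.gene_id or ".",
            "region": a.region,
            "categories": ",".join(sorted(a.categories)) or ".",
            "window": a.window,
        }
        for a in annotations
    ]
    return pd.DataFrame(
        rows, columns=["key", "rsid", "gene_id", "region", "categories", "window"]
    )
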