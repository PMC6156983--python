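"""Gene models: exon structure used to classify SNPs as exonic or intronic.

Internal coordinates are 1-based closed intervals (VCF convention). BED12 is
0-based half-open and GFF3 is 1-based closed; both readers convert at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["GeneModel", "read_bed12", "read_gff3", "read_gene_models"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based closed, sorted, non-overlapping

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) has start > end")
            if s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        )


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 file (blocks = exons)."""
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 columns, got {len(f)}")
            contig, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{ln}: blockCount does not match block lists")
            # 0-based half-open blocks -> 1-based closed exons
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            models.append(GeneModel(name, contig, strand, exons))
    return models


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Exon features are grouped by their ``gene_id`` attribute if present,
    otherwise by ``Parent``. GFF3 is already 1-based closed.
    """
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2].lower() != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].strip(";").split(";") if "=" in kv
            )
            gid = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID")
            if gid is None:
                raise ValueError(f"exon feature without gene_id/Parent in {path}")
            exons_by_gene.setdefault(gid, []).append((int(f[3]), int(f[4])))
            meta[gid] = (f[0], f[6])
    models = []
    for gid, exons in exons_by_gene.items():
        contig, strand = meta[gid]
        models.append(GeneModel(gid, contig, strand, tuple(sorted(exons))))
    return models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .bed -> BED12, .gff/.gff3 -> GFF3."""
    p = Path(path)
    if p.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3(p)
    return read_bed12(p)
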