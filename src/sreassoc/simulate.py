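"""Synthetic cohort generator.

Emulates the study design the pipeline targets: a WGS cohort of ~700
individuals with biallelic SNPs in splicing-regulatory-element (SRE) loci,
and a continuous imaging-derived endophenotype that is a linear function of
age, sex and a planted per-gene rare-variant burden plus Gaussian noise.

The generator writes every input the pipeline consumes — reference FASTA,
BED12 gene models, ESE/ESS/ISE hexamer catalogs, a VCF with genotypes, and a
phenotype/covariate TSV — plus a truth table of what was planted, so every
downstream stage can be validated without external data.

Design notes
------------
* One contig per gene region, named ``gene<k>``; exons are laid out as
  flank / exon / intron / ... / exon / flank on that contig.
* Genotypes are drawn i.i.d. binomial(2, MAF) per variant (Hardy–Weinberg,
  no linkage disequilibrium): the downstream gene-based test treats loci
  within a bin exchangeably, so LD is deliberately out of scope.
* Each variant site gets a hexamer of the region-appropriate category
  (ESE/ESS for exonic sites, ISE for intronic sites) planted so that the
  11-mer window around the site contains it; causal variants are always
  exonic with a planted ESE or ESS, mirroring the coding-SRE analysis mode.
* Sex is encoded 0 = female, 1 = male.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "plant_sre_site",
    "random_motif_sets",
]

_BASES = "ACGT"

#: Cohort-scale defaults follow the demographic summary of the emulated
#: study cohort (n=695; 391 male / 304 female; age 72.95 +/- 7.05 years).
_DEF_N = 695
_DEF_AGE_MEAN = 72.95
_DEF_AGE_SD = 7.05
_DEF_SEX_RATIO = 391 / 695


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    ``maf_range`` is the support of the uniform MAF spectrum; the default
    lower bound ``None`` means one minor-allele copy in the cohort,
    1/(2*n_samples).
    """

    n_samples: int = _DEF_N
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_len: int = 150
    intron_len: int = 300
    flank_len: int = 50
    n_variants_per_gene: int = 10
    exonic_fraction: float = 0.6
    maf_range: tuple[float | None, float] = (None, 0.05)
    causal_genes: tuple[str, ...] = ()
    n_causal_variants: int = 4
    effect_size: float = 0.0
    b_age: float = 0.02
    b_sex: float = 0.1
    age_mean: float = _DEF_AGE_MEAN
    age_sd: float = _DEF_AGE_SD
    sex_ratio: float = _DEF_SEX_RATIO
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    motifs_per_category: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_genes",
            "exons_per_gene",
            "exon_len",
            "intron_len",
            "flank_len",
            "n_variants_per_gene",
            "n_causal_variants",
            "motifs_per_category",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (got {getattr(self, name)})")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_range
        if lo is not None and not 0 < lo <= hi:
            raise ValueError("maf_range lower bound must satisfy 0 < lo <= hi")
        if not 0 < hi <= 0.5:
            raise ValueError("maf_range upper bound must lie in (0, 0.5]")
        # spacing guarantees a variant's 11-mer window never overlaps the
        # planted hexamer of a neighbouring variant
        n_ex = int(round(self.n_variants_per_gene * self.exonic_fraction))
        n_ex = min(max(n_ex, self.n_causal_variants if self.causal_genes else 0), self.n_variants_per_gene)
        n_in = self.n_variants_per_gene - n_ex
        per_exon = -(-n_ex // self.exons_per_gene)  # ceil
        if self.exon_len < 12 * per_exon + 12:
            raise ValueError(
                "exon_len too small to hold the requested exonic variants "
                f"({n_ex} across {self.exons_per_gene} exons of {self.exon_len} bp)"
            )
        n_introns = self.exons_per_gene - 1
        if n_in > 0 and (n_introns == 0 or self.intron_len < 12 * (-(-n_in // n_introns)) + 12):
            raise ValueError(
                "intron_len/exons_per_gene too small to hold the requested intronic variants"
            )
        if self.flank_len < 6:
            raise ValueError("flank_len must be >= 6 so edge windows stay in bounds")


@dataclass
class GeneTruth:
    """Planted configuration of one gene."""

    gene_id: str
    causal: bool
    beta: float
    variant_positions: list[int]  # 1-based on the gene's contig
    causal_positions: list[int]
    planted_categories: dict[int, str]  # pos -> ESE/ESS/ISE
    mafs: dict[int, float]


@dataclass
class SyntheticCohort:
    """Paths to the generated inputs plus the planted truth table."""

    fasta_path: Path
    gene_model_path: Path
    motif_paths: dict[str, Path]  # category -> file
    vcf_path: Path
    phenotype_path: Path
    truth: dict[str, GeneTruth]
    sample_ids: list[str]
    config: SimConfig


def plant_sre_site(sequence: str, pos: int, motif: str) -> str:
    """Overwrite ``sequence`` so the 11-mer window around ``pos`` contains ``motif``.

    ``pos`` is 1-based. The motif is written starting 3 bp left of the site,
    so it spans [pos-3, pos+2] — entirely inside the [pos-5, pos+5] window.

    Raises ``ValueError`` if the motif is not a hexamer or the 11-mer window
    does not fit inside the sequence.
    """
    if len(motif) != 6:
        raise ValueError(f"motif must be a hexamer, got {motif!r}")
    if pos - 5 < 1 or pos + 5 > len(sequence):
        raise ValueError(
            f"11-mer window around position {pos} out of bounds for sequence of length {len(sequence)}"
        )
    start = pos - 3  # 1-based start of the motif
    return sequence[: start - 1] + motif + sequence[start - 1 + 6 :]


def random_motif_sets(
    rng: random.Random, per_category: int = 30
) -> dict[str, list[str]]:
    """Draw disjoint hexamer catalogs for ESE, ESS and ISE.

    Disjointness avoids ambiguous category assignment when the tests reason
    about which catalog a planted motif came from; poly-A/C/G/T hexamers are
    excluded so a motif is never created by accident in homopolymer runs.
    """
    banned = {b * 6 for b in _BASES}
    pool: list[str] = []
    seen = set(banned)
    while len(pool) < 3 * per_category:
        hexamer = "".join(rng.choice(_BASES) for _ in range(6))
        if hexamer not in seen:
            seen.add(hexamer)
            pool.append(hexamer)
    return {
        "ESE": pool[:per_category],
        "ESS": pool[per_category : 2 * per_category],
        "ISE": pool[2 * per_category :],
    }


def _gene_layout(cfg: SimConfig) -> tuple[int, list[tuple[int, int]]]:
    """Contig length and 1-based closed exon intervals shared by all genes."""
    exons = []
    cursor = cfg.flank_len + 1
    for i in range(cfg.exons_per_gene):
        exons.append((cursor, cursor + cfg.exon_len - 1))
        cursor += cfg.exon_len
        if i < cfg.exons_per_gene - 1:
            cursor += cfg.intron_len
    contig_len = cursor - 1 + cfg.flank_len
    return contig_len, exons


def _spread_positions(rng: random.Random, start: int, end: int, k: int) -> list[int]:
    """k positions in [start, end], pairwise >= 12 bp apart."""
    if k == 0:
        return []
    span = end - start
    slot = span // k
    positions = []
    for i in range(k):
        lo = start + i * slot + 6
        hi = min(start + (i + 1) * slot - 6, end - 6)
        positions.append(rng.randint(lo, max(lo, hi)))
    return positions


def _write_fasta(path: Path, contigs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_bed12(path: Path, genes: list[tuple[str, str, list[tuple[int, int]]]]) -> None:
    # BED12 is 0-based half-open; internal coordinates are 1-based closed
    with open(path, "w") as fh:
        for contig, gene_id, exons in genes:
            chrom_start = exons[0][0] - 1
            chrom_end = exons[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in exons)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in exons)
            fh.write(
                "\t".join(
                    [
                        contig,
                        str(chrom_start),
                        str(chrom_end),
                        gene_id,
                        "0",
                        "+",
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def _write_vcf(
    path: Path,
    contigs: dict[str, str],
    records: list[tuple[str, int, str, str, np.ndarray]],
    sample_ids: list[str],
) -> None:
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, seq in contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for contig, pos, ref, alt, dosages in records:
            rsid = f"sim_{contig}_{pos}"
            gts = "\t".join(gt_code[int(d)] for d in dosages)
            fh.write(f"{contig}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> SyntheticCohort:
    """Generate a complete synthetic cohort under ``out_dir``.

    The phenotype is ``y_i = b_age*age_i + b_sex*sex_i +
    sum_{causal j} beta*g_ij + eps_i`` with ``eps ~ N(0, noise_sd^2)``.
    Deterministic given ``config`` (including the seed): identical configs
    yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    nprng = np.random.default_rng(config.seed)

    motif_sets = random_motif_sets(rng, config.motifs_per_category)
    motif_paths = {}
    for cat, motifs in motif_sets.items():
        p = out_dir / f"motifs_{cat}.txt"
        with open(p, "w") as fh:
            fh.write(f"# synthetic {cat} hexamer catalog\n")
            fh.write("\n".join(motifs) + "\n")
        motif_paths[cat] = p

    contig_len, exons = _gene_layout(config)
    introns = [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]

    gene_ids = [f"gene{k}" for k in range(1, config.n_genes + 1)]
    unknown = set(config.causal_genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"causal_genes not in cohort: {sorted(unknown)}")

    n_ex = int(round(config.n_variants_per_gene * config.exonic_fraction))
    if config.causal_genes:
        n_ex = max(n_ex, config.n_causal_variants)
    n_ex = min(n_ex, config.n_variants_per_gene)
    n_in = config.n_variants_per_gene - n_ex

    maf_lo = config.maf_range[0]
    if maf_lo is None:
        maf_lo = 1.0 / (2 * config.n_samples)
    maf_hi = config.maf_range[1]

    contigs: dict[str, str] = {}
    bed_genes = []
    vcf_records: list[tuple[str, int, str, str, np.ndarray]] = []
    truth: dict[str, GeneTruth] = {}
    burden = np.zeros(config.n_samples)

    for gid in gene_ids:
        seq = "".join(rng.choice(_BASES) for _ in range(contig_len))
        causal = gid in config.causal_genes

        ex_pos: list[int] = []
        per_exon = [n_ex // len(exons)] * len(exons)
        for i in range(n_ex % len(exons)):
            per_exon[i] += 1
        for (s, e), k in zip(exons, per_exon):
            ex_pos.extend(_spread_positions(rng, s, e, k))
        in_pos: list[int] = []
        if introns and n_in:
            per_intron = [n_in // len(introns)] * len(introns)
            for i in range(n_in % len(introns)):
                per_intron[i] += 1
            for (s, e), k in zip(introns, per_intron):
                in_pos.extend(_spread_positions(rng, s, e, k))

        planted: dict[int, str] = {}
        for pos in ex_pos:
            cat = rng.choice(["ESE", "ESS"])
            seq = plant_sre_site(seq, pos, rng.choice(motif_sets[cat]))
            planted[pos] = cat
        for pos in in_pos:
            seq = plant_sre_site(seq, pos, rng.choice(motif_sets["ISE"]))
            planted[pos] = "ISE"
        contigs[gid] = seq
        bed_genes.append((gid, gid, exons))

        causal_positions = sorted(rng.sample(ex_pos, config.n_causal_variants)) if causal else []
        positions = sorted(ex_pos + in_pos)
        mafs: dict[int, float] = {}
        for pos in positions:
            maf = nprng.uniform(maf_lo, maf_hi)
            mafs[pos] = float(maf)
            dosages = nprng.binomial(2, maf, size=config.n_samples).astype(np.int8)
            if config.missing_rate > 0:
                miss = nprng.random(config.n_samples) < config.missing_rate
                dosages = np.where(miss, -1, dosages)
            ref = seq[pos - 1]
            alt = rng.choice([b for b in _BASES if b != ref])
            vcf_records.append((gid, pos, ref, alt, dosages))
            if pos in causal_positions:
                burden += config.effect_size * np.maximum(dosages, 0)

        truth[gid] = GeneTruth(
            gene_id=gid,
            causal=causal,
            beta=config.effect_size if causal else 0.0,
            variant_positions=positions,
            causal_positions=causal_positions,
            planted_categories=planted,
            mafs=mafs,
        )

    sample_ids = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    age = nprng.normal(config.age_mean, config.age_sd, size=config.n_samples)
    sex = (nprng.random(config.n_samples) < config.sex_ratio).astype(int)
    noise = nprng.normal(0.0, config.noise_sd, size=config.n_samples)
    phenotype = config.b_age * age + config.b_sex * sex + burden + noise

    fasta_path = out_dir / "genome.fa"
    _write_fasta(fasta_path, contigs)
    gene_model_path = out_dir / "genes.bed"
    _write_bed12(gene_model_path, bed_genes)
    vcf_path = out_dir / "cohort.vcf"
    _write_vcf(vcf_path, contigs, vcf_records, sample_ids)

    phenotype_path = out_dir / "phenotypes.tsv"
    with open(phenotype_path, "w") as fh:
        fh.write("sample_id\tphenotype\tage\tsex\n")
        for sid, y, a, s in zip(sample_ids, phenotype, age, sex):
            fh.write(f"{sid}\t{y:.6f}\t{a:.3f}\t{s}\n")

    return SyntheticCohort(
        fasta_path=fasta_path,
        gene_model_path=gene_model_path,
        motif_paths=motif_paths,
        vcf_path=vcf_path,
        phenotype_path=phenotype_path,
        truth=truth,
        sample_ids=sample_ids,
        config=config,
    )
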