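# Methods

## Model and procedure

The pipeline tests whether rare variants located in splicing regulatory
elements (SREs) of a gene are jointly associated with a continuous
phenotype, adjusting for age and sex. Its stages, each behind a library
surface in `src/sreassoc/`:

1. **SRE annotation** (`annotate`). A SNP's 11-mer reference window
   (position ± 5 bp) is scanned against hexamer catalogs. Category and
   region are tied: ESE/ESS can only fire for exonic SNPs, ISE only for
   intronic SNPs, and an intronic SNP belongs to the gene owning both exons
   bordering its intron. Scanning uses the forward reference strand and the
   reference allele; `scan_alt` and `stranded` flags enable
   alternate-allele and reverse-complement scanning for exploration, both
   off by default. A VCF REF allele that contradicts the FASTA base raises
   a warning and the FASTA base wins, since the windows are defined on the
   reference sequence; the event is counted in the QC summary.
2. **Binning** (`binning`). Variants whose SRE categories intersect the
   category mode (coding = ESE+ESS, intronic = ISE, combined = all) and
   whose cohort MAF lies in (0, 0.01) — strict at both ends — are grouped
   by gene. A bin is tested only if its total observed minor-allele count
   is at least five ("five variants across samples"); an alternative
   reading, at least five distinct loci, is available via
   `min_size_unit="loci"` but is not the default, because the study's
   tables show genes whose allele totals exceed their locus counts.
   Missing genotypes are mean-imputed at 2·MAF in the dosage matrix but
   count as non-carriers in the allele total. Major/minor coding is folded
   so dosages always count minor alleles.
3. **Association** (`skato`, `chi2mix`). SKAT-O for a continuous trait;
   details below.
4. **Post hoc** (`posthoc`). Benjamini–Hochberg FDR ("fdr" = "BH" in R's
   p.adjust) applied within one category mode over exactly the genes that
   survived binning in that mode; significant means FDR < 0.05, suggestive
   FDR < 0.1. Leave-one-out re-tests a bin with each locus column removed
   (m ≥ 2 required) and labels the removal *less significant* (p rose;
   the locus carried signal) or *more significant* (p fell).
5. **Orchestration** (`pipeline`, `cli`). One pass per requested mode,
   with per-mode results tables, contribution tables for every suggestive
   gene, Manhattan plot data (reference values at raw p = 0.05 and at the
   raw-p level separating FDR-significant genes from the rest), an exact
   variant-accounting QC summary, and a manifest with a config hash.

## SKAT-O: statistic and null distribution

Null model: ordinary least squares of the phenotype on [1, age, sex];
residuals r, residual dimension d = n − 3. Weighted genotypes
G_w = G·diag(w) with w_j the Beta(1, 25) density at MAF_j (the SKAT
default; configurable). Score vector S = G_w' r and

    Q_rho = (1 − rho) Σ_j S_j² + rho (Σ_j S_j)²

on the grid rho ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}.

Conditional on the genotypes, under Gaussian errors the direction
u = r/‖r‖ is uniform on the unit sphere of the d-dimensional residual
subspace. Therefore T_rho = Q_rho/‖r‖² = u' M_rho u with
M_rho = (P₀G_w) R_rho (P₀G_w)' is a ratio of quadratic forms whose null
distribution is known exactly — no plug-in of an estimated residual
variance, no large-sample step. `chi2mix.spherical_sf` evaluates

    P(Σ_k λ_k z_k² > c ‖z‖²) = P(Σ_k (λ_k − c) z_k² − c χ²_{d−m} > 0)

(λ_k the nonzero eigenvalues of R_rho^{1/2} A R_rho^{1/2}, A = G_w'P₀G_w)
by Imhof characteristic-function inversion, with a Lugannani–Rice
saddlepoint below p ≈ 1e−8 where inversion is absolute-error limited. As
d → ∞ this converges to the familiar mixture-of-chi-squares null, which
`chi2mix.chi2mix_sf` provides (Imhof with oscillation-aware Fourier
quadrature, Liu moment-matching fallback, saddlepoint deep tail); the
mixture form is the one checked against closed forms and Monte Carlo in
the acceptance suite.

**Min-p combination.** SKAT-O's statistic is the grid-minimum p-value. Its
tail probability is the probability of the union
∪_rho {T_rho ≥ c*_rho}, with each threshold c*_rho inverted from the
per-rho tail at the observed minimum p. The union is evaluated under the
exact null by reduced-dimension Monte Carlo: with A = U L U', draws
g ~ N(0, I_rank) give the score vector through U L^{1/2} g, ‖g‖² is the
score-space component of the residual direction, and an independent
χ²_{d−rank} completes the denominator. Draws are seeded in the
configuration (default 10⁶, staged with a pilot fifth), so all outputs are
byte-reproducible. Below a grid-minimum p of 1e−4, where direct Monte
Carlo has no resolution, the union probability is written as pmin times a
union-inflation factor measured at the 1e−3 level and carried down; the
factor is a slowly varying dependence summary and the result is clamped to
the exact [pmin, 8·pmin] envelope. Degenerate bins (one locus, or rank-1
A) make every per-rho test identical, and the combination returns pmin —
for m = 1 this is exactly the single-variant score test.

The widely used one-dimensional integration approximation for the min-p
combination was implemented first and rejected: on sparse rare-variant
kernels (a handful of carriers per locus) it overestimated the union
probability by up to ~1.8× pmin where the exact answer is ≈ pmin, making
the test conservative precisely in this package's target regime. The
acceptance suite's residual-permutation oracle and the null-calibration
study both verify the exact route.

Numerical conventions: eigenvalues below 1e−10 of the largest are treated
as zero; duplicated genotype columns are kept (a warning lists them);
p-values are clipped to (1e−300, 1]; the combined p always satisfies
pmin ≤ p ≤ min(1, 8·pmin). The per-rho p at rho = 1 equals an
independently coded weighted burden score test; both identities are
asserted in the tests.

## Synthetic cohorts

The generator (`simulate`) writes every pipeline input: FASTA (one contig
per gene, flank/exon/intron layout), BED12 gene models, three disjoint
hexamer catalogs, VCF v4.2 genotypes, and a phenotype/covariate TSV. It
emulates the study design the pipeline targets:

* cohort scale n = 695, sex ratio 391:304 male:female, age ~ N(72.95, 7.05²);
* phenotype y = 0.02·age + 0.1·sex + Σ_causal β·g + ε, ε ~ N(0, noise_sd²),
  with sex coded 0 = female, 1 = male. The covariate coefficients are
  arbitrary but nonzero so adjustment is genuinely exercised; the
  phenotype's scale is chosen for test power, not to mimic SUVR units;
* genotypes i.i.d. binomial(2, MAF) per variant (Hardy–Weinberg, no
  linkage disequilibrium — the gene-based test treats loci within a bin
  exchangeably, so LD is out of scope);
* MAF drawn uniform on [1/(2n), 0.05] by default; every variant site gets
  a region-appropriate hexamer planted so its 11-mer window contains it,
  and causal variants are always exonic with an ESE or ESS planted;
* variant sites are spaced ≥ 12 bp so planting one motif never disturbs a
  neighbour's window; a truth table records causal loci, planted
  categories and drawn MAFs.

What the generator does **not** emulate: LD and population structure,
sequencing/genotyping error, indels and multi-allelic sites, realistic
site-frequency spectra, motif clustering, or the neuroimaging measurement
process. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated model, not that the biological
findings of any particular cohort would replicate.

## Standing studies and their sizes

`studies.py` fixes the experiments used by the analysis drivers, the
acceptance tests and `scripts/acceptance.py`:

* **Null calibration**: cohorts of n = 400, 100 genes × 10 SRE variants,
  MAF uniform on [0.002, 0.0095] (safely inside the rarity filter),
  effect 0, combined mode; 20 cohorts (2,000 gene-tests) in the test
  suite, 10 in the acceptance script. Checks: rejection at α = 0.05
  inside the 99% binomial band, KS uniformity.
* **Power**: 50 replicates of n = 500, 10 genes, causal gene with four
  exonic SRE variants at β = 0.8 per minor allele, noise_sd = 1, coding
  mode. Pilot: causal gene top-ranked in 42/50 (0.84).
* **Leave-one-out attribution**: single-gene cohorts, three exonic loci,
  one causal, MAF on [0.004, 0.008] — narrower than the other studies so
  all three loci survive the empirical rarity filter, since this
  experiment is about attribution, not filtering. Pilot: 34/50 replicates
  usable, causal locus most-p-increasing in 20/34 (0.588). That modest
  fraction is a finding, not a defect: with 4–8 carriers per locus the
  removal of a single causal locus shifts the gene statistic by only
  ~1–2 SD, so per-locus attribution at these allele counts is inherently
  noisy — a caveat that applies equally to reading real per-rsID
  contribution tables.

## Known limitations

* Continuous phenotypes only; binary-trait SKAT-O (and its small-sample
  moment corrections) is out of scope.
* Exactness of the null rests on Gaussian errors; gross phenotype
  non-normality would call for rank-transforming upstream.
* Motif matching is forward-strand and reference-allele by default — the
  faithful reading of the emulated design; both alternatives exist as
  flags but are untested against any truth set.
* A SNP in overlapping genes contributes to each gene's bin under its
  per-gene region; the tables therefore do not dedupe across genes.
* BH-FDR families are per category mode; combined-mode results are not
  corrected across modes.
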