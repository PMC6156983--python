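"""Power and per-locus attribution on cohorts with planted causal genes.

Two replicated experiments: (1) does the causal gene (four exonic SRE
variants, beta = 0.8 per minor allele, n = 500) rank first among all tested
genes in coding mode; (2) in a three-locus gene with one causal locus, does
removing the causal locus raise the SKAT-O p-value more than removing
either null locus. Writes per-replicate tables under results/.
"""

from pathlib import Path

from sreassoc.studies import loo_study, power_study

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

power = power_study(n_replicates=25, seed=2026)
power.to_csv(OUT / "power_replicates.tsv", sep="\t", index=False)
print(
    f"power: causal gene top-ranked in {int(power['causal_top'].sum())}/{len(power)} "
    f"replicates (median causal p = {power['p_causal'].median():.2e})"
)

loo = loo_study(n_replicates=25, seed=2026)
loo.to_csv(OUT / "loo_replicates.tsv", sep="\t", index=False)
print(
    f"leave-one-out: causal locus most p-increasing in "
    f"{int(loo['causal_identified'].sum())}/{len(loo)} usable replicates"
)
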