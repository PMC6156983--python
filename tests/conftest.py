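import numpy as np
import pytest

from sreassoc import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small null cohort exercised by several modules."""
    cfg = SimConfig(n_samples=120, n_genes=4, seed=11)
    return simulate_cohort(cfg, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def causal_cohort(tmp_path_factory):
    """A cohort with one planted causal gene and a rare-variant-only spectrum."""
    cfg = SimConfig(
        n_samples=400,
        n_genes=8,
        maf_range=(0.002, 0.0095),
        causal_genes=("gene3",),
        effect_size=0.9,
        seed=5,
    )
    return simulate_cohort(cfg, tmp_path_factory.mktemp("causal"))


def toy_bin(n, m, seed, effect=0.0, maf_lo=0.1, maf_hi=0.4):
    """A toy genotype bin + fitted null model for association unit tests."""
    from sreassoc.binning import GeneBin
    from sreassoc.skato import fit_null_model

    r = np.random.default_rng(seed)
    mafs = r.uniform(maf_lo, maf_hi, m)
    G = r.binomial(2, mafs, size=(n, m)).astype(float)
    age = r.normal(70, 7, n)
    sex = r.binomial(1, 0.5, n)
    y = 0.02 * age + 0.1 * sex + effect * G[:, 0] + r.normal(0, 1, n)
    null = fit_null_model(y, np.column_stack([age, sex]))
    b = GeneBin(
        gene_id="toy",
        loci=[f"c:{100 + i}" for i in range(m)],
        rsids=[f"rs{i}" for i in range(m)],
        G=G,
        mafs=mafs,
        total_allele_count=int(G.sum()),
    )
    return b, null
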