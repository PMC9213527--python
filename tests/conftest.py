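import numpy as np
import pytest

from htnprs.genodata import GenotypeDataset, KinshipGraph
from htnprs.sumstats import SumStats, SumStatsRecord, VariantKey
from htnprs.synthdata import SimConfig, simulate_cohort


def make_variant(pos: int, ea: str = "A", oa: str = "G", chrom: str = "1") -> VariantKey:
    return VariantKey(chrom, pos, ea, oa)


def make_record(pos, beta=0.1, se=0.05, p=1e-4, eaf=0.3, ea="A", oa="G", chrom="1"):
    return SumStatsRecord(
        key=VariantKey(chrom, pos, ea, oa), beta=beta, se=se, pvalue=p, eaf=eaf, n=1000.0
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-sample, 300-variant cohort reused by read-only tests."""
    cfg = SimConfig(seed=1234, n_samples={"groupA": 200, "groupB": 200}, n_variants=300)
    g, kinship, truth, visits, covars = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "genotypes": g,
        "kinship": kinship,
        "truth": truth,
        "visits": visits,
        "covars": covars,
    }


def random_genotypes(rng: np.random.Generator, n_samples: int, n_variants: int, chroms=("1",)):
    """Small random genotype dataset with random map positions (for oracles)."""
    variants = []
    used = set()
    for _ in range(n_variants):
        while True:
            chrom = str(rng.choice(chroms))
            pos = int(rng.integers(1, 2_000_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        variants.append(VariantKey(chrom, pos, "A", "G"))
    variants.sort()
    freqs = rng.uniform(0.1, 0.9, n_variants)
    dos = rng.binomial(2, freqs, size=(n_samples, n_variants)).astype(float)
    ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeDataset(ids, variants, dos)
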