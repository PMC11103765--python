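import numpy as np
import pandas as pd
import pytest

from gtpanel.matrix import GenotypeMatrix
from gtpanel.snp_select import LocusDef

CODES = ["hom1", "het", "hom2", "missing"]


def make_matrix(columns: dict[str, list[str]], populations=None, sample_types=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from locus -> per-individual call lists."""
    n = len(next(iter(columns.values())))
    idx = pd.Index([f"ind{i + 1:03d}" for i in range(n)], name="individual")
    calls = pd.DataFrame(columns, index=idx)
    meta = pd.DataFrame(
        {
            "population": populations if populations is not None else ["pop1"] * n,
            "sample_type": sample_types if sample_types is not None else ["tissue"] * n,
        },
        index=idx,
    )
    return GenotypeMatrix(calls, meta)


def random_matrix(rng: np.random.Generator, n_ind=12, n_loci=20, miss_rate=0.15):
    """Random genotype matrix plus matching locus definitions."""
    calls = {}
    defs = []
    for j in range(n_loci):
        p = rng.uniform(0.05, 0.95)
        col = []
        for _ in range(n_ind):
            if rng.random() < miss_rate:
                col.append("missing")
            else:
                g = rng.binomial(2, p)
                col.append({2: "hom1", 1: "het", 0: "hom2"}[g])
        lid = f"L{j + 1:03d}"
        calls[lid] = col
        defs.append(
            LocusDef(
                locus_id=lid,
                scaffold=f"sc{rng.integers(1, 6)}",
                position=int(rng.integers(1, 100_000)),
                allele1="A",
                allele2="C",
            )
        )
    return make_matrix(calls), defs


@pytest.fixture
def toy_matrix():
    return make_matrix(
        {
            "L1": ["hom1", "het", "hom2", "het"],
            "L2": ["het", "het", "hom1", "hom2"],
            "L3": ["hom1", "hom1", "hom1", "hom1"],
            "L4": ["missing", "het", "hom1", "het"],
        }
    )
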